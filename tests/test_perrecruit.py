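"""Per-recruit model: closed-form and hand-enumerated oracles, reference
curve invariants and growth-scenario comparisons."""

import numpy as np
import pytest

from corvgrowth import (
    GrowthModel,
    PerRecruitConfig,
    compare_growth_scenarios,
    make_params,
    per_recruit_curves,
    ssbr,
    survivorship_schedule,
    weight_at_age,
    ypr,
)
from corvgrowth.errors import InputError

from conftest import BOLSTERED_PARAMS, RAW_PARAMS

VB = GrowthModel.VON_BERTALANFFY
SR = GrowthModel.SCHNUTE_RICHARDS

# a growth curve that yields W = 1 for every age, to isolate the dynamics
FLAT_GROWTH = (VB, make_params("von_bertalanffy", L_inf=1.0, K=50.0, t0=-10.0))


def flat_cfg(**kw):
    base = dict(M=0.0, lw_a=1.0, lw_b=1.0, growth=FLAT_GROWTH, E_OA=0.0,
                female_fraction=1.0)
    base.update(kw)
    return PerRecruitConfig(**base)


def vb_cfg(**kw):
    base = dict(M=0.47, lw_a=9.5e-9, lw_b=3.0,
                growth=(VB, RAW_PARAMS[VB]), E_OA=0.825)
    base.update(kw)
    return PerRecruitConfig(**base)


class TestWeightAtAge:
    def test_identity_coefficients_return_length(self):
        cfg = vb_cfg(lw_a=1.0, lw_b=1.0)
        from corvgrowth.models import predict_length

        assert weight_at_age(cfg, 5.0) == pytest.approx(
            predict_length(VB, RAW_PARAMS[VB], 5.0)
        )

    def test_cubic_scaling(self):
        c1 = vb_cfg(lw_a=1.0, lw_b=3.0,
                    growth=(VB, make_params("von_bertalanffy", L_inf=100.0, K=50.0, t0=-10.0)))
        c2 = vb_cfg(lw_a=1.0, lw_b=3.0,
                    growth=(VB, make_params("von_bertalanffy", L_inf=200.0, K=50.0, t0=-10.0)))
        assert weight_at_age(c2, 5.0) == pytest.approx(8 * weight_at_age(c1, 5.0))

    def test_weights_monotone_over_modelled_ages(self):
        cfg = vb_cfg()
        w = [float(weight_at_age(cfg, a)) for a in range(1, 9)]
        assert all(w2 >= w1 for w1, w2 in zip(w, w[1:]))


class TestSurvivorship:
    def test_no_mortality_keeps_cohort_intact(self):
        n = survivorship_schedule(flat_cfg())
        assert n == pytest.approx(np.ones(8))

    def test_complete_old_adult_removal(self):
        n = survivorship_schedule(flat_cfg(E_OA=1.0))
        assert n[:5] == pytest.approx(np.ones(5))  # ages 1-5 still alive/reached
        assert n[5:] == pytest.approx(np.zeros(3))  # nobody survives past a_OA

    def test_pure_natural_mortality_closed_form(self):
        cfg = flat_cfg(M=0.2)
        ages = np.arange(1, 9)
        assert survivorship_schedule(cfg) == pytest.approx(np.exp(-0.2 * (ages - 1)))

    def test_conservation(self):
        n = survivorship_schedule(vb_cfg())
        assert np.all(n[1:] <= n[:-1] + 1e-12)
        assert np.all((0 <= n) & (n <= 1))


class TestYPROracle:
    def test_no_harvest_no_yield(self):
        assert ypr(vb_cfg(), E_OA=0.0) == 0.0

    def test_two_age_toy_enumeration(self):
        """a_OA = 1, A_max = 2, M = 0, W = 1: YPR(E) = E + (1-E)E, max at E=1."""
        cfg = flat_cfg(a_R=1, a_OA=1, A_max=2)
        for e in (0.0, 0.3, 0.7, 1.0):
            assert ypr(cfg, e) == pytest.approx(e + (1 - e) * e)
        curves = per_recruit_curves(cfg, step=0.01)
        assert curves.E_at_ypr_max == pytest.approx(1.0)

    def test_three_age_hand_enumeration_with_mortality(self):
        """A_max = 3, unit weights, M = 0.5, harvest from a_OA = 2:
        hand recursion N = (1, e^-M, (1-E) e^-2M)."""
        m = 0.5
        cfg = flat_cfg(M=m, a_R=1, a_OA=2, A_max=3)
        e = 0.4
        n1, n2, n3 = 1.0, np.exp(-m), (1 - e) * np.exp(-2 * m)
        assert ypr(cfg, e) == pytest.approx(e * n2 + e * n3)
        # post-harvest spawners from a_R = 1
        assert ssbr(cfg, e) == pytest.approx(n1 + (1 - e) * n2 + (1 - e) * n3)

    def test_harvest_ordering_flag_changes_yield(self):
        cfg_pre = flat_cfg(M=0.5, a_R=1, a_OA=1, A_max=2)
        cfg_post = flat_cfg(M=0.5, a_R=1, a_OA=1, A_max=2, harvest_before_M=False)
        assert ypr(cfg_post, 0.5) < ypr(cfg_pre, 0.5)


class TestSSBR:
    def test_unfished_closed_form(self):
        cfg = vb_cfg(E_OA=0.0)
        ages = np.arange(1, 9)
        w = np.array([float(weight_at_age(cfg, a)) for a in ages])
        adult = ages >= cfg.a_R
        expected = 0.5 * np.sum(np.exp(-cfg.M * (ages[adult] - 1)) * w[adult])
        assert ssbr(cfg, 0.0) == pytest.approx(expected)

    def test_adult_age_count_with_unit_weights(self):
        cfg = flat_cfg(a_R=2, A_max=8)
        assert ssbr(cfg, 0.0) == pytest.approx(7.0)

    def test_strictly_decreasing_in_exploitation(self):
        cfg = vb_cfg()
        vals = [ssbr(cfg, e) for e in np.linspace(0, 1, 21)]
        assert all(b < a for a, b in zip(vals, vals[1:]))


class TestCurves:
    def test_fnssbr_normalisation_and_monotonicity(self):
        for model, params in [(VB, RAW_PARAMS[VB]), (SR, RAW_PARAMS[SR])]:
            cfg = vb_cfg(growth=(model, params))
            curves = per_recruit_curves(cfg, step=0.02)
            assert curves.fnssbr[0] == pytest.approx(1.0)
            assert curves.fnssbr.max() == pytest.approx(1.0)
            assert np.all(np.diff(curves.fnssbr) <= 1e-12)
            assert np.all((0 <= curves.fnssbr) & (curves.fnssbr <= 1.0 + 1e-12))
            assert np.all(curves.ypr >= 0)

    def test_ypr_continuous_in_E(self):
        cfg = vb_cfg()
        curves = per_recruit_curves(cfg, step=0.005)
        # finite-difference bound: no jumps beyond a small multiple of step
        jumps = np.abs(np.diff(curves.ypr))
        assert jumps.max() < 0.05 * max(curves.ypr_max, 1e-12)

    def test_grid_without_zero_rejected(self):
        with pytest.raises(InputError):
            per_recruit_curves(vb_cfg(), E_grid=np.linspace(0.1, 1, 10))


class TestScenarioComparison:
    def five_scenarios(self):
        return {
            "reference_vb": PerRecruitConfig(
                M=0.47, lw_a=9.5e-9, lw_b=3.0, E_OA=0.825,
                growth=(VB, make_params("von_bertalanffy", L_inf=1006.0, K=0.23, t0=-0.5)),
            ),
            "vb_raw": vb_cfg(),
            "vb_bolstered": vb_cfg(growth=(VB, BOLSTERED_PARAMS[VB])),
            "sr_raw": vb_cfg(growth=(SR, RAW_PARAMS[SR])),
            "sr_bolstered": vb_cfg(growth=(SR, BOLSTERED_PARAMS[SR])),
        }

    def test_identical_growth_gives_identical_ratios(self):
        cfgs = {"a": vb_cfg(), "b": vb_cfg()}
        out = compare_growth_scenarios(cfgs, E_current=0.825, step=0.02)
        assert out.fnssbr.iloc[0] == pytest.approx(out.fnssbr.iloc[1])
        assert out.ypr_over_ypr_max.iloc[0] == pytest.approx(
            out.ypr_over_ypr_max.iloc[1]
        )

    def test_low_asymptote_scenario_predicts_healthiest_stock(self):
        """The flexible-model raw fit (smallest L_inf, lightest old fish)
        yields the largest depletion ratio FNSSBR of the five scenarios —
        the false-resiliency signature of a biased growth model."""
        out = compare_growth_scenarios(self.five_scenarios(), E_current=0.825,
                                       step=0.01).set_index("scenario")
        assert out.fnssbr.idxmax() == "sr_raw"
        assert out.fnssbr.max() > out.fnssbr.drop("sr_raw").max() + 0.02

    def test_smaller_old_age_weight_gives_larger_fnssbr(self):
        """Directional sensitivity: shrinking length (hence weight) at old
        ages raises the depletion ratio at the same exploitation rate."""
        small = vb_cfg(growth=(VB, make_params("von_bertalanffy", L_inf=700.0, K=0.28, t0=-0.17)))
        large = vb_cfg()
        out = compare_growth_scenarios(
            {"small": small, "large": large}, E_current=0.825, step=0.02
        ).set_index("scenario")
        assert out.loc["small", "fnssbr"] >= out.loc["large", "fnssbr"]

    def test_demographic_mismatch_rejected(self):
        cfgs = {"a": vb_cfg(), "b": vb_cfg(M=0.3)}
        with pytest.raises(InputError):
            compare_growth_scenarios(cfgs, E_current=0.825)
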