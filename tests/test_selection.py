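"""Information criteria, Akaike weights and model averaging.

The worked examples freeze the published comparison tables' deltas and the
asymptotic lengths of the bolstered fits as inputs and check the arithmetic
of the criteria against hand computation.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from corvgrowth import (
    GrowthModel,
    aic,
    aicc,
    akaike_weights,
    bic,
    build_selection_table,
    fit_model,
    model_average_linf,
    weighted_average_linf,
)
from corvgrowth.errors import DomainError, InputError
from corvgrowth.fitting import GrowthFit
from corvgrowth.models import criteria_k

from conftest import RAW_PARAMS


def synthetic_fit(model, log_lik, n, k=None):
    """A GrowthFit shell with hand-set likelihood, for table arithmetic."""
    model = GrowthModel.coerce(model)
    return GrowthFit(
        model=model,
        params=RAW_PARAMS[model],
        rss=1.0,
        n=n,
        log_lik=log_lik,
        k=k if k is not None else criteria_k(model),
        converged=True,
        n_restarts_used=1,
    )


class TestCriteria:
    def test_aic_direct_substitution(self):
        assert aic(0.0, 4) == 8.0
        assert aic(-10.0, 3) == 26.0

    def test_aicc_equals_aic_plus_correction(self):
        # k = 4, n = 749: correction = 2*4*5 / 744
        assert aicc(-100.0, 4, 749) == pytest.approx(aic(-100.0, 4) + 40.0 / 744.0)

    def test_aicc_converges_to_aic_at_large_n(self):
        assert abs(aicc(-50.0, 4, 10**9) - aic(-50.0, 4)) < 1e-6

    def test_aicc_undefined_for_tiny_n(self):
        with pytest.raises(DomainError):
            aicc(-5.0, 4, 5)

    def test_bic_penalty_with_natural_log(self):
        assert bic(0.0, 2, int(np.e) + 1) == pytest.approx(2 * np.log(int(np.e) + 1))
        assert bic(0.0, 1, 1) == 0.0

    def test_bic_penalises_extra_parameters(self):
        assert bic(-100.0, 6, 500) > bic(-100.0, 4, 500)


class TestAkaikeWeights:
    def test_symmetric_pair(self):
        assert akaike_weights([0.0, 0.0]) == pytest.approx([0.5, 0.5])

    def test_published_bolstered_deltas_round_to_printed_weights(self):
        # deltas 0 / 0.94 / 2.57 / 23.89 / 1213.01 -> 0.53 / 0.33 / 0.15 / 0 / 0
        w = akaike_weights([0.0, 0.94, 2.57, 23.89, 1213.01])
        assert np.round(w, 2).tolist() == [0.53, 0.33, 0.15, 0.0, 0.0]

    def test_published_raw_deltas_give_full_support_to_best(self):
        w = akaike_weights([0.0, 13.80, 29.87, 53.84, 388.96])
        assert round(w[0], 2) == 1.0

    def test_weights_sum_to_one(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            d = np.sort(rng.uniform(0, 50, size=6))
            d -= d[0]
            assert akaike_weights(d).sum() == pytest.approx(1.0, abs=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=500.0), min_size=1, max_size=8),
        st.floats(min_value=-1e4, max_value=1e4),
    )
    def test_normalisation_and_shift_invariance(self, raw, shift):
        """Weights always sum to one, order with the deltas, and are
        unchanged by adding a constant to every criterion value."""
        deltas = np.asarray(raw) - min(raw)
        w = akaike_weights(deltas)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)
        # smaller delta never gets smaller weight
        order = np.argsort(deltas, kind="stable")
        assert np.all(np.diff(w[order]) <= 1e-15)
        shifted = (deltas + shift) - (deltas + shift).min()
        assert akaike_weights(shifted) == pytest.approx(w, abs=1e-9)

    def test_negative_or_empty_deltas_rejected(self):
        with pytest.raises(InputError):
            akaike_weights([])
        with pytest.raises(InputError):
            akaike_weights([0.0, -1.0])


class TestSelectionTable:
    def test_hand_arithmetic_on_three_model_toy(self):
        """Table values match hand evaluation of the criteria formulas."""
        n = 100
        fits = [
            synthetic_fit("von_bertalanffy", -200.0, n),  # k=4
            synthetic_fit("gompertz", -201.0, n),  # k=4
            synthetic_fit("schnute", -205.0, n),  # k=3
        ]
        table = build_selection_table(fits)
        # hand: AICc_vb = 400+8+40/95; AICc_gom = 402+8+40/95; AICc_sch = 410+6+24/96
        aicc_vb = 408 + 40 / 95
        aicc_sch = 416 + 24 / 96
        row_vb = table[table.model == "von_bertalanffy"].iloc[0]
        row_sch = table[table.model == "schnute"].iloc[0]
        assert row_vb.aicc == pytest.approx(aicc_vb)
        assert row_vb.delta_aicc == 0.0
        assert row_sch.delta_aicc == pytest.approx(aicc_sch - aicc_vb)
        assert row_vb.bic == pytest.approx(400 + 4 * np.log(n))
        deltas = table.delta_aicc.to_numpy()
        assert table.weight.to_numpy() == pytest.approx(
            np.exp(-deltas / 2) / np.exp(-deltas / 2).sum()
        )

    def test_equal_likelihood_orders_by_parameter_count(self):
        fits = [synthetic_fit(m, -500.0, 200) for m in GrowthModel]
        table = build_selection_table(fits)
        assert table.k.is_monotonic_increasing
        assert table.model.iloc[0] == "schnute"

    def test_single_zero_delta_row_and_normalised_weights(self, fishery_table):
        fits = [fit_model(m, fishery_table, seed=0) for m in GrowthModel]
        table = build_selection_table(fits)
        assert (table.delta_aicc == 0.0).sum() == 1
        assert table.weight.sum() == pytest.approx(1.0, abs=1e-12)

    def test_mixed_sample_sizes_rejected(self):
        fits = [
            synthetic_fit("von_bertalanffy", -10.0, 100),
            synthetic_fit("gompertz", -10.0, 101),
        ]
        with pytest.raises(InputError):
            build_selection_table(fits)

    def test_deltas_invariant_to_additive_likelihood_constant(self):
        """Dropping an additive constant from every log-likelihood (e.g. the
        2*pi term) leaves deltas and weights unchanged."""
        n = 300
        lls = [-410.0, -412.5, -430.0]
        models = ["von_bertalanffy", "gompertz", "schnute"]
        t1 = build_selection_table(
            [synthetic_fit(m, ll, n) for m, ll in zip(models, lls)]
        )
        shift = n / 2 * np.log(2 * np.pi)
        t2 = build_selection_table(
            [synthetic_fit(m, ll + shift, n) for m, ll in zip(models, lls)]
        )
        assert t1.delta_aicc.to_numpy() == pytest.approx(t2.delta_aicc.to_numpy())
        assert t1.delta_bic.to_numpy() == pytest.approx(t2.delta_bic.to_numpy())
        assert t1.weight.to_numpy() == pytest.approx(t2.weight.to_numpy())


class TestModelAveraging:
    def test_printed_weights_times_published_linf(self):
        # 0.53*951.30 + 0.33*938.80 + 0.15*870.48 = 944.57, rounding to 945
        avg = weighted_average_linf([0.53, 0.33, 0.15], [951.30, 938.80, 870.48])
        assert avg == pytest.approx(944.565, abs=1e-9)
        assert round(avg) == 945

    def test_equal_weights_reduce_to_arithmetic_mean(self):
        assert weighted_average_linf([0.5, 0.5], [800.0, 900.0]) == 850.0

    def test_renormalisation_path(self):
        assert weighted_average_linf(
            [0.2, 0.2], [800.0, 900.0], renormalize=True
        ) == pytest.approx(850.0)

    def test_degenerate_single_model_average(self, fishery_table):
        fit = fit_model("von_bertalanffy", fishery_table, seed=0)
        table = build_selection_table([fit])
        assert model_average_linf(table, [fit]) == pytest.approx(fit.params.L_inf)

    def test_schnute_excluded_from_average(self, fishery_table):
        fits = [fit_model(m, fishery_table, seed=0) for m in GrowthModel]
        table = build_selection_table(fits)
        avg = model_average_linf(table, fits)
        linfs = [700.0, 1100.0]  # generous envelope of the non-Schnute asymptotes
        assert linfs[0] < avg < linfs[1]

    def test_all_weight_on_undefined_linf_is_domain_error(self):
        fit = synthetic_fit("schnute", -100.0, 50)
        table = build_selection_table([fit])
        with pytest.raises(DomainError):
            model_average_linf(table, [fit])
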