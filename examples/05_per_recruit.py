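"""Propagate growth-model choice into per-recruit assessment quantities.

Runs the per-recruit model under five growth scenarios sharing the same
demographics (M = 0.47/y, maturity at 2 y, old-adult stage from 5 y, cubic
weight-length) and prints the current depletion ratio FNSSBR and YPR over
its maximum at the current old-adult exploitation rate of 0.825/y.

The demographic values here are illustrative; supply your own via
PerRecruitConfig for a real assessment.
"""

from corvgrowth import (
    GrowthModel,
    PerRecruitConfig,
    compare_growth_scenarios,
    make_params,
    per_recruit_curves,
)

VB, SR = GrowthModel.VON_BERTALANFFY, GrowthModel.SCHNUTE_RICHARDS
demo = dict(M=0.47, lw_a=9.5e-9, lw_b=3.0, E_OA=0.825)

scenarios = {
    "reference_vb": (VB, make_params("von_bertalanffy", L_inf=1006.0, K=0.23, t0=-0.5)),
    "vb_raw": (VB, make_params("von_bertalanffy", L_inf=916.05, K=0.28, t0=-0.17)),
    "vb_bolstered": (VB, make_params("von_bertalanffy", L_inf=951.30, K=0.25, t0=-0.33)),
    "sr_raw": (SR, make_params("schnute_richards", L_inf=730.91, alpha=-0.003,
                               a=0.12, b=0.003, c=2.18)),
    "sr_bolstered": (SR, make_params("schnute_richards", L_inf=938.80, alpha=-0.0046,
                                     a=0.67, b=0.0019, c=0.72)),
}
cfgs = {name: PerRecruitConfig(growth=g, **demo) for name, g in scenarios.items()}

table = compare_growth_scenarios(cfgs, E_current=0.825)
print(table.to_string(index=False, float_format=lambda v: f"{v:0.3f}"))
print()

curves = per_recruit_curves(cfgs["vb_raw"], step=0.005)
print(f"vb_raw scenario: NSSBR = {curves.nssbr:.3f} kg/recruit, "
      f"SSBR(0.825) = {curves.ssbr[curves.E_grid == 0.825][0]:.3f} kg/recruit")
print()
print("FNSSBR is spawning biomass relative to the unfished level (1 = "
      "unfished).  The low-asymptote sr_raw scenario predicts the least "
      "depletion — choosing a growth model biased by missing large fish "
      "makes the stock look healthier than the other scenarios suggest.")
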