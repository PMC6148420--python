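"""Expose sampling bias in a fishery sample with the simple indicators.

Shows the bimodal age frequency, the empirical asymptotic-length check from
the largest fish, and the effect of bolstering every age class to 200
records on the fitted von Bertalanffy asymptote.
"""

from corvgrowth import (
    GrowthModel,
    bolster_dataset,
    fit_model,
    frequency_histogram,
    froese_binohlan_linf,
    make_params,
    per_age_stats,
)
from corvgrowth.simulate import SyntheticSpec, generate_dataset

truth = make_params("von_bertalanffy", L_inf=900.0, K=0.3, t0=-0.2)
spec = SyntheticSpec(truth=(GrowthModel.VON_BERTALANFFY, truth), seed=3)
data = generate_dataset(spec)

print("age frequency (unit bins):")
hist = frequency_histogram(data, "age")
for _, row in hist.iterrows():
    print(f"  age {int(row.bin_left)}: {'#' * (int(row['count']) // 5)} {int(row['count'])}")
print("Two modes: young fish from bycatch, and the directed fishery's mode "
      "near age 5.\n")

print(per_age_stats(data).to_string(index=False, float_format=lambda v: f"{v:0.1f}"))

fb = froese_binohlan_linf(data.length_max)
print(f"\nlargest fish: {data.length_max:.0f} mm -> empirical L_inf "
      f"prediction: {fb:.0f} mm")

raw_fit = fit_model("von_bertalanffy", data, seed=3)
bolstered = bolster_dataset(data, target_per_age=200, seed=3)
bol_fit = fit_model("von_bertalanffy", bolstered, seed=3)
print(f"VB L_inf fitted to raw sample:      {raw_fit.params.L_inf:.1f} mm")
print(f"VB L_inf fitted after bolstering:   {bol_fit.params.L_inf:.1f} mm "
      f"({bolstered.n} records, 200 per age)")
print("A fitted asymptote far below the empirical prediction, or one that "
      "moves when classes are equalised, flags distribution-driven estimates.")
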