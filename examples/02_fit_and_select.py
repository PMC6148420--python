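"""Fit all five growth models to a simulated fishery sample and rank them.

Generates a 749-record bimodal sample (bycatch mode at young ages, fishery
mode near age 5) from a known von Bertalanffy truth, fits every model by
Levenberg-Marquardt least squares, and prints the AICc/BIC comparison with
Akaike weights and the weight-averaged asymptotic length.
"""

from corvgrowth import (
    GrowthModel,
    build_selection_table,
    fit_model,
    make_params,
    model_average_linf,
)
from corvgrowth.simulate import SyntheticSpec, generate_dataset

truth = make_params("von_bertalanffy", L_inf=900.0, K=0.3, t0=-0.2)
spec = SyntheticSpec(truth=(GrowthModel.VON_BERTALANFFY, truth), seed=7)
data = generate_dataset(spec)
print(f"simulated {data.n} records, ages {data.age_min}-{data.age_max}, "
      f"lengths {data.length_min:.0f}-{data.length_max:.0f} mm\n")

fits = [fit_model(m, data, seed=7) for m in GrowthModel]
table = build_selection_table(fits)
print(table.to_string(index=False, float_format=lambda v: f"{v:0.2f}"))
print()
print(f"model-averaged L_inf: {model_average_linf(table, fits):.1f} mm "
      f"(truth: {truth.L_inf:.0f} mm)")
print("The best (lowest-AICc) row carries the bulk of the Akaike weight; "
      "weights sum to 1 and quantify relative evidence, not absolute fit.")
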