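"""Quantify how sampling design distorts growth-parameter estimates.

Runs two generate-and-refit Monte-Carlo experiments against the same von
Bertalanffy truth: ideal uniform sampling, and a truncated design with no
fish older than 6 years or longer than 750 mm (the signature of a heavily
size-selectively exploited stock).  Prints per-parameter bias and RMSE.
"""

import numpy as np

from corvgrowth import GrowthModel, make_params
from corvgrowth.simulate import SyntheticSpec, recovery_experiment

truth = make_params("von_bertalanffy", L_inf=900.0, K=0.3, t0=-0.2)

uniform = SyntheticSpec(
    truth=(GrowthModel.VON_BERTALANFFY, truth),
    n_total=1600, sampling="uniform", noise_sd=40.0,
)
truncated_weights = (0.3 * np.array([0.6, 0.4, 0, 0, 0, 0, 0, 0])
                     + 0.7 * np.array([0, 0.05, 0.15, 0.3, 0.3, 0.2, 0, 0]))
truncated = SyntheticSpec(
    truth=(GrowthModel.VON_BERTALANFFY, truth),
    n_total=749, sampling="custom", custom_weights=tuple(truncated_weights),
    noise_sd=40.0, length_cap=750.0,
)

for label, spec in [("ideal uniform sampling", uniform),
                    ("age/size-truncated sampling", truncated)]:
    out = recovery_experiment(spec, "von_bertalanffy", n_reps=40, seed=1,
                              restarts=1)
    print(f"{label} (n={spec.n_total}, 40 replicates):")
    print(out.to_string(index=False, float_format=lambda v: f"{v:0.3f}"))
    print()

print("Under truncation the asymptote L_inf is biased low and the growth "
      "coefficient K high: missing old, large fish make the stock look "
      "faster-growing and shorter-lived than it is.")
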