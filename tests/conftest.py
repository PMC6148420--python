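import numpy as np
import pytest

from corvgrowth import (
    AgeLengthTable,
    GrowthModel,
    SchnuteParams,
    make_params,
)
from corvgrowth.simulate import SyntheticSpec, generate_dataset

# Fitted parameter sets as published for the raw and bolstered comparisons;
# used as realistic fixed inputs for prediction/monotonicity/per-recruit
# checks (not as fitting targets).
RAW_PARAMS = {
    GrowthModel.VON_BERTALANFFY: make_params(
        "von_bertalanffy", L_inf=916.05, K=0.28, t0=-0.17
    ),
    GrowthModel.GOMPERTZ: make_params("gompertz", L_inf=820.64, K=0.51, t0=1.29),
    GrowthModel.LOGISTIC: make_params("logistic", L_inf=778.88, K=0.76, t_infl=1.92),
    GrowthModel.SCHNUTE: SchnuteParams(a=3.36, b=-0.33, T1=1, T2=8, L1=141, L2=1013),
    GrowthModel.SCHNUTE_RICHARDS: make_params(
        "schnute_richards", L_inf=730.91, alpha=-0.003, a=0.12, b=0.003, c=2.18
    ),
}

BOLSTERED_PARAMS = {
    GrowthModel.VON_BERTALANFFY: make_params(
        "von_bertalanffy", L_inf=951.30, K=0.25, t0=-0.33
    ),
    GrowthModel.GOMPERTZ: make_params("gompertz", L_inf=870.48, K=0.62, t0=1.34),
    GrowthModel.LOGISTIC: make_params("logistic", L_inf=834.34, K=0.62, t_infl=2.10),
    GrowthModel.SCHNUTE: SchnuteParams(a=6.06, b=-0.78, T1=1, T2=8, L1=141, L2=1013),
    GrowthModel.SCHNUTE_RICHARDS: make_params(
        "schnute_richards", L_inf=938.80, alpha=-0.0046, a=0.67, b=0.0019, c=0.72
    ),
}

VB_TRUTH = make_params("von_bertalanffy", L_inf=900.0, K=0.3, t0=-0.2)


@pytest.fixture(scope="session")
def vb_truth():
    return VB_TRUTH


@pytest.fixture(scope="session")
def noiseless_table() -> AgeLengthTable:
    """Zero-noise table from the VB truth: 5 records at each age 1-8."""
    spec = SyntheticSpec(
        truth=(GrowthModel.VON_BERTALANFFY, VB_TRUTH),
        n_total=40,
        sampling="uniform",
        noise_sd=0.0,
        seed=0,
    )
    return generate_dataset(spec)


@pytest.fixture(scope="session")
def fishery_table() -> AgeLengthTable:
    """A 749-record bimodal synthetic sample from the VB truth (sd 40 mm)."""
    spec = SyntheticSpec(
        truth=(GrowthModel.VON_BERTALANFFY, VB_TRUTH),
        n_total=749,
        sampling="bimodal",
        noise_sd=40.0,
        seed=7,
    )
    return generate_dataset(spec)


@pytest.fixture
def tiny_table() -> AgeLengthTable:
    ages = np.array([1, 1, 2, 3, 4, 5, 6, 7, 8])
    lengths = np.array([150.0, 160.0, 300.0, 430.0, 520.0, 610.0, 660.0, 700.0, 730.0])
    return AgeLengthTable(ages=ages, lengths=lengths)
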