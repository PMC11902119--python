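import numpy as np
import pandas as pd
import pytest

from cndclr import COMPONENTS, NUTRIENTS, GroupConfig, generate_group

# Group-mean clr coordinates published for the Sangiovese abscission-stage
# population (whole group, 12 components).  Frozen to the printed precision;
# any valid clr vector must sum to zero, and these do.
PUBLISHED_GROUP_CLR_MEANS = {
    "N": 2.620, "P": -0.015, "K": 1.253, "Ca": 3.459, "Mg": 1.465, "S": -0.068,
    "B": -2.979, "Cu": -2.058, "Fe": -1.455, "Mn": -2.606, "Zn": -3.227, "R": 3.611,
}

# A moderate-spread clr mean/SD for calibration groups: the Sangiovese
# abscission reference means (filler closing the vector) with a common
# nutrient spread of 0.2 on the clr scale.
CALIBRATION_CLR_MEAN = {
    "N": 2.56, "P": 0.08, "K": 1.03, "Ca": 3.55, "Mg": 1.48, "S": -0.09,
    "B": -3.04, "Cu": -2.26, "Fe": -1.02, "Mn": -2.64, "Zn": -2.97,
}
CALIBRATION_CLR_MEAN["R"] = -float(np.sum(list(CALIBRATION_CLR_MEAN.values())))


def calibration_config(n=100, seed_unused=None, sd=0.2, **overrides) -> GroupConfig:
    """A single synthetic group with known, moderate-spread parameters."""
    kwargs = dict(
        group_id="calib",
        n=n,
        clr_mean=dict(CALIBRATION_CLR_MEAN),
        clr_sd={c: (sd if c != "R" else 0.05) for c in COMPONENTS},
        yield_mean=40.0,
        yield_sd=3.0,
        imbalance_yield_slope=-0.3,
        region="calib-region",
        cultivar="calib-cv",
        years=(2021, 2022),
    )
    kwargs.update(overrides)
    return GroupConfig(**kwargs)


@pytest.fixture
def printed_clr_means() -> pd.Series:
    return pd.Series(PUBLISHED_GROUP_CLR_MEANS)


@pytest.fixture
def calib_samples() -> pd.DataFrame:
    """100 samples from the calibration group, fixed seed."""
    df, _ = generate_group(calibration_config(n=100), 42)
    return df


@pytest.fixture
def calib_truth():
    df, truth = generate_group(calibration_config(n=100), 42)
    return df, truth


def random_conc_frame(n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Random strictly positive native-unit concentrations."""
    data = {}
    for nut in NUTRIENTS:
        scale = 10.0 if nut in ("N", "P", "K", "Ca", "Mg", "S") else 100.0
        data[nut] = rng.uniform(0.1, scale, size=n)
    return pd.DataFrame(data)
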