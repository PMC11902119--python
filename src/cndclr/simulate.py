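"""Synthetic vineyard leaf-analysis datasets with known ground truth.

The survey this package targets is not publicly deposited, so every pipeline
stage is exercised against generated data whose generating parameters are
known exactly.  The generator works in clr space: each group draws clr
vectors around a configured mean with configured per-component spread
(optionally with exchangeable correlation), maps them through the inverse clr
onto closed compositions — which guarantees feasibility (strictly positive
parts, exact closure) by construction — and back-converts to native-unit
concentrations.  Yield is coupled to nutritional imbalance: the further a
sample sits from the group's clr mean (its generating r²), the lower its
yield, via a configurable non-positive slope.  A configurable fraction of
samples is planted as multivariate outliers, shifted several SDs in two
random nutrient components.

``default_study_config`` reproduces the structure of a seven-group grapevine
survey spanning Emilia-Romagna (Italy), São Paulo and Rio Grande do Sul
(Brazil): group names, sizes, published clr mean/SD standards for the 11
nutrients (the filler closes each mean vector to zero sum) and the reported
yield ranges.  Because those published clr means, once closed, fix the full
composition, the implied native-unit concentrations reproduce the clr
geometry of the standards rather than typical leaf mass fractions; the
pipeline is unit-agnostic, so this is immaterial to every computation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .composition import (
    COMPONENTS,
    MACRONUTRIENTS,
    NUTRIENTS,
    inverse_clr,
    write_leaf_csv,
)

#: Published clr standards (reference-population Mean and SD per nutrient) and
#: reported yield ranges (t/ha) for the seven survey groups.
STUDY_STANDARDS: dict[str, dict] = {
    "Bologna-Abs": {
        "region": "Bologna", "cultivar": "Sangiovese-Abs", "years": (2020, 2021, 2022),
        "n": 53, "yield_range": (21.1, 53.2),
        "clr_mean": [2.56, 0.08, 1.03, 3.55, 1.48, -0.09, -3.04, -2.26, -1.02, -2.64, -2.97],
        "clr_sd": [0.24, 0.16, 0.32, 0.12, 0.23, 0.10, 0.34, 0.27, 0.49, 0.15, 0.21],
    },
    "Bologna-Est": {
        "region": "Bologna", "cultivar": "Sangiovese-Est", "years": (2020, 2021, 2022),
        "n": 93, "yield_range": (30.4, 53.2),
        "clr_mean": [3.28, 0.61, 1.66, 3.12, 1.37, 0.48, -2.77, -2.22, -2.67, -2.98, -3.27],
        "clr_sd": [0.12, 0.08, 0.24, 0.09, 0.14, 0.11, 0.19, 0.78, 0.10, 0.17, 0.19],
    },
    "Pilar-do-Sul": {
        "region": "Pilar do Sul", "cultivar": "APPC7-Estela", "years": (2022, 2023),
        "n": 95, "yield_range": (13.0, 33.0),
        "clr_mean": [3.02, 0.80, 1.87, 2.14, 0.42, 0.42, -4.09, -2.99, -2.53, -2.00, -3.51],
        "clr_sd": [0.14, 0.32, 0.20, 0.21, 0.29, 0.31, 0.43, 0.92, 0.16, 0.56, 0.55],
    },
    "Farroupilha-MB": {
        "region": "Farroupilha", "cultivar": "Moscato Branco", "years": (2020, 2021),
        "n": 96, "yield_range": (26.0, 81.6),
        "clr_mean": [2.50, 0.48, 1.65, 1.60, 0.10, 0.80, -3.83, -4.64, -3.09, -1.27, -2.69],
        "clr_sd": [0.27, 0.40, 0.28, 0.37, 0.28, 0.59, 0.72, 1.15, 0.27, 0.37, 0.60],
    },
    "Farroupilha-B": {
        "region": "Farroupilha", "cultivar": "Bordo", "years": (2020, 2021),
        "n": 99, "yield_range": (22.9, 53.5),
        "clr_mean": [2.65, 0.94, 1.79, 1.68, 0.14, 0.66, -3.42, -5.06, -2.41, -2.38, -3.18],
        "clr_sd": [0.15, 0.43, 0.17, 0.47, 0.43, 0.52, 0.70, 0.30, 0.39, 0.37, 0.65],
    },
    "Dom-Pedrito": {
        "region": "Dom Pedrito", "cultivar": "mixed", "years": tuple(range(2006, 2017)),
        "n": 21, "yield_range": (37.9, 45.9),
        "clr_mean": [2.40, 1.08, 2.92, 2.42, 1.70, 0.35, -3.47, -4.49, -3.06, -1.04, -2.52],
        "clr_sd": [0.41, 0.54, 0.45, 0.24, 0.53, 0.36, 0.34, 0.57, 0.57, 0.66, 0.39],
    },
    "Macambara": {
        "region": "Macambara", "cultivar": "mixed", "years": tuple(range(2010, 2017)),
        "n": 36, "yield_range": (5.7, 16.7),
        "clr_mean": [2.01, 1.38, 2.81, 2.43, 1.84, 0.19, -3.63, -4.56, -3.24, -0.13, -2.66],
        "clr_sd": [0.37, 0.53, 0.51, 0.24, 0.30, 0.36, 0.17, 0.42, 0.37, 0.59, 0.39],
    },
}

#: clr spread assumed for the filler (the standards tables publish none; the
#: filler is >90% of dry mass and varies little on the log scale).
FILLER_CLR_SD: float = 0.08


@dataclass
class GroupConfig:
    """Generating parameters for one group.

    ``clr_mean``/``clr_sd`` map all 12 components; the mean vector must sum
    to ≈0.  ``yield_mean`` is the expected yield of a perfectly balanced
    sample; the realized group mean is ≈ yield_mean + 12·slope because the
    generating r² of a typical sample is the component count.
    """

    group_id: str
    n: int
    clr_mean: dict[str, float]
    clr_sd: dict[str, float]
    yield_mean: float
    yield_sd: float
    imbalance_yield_slope: float = -0.3  # t/ha per unit r2, must be <= 0
    outlier_fraction: float = 0.0
    outlier_shift: float = 6.0  # in SD units, applied to 2 random nutrients
    exchangeable_rho: float = 0.0
    region: str = ""
    cultivar: str = ""
    years: tuple[int, ...] = (2021,)

    def __post_init__(self) -> None:
        if self.n < 5:
            raise ValueError("group size must be at least 5")
        if not 0 <= self.outlier_fraction <= 0.2:
            raise ValueError("outlier_fraction must be in [0, 0.2]")
        if self.imbalance_yield_slope > 0:
            raise ValueError("imbalance_yield_slope must be <= 0")
        mu = np.array([self.clr_mean[c] for c in COMPONENTS])
        if abs(mu.sum()) > 1e-6:
            raise ValueError(f"clr_mean must sum to 0, sums to {mu.sum():.3g}")
        if any(self.clr_sd[c] <= 0 for c in COMPONENTS):
            raise ValueError("all clr_sd entries must be positive")
        if not -1.0 / (len(COMPONENTS) - 1) < self.exchangeable_rho < 1:
            raise ValueError("exchangeable_rho out of the positive-definite range")


@dataclass
class GeneratorConfig:
    """A full synthetic study: a list of group configurations plus the seed."""

    groups: list[GroupConfig] = field(default_factory=list)
    seed: int = 0


def equilibrium_concentrations(clr_mean: dict[str, float]) -> pd.Series:
    """Native-unit concentrations of the composition at the group's clr mean.

    This is the ground-truth equilibrium: a sample sitting exactly at the clr
    mean has all CND indices zero, so these are the concentrations a
    critical-level fit should recover at index zero.
    """
    row = pd.DataFrame([clr_mean])[list(COMPONENTS)]
    comp = inverse_clr(row)
    conc = comp[list(NUTRIENTS)].iloc[0].copy()
    conc[list(MACRONUTRIENTS)] /= 1000.0
    return conc


def generate_group(
    cfg: GroupConfig, rng: np.random.Generator | int
) -> tuple[pd.DataFrame, dict]:
    """Draw one group of leaf samples; deterministic under a fixed seed.

    Returns the sample frame (standard columns, native units) and a ground
    truth dict: generating clr mean/SD, equilibrium concentrations, planted
    outlier ids and the yield-coupling parameters.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    mu = np.array([cfg.clr_mean[c] for c in COMPONENTS])
    sd = np.array([cfg.clr_sd[c] for c in COMPONENTS])
    d = len(COMPONENTS)
    if cfg.exchangeable_rho:
        corr = np.full((d, d), cfg.exchangeable_rho)
        np.fill_diagonal(corr, 1.0)
        cov = np.outer(sd, sd) * corr
        draws = rng.multivariate_normal(mu, cov, size=cfg.n, method="cholesky")
    else:
        draws = mu + rng.standard_normal((cfg.n, d)) * sd

    n_out = int(round(cfg.outlier_fraction * cfg.n))
    out_rows = np.sort(rng.choice(cfg.n, size=n_out, replace=False)) if n_out else np.array([], int)
    for i in out_rows:
        # shift in nutrient coordinates only: a filler-only shift would be
        # invisible to the distance screen, which drops the filler
        comps = rng.choice(len(NUTRIENTS), size=2, replace=False)
        draws[i, comps] += cfg.outlier_shift * sd[comps]

    z = (draws - mu) / sd
    r2 = (z**2).sum(axis=1)
    noise = rng.standard_normal(cfg.n) * cfg.yield_sd
    yields = np.maximum(0.0, cfg.yield_mean + cfg.imbalance_yield_slope * r2 + noise)

    clr = pd.DataFrame(draws, columns=list(COMPONENTS))
    # inverse_clr requires zero-sum rows; centring changes nothing else
    clr = clr.sub(clr.mean(axis=1), axis=0)
    comp = inverse_clr(clr)
    conc = comp[list(NUTRIENTS)].copy()
    conc[list(MACRONUTRIENTS)] /= 1000.0

    ids = [f"{cfg.group_id}-{i + 1:03d}" for i in range(cfg.n)]
    df = pd.DataFrame(
        {
            "sample_id": ids,
            "region": cfg.region or cfg.group_id,
            "cultivar": cfg.cultivar or cfg.group_id,
            "year": rng.choice(cfg.years, size=cfg.n),
            "yield_t_ha": yields,
        }
    )
    for nut in NUTRIENTS:
        df[nut] = conc[nut].to_numpy()
    truth = {
        "group_id": cfg.group_id,
        "n": cfg.n,
        "clr_mean": dict(cfg.clr_mean),
        "clr_sd": dict(cfg.clr_sd),
        "equilibrium_conc": {k: float(v) for k, v in equilibrium_concentrations(cfg.clr_mean).items()},
        "outlier_ids": [ids[i] for i in out_rows],
        "yield_mean": cfg.yield_mean,
        "yield_sd": cfg.yield_sd,
        "imbalance_yield_slope": cfg.imbalance_yield_slope,
    }
    return df, truth


def generate_dataset(config: GeneratorConfig) -> tuple[pd.DataFrame, dict]:
    """Generate every group of a study config with independent child streams."""
    children = np.random.SeedSequence(config.seed).spawn(len(config.groups))
    frames, truth = [], {"seed": config.seed, "groups": {}}
    for cfg, child in zip(config.groups, children):
        df, t = generate_group(cfg, np.random.default_rng(child))
        frames.append(df)
        truth["groups"][cfg.group_id] = t
    return pd.concat(frames, ignore_index=True), truth


def _closed_mean(values: list[float]) -> dict[str, float]:
    mean = dict(zip(NUTRIENTS, values))
    mean["R"] = -float(np.sum(values))
    return mean


def default_study_config(
    seed: int = 0,
    outlier_fraction: float = 0.02,
    imbalance_yield_slope: float = -0.3,
) -> GeneratorConfig:
    """The seven-group survey configuration with published standards.

    Group names and sizes (53, 93, 95, 96, 99, 21, 36), clr means/SDs per
    nutrient and yield ranges follow the published survey tables; the filler
    clr mean closes each vector to zero sum.
    """
    groups = []
    for gid, spec in STUDY_STANDARDS.items():
        lo, hi = spec["yield_range"]
        mid = 0.5 * (lo + hi)
        sd_map = dict(zip(NUTRIENTS, spec["clr_sd"]))
        sd_map["R"] = FILLER_CLR_SD
        groups.append(
            GroupConfig(
                group_id=gid,
                n=spec["n"],
                clr_mean=_closed_mean(spec["clr_mean"]),
                clr_sd=sd_map,
                # balanced-sample baseline chosen so the realized group mean
                # sits at the midpoint of the reported yield range
                yield_mean=mid - 12.0 * imbalance_yield_slope,
                yield_sd=(hi - lo) / 6.0,
                imbalance_yield_slope=imbalance_yield_slope,
                outlier_fraction=outlier_fraction,
                outlier_shift=6.0,
                region=spec["region"],
                cultivar=spec["cultivar"],
                years=spec["years"],
            )
        )
    return GeneratorConfig(groups=groups, seed=seed)


def write_dataset(df: pd.DataFrame, truth: dict, csv_path, truth_path=None) -> None:
    """Write the standard CSV and, optionally, the ground-truth JSON."""
    write_leaf_csv(df, csv_path)
    if truth_path is not None:
        with open(truth_path, "w") as fh:
            json.dump(truth, fh, indent=2)
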