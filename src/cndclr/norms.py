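"""CND reference norms, nutrient indices and global imbalance.

The diagnosis standardizes a sample's clr coordinates against *norms* derived
from a high-yield reference subpopulation: per-component clr means V* and
standard deviations SD*.  The CND index of component X is

    I_X = (V_X − V*_X) / SD*_X,

and the global imbalance is r² = Σ_X I_X² over all 12 components (filler
included).  Because the reference is a sample of the ideal population, the
norms carry two-sided t confidence bounds V* ± t_{1−α/2, n−1}·SD*/√n, which
translate into an acceptable band around the equilibrium point of each index.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .composition import COMPONENTS, NUTRIENTS, samples_to_clr
from .exceptions import SchemaError, ZeroVarianceError

log = logging.getLogger(__name__)

BALANCED = "balanced"
DEFICIENT = "deficient"
EXCESS = "excess"


@dataclass
class CndNorms:
    """Reference-population statistics for one group.

    Attributes
    ----------
    clr_mean, clr_sd
        V* and SD* per component (12 entries, filler included).
    ucb, lcb
        Two-sided t confidence bounds on V*; symmetric about the mean.
    conc_sd
        Standard deviation of the raw concentrations (native units) in the
        same reference subpopulation; feeds the sufficiency ranges.
    """

    group_id: str
    n_ref: int
    clr_mean: pd.Series
    clr_sd: pd.Series
    ucb: pd.Series
    lcb: pd.Series
    conc_sd: pd.Series
    alpha: float = 0.05

    def index_band(self) -> tuple[pd.Series, pd.Series]:
        """The confidence bounds expressed on the index scale.

        Standardizing LCB/UCB by (·−V*)/SD* gives the symmetric band
        ∓ t_{1−α/2, n−1}/√n around the equilibrium point I_X = 0.
        """
        lo = (self.lcb - self.clr_mean) / self.clr_sd
        hi = (self.ucb - self.clr_mean) / self.clr_sd
        return lo, hi

    def to_dict(self) -> dict:
        return {
            "group_id": self.group_id,
            "n_ref": int(self.n_ref),
            "alpha": self.alpha,
            "clr_mean": {k: float(v) for k, v in self.clr_mean.items()},
            "clr_sd": {k: float(v) for k, v in self.clr_sd.items()},
            "ucb": {k: float(v) for k, v in self.ucb.items()},
            "lcb": {k: float(v) for k, v in self.lcb.items()},
            "conc_sd": {k: float(v) for k, v in self.conc_sd.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CndNorms":
        def ser(key, order):
            return pd.Series({k: d[key][k] for k in order})

        return cls(
            group_id=d["group_id"],
            n_ref=int(d["n_ref"]),
            alpha=float(d.get("alpha", 0.05)),
            clr_mean=ser("clr_mean", COMPONENTS),
            clr_sd=ser("clr_sd", COMPONENTS),
            ucb=ser("ucb", COMPONENTS),
            lcb=ser("lcb", COMPONENTS),
            conc_sd=ser("conc_sd", NUTRIENTS),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "CndNorms":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def select_reference(
    samples: pd.DataFrame,
    top_fraction: float | None = None,
    yield_threshold: float | None = None,
    ids: list | None = None,
) -> pd.DataFrame:
    """Pick the high-yield reference subpopulation.

    Exactly one rule must be given:

    ``top_fraction q``
        The ⌈q·n⌉ highest-yield samples; samples tied with the boundary yield
        are all included.
    ``yield_threshold y``
        All samples with yield ≥ y.
    ``ids``
        An explicit list of sample_id values.

    A reference smaller than 5 is allowed but logged as a warning; an empty
    reference is an error.
    """
    rules = [top_fraction is not None, yield_threshold is not None, ids is not None]
    if sum(rules) != 1:
        raise ValueError("give exactly one of top_fraction, yield_threshold, ids")
    if top_fraction is not None:
        if not 0 < top_fraction <= 1:
            raise ValueError("top_fraction must be in (0, 1]")
        n = len(samples)
        k = max(1, int(np.ceil(top_fraction * n)))
        boundary = samples["yield_t_ha"].sort_values(ascending=False).iloc[k - 1]
        ref = samples[samples["yield_t_ha"] >= boundary]
    elif yield_threshold is not None:
        ref = samples[samples["yield_t_ha"] >= yield_threshold]
    else:
        ref = samples[samples["sample_id"].isin(ids)]
    if ref.empty:
        raise ValueError("reference subpopulation is empty")
    if len(ref) < 5:
        log.warning("reference subpopulation has only %d samples", len(ref))
    return ref


def compute_norms(
    reference: pd.DataFrame, group_id: str = "", alpha: float = 0.05
) -> CndNorms:
    """Derive CND norms from a reference subpopulation.

    V* and SD* are the per-component mean and SD (ddof=1) of the reference
    clr coordinates; UCB/LCB = V* ± t_{1−α/2, n−1}·SD*/√n; ``conc_sd`` is the
    native-unit concentration SD of the same subpopulation.

    Raises
    ------
    ZeroVarianceError
        Naming the first component with no variance.
    ValueError
        If the reference has fewer than 5 samples.
    """
    n = len(reference)
    if n < 5:
        raise ValueError(f"reference subpopulation must have at least 5 samples, got {n}")
    clr = samples_to_clr(reference)
    mean = clr.mean()
    sd = clr.std(ddof=1)
    if (sd <= 0).any() or not np.isfinite(sd).all():
        comp = sd.index[(sd <= 0) | ~np.isfinite(sd)][0]
        raise ZeroVarianceError(f"zero variance in clr component {comp!r}")
    half = stats.t.ppf(1.0 - alpha / 2.0, n - 1) * sd / np.sqrt(n)
    conc_sd = reference[list(NUTRIENTS)].std(ddof=1)
    return CndNorms(
        group_id=group_id,
        n_ref=n,
        clr_mean=mean,
        clr_sd=sd,
        ucb=mean + half,
        lcb=mean - half,
        conc_sd=conc_sd,
        alpha=alpha,
    )


def cnd_indices(clr: pd.DataFrame, norms: CndNorms) -> pd.DataFrame:
    """CND indices and global imbalance for each sample.

    Returns a frame with one column per component (I_X) plus ``r2``, the sum
    of squared indices.

    Raises
    ------
    SchemaError
        If the clr frame lacks a component present in the norms.
    """
    missing = [c for c in COMPONENTS if c not in clr.columns]
    if missing:
        raise SchemaError(f"clr frame is missing components: {missing}")
    idx = (clr[list(COMPONENTS)] - norms.clr_mean) / norms.clr_sd
    out = idx.copy()
    out["r2"] = (idx**2).sum(axis=1)
    return out


def classify_balance(diagnosis: pd.DataFrame, norms: CndNorms) -> pd.DataFrame:
    """Classify each component as deficient / balanced / excess.

    A component is balanced iff its index lies within the standardized
    confidence band (closed interval: the band edges themselves count as
    balanced); below the band is deficient, above is excess.
    """
    lo, hi = norms.index_band()
    out = {}
    for c in COMPONENTS:
        v = diagnosis[c]
        out[c] = np.where(v < lo[c], DEFICIENT, np.where(v > hi[c], EXCESS, BALANCED))
    return pd.DataFrame(out, index=diagnosis.index)


def diagnose(samples: pd.DataFrame, norms: CndNorms) -> pd.DataFrame:
    """Full per-sample diagnosis: indices, r² and balance classes.

    Convenience wrapper producing one row per sample with the 12 index
    columns, ``r2``, and ``<X>_class`` columns.
    """
    clr = samples_to_clr(samples)
    diag = cnd_indices(clr, norms)
    classes = classify_balance(diag, norms)
    out = diag.copy()
    for c in COMPONENTS:
        out[f"{c}_class"] = classes[c]
    if "sample_id" in samples.columns:
        out.insert(0, "sample_id", samples["sample_id"].to_numpy())
    return out
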