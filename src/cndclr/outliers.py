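"""Mahalanobis screening of atypical samples on clr coordinates.

Before norms are derived, each dataset is cleaned of multivariate outliers:
samples whose squared Mahalanobis distance from the group centroid, computed
on the 11 nutrient clr coordinates, exceeds a chi-square quantile.  The filler
R is excluded from the distance because the zero-sum constraint makes the full
12-coordinate covariance singular.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .composition import FILLER, samples_to_clr
from .exceptions import GroupSizeError, SingularCovarianceError

_COND_LIMIT = 1e12


@dataclass
class OutlierReport:
    """Per-sample squared Mahalanobis distances and the exclusion decision.

    ``excluded_ids`` is exactly the set of samples with distance above
    ``cutoff`` (the chi-square quantile at 1 − alpha with ``df`` degrees of
    freedom).
    """

    distances: pd.Series
    cutoff: float
    alpha: float
    df: int
    excluded_ids: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "cutoff": self.cutoff,
            "alpha": self.alpha,
            "df": self.df,
            "distances": {str(k): float(v) for k, v in self.distances.items()},
            "excluded_ids": [str(i) for i in self.excluded_ids],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def mahalanobis_distances(clr: pd.DataFrame, drop_filler: bool = True) -> pd.Series:
    """Squared Mahalanobis distance of each row from the group's own centroid.

    The mean and covariance (unbiased, divisor n−1) are estimated from the
    group itself.  With the n−1 estimator the distances satisfy the trace
    identity Σᵢ MDᵢ = d·(n−1).

    Parameters
    ----------
    clr
        Frame of clr coordinates (rows = samples).  If ``drop_filler`` and an
        ``R`` column is present it is removed first.

    Raises
    ------
    GroupSizeError
        If n < d + 2 (covariance not reliably invertible).
    SingularCovarianceError
        If the covariance matrix is numerically singular.
    """
    X = clr.drop(columns=[FILLER], errors="ignore") if drop_filler else clr
    A = X.to_numpy(float)
    n, d = A.shape
    if n < d + 2:
        raise GroupSizeError(
            f"need at least {d + 2} samples to invert a {d}x{d} covariance; got {n}"
        )
    mu = A.mean(axis=0)
    cov = np.cov(A, rowvar=False, ddof=1)
    if np.linalg.cond(cov) > _COND_LIMIT:
        raise SingularCovarianceError(
            "singular clr covariance; drop redundant components, regularize, "
            "or use a larger group"
        )
    dev = A - mu
    md = np.einsum("ij,ij->i", dev @ np.linalg.inv(cov), dev)
    return pd.Series(np.maximum(md, 0.0), index=clr.index, name="mahalanobis_sq")


def filter_outliers(
    samples: pd.DataFrame, alpha: float = 0.05, clr: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, OutlierReport]:
    """Single-pass exclusion of samples above the chi-square cutoff.

    The cutoff is the upper-``alpha`` quantile of chi-square with df equal to
    the number of retained clr coordinates (11 for the full nutrient panel).
    Filtering is applied once: the distances are not recomputed after
    exclusion.

    Parameters
    ----------
    samples
        Native-unit sample frame; clr coordinates are computed from it unless
        a precomputed ``clr`` frame (same index) is supplied.
    alpha
        Significance level in (0, 0.5].

    Returns
    -------
    (retained samples, OutlierReport)

    Raises
    ------
    ValueError
        If alpha is out of range or every sample would be excluded.
    """
    if not 0 < alpha <= 0.5:
        raise ValueError(f"alpha must be in (0, 0.5], got {alpha}")
    if clr is None:
        clr = samples_to_clr(samples)
    md = mahalanobis_distances(clr)
    df = clr.drop(columns=[FILLER], errors="ignore").shape[1]
    cutoff = float(stats.chi2.ppf(1.0 - alpha, df))
    keep = md <= cutoff
    if not keep.any():
        raise ValueError("outlier filter would exclude every sample; degenerate group")
    ids = samples["sample_id"] if "sample_id" in samples.columns else samples.index.to_series()
    report = OutlierReport(
        distances=pd.Series(md.to_numpy(), index=ids),
        cutoff=cutoff,
        alpha=alpha,
        df=df,
        excluded_ids=list(ids[~keep.to_numpy()]),
    )
    return samples.loc[keep.to_numpy()], report
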