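"""Multivariate group-structure screens over clr variables.

Four screens answer whether populations (regions, cultivars, years) share a
nutritional profile:

* correlation-matrix PCA with the eigenvalue-greater-than-one retention rule
  and |loading| ≥ 0.70 contribution flags;
* canonical discriminant analysis (eigenstructure of W⁻¹B) with Wilks' lambda
  overall, stepwise per root, and per variable;
* per-variable two-group comparisons (pooled-variance t by default, Welch on
  request), with groups called similar at p > 0.05;
* Pearson correlations of yield against concentrations and clr variables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .composition import COMPONENTS, NUTRIENTS, samples_to_clr
from .exceptions import GroupSizeError, SingularCovarianceError, ZeroVarianceError

_COND_LIMIT = 1e12


# ---------------------------------------------------------------- PCA screen

@dataclass
class FactorModel:
    """Correlation-matrix PCA: loadings, eigenvalues and retention."""

    loadings: pd.DataFrame  # variables x factors; entries are corr(variable, factor)
    eigenvalues: np.ndarray  # nonincreasing
    explained: np.ndarray  # proportion of total variance per factor
    retained: int  # factors with eigenvalue > 1
    flagged: pd.DataFrame  # |loading| >= 0.70


def encode_design_matrix(
    samples: pd.DataFrame,
    categoricals: tuple[str, ...] = ("region", "cultivar", "year"),
    include_yield: bool = True,
    clr: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Assemble the PCA input: clr variables + integer-coded categoricals + yield.

    Categorical levels are coded by first appearance (0, 1, 2, …), which is
    statistically unorthodox but mirrors established survey practice of
    loading grouping factors into the factor model; the coding is logged in
    the column attrs.
    """
    if clr is None:
        clr = samples_to_clr(samples)
    out = pd.DataFrame(index=samples.index)
    codes = {}
    for col in categoricals:
        levels = list(dict.fromkeys(samples[col]))
        codes[col] = {lev: i for i, lev in enumerate(levels)}
        out[col] = samples[col].map(codes[col]).astype(float)
    for c in COMPONENTS:
        out[c] = clr[c].to_numpy()
    if include_yield:
        out["yield"] = samples["yield_t_ha"].to_numpy(float)
    out.attrs["categorical_codes"] = codes
    return out


def pca_screen(X: pd.DataFrame, loading_flag: float = 0.70) -> FactorModel:
    """Eigen-decomposition of the correlation matrix with >1 retention.

    Variables are standardized (correlation-matrix PCA); loadings are scaled
    eigenvectors (columns satisfy loadings·loadingsᵀ = correlation matrix when
    all factors are kept).  Factors with eigenvalue > 1 are retained and
    loadings with |value| ≥ ``loading_flag`` are flagged as contributing.

    Raises
    ------
    ZeroVarianceError
        Naming a constant column.
    """
    if X.shape[1] < 2 or X.shape[0] < 3:
        raise ValueError("PCA screen needs at least 2 variables and 3 rows")
    sd = X.std(ddof=1)
    if (sd <= 0).any():
        raise ZeroVarianceError(f"constant column {sd.index[(sd <= 0)][0]!r} in PCA input")
    R = np.corrcoef(X.to_numpy(float), rowvar=False)
    evals, evecs = np.linalg.eigh(R)
    order = np.argsort(evals)[::-1]
    evals = np.maximum(evals[order], 0.0)
    evecs = evecs[:, order]
    # deterministic sign: largest-magnitude element of each factor positive
    signs = np.sign(evecs[np.abs(evecs).argmax(axis=0), np.arange(evecs.shape[1])])
    evecs = evecs * np.where(signs == 0, 1.0, signs)
    loadings = evecs * np.sqrt(evals)
    factors = [f"factor_{k + 1}" for k in range(len(evals))]
    ldf = pd.DataFrame(loadings, index=X.columns, columns=factors)
    return FactorModel(
        loadings=ldf,
        eigenvalues=evals,
        explained=evals / len(evals),
        retained=int((evals > 1.0).sum()),
        flagged=ldf.abs() >= loading_flag,
    )


# --------------------------------------------------- canonical discriminants

@dataclass
class DiscriminantModel:
    """Canonical discriminant solution for one grouping factor."""

    coefficients: pd.DataFrame  # variables x roots (raw canonical coefficients)
    eigenvalues: np.ndarray  # of W^-1 B, nonincreasing, >= 0
    cumulative_proportion: np.ndarray  # of discrimination, ends at 1
    wilks_overall: float  # prod 1/(1+lambda_k)
    wilks_stepwise: np.ndarray  # lambda_k..end removed successively
    wilks_per_variable: pd.Series  # univariate SSW/SST per variable
    scores: pd.DataFrame  # samples x roots


def canonical_discriminant(X: pd.DataFrame, groups: pd.Series) -> DiscriminantModel:
    """Eigen-solution of the within/between scatter problem W⁻¹B.

    Requires ≥ 2 groups with ≥ 2 samples each and an invertible within-group
    scatter.  The number of non-trivial roots is min(groups − 1, variables);
    Wilks' lambda is Π 1/(1+λ) over all roots (overall), over roots k…end
    (stepwise), and the univariate within/total sum-of-squares ratio per
    variable.
    """
    groups = pd.Series(np.asarray(groups), index=X.index)
    levels = list(dict.fromkeys(groups))
    if len(levels) < 2:
        raise GroupSizeError("discriminant analysis needs at least 2 groups")
    counts = groups.value_counts()
    if (counts < 2).any():
        raise GroupSizeError("every group needs at least 2 samples")
    A = X.to_numpy(float)
    n, p = A.shape
    grand = A.mean(axis=0)
    W = np.zeros((p, p))
    B = np.zeros((p, p))
    for lev in levels:
        sub = A[(groups == lev).to_numpy()]
        m = sub.mean(axis=0)
        dev = sub - m
        W += dev.T @ dev
        dm = (m - grand)[:, None]
        B += len(sub) * (dm @ dm.T)
    if np.linalg.cond(W) > _COND_LIMIT:
        raise SingularCovarianceError(
            "singular within-group scatter; reduce variables or enlarge groups"
        )
    evals, evecs = linalg.eigh(B, W)  # generalized symmetric-definite problem
    order = np.argsort(evals)[::-1]
    evals = np.maximum(evals[order], 0.0)
    evecs = evecs[:, order]
    r = min(len(levels) - 1, p)
    evals, evecs = evals[:r], evecs[:, :r]
    signs = np.sign(evecs[np.abs(evecs).argmax(axis=0), np.arange(r)])
    evecs = evecs * np.where(signs == 0, 1.0, signs)
    total = evals.sum()
    cumulative = np.cumsum(evals) / total if total > 0 else np.ones(r)
    stepwise = np.array([np.prod(1.0 / (1.0 + evals[k:])) for k in range(r)])
    T = W + B
    per_var = pd.Series(np.diag(W) / np.diag(T), index=X.columns, name="wilks_lambda")
    roots = [f"root_{k + 1}" for k in range(r)]
    return DiscriminantModel(
        coefficients=pd.DataFrame(evecs, index=X.columns, columns=roots),
        eigenvalues=evals,
        cumulative_proportion=cumulative,
        wilks_overall=float(np.prod(1.0 / (1.0 + evals))),
        wilks_stepwise=stepwise,
        wilks_per_variable=per_var,
        scores=pd.DataFrame((A - grand) @ evecs, index=X.index, columns=roots),
    )


def plot_canonical_scores(model: DiscriminantModel, groups: pd.Series, path) -> None:
    """Scatter of the first two canonical roots, coloured by group."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    ycol = "root_2" if "root_2" in model.scores.columns else "root_1"
    for lev in dict.fromkeys(groups):
        mask = (pd.Series(np.asarray(groups), index=model.scores.index) == lev).to_numpy()
        ax.scatter(model.scores.loc[mask, "root_1"], model.scores.loc[mask, ycol],
                   s=12, alpha=0.7, label=str(lev))
    ax.set_xlabel("canonical root 1")
    ax.set_ylabel("canonical root 2" if ycol == "root_2" else "root 1")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ----------------------------------------------------- two-group comparisons

def compare_groups(
    clr_a: pd.DataFrame, clr_b: pd.DataFrame, welch: bool = False
) -> pd.DataFrame:
    """Per-variable two-sample t comparison of clr means.

    Pooled-variance t by default (equivalent to a one-way ANOVA with two
    groups); Welch's t on request.  ``similar`` is True at p > 0.05.

    Returns a frame indexed by component with columns ``mean_a``, ``mean_b``,
    ``t_value``, ``p_value``, ``similar``.
    """
    if len(clr_a) < 2 or len(clr_b) < 2:
        raise GroupSizeError("both groups need at least 2 samples")
    rows = {}
    for c in COMPONENTS:
        a = clr_a[c].to_numpy(float)
        b = clr_b[c].to_numpy(float)
        if np.var(a, ddof=1) + np.var(b, ddof=1) == 0:
            raise ZeroVarianceError(f"zero pooled variance for component {c!r}")
        t, p = stats.ttest_ind(a, b, equal_var=not welch)
        rows[c] = {
            "mean_a": a.mean(),
            "mean_b": b.mean(),
            "t_value": float(t),
            "p_value": float(p),
            "similar": bool(p > 0.05),
        }
    return pd.DataFrame.from_dict(rows, orient="index").reindex(list(COMPONENTS))


# -------------------------------------------------------- yield correlations

def yield_correlations(samples: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation of yield with concentrations and clr variables.

    Two rows per group of variables — stage ``concentration`` (11 nutrients,
    native units) and stage ``clr`` (12 components) — with r, two-sided p and
    a significance star at p < 0.05.  Zero-variance variables yield missing r.
    """
    if len(samples) < 4:
        raise GroupSizeError("need at least 4 samples with yield")
    y = samples["yield_t_ha"].to_numpy(float)
    clr = samples_to_clr(samples)
    rows = []
    for stage, frame, cols in (
        ("concentration", samples, NUTRIENTS),
        ("clr", clr, COMPONENTS),
    ):
        for c in cols:
            x = frame[c].to_numpy(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                r, p = np.nan, np.nan
            else:
                r, p = stats.pearsonr(x, y)
            rows.append(
                {
                    "stage": stage,
                    "variable": c,
                    "r": float(r) if np.isfinite(r) else np.nan,
                    "p_value": float(p) if np.isfinite(p) else np.nan,
                    "significant": bool(np.isfinite(p) and p < 0.05),
                }
            )
    return pd.DataFrame(rows)
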