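"""Critical levels and sufficiency ranges from concentration–index regressions.

For each nutrient, an ordinary least-squares model links the tissue
concentration (response, native units) to the nutrient's CND index
(predictor).  Setting the index to zero — the equilibrium point of the
reference norms — and reading the prediction gives the critical level NC.
The sufficiency range spans NC ± ⅔·SD of the concentration in the reference
subpopulation, so NC is always the midpoint of the range (unless the lower
bound would be negative, in which case it is clipped at zero and logged).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .composition import NUTRIENTS, samples_to_clr
from .exceptions import ZeroVarianceError
from .norms import CndNorms, cnd_indices

log = logging.getLogger(__name__)


@dataclass
class IndexModel:
    """OLS fit of concentration on CND index for one nutrient."""

    nutrient: str
    form: str  # "linear" or "quadratic"
    params: np.ndarray  # intercept, slope(, quadratic)
    r2: float
    n: int

    def predict(self, index_value: float) -> float:
        x = float(index_value)
        value = self.params[0] + self.params[1] * x
        if self.form == "quadratic":
            value += self.params[2] * x * x
        return float(value)


def fit_index_model(conc: pd.Series, index: pd.Series, form: str = "linear") -> IndexModel:
    """Fit concentration (response) on CND index (predictor) by OLS.

    Parameters
    ----------
    conc, index
        Aligned per-sample series (≥ 5 samples).
    form
        ``linear`` (default) or ``quadratic``.

    Raises
    ------
    ZeroVarianceError
        If the index has no variance.
    """
    if form not in ("linear", "quadratic"):
        raise ValueError(f"unknown model form {form!r}")
    y = np.asarray(conc, float)
    x = np.asarray(index, float)
    if len(y) < 5:
        raise ValueError(f"need at least 5 samples to fit, got {len(y)}")
    if np.ptp(x) == 0:
        raise ZeroVarianceError(f"index for {getattr(conc, 'name', '?')!r} has zero variance")
    X = np.column_stack([x, x * x]) if form == "quadratic" else x[:, None]
    res = sm.OLS(y, sm.add_constant(X)).fit()
    return IndexModel(
        nutrient=str(getattr(conc, "name", "")),
        form=form,
        params=np.asarray(res.params, float),
        r2=float(res.rsquared),
        n=len(y),
    )


def critical_level(model: IndexModel) -> float:
    """Concentration at index zero — the nutrient's critical level NC."""
    return model.predict(0.0)


def sufficiency_range(nc: float, sd_conc: float) -> tuple[float, float]:
    """Sufficiency range NC ∓ ⅔·SD of the reference concentration.

    The lower bound is clipped at 0 if NC < ⅔·SD (non-physical negative
    concentration); the clip is logged and warned, and breaks the midpoint
    identity for that row only.
    """
    if not sd_conc > 0:
        raise ValueError(f"sd_conc must be positive, got {sd_conc}")
    half = (2.0 / 3.0) * sd_conc
    lower, upper = nc - half, nc + half
    if lower < 0:
        msg = f"sufficiency lower bound {lower:.3g} < 0; clipped to 0"
        log.warning(msg)
        warnings.warn(msg, RuntimeWarning, stacklevel=2)
        lower = 0.0
    return lower, upper


def build_sufficiency_table(
    samples: pd.DataFrame, norms: CndNorms, form: str = "linear"
) -> pd.DataFrame:
    """Per-nutrient critical levels, sufficiency bounds and model fit.

    Indices are computed for ``samples`` against ``norms``; one OLS model is
    fitted per nutrient.  Returns a frame indexed by nutrient with columns
    ``critical_level``, ``lower``, ``upper`` (native units), ``model_r2``,
    ``intercept`` and ``slope`` (plus ``quadratic`` for that form).
    """
    clr = samples_to_clr(samples)
    indices = cnd_indices(clr, norms)
    rows = {}
    for nut in NUTRIENTS:
        model = fit_index_model(samples[nut].rename(nut), indices[nut], form=form)
        nc = critical_level(model)
        lower, upper = sufficiency_range(nc, float(norms.conc_sd[nut]))
        row = {
            "critical_level": nc,
            "lower": lower,
            "upper": upper,
            "model_r2": model.r2,
            "intercept": model.params[0],
            "slope": model.params[1],
        }
        if form == "quadratic":
            row["quadratic"] = model.params[2]
        rows[nut] = row
    return pd.DataFrame.from_dict(rows, orient="index").reindex(list(NUTRIENTS))
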