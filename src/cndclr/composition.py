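"""Closed leaf-tissue compositions and the centred log-ratio (clr) transform.

A routine leaf analysis reports 11 nutrient concentrations: the macronutrients
N, P, K, Ca, Mg and S in g kg⁻¹ of dry matter, and the micronutrients B, Cu, Fe,
Mn and Zn in mg kg⁻¹.  Compositional nutrient diagnosis treats each sample as a
point on the simplex: the 11 nutrients are expressed in a common unit
(mg kg⁻¹) and closed with a filler component ``R`` — the rest of the dry
matter — so that the 12 parts sum to 1,000,000 mg kg⁻¹.  The centred log-ratio
transform

    clr_j = ln(x_j / g(x)),     g(x) = (∏_j x_j)^(1/12)

maps the closed composition to a zero-sum vector in which every coordinate is
a *multinutrient* variable: it carries information about its nutrient relative
to the whole composition, which is what the diagnosis standardizes.

All public functions are vectorized over pandas DataFrames whose rows are
samples.  Concentration frames use native units and the plain nutrient names
(``N`` … ``Zn``); composition and clr frames use the 12 component names
(``N`` … ``Zn``, ``R``).
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

from .exceptions import CompositionError, InfeasibleCompositionError, SchemaError

#: Macronutrients, reported in g kg^-1 at I/O.
MACRONUTRIENTS: tuple[str, ...] = ("N", "P", "K", "Ca", "Mg", "S")
#: Micronutrients, reported in mg kg^-1 at I/O.
MICRONUTRIENTS: tuple[str, ...] = ("B", "Cu", "Fe", "Mn", "Zn")
#: All measured nutrients, in reporting order.
NUTRIENTS: tuple[str, ...] = MACRONUTRIENTS + MICRONUTRIENTS
#: The filler component closing the composition.
FILLER: str = "R"
#: The 12 compositional components.
COMPONENTS: tuple[str, ...] = NUTRIENTS + (FILLER,)
#: Total dry matter in mg kg^-1; the closure constant.
TOTAL_MG_KG: float = 1_000_000.0

#: Sample-level metadata columns of the standard CSV layout.
META_COLUMNS: tuple[str, ...] = ("sample_id", "region", "cultivar", "year", "yield_t_ha")

#: CSV header -> plain nutrient name (and the inverse), fixing the unit suffix.
CSV_CONC_COLUMNS: dict[str, str] = {
    **{f"{n}_g_kg": n for n in MACRONUTRIENTS},
    **{f"{n}_mg_kg": n for n in MICRONUTRIENTS},
}
CONC_CSV_NAMES: dict[str, str] = {v: k for k, v in CSV_CONC_COLUMNS.items()}


def _require_columns(df: pd.DataFrame, columns: Iterable[str], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} is missing columns: {missing}")


def validate_samples(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample frame (metadata + native-unit concentrations).

    Checks that all 11 nutrient columns are present and strictly positive and
    that yields are finite and non-negative.  Returns the frame unchanged.

    Raises
    ------
    SchemaError
        If a required column is absent.
    CompositionError
        Naming the offending nutrient and sample on a non-positive or
        non-finite concentration, or on an invalid yield.
    """
    _require_columns(df, META_COLUMNS, "sample frame")
    _require_columns(df, NUTRIENTS, "sample frame")
    conc = df[list(NUTRIENTS)]
    bad = ~np.isfinite(conc.to_numpy(float)) | (conc.to_numpy(float) <= 0)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise CompositionError(
            f"non-positive or non-finite concentration for nutrient "
            f"{NUTRIENTS[j]!r} in sample {df['sample_id'].iloc[i]!r}"
        )
    y = df["yield_t_ha"].to_numpy(float)
    if (~np.isfinite(y) | (y < 0)).any():
        i = int(np.argwhere(~np.isfinite(y) | (y < 0))[0][0])
        raise CompositionError(f"invalid yield for sample {df['sample_id'].iloc[i]!r}")
    return df


def read_leaf_csv(path) -> pd.DataFrame:
    """Read the standard leaf-analysis CSV into a validated sample frame.

    Expected header: ``sample_id,region,cultivar,year,yield_t_ha`` followed by
    the 11 unit-suffixed nutrient columns (``N_g_kg`` ... ``Zn_mg_kg``).
    Nutrient columns are renamed to plain names; units stay native.
    """
    df = pd.read_csv(path)
    _require_columns(df, list(META_COLUMNS) + list(CSV_CONC_COLUMNS), "leaf CSV")
    df = df.rename(columns=CSV_CONC_COLUMNS)
    return validate_samples(df)


def write_leaf_csv(df: pd.DataFrame, path) -> None:
    """Write a sample frame back to the standard CSV layout (UTF-8, dot decimal)."""
    out = df[list(META_COLUMNS) + list(NUTRIENTS)].rename(columns=CONC_CSV_NAMES)
    out.to_csv(path, index=False)


def to_composition(conc: pd.DataFrame) -> pd.DataFrame:
    """Close native-unit concentrations into a 12-part composition in mg kg⁻¹.

    Macronutrients are converted g kg⁻¹ → mg kg⁻¹ (×1000); the filler is
    ``R = 1,000,000 − Σ(nutrients in mg kg⁻¹)``, so every row sums to exactly
    the closure total.

    Parameters
    ----------
    conc
        Frame with the 11 nutrient columns in native units (extra columns,
        e.g. metadata, are ignored).

    Raises
    ------
    CompositionError
        On a non-positive concentration (names the nutrient).
    InfeasibleCompositionError
        If the nutrient total reaches the 1,000,000 mg kg⁻¹ closure.
    """
    _require_columns(conc, NUTRIENTS, "concentration frame")
    x = conc[list(NUTRIENTS)].astype(float).copy()
    bad = ~np.isfinite(x.to_numpy()) | (x.to_numpy() <= 0)
    if bad.any():
        j = int(np.argwhere(bad)[0][1])
        raise CompositionError(f"non-positive concentration in nutrient {NUTRIENTS[j]!r}")
    x[list(MACRONUTRIENTS)] *= 1000.0
    total = x.sum(axis=1)
    if (total >= TOTAL_MG_KG).any():
        idx = total.index[total >= TOTAL_MG_KG][0]
        raise InfeasibleCompositionError(
            f"nutrient total {total[idx]:.0f} mg/kg reaches the closure total "
            f"for row {idx!r}; no mass left for the filler"
        )
    x[FILLER] = TOTAL_MG_KG - total
    return x[list(COMPONENTS)]


def composition_to_conc(comp: pd.DataFrame) -> pd.DataFrame:
    """Back-convert a 12-part composition to native-unit nutrient columns."""
    _require_columns(comp, COMPONENTS, "composition frame")
    out = comp[list(NUTRIENTS)].astype(float).copy()
    out[list(MACRONUTRIENTS)] /= 1000.0
    return out


def clr_transform(comp: pd.DataFrame) -> pd.DataFrame:
    """Centred log-ratio coordinates of closed compositions.

    ``clr_j = ln(x_j) − mean_j ln(x_j)`` over the 12 components; each row of
    the result sums to zero to machine precision.

    Raises
    ------
    CompositionError
        If any part is zero or negative (log undefined).
    """
    _require_columns(comp, COMPONENTS, "composition frame")
    x = comp[list(COMPONENTS)].to_numpy(float)
    if (~np.isfinite(x) | (x <= 0)).any():
        raise CompositionError("clr transform requires strictly positive parts")
    logs = np.log(x)
    clr = logs - logs.mean(axis=1, keepdims=True)
    return pd.DataFrame(clr, index=comp.index, columns=list(COMPONENTS))


def inverse_clr(clr: pd.DataFrame, atol: float = 1e-6) -> pd.DataFrame:
    """Map zero-sum clr coordinates back to compositions in mg kg⁻¹.

    Softmax-style closure: ``x_j = 1,000,000 · e^{v_j} / Σ_k e^{v_k}``.  Rows
    whose coordinates do not sum to ≈0 are rejected rather than silently
    re-centred.  ``inverse_clr(clr_transform(c))`` reproduces ``c`` to better
    than 1e-9 relative.
    """
    _require_columns(clr, COMPONENTS, "clr frame")
    v = clr[list(COMPONENTS)].to_numpy(float)
    if not np.isfinite(v).all():
        raise CompositionError("clr coordinates must be finite")
    sums = v.sum(axis=1)
    if (np.abs(sums) > atol).any():
        i = int(np.argmax(np.abs(sums)))
        raise CompositionError(
            f"clr row {clr.index[i]!r} sums to {sums[i]:.3g}, not 0; not a valid clr vector"
        )
    e = np.exp(v - v.max(axis=1, keepdims=True))  # overflow-safe
    x = TOTAL_MG_KG * e / e.sum(axis=1, keepdims=True)
    return pd.DataFrame(x, index=clr.index, columns=list(COMPONENTS))


def samples_to_clr(df: pd.DataFrame) -> pd.DataFrame:
    """Convenience: native-unit sample frame → clr frame (close, then transform)."""
    return clr_transform(to_composition(df))
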