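"""End-to-end group pipelines and report assembly in survey-table layouts.

`standards_pipeline` runs, per group: outlier filtering → reference selection
→ norms → sufficiency table.  The assembly helpers lay the results out the
way nutritional-standards surveys print them: per group, three native-unit
rows (sufficiency upper bound, critical level, lower bound) followed by four
clr rows (Mean, SD, UCB, LCB), plus a summary of sample counts and
per-nutrient model R².
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .composition import COMPONENTS, NUTRIENTS, samples_to_clr
from .exceptions import CndError, GroupSizeError
from .norms import CndNorms, compute_norms, diagnose, select_reference
from .outliers import OutlierReport, filter_outliers
from .screen import (
    canonical_discriminant,
    compare_groups,
    encode_design_matrix,
    pca_screen,
    yield_correlations,
)
from .sufficiency import build_sufficiency_table

log = logging.getLogger(__name__)

DEFAULT_GROUPBY = ("region", "cultivar")


@dataclass
class GroupStandards:
    """Everything the pipeline derives for one group."""

    group_id: str
    n_start: int
    n_end: int
    n_ref: int
    outliers: OutlierReport
    norms: CndNorms
    sufficiency: pd.DataFrame


def _group_key(values) -> str:
    return "/".join(str(v) for v in (values if isinstance(values, tuple) else (values,)))


def parse_ref_rule(rule: str) -> dict:
    """Parse ``top_fraction:0.33`` or ``threshold:30.4`` into kwargs."""
    kind, _, value = rule.partition(":")
    if kind == "top_fraction":
        return {"top_fraction": float(value)}
    if kind == "threshold":
        return {"yield_threshold": float(value)}
    raise ValueError(f"unknown reference rule {rule!r}")


def standards_pipeline(
    samples: pd.DataFrame,
    groupby: tuple[str, ...] = DEFAULT_GROUPBY,
    ref_rule: str = "top_fraction:0.5",
    alpha_outlier: float = 0.05,
    alpha_ci: float = 0.05,
    model: str = "linear",
) -> dict[str, GroupStandards]:
    """Run the full standards pipeline per group.

    Groups too small for any stage are skipped with a warning rather than
    aborting the run; every exclusion is itemized in the outlier report.
    """
    kwargs = parse_ref_rule(ref_rule)
    results: dict[str, GroupStandards] = {}
    for key, group in samples.groupby(list(groupby), sort=False):
        gid = _group_key(key)
        try:
            retained, report = filter_outliers(group, alpha=alpha_outlier)
            for sid in report.excluded_ids:
                log.info("group %s: excluded outlier %s", gid, sid)
            ref = select_reference(retained, **kwargs)
            norms = compute_norms(ref, group_id=gid, alpha=alpha_ci)
            suff = build_sufficiency_table(retained, norms, form=model)
        except (CndError, GroupSizeError, ValueError) as exc:
            log.warning("skipping group %s: %s", gid, exc)
            continue
        results[gid] = GroupStandards(
            group_id=gid,
            n_start=len(group),
            n_end=len(retained),
            n_ref=norms.n_ref,
            outliers=report,
            norms=norms,
            sufficiency=suff,
        )
    if not results:
        raise ValueError("no group was large enough to analyze")
    return results


def standards_frame(results: dict[str, GroupStandards]) -> pd.DataFrame:
    """Survey-layout standards table.

    One row per (group, statistic): native-unit rows ``sufficiency_upper`` /
    ``critical_level`` / ``sufficiency_lower`` over the 11 nutrients, then
    clr rows ``clr_mean`` / ``clr_sd`` / ``clr_ucb`` / ``clr_lcb`` over all
    12 components.  Values are unrounded; presentation rounding is left to
    the caller.
    """
    rows = []
    for gid, res in results.items():
        native = {
            "sufficiency_upper": res.sufficiency["upper"],
            "critical_level": res.sufficiency["critical_level"],
            "sufficiency_lower": res.sufficiency["lower"],
        }
        for stat, series in native.items():
            rows.append({"group": gid, "statistic": stat, **{n: series[n] for n in NUTRIENTS}})
        clr_rows = {
            "clr_mean": res.norms.clr_mean,
            "clr_sd": res.norms.clr_sd,
            "clr_ucb": res.norms.ucb,
            "clr_lcb": res.norms.lcb,
        }
        for stat, series in clr_rows.items():
            rows.append({"group": gid, "statistic": stat, **{c: series[c] for c in COMPONENTS}})
    return pd.DataFrame(rows)


def summary_frame(results: dict[str, GroupStandards]) -> pd.DataFrame:
    """Per-group sample accounting and per-nutrient model R²."""
    rows = []
    for gid, res in results.items():
        row = {
            "group": gid,
            "n_start": res.n_start,
            "n_end": res.n_end,
            "n_ref": res.n_ref,
        }
        row.update({f"r2_{n}": res.sufficiency.loc[n, "model_r2"] for n in NUTRIENTS})
        rows.append(row)
    return pd.DataFrame(rows)


def diagnose_frame(samples: pd.DataFrame, norms: CndNorms) -> pd.DataFrame:
    """Per-sample diagnosis report (indices, r², balance classes)."""
    return diagnose(samples, norms)


def screen_frames(
    samples: pd.DataFrame, groupby: tuple[str, ...] = DEFAULT_GROUPBY
) -> dict[str, pd.DataFrame]:
    """The four group-structure screens as report frames.

    Returns ``pca`` (loadings, eigenvalues, retention flags), ``discriminant``
    (canonical coefficients, eigenvalues, cumulative proportion, Wilks'
    lambda), ``comparisons`` (pairwise two-group t results, all group pairs)
    and ``correlations`` (per-group yield correlations).
    """
    key = samples[list(groupby)].astype(str).agg("/".join, axis=1)
    levels = list(dict.fromkeys(key))
    if len(levels) < 2:
        raise GroupSizeError("screens need at least 2 groups")
    clr = samples_to_clr(samples)

    X = encode_design_matrix(samples, clr=clr)
    fm = pca_screen(X)
    pca = fm.loadings.copy()
    pca["flagged"] = fm.flagged.any(axis=1)
    pca.loc["eigenvalue"] = list(fm.eigenvalues) + [None]
    pca.loc["explained"] = list(fm.explained) + [None]
    pca.attrs["retained"] = fm.retained

    # zero-sum clr rows make the within scatter singular; the discriminant
    # screen therefore runs on the 11 nutrient coordinates, like the distance
    dm = canonical_discriminant(clr[list(NUTRIENTS)], key)
    disc = dm.coefficients.copy()
    disc["wilks_per_variable"] = dm.wilks_per_variable
    disc.loc["eigenvalue"] = list(dm.eigenvalues) + [None]
    disc.loc["cumulative_proportion"] = list(dm.cumulative_proportion) + [None]
    disc.loc["wilks_stepwise"] = list(dm.wilks_stepwise) + [dm.wilks_overall]

    comp_rows = []
    for i, a in enumerate(levels):
        for b in levels[i + 1:]:
            table = compare_groups(clr[(key == a).to_numpy()], clr[(key == b).to_numpy()])
            table = table.reset_index(names="variable")
            table.insert(0, "group_a", a)
            table.insert(1, "group_b", b)
            comp_rows.append(table)

    corr_rows = []
    for lev in levels:
        sub = samples[(key == lev).to_numpy()]
        if len(sub) < 4:
            log.warning("skipping yield correlations for small group %s", lev)
            continue
        table = yield_correlations(sub)
        table.insert(0, "group", lev)
        corr_rows.append(table)

    return {
        "pca": pca,
        "discriminant": disc,
        "comparisons": pd.concat(comp_rows, ignore_index=True),
        "correlations": pd.concat(corr_rows, ignore_index=True),
    }
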