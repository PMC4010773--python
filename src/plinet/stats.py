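"""Statistical layer: paired t-tests, the 2x2 repeated-measures interaction,
and per-band Benjamini-Hochberg FDR correction.

Within each group the routine and sleep-deprived recordings are compared
measure-by-measure with a paired t-test.  The group-by-condition question
— do patients and controls change *differently* after sleep deprivation —
is the interaction of a repeated-measures ANOVA with condition as the
within-subject factor and group as the between-subject factor.  In a 2x2
design that interaction F is algebraically identical to the square of the
two-sample t statistic on the per-subject difference scores, which is how
it is computed here (df = 1 and n_patients + n_controls - 2).  Multiple
testing is corrected per frequency band, treating the measures within one
band as one Benjamini-Hochberg family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "StatResult",
    "paired_t",
    "rm_anova_interaction",
    "fdr_correct",
    "build_tables",
]

#: Measures expected in the network/MST analysis tables, in display order.
NETWORK_MEASURES = ("path_length", "clustering", "diameter", "leaf_number")


@dataclass
class StatResult:
    """One test: identity, statistic, df, p, and FDR flag once corrected."""

    test: str
    statistic: float
    df: tuple[int, ...]
    p: float
    band: str | None = None
    measure: str | None = None
    scope: str | None = None
    fdr_significant: bool | None = None


def paired_t(values_pre: np.ndarray, values_post: np.ndarray,
             **ids) -> StatResult:
    """Classical paired t-test (two-sided), t = mean(d) / (sd(d)/sqrt(n)).

    ``d = post - pre``, so a positive t means the measure increased after
    sleep deprivation.  Zero variance of the differences is an error (the
    statistic is undefined).
    """
    pre = np.asarray(values_pre, dtype=float)
    post = np.asarray(values_post, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1:
        raise ValueError("paired samples must be equal-length 1-D arrays")
    n = pre.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if not (np.all(np.isfinite(pre)) and np.all(np.isfinite(post))):
        raise ValueError("non-finite values in paired samples")
    d = post - pre
    sd = d.std(ddof=1)
    if sd == 0:
        if np.all(d == 0):  # no change at all: t = 0 by continuity
            return StatResult(test="paired_t", statistic=0.0, df=(n - 1,),
                              p=1.0, **ids)
        raise ValueError("zero variance of paired differences")
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), n - 1)
    return StatResult(test="paired_t", statistic=float(t), df=(n - 1,),
                      p=float(p), **ids)


def rm_anova_interaction(records: pd.DataFrame, *,
                         group_col: str = "group",
                         subject_col: str = "subject_id",
                         condition_col: str = "condition",
                         value_col: str = "value",
                         conditions: tuple[str, str] = ("routine", "sd"),
                         **ids) -> StatResult:
    """Condition-by-group interaction F for one measure in one band.

    Computed through the exact 2x2 identity: per-subject difference scores
    (second condition minus first) are compared between the two groups with
    a pooled two-sample t; F = t^2 with df = (1, n - 2).  Every subject
    must have both conditions.
    """
    pivot = records.pivot_table(index=[subject_col, group_col],
                                columns=condition_col, values=value_col,
                                aggfunc="first")
    missing = pivot[pivot[list(conditions)].isna().any(axis=1)]
    if len(missing):
        bad = sorted({s for s, _ in missing.index})
        raise ValueError(f"subject(s) missing a condition: {bad}")
    diff = pivot[conditions[1]] - pivot[conditions[0]]
    groups = diff.index.get_level_values(group_col)
    names = sorted(set(groups))
    if len(names) != 2:
        raise ValueError(f"need exactly two groups, got {names}")
    a = diff[groups == names[0]].to_numpy()
    b = diff[groups == names[1]].to_numpy()
    if min(a.size, b.size) < 2:
        raise ValueError("need at least 2 subjects per group")
    t, _ = sps.ttest_ind(a, b, equal_var=True)
    n = a.size + b.size
    f = float(t) ** 2
    p = float(sps.f.sf(f, 1, n - 2))
    return StatResult(test="rm_anova_interaction", statistic=f,
                      df=(1, n - 2), p=p, **ids)


def fdr_correct(results: list[StatResult], q: float = 0.05,
                by: str = "band") -> list[StatResult]:
    """Benjamini-Hochberg step-up within each band family.

    Families are formed by the ``by`` attribute (default: all results
    sharing one frequency band); flags are written back onto the results
    (which are also returned).  Empty input is a no-op.
    """
    if not results:
        return results
    families: dict[object, list[StatResult]] = {}
    for r in results:
        families.setdefault(getattr(r, by), []).append(r)
    for members in families.values():
        pvals = [r.p for r in members]
        flags = multipletests(pvals, alpha=q, method="fdr_bh")[0]
        for r, flag in zip(members, flags):
            r.fdr_significant = bool(flag)
    return results


def _results_frame(results: list[StatResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "test": r.test, "scope": r.scope, "measure": r.measure,
        "band": r.band, "statistic": r.statistic,
        "df": "x".join(str(d) for d in r.df), "p": r.p,
        "fdr_significant": r.fdr_significant,
    } for r in results])


def _wide(frame: pd.DataFrame, stat_name: str) -> pd.DataFrame:
    """One row per measure, (band, column) pairs across the top."""
    if frame.empty:
        return frame
    wide = frame.pivot_table(index="measure", columns="band",
                             values=["statistic", "p"], aggfunc="first")
    wide = wide.swaplevel(axis=1).sort_index(axis=1)
    wide.columns = [f"{band}_{'t' if stat_name == 't' else 'F'}"
                    if val == "statistic" else f"{band}_p"
                    for band, val in wide.columns]
    order = [m for m in NETWORK_MEASURES if m in wide.index]
    order += [m for m in wide.index if m not in order]
    return wide.loc[order]


def build_tables(measures: pd.DataFrame, q: float = 0.05,
                 conditions: tuple[str, str] = ("routine", "sd"),
                 power_measures: tuple[str, ...] | None = None
                 ) -> dict[str, pd.DataFrame]:
    """All report tables from a long-format measure table.

    ``measures`` needs columns subject_id, group, condition, band, measure,
    value, and (for the added-value subset analysis) added_value.  Returns:

    - ``power_paired``      per-group paired t-tests on relative band power
    - ``paired_patients`` / ``paired_controls``  per-band paired t-tests on
      the network and tree measures
    - ``interaction``       condition-by-group interaction F per measure and
      band, on the full cohort and on the added-value patient subset (the
      subset keeps *all* controls)
    - ``long``              every test as one row, with FDR flags
    """
    required = {"subject_id", "group", "condition", "band", "measure",
                "value"}
    if not required.issubset(measures.columns):
        raise ValueError(f"measures table must have columns {sorted(required)}")
    if power_measures is None:
        power_measures = tuple(sorted(
            m for m in measures["measure"].unique() if m.startswith("power_")))

    all_results: list[StatResult] = []

    def _paired_block(sub: pd.DataFrame, names: tuple[str, ...],
                      scope: str) -> list[StatResult]:
        out = []
        for (band, measure), grp in sub.groupby(["band", "measure"],
                                                sort=False):
            if measure not in names:
                continue
            pivot = grp.pivot_table(index="subject_id", columns="condition",
                                    values="value", aggfunc="first")
            out.append(paired_t(pivot[conditions[0]].to_numpy(),
                                pivot[conditions[1]].to_numpy(),
                                band=band, measure=measure, scope=scope))
        return fdr_correct(out, q=q)

    net = measures[measures["measure"].isin(NETWORK_MEASURES)]
    power = measures[measures["measure"].isin(power_measures)]
    tables: dict[str, pd.DataFrame] = {}

    power_results: list[StatResult] = []
    for group in ("patient", "control"):
        power_results += _paired_block(power[power["group"] == group],
                                       power_measures, f"power_{group}")
    all_results += power_results
    tables["power_paired"] = _results_frame(power_results)

    for group in ("patient", "control"):
        res = _paired_block(net[net["group"] == group], NETWORK_MEASURES,
                            group)
        all_results += res
        tables[f"paired_{group}s"] = _wide(_results_frame(res), "t")

    def _interaction_block(sub: pd.DataFrame, scope: str) -> list[StatResult]:
        out = []
        for (band, measure), grp in sub.groupby(["band", "measure"],
                                                sort=False):
            if measure not in NETWORK_MEASURES:
                continue
            out.append(rm_anova_interaction(grp, conditions=conditions,
                                            band=band, measure=measure,
                                            scope=scope))
        return fdr_correct(out, q=q)

    inter_full = _interaction_block(net, "all")
    all_results += inter_full
    frames = [_results_frame(inter_full).assign(cohort="all")]

    if "added_value" in measures.columns:
        subset = net[(net["group"] == "control")
                     | ((net["group"] == "patient") & net["added_value"])]
        if (subset["group"] == "patient").any():
            inter_sub = _interaction_block(subset, "added_value")
            all_results += inter_sub
            frames.append(_results_frame(inter_sub).assign(
                cohort="added_value"))
        else:
            warnings.warn("added-value patient subset is empty; subset "
                          "interaction omitted", stacklevel=2)
    tables["interaction"] = pd.concat(frames, ignore_index=True)

    tables["long"] = _results_frame(all_results)
    return tables
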