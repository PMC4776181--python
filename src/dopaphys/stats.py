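"""Group-level statistics: Mann-Whitney U, two-sample KS, one-way ANOVA.

Cells are the unit of analysis (animal counts are carried for transparency
only, not modelled hierarchically). The Mann-Whitney U test is exact for
combined n <= 20 without ties and uses the tie-corrected normal
approximation otherwise; ANOVA post-hoc pairwise comparisons use
Holm-adjusted Mann-Whitney tests by default (distribution-free, consistent
with the primary test; the procedure is a config option). Significance is
assessed at alpha = 0.05 throughout.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datatypes import GroupComparison, SummaryRow
from .errors import InsufficientDataError, ValidationError

EXACT_U_MAX_COMBINED_N = 20


def mann_whitney(group_a, group_b, measure: str = "") -> GroupComparison:
    """Two-sided Mann-Whitney U test.

    Exact null distribution when the combined sample size is <= 20 and
    there are no ties; otherwise the normal approximation with tie and
    continuity correction. Fully tied samples return p = 1 with a warning.

    Raises
    ------
    InsufficientDataError
        Either group has n < 3.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise InsufficientDataError("Mann-Whitney requires n >= 3 per group")
    if np.unique(np.concatenate([a, b])).size == 1:
        warnings.warn("all observations tied; p = 1", stacklevel=2)
        return GroupComparison(
            test_name="mann_whitney",
            statistic=float(a.size * b.size / 2.0),
            p_value=1.0,
            n_per_group=(a.size, b.size),
            measure=measure,
        )
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (a.size + b.size <= EXACT_U_MAX_COMBINED_N and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return GroupComparison(
        test_name="mann_whitney",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n_per_group=(a.size, b.size),
        measure=measure,
    )


def ks_test(pooled_a, pooled_b, measure: str = "") -> GroupComparison:
    """Two-sample Kolmogorov-Smirnov test (asymptotic p-value).

    Raises
    ------
    InsufficientDataError
        Fewer than 10 observations on either side.
    """
    a = np.asarray(pooled_a, dtype=float)
    b = np.asarray(pooled_b, dtype=float)
    if a.size < 10 or b.size < 10:
        raise InsufficientDataError("KS test requires n >= 10 per side")
    res = sps.ks_2samp(a, b, method="asymp")
    return GroupComparison(
        test_name="ks",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n_per_group=(a.size, b.size),
        measure=measure,
    )


def _holm(pvals: list[float]) -> list[float]:
    """Holm step-down adjustment."""
    m = len(pvals)
    order = np.argsort(pvals)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * pvals[idx])
        adj[idx] = min(running, 1.0)
    return adj.tolist()


def oneway_anova_with_posthoc(
    samples: dict[str, np.ndarray],
    measure: str = "",
    posthoc: str = "mann_whitney_holm",
):
    """One-way ANOVA across >= 3 labelled groups, with pairwise post-hoc.

    Returns (GroupComparison for the F test, DataFrame of pairwise
    Holm-adjusted comparisons).

    Raises
    ------
    InsufficientDataError
        Fewer than 3 groups or any group with n < 3.
    ValidationError
        All observations identical (F undefined).
    """
    labels = sorted(samples)
    arrays = [np.asarray(samples[k], dtype=float) for k in labels]
    if len(arrays) < 3:
        raise InsufficientDataError("ANOVA requires >= 3 groups")
    if any(a.size < 3 for a in arrays):
        raise InsufficientDataError("every group must have n >= 3")
    if np.unique(np.concatenate(arrays)).size == 1:
        raise ValidationError("all observations identical; F statistic undefined")
    f, p = sps.f_oneway(*arrays)
    comparison = GroupComparison(
        test_name="anova",
        statistic=float(f),
        p_value=float(p),
        n_per_group=tuple(a.size for a in arrays),
        measure=measure,
    )
    if posthoc != "mann_whitney_holm":
        raise ValidationError(f"unknown post-hoc procedure {posthoc!r}")
    pairs, raw = [], []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            res = mann_whitney(arrays[i], arrays[j])
            pairs.append((labels[i], labels[j], res.statistic))
            raw.append(res.p_value)
    adj = _holm(raw)
    table = pd.DataFrame(
        [
            {"group_a": a, "group_b": b, "U": u, "p_raw": pr, "p_holm": pa,
             "significant": pa < 0.05}
            for (a, b, u), pr, pa in zip(pairs, raw, adj)
        ],
        columns=["group_a", "group_b", "U", "p_raw", "p_holm", "significant"],
    )
    return comparison, table


def summarize(values, measure: str, group: str, n_animals: int = 0) -> SummaryRow:
    """Mean +/- SEM summary row (SEM = sd / sqrt(n), NaN for n = 1)."""
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 1:
        raise InsufficientDataError(f"{measure}/{group}: no finite observations")
    sem = float(np.std(x, ddof=1) / np.sqrt(x.size)) if x.size > 1 else float("nan")
    return SummaryRow(
        measure=measure,
        group=group,
        n_cells=int(x.size),
        mean=float(np.mean(x)),
        sem=sem,
        n_animals=n_animals,
    )


def build_results_report(measures: dict[str, pd.DataFrame]):
    """Assemble per-measure summary rows and between-group tests.

    Parameters
    ----------
    measures : dict
        Maps a measure name to a DataFrame with columns ``group`` and
        ``value`` (one row per cell).

    Returns
    -------
    (summary_df, comparisons_df, report) : (DataFrame, DataFrame, dict)
        ``report`` is a JSON-serializable dict with the same content.
        Measures whose table is empty are listed under
        ``report["incomplete"]`` and skipped with a warning.
    """
    summary_rows, comparison_rows, incomplete = [], [], []
    for measure in sorted(measures):
        df = measures[measure]
        if df is None or df.empty:
            incomplete.append(measure)
            continue
        groups = sorted(df["group"].unique())
        arrays = {}
        for g in groups:
            vals = df.loc[df["group"] == g, "value"].to_numpy(dtype=float)
            vals = vals[np.isfinite(vals)]
            arrays[g] = vals
            if vals.size == 0:
                incomplete.append(f"{measure}/{g}")
                continue
            row = summarize(vals, measure, g)
            summary_rows.append(
                {"measure": measure, "group": g, "n_cells": row.n_cells,
                 "mean": row.mean, "sem": row.sem}
            )
        if len(groups) == 2 and all(a.size >= 3 for a in arrays.values()):
            res = mann_whitney(arrays[groups[0]], arrays[groups[1]], measure=measure)
            comparison_rows.append(
                {"measure": measure, "test": res.test_name,
                 "statistic": res.statistic, "p_value": res.p_value,
                 "n_a": res.n_per_group[0], "n_b": res.n_per_group[1]}
            )
    if incomplete:
        warnings.warn(f"incomplete report; missing measures: {incomplete}", stacklevel=2)
    summary_df = pd.DataFrame(
        summary_rows, columns=["measure", "group", "n_cells", "mean", "sem"]
    )
    comparisons_df = pd.DataFrame(
        comparison_rows,
        columns=["measure", "test", "statistic", "p_value", "n_a", "n_b"],
    )
    report = {
        "schema_version": 1,
        "summary": summary_rows,
        "comparisons": comparison_rows,
        "incomplete": incomplete,
    }
    return summary_df, comparisons_df, report
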