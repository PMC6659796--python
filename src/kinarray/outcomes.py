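"""Cluster-versus-outcome statistics.

Overall survival by Kaplan-Meier with a log-rank comparison, cumulative
incidence of relapse as a relapse-frequency chi-square (plus 1 - KM curves
of time to relapse), and per-variable patient-characteristics tests:
Mann-Whitney U for continuous covariates, Pearson chi-square (no continuity
correction) for categorical ones.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

from .datatypes import ClinicalTable, TestResult, ValidationError, as_group_series

log = logging.getLogger(__name__)

CONTINUOUS_VARS = ("age", "blast_pct", "wbc", "rbc", "plt")
CATEGORICAL_VARS = ("sex", "source", "relapse", "death", "complete_response")


def km_estimate(times: Sequence[float], events: Sequence[int]) -> pd.DataFrame:
    """Product-limit (Kaplan-Meier) survival curve with right censoring.

    Returns a step-function table with columns ``time`` and ``survival``,
    starting at (0, 1).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if len(times) == 0:
        raise ValidationError("empty input to KM estimator")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    sf = kmf.survival_function_
    return pd.DataFrame(
        {"time": sf.index.to_numpy(float), "survival": sf.iloc[:, 0].to_numpy(float)}
    )


def logrank_test(
    times: Sequence[float], events: Sequence[int], group: Sequence
) -> TestResult:
    """Two-group log-rank chi-square test (df = 1), two-sided."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    group = np.asarray(group)
    values = np.unique(group)
    if len(values) != 2:
        raise ValidationError(f"log-rank needs exactly 2 groups, got {len(values)}")
    a, b = (group == values[0]), (group == values[1])
    if a.sum() == 0 or b.sum() == 0:
        raise ValidationError("a group has no subjects")
    res = _ll_logrank(times[a], times[b], event_observed_A=events[a], event_observed_B=events[b])
    return TestResult(
        statistic=float(res.test_statistic), p_value=float(res.p_value),
        method="log-rank", df=1,
    )


def chi_square_2x2(table: np.ndarray | Sequence[Sequence[int]]) -> TestResult:
    """Pearson chi-square on a 2x2 count table, no continuity correction."""
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2):
        raise ValidationError(f"expected a 2x2 table, got shape {table.shape}")
    if (table < 0).any():
        raise ValidationError("counts must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValidationError("zero margin in contingency table")
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    return TestResult(statistic=float(chi2), p_value=float(p), method="pearson-chi2", df=df)


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided Mann-Whitney U test.

    Exact null distribution (full enumeration) when the combined sample size
    is at most 12 and there are no ties; otherwise the normal approximation
    with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValidationError("empty sample in Mann-Whitney test")
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(pooled) <= 12 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    return TestResult(
        statistic=float(res.statistic), p_value=float(res.pvalue),
        method=f"mann-whitney-{method}",
    )


def cumulative_incidence_relapse(
    clinical: ClinicalTable, labels: Mapping[str, int] | pd.Series
) -> tuple[dict[int, float], TestResult, dict[int, pd.DataFrame]]:
    """Relapse frequency per cluster, chi-square comparison, and CIR curves.

    The test is a Pearson chi-square on the relapse-by-cluster count table
    (relapse frequency during follow-up); the curves are 1 - KM of time to
    relapse per cluster.  Samples lacking a relapse flag are excluded with a
    log entry.
    """
    labels = as_group_series(labels)
    df = clinical.data.loc[clinical.data.index.intersection(labels.index)].copy()
    df["cluster"] = labels.loc[df.index]
    missing = df["relapse"].isna()
    if missing.any():
        for s in df.index[missing]:
            log.info("excluding sample %s: missing relapse flag", s)
        df = df[~missing]

    clusters = sorted(df["cluster"].unique())
    if len(clusters) != 2:
        raise ValidationError(f"expected 2 clusters, got {clusters}")
    counts = []
    proportions: dict[int, float] = {}
    curves: dict[int, pd.DataFrame] = {}
    for c in clusters:
        sub = df[df["cluster"] == c]
        n_rel = int(sub["relapse"].sum())
        counts.append([n_rel, len(sub) - n_rel])
        proportions[int(c)] = n_rel / len(sub)
        km = km_estimate(sub["time_to_relapse"], sub["relapse"].astype(int))
        curves[int(c)] = pd.DataFrame(
            {"time": km["time"], "cumulative_incidence": 1.0 - km["survival"]}
        )
    if np.array(counts).sum() == 0 or all(row[0] == 0 for row in counts):
        test = TestResult(statistic=0.0, p_value=1.0, method="pearson-chi2", df=1)
    else:
        test = chi_square_2x2(np.asarray(counts))
    return proportions, test, curves


def characteristics_table(
    clinical: ClinicalTable, labels: Mapping[str, int] | pd.Series
) -> pd.DataFrame:
    """Per-variable cluster-1 vs cluster-2 comparison.

    Mann-Whitney U for continuous covariates; Pearson chi-square for
    categorical ones.  Unknown categories (e.g. unrecorded sex) are excluded
    from their variable's test, never imputed.
    """
    labels = as_group_series(labels)
    df = clinical.data.loc[clinical.data.index.intersection(labels.index)].copy()
    df["cluster"] = labels.loc[df.index]
    c1 = df[df["cluster"] == 1]
    c2 = df[df["cluster"] == 2]

    rows = []
    for var in CONTINUOUS_VARS:
        res = mann_whitney_u(c1[var].dropna(), c2[var].dropna())
        rows.append((var, res))
    for var in CATEGORICAL_VARS:
        sub = df[~df[var].isin(["unknown"]) & df[var].notna()]
        levels = sorted(sub[var].unique())
        if len(levels) != 2:
            log.warning("skipping %s: %d levels after excluding unknowns", var, len(levels))
            continue
        table = [
            [int(((sub["cluster"] == c) & (sub[var] == lv)).sum()) for lv in levels]
            for c in (1, 2)
        ]
        rows.append((var, chi_square_2x2(np.asarray(table))))

    out = pd.DataFrame(
        {
            "variable": [v for v, _ in rows],
            "method": [r.method for _, r in rows],
            "statistic": [r.statistic for _, r in rows],
            "p_value": [r.p_value for _, r in rows],
        }
    ).set_index("variable")
    return out


def overall_survival(
    clinical: ClinicalTable, labels: Mapping[str, int] | pd.Series
) -> tuple[dict[int, pd.DataFrame], TestResult]:
    """KM curves of overall survival per cluster plus the log-rank test.

    Survival time is follow-up time with death as the event.
    """
    labels = as_group_series(labels)
    df = clinical.data.loc[clinical.data.index.intersection(labels.index)].copy()
    df["cluster"] = labels.loc[df.index]
    curves = {
        int(c): km_estimate(sub["followup_time"], sub["death"].astype(int))
        for c, sub in df.groupby("cluster")
    }
    test = logrank_test(df["followup_time"], df["death"].astype(int), df["cluster"])
    return curves, test
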