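"""Per-peptide differential activation between cluster-1, cluster-2 and
CD34+ NBM controls.

The omnibus test is a one-way fixed-effects ANOVA per peptide; all three
pairwise comparisons are added as two-sample t-tests.  Tests run on
log2(1 + x) of the collapsed, quantile-normalized intensities -- intensity
noise is multiplicative, and testing on the log scale keeps the F-test's
far-tail calibration, which Bonferroni correction relies on -- while fold
differences are reported in natural intensity space.  P-values carry
Bonferroni correction over the number of peptides tested (by default the
variance-filtered set).
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import PeptideMatrix, ValidationError, as_group_series

log = logging.getLogger(__name__)


def anova_per_peptide(
    m: PeptideMatrix, groups: Mapping[str, str] | pd.Series
) -> pd.DataFrame:
    """One-way ANOVA per peptide across the given sample groups.

    F = MS_between / MS_within with df (g - 1, N - g).  Peptides where all
    values are identical across every group have F defined as 0 with p = 1
    and are flagged ``degenerate``.
    """
    groups = as_group_series(groups)
    samples = [s for s in m.samples if s in groups.index]
    groups = groups.loc[samples]
    names = list(dict.fromkeys(groups))
    blocks = {g: m.data[groups.index[groups == g]].to_numpy(float) for g in names}
    for g, block in blocks.items():
        if block.shape[1] < 2:
            raise ValidationError(f"group {g!r} has fewer than 2 samples")
    if len(names) < 2:
        raise ValidationError("need at least 2 groups")

    n_tot = sum(b.shape[1] for b in blocks.values())
    grand = np.hstack(list(blocks.values())).mean(axis=1)
    ss_between = np.zeros(m.data.shape[0])
    ss_within = np.zeros(m.data.shape[0])
    means = {}
    for g, block in blocks.items():
        mu = block.mean(axis=1)
        means[g] = mu
        ss_between += block.shape[1] * (mu - grand) ** 2
        ss_within += ((block - mu[:, None]) ** 2).sum(axis=1)
    df1, df2 = len(names) - 1, n_tot - len(names)

    degenerate = ss_within == 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_between / df1) / (ss_within / df2)
    p = stats.f.sf(f, df1, df2)
    # all-equal values: 0/0 -> report F = 0, p = 1
    all_equal = degenerate & (ss_between == 0.0)
    f = np.where(all_equal, 0.0, f)
    p = np.where(degenerate & ~all_equal, 0.0, p)
    p = np.where(all_equal, 1.0, p)

    out = pd.DataFrame(index=m.data.index)
    for g in names:
        out[f"mean_{g}"] = means[g]
    out["F"] = f
    out["df1"] = df1
    out["df2"] = df2
    out["p_anova"] = p
    out["degenerate"] = all_equal
    return out


def bonferroni_adjust(p: Sequence[float] | np.ndarray, n_tested: int | None = None) -> np.ndarray:
    """p_adj = min(1, p * n_tested); n_tested defaults to len(p)."""
    p = np.asarray(p, dtype=float)
    n = len(p) if n_tested is None else n_tested
    return np.minimum(1.0, p * n)


def fold_changes(
    m: PeptideMatrix, group_a: Sequence[str], group_b: Sequence[str]
) -> pd.Series:
    """Per-peptide ratio of arithmetic group means, mean(A) / mean(B).

    A zero denominator yields +inf (flagged by the caller's table); empty
    groups are an error.
    """
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValidationError("empty group in fold computation")
    mean_a = m.data[list(group_a)].mean(axis=1)
    mean_b = m.data[list(group_b)].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = mean_a / mean_b
    fold[(mean_b == 0) & (mean_a > 0)] = np.inf
    fold[(mean_b == 0) & (mean_a == 0)] = np.nan
    return fold


def differential_table(
    m: PeptideMatrix,
    cluster_labels: Mapping[str, int] | pd.Series,
    nbm_samples: Sequence[str],
    alpha: float = 0.05,
    n_tested: int | None = None,
    peptides: Sequence[str] | None = None,
    test_on_log: bool = True,
) -> pd.DataFrame:
    """Full three-group differential table for the tested peptide set.

    Combines the omnibus ANOVA, the three pairwise t-tests, fold changes of
    each cluster versus NBM and cluster-2 versus cluster-1, Bonferroni
    adjustment over ``n_tested`` peptides (default: the number tested here)
    and a significance flag at ``alpha``.  With ``test_on_log`` (default)
    the tests see log2(1 + x) while folds stay in natural intensity space.
    """
    labels = as_group_series(cluster_labels)
    if peptides is not None:
        m = m.advance(m.stage, m.data.loc[list(peptides)])
    group_of = {s: f"cluster-{labels[s]}" for s in labels.index}
    group_of.update({s: "NBM" for s in nbm_samples})
    groups = pd.Series({s: group_of[s] for s in m.samples if s in group_of})

    test_m = m.advance(m.stage, np.log2(1.0 + m.data)) if test_on_log else m
    table = anova_per_peptide(test_m, groups)
    n = len(table) if n_tested is None else n_tested
    table["p_anova_bonferroni"] = bonferroni_adjust(table["p_anova"], n)

    members = {g: list(groups.index[groups == g]) for g in ("cluster-1", "cluster-2", "NBM")}
    # report group means in natural intensity space regardless of test scale
    for g, samp in members.items():
        table[f"mean_{g}"] = m.data[samp].mean(axis=1)
    pairs = [("cluster-1", "NBM"), ("cluster-2", "NBM"), ("cluster-2", "cluster-1")]
    for a, b in pairs:
        xa = test_m.data[members[a]].to_numpy(float)
        xb = test_m.data[members[b]].to_numpy(float)
        t_res = stats.ttest_ind(xa, xb, axis=1)
        key = f"{a}_vs_{b}".replace("cluster-", "c")
        p_pair = np.nan_to_num(t_res.pvalue, nan=1.0)  # zero-variance rows
        table[f"p_{key}"] = p_pair
        table[f"p_{key}_bonferroni"] = bonferroni_adjust(p_pair, n)
        table[f"fold_{key}"] = fold_changes(m, members[a], members[b])

    table["significant"] = table["p_anova_bonferroni"] < alpha
    log.info(
        "differential: %d/%d peptides significant at Bonferroni alpha=%g",
        int(table["significant"].sum()), len(table), alpha,
    )
    return table
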