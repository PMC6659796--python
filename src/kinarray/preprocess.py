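"""Spot-level preprocessing: background subtraction, quantile normalization,
triplicate-concordance QC and median collapse.

The stages run in fixed order: subtract background, quantile-normalize spot
columns across samples, exclude samples whose triplicate Pearson r-squared
falls below threshold, then collapse the triplicates to per-peptide medians.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datatypes import ArrayScanSet, PeptideMatrix, QCReport, ValidationError

log = logging.getLogger(__name__)

DEFAULT_R2_THRESHOLD = 0.6


def subtract_background(scan: ArrayScanSet) -> PeptideMatrix:
    """Background-subtracted spot intensities, floored at zero.

    Returns a spot-level matrix (rows: MultiIndex (peptide, replicate) in
    peptide-major order; columns: samples) at stage ``raw``.  Spots whose
    background exceeds the foreground are floored at 0 and counted in the
    log -- the readout is a non-negative activity.
    """
    values = scan.fg - scan.bg
    n_floored = int((values < 0).sum())
    if n_floored:
        log.info("floored %d spots with fg < bg at 0", n_floored)
    values = np.maximum(values, 0.0)
    n_s, n_p, n_r = values.shape
    index = pd.MultiIndex.from_product(
        [scan.peptides, range(1, n_r + 1)], names=["peptide_id", "replicate"]
    )
    df = pd.DataFrame(
        values.reshape(n_s, n_p * n_r).T, index=index, columns=scan.samples
    )
    return PeptideMatrix(
        data=df, stage="raw", sample_groups=scan.sample_groups()
    )


def quantile_normalize(m: PeptideMatrix) -> PeptideMatrix:
    """Classic rank/mean quantile normalization across sample columns.

    Each column is sorted, values are averaged across samples at each rank,
    and the rank-means are mapped back through each column's original
    ordering.  Ties within a column receive the mean of the rank-means they
    span.  Afterwards all tie-free columns share an identical sorted value
    multiset.
    """
    df = m.data
    if df.shape[1] < 2:
        raise ValidationError("nothing to normalize across: need >= 2 samples")
    vals = df.to_numpy(float)
    order = np.argsort(vals, axis=0, kind="stable")
    rank_means = np.take_along_axis(vals, order, axis=0).mean(axis=1)

    out = np.empty_like(vals)
    for j in range(vals.shape[1]):
        assigned = np.empty(vals.shape[0])
        assigned[order[:, j]] = rank_means
        col = vals[:, j]
        if len(np.unique(col)) != len(col):  # ties: average spanned rank-means
            assigned = pd.Series(assigned).groupby(col).transform("mean").to_numpy()
        out[:, j] = assigned
    return m.advance("normalized", pd.DataFrame(out, index=df.index, columns=df.columns))


def _replicate_pivot(m: PeptideMatrix, sample: str) -> np.ndarray:
    """(n_peptides, 3) replicate vectors for one sample."""
    col = m.data[sample]
    n_rep = len(m.data.index.get_level_values("replicate").unique())
    return col.to_numpy(float).reshape(-1, n_rep)


def replicate_concordance(m: PeptideMatrix, sample: str, method: str = "mean") -> float:
    """Triplicate concordance: pairwise squared Pearson correlations.

    ``method="mean"`` (default) averages the three pairwise r-squared values
    between replicate vectors; ``method="min"`` takes their minimum.  A
    zero-variance replicate vector makes that pair's correlation 0 (logged).
    """
    reps = _replicate_pivot(m, sample)
    n_rep = reps.shape[1]
    r2s = []
    for i in range(n_rep):
        for j in range(i + 1, n_rep):
            si, sj = reps[:, i].std(), reps[:, j].std()
            if si == 0.0 or sj == 0.0:
                log.warning("zero-variance replicate for sample %s; pair r set to 0", sample)
                r2s.append(0.0)
            else:
                r = np.corrcoef(reps[:, i], reps[:, j])[0, 1]
                r2s.append(r * r)
    if method == "mean":
        return float(np.mean(r2s))
    if method == "min":
        return float(np.min(r2s))
    raise ValidationError(f"unknown concordance method {method!r}")


def qc_filter_samples(
    m: PeptideMatrix,
    threshold: float = DEFAULT_R2_THRESHOLD,
    method: str = "mean",
) -> tuple[PeptideMatrix, QCReport]:
    """Exclude samples whose triplicate r-squared is strictly below threshold.

    Returns the matrix restricted to included samples and a QC report listing
    every sample with its concordance and decision.
    """
    r2 = {s: replicate_concordance(m, s, method=method) for s in m.samples}
    table = pd.DataFrame(
        {
            "r_squared": pd.Series(r2),
            "included": pd.Series({s: v >= threshold for s, v in r2.items()}),
        }
    )
    table.index.name = "sample_id"
    report = QCReport(table=table.loc[m.samples], threshold=threshold)
    excluded = report.excluded_samples
    for s in excluded:
        log.info("QC excluded sample %s (r^2 = %.3f < %.2f)", s, r2[s], threshold)
    if len(excluded) == len(m.samples):
        raise ValidationError("empty cohort after QC")
    return m.restrict_samples(report.included_samples), report


def collapse_replicates(m: PeptideMatrix) -> PeptideMatrix:
    """Per-(sample, peptide) median of the triplicate spots."""
    peptides = list(m.data.index.get_level_values("peptide_id").unique())
    n_rep = len(m.data.index.get_level_values("replicate").unique())
    vals = m.data.to_numpy(float).reshape(len(peptides), n_rep, -1)
    med = np.median(vals, axis=1)
    df = pd.DataFrame(med, index=pd.Index(peptides, name="peptide_id"), columns=m.data.columns)
    return m.advance("collapsed", df)


def run_preprocess(
    scan: ArrayScanSet,
    r2_threshold: float = DEFAULT_R2_THRESHOLD,
    concordance_method: str = "mean",
) -> tuple[PeptideMatrix, QCReport]:
    """Full preprocessing chain: subtract -> normalize -> QC -> collapse."""
    raw = subtract_background(scan)
    log.info("background-subtracted %d spots x %d samples", *raw.data.shape)
    normalized = quantile_normalize(raw)
    kept, report = qc_filter_samples(normalized, threshold=r2_threshold, method=concordance_method)
    log.info(
        "QC retained %d/%d samples at r^2 >= %.2f",
        len(report.included_samples), len(scan.samples), r2_threshold,
    )
    collapsed = collapse_replicates(kept)
    log.info("collapsed to %d peptides x %d samples", *collapsed.data.shape)
    return collapsed, report
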