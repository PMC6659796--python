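"""Readers and writers for the pipeline's plain-text table formats.

Three input dialects:

* spot table -- tab-separated, one row per spot, columns
  ``sample_id, group, peptide_id, replicate, fg, bg``;
* clinical table -- comma-separated, one row per sample (empty cell means
  unknown);
* dose-response table -- comma-separated long format
  ``sample, drug, concentration, viability_pct``.

All round-trips are lossless; readers never silently drop rows.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .datatypes import (
    N_REPLICATES,
    ArrayScanSet,
    ClinicalTable,
    DoseResponseRecord,
    DoseResponseSet,
    PeptideMatrix,
    QCReport,
    ValidationError,
)

log = logging.getLogger(__name__)

SPOT_COLUMNS = ["sample_id", "group", "peptide_id", "replicate", "fg", "bg"]
DOSE_COLUMNS = ["sample", "drug", "concentration", "viability_pct"]


def read_spot_table(path: str | Path) -> ArrayScanSet:
    """Read a long-format TSV of spot intensities into an :class:`ArrayScanSet`.

    Sample and peptide order follow first appearance in the file.  Every
    (sample, peptide) must carry replicates 1..3 exactly once.
    """
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = set(SPOT_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"spot table missing columns: {sorted(missing)}")
    if len(df) == 0:
        raise ValidationError("no records")
    if (df[["fg", "bg"]] < 0).any().any():
        raise ValidationError("negative intensity in spot table")

    samples = list(dict.fromkeys(df["sample_id"]))
    peptides = list(dict.fromkeys(df["peptide_id"]))
    s_idx = {s: i for i, s in enumerate(samples)}
    p_idx = {p: i for i, p in enumerate(peptides)}

    bad_rep = ~df["replicate"].isin(range(1, N_REPLICATES + 1))
    if bad_rep.any():
        row = df[bad_rep].iloc[0]
        raise ValidationError(
            f"replicate {row['replicate']} out of range for sample "
            f"{row['sample_id']}, peptide {row['peptide_id']}"
        )

    shape = (len(samples), len(peptides), N_REPLICATES)
    fg = np.full(shape, np.nan)
    bg = np.full(shape, np.nan)
    si = df["sample_id"].map(s_idx).to_numpy()
    pi = df["peptide_id"].map(p_idx).to_numpy()
    ri = df["replicate"].to_numpy(int) - 1
    if len(df) != len(set(zip(si, pi, ri))):
        raise ValidationError("duplicate (sample, peptide, replicate) rows")
    fg[si, pi, ri] = df["fg"].to_numpy(float)
    bg[si, pi, ri] = df["bg"].to_numpy(float)
    if np.isnan(fg).any():
        s, p, _ = np.argwhere(np.isnan(fg))[0]
        raise ValidationError(
            f"missing replicate for sample {samples[s]}, peptide {peptides[p]}"
        )

    groups_per_sample = df.groupby("sample_id", sort=False)["group"].agg(set)
    inconsistent = groups_per_sample[groups_per_sample.map(len) > 1]
    if len(inconsistent):
        raise ValidationError(
            f"inconsistent group labels for samples: {list(inconsistent.index)}"
        )
    group = [next(iter(groups_per_sample[s])) for s in samples]
    return ArrayScanSet(samples=samples, peptides=peptides, fg=fg, bg=bg, group=group)


def write_spot_table(scan: ArrayScanSet, path: str | Path) -> None:
    """Write an :class:`ArrayScanSet` as long-format TSV (inverse of reader)."""
    n_s, n_p, n_r = scan.fg.shape
    rows = {
        "sample_id": np.repeat(scan.samples, n_p * n_r),
        "group": np.repeat(scan.group, n_p * n_r),
        "peptide_id": np.tile(np.repeat(scan.peptides, n_r), n_s),
        "replicate": np.tile(np.arange(1, n_r + 1), n_s * n_p),
        "fg": scan.fg.ravel(),
        "bg": scan.bg.ravel(),
    }
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_clinical_table(path: str | Path) -> ClinicalTable:
    """Read the per-sample clinical CSV; empty cells become unknown/NaN."""
    try:
        df = pd.read_csv(path, index_col="sample_id", float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise ValidationError("no records") from None
    if len(df) == 0:
        raise ValidationError("no records")
    df["sex"] = df["sex"].fillna("unknown")
    df["source"] = df["source"].fillna("unknown")
    return ClinicalTable(data=df)


def write_clinical_table(table: ClinicalTable, path: str | Path) -> None:
    table.data.to_csv(path, index_label="sample_id")


def read_dose_response(path: str | Path) -> DoseResponseSet:
    """Read the long-format viability CSV, grouping rows per (sample, drug).

    Concentrations are sorted ascending within each record; a duplicated
    concentration for one (sample, drug) is an error.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(DOSE_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"dose-response table missing columns: {sorted(missing)}")
    records = []
    for (sample, drug), grp in df.groupby(["sample", "drug"], sort=False):
        grp = grp.sort_values("concentration")
        conc = grp["concentration"].to_numpy(float)
        if np.any(np.diff(conc) == 0):
            raise ValidationError(f"duplicate concentration for {sample}/{drug}")
        records.append(
            DoseResponseRecord(
                sample=str(sample),
                drug=str(drug),
                concentrations=conc,
                viability_pct=grp["viability_pct"].to_numpy(float),
            )
        )
    return DoseResponseSet(records=records)


def write_dose_response(drset: DoseResponseSet, path: str | Path) -> None:
    frames = [
        pd.DataFrame(
            {
                "sample": rec.sample,
                "drug": rec.drug,
                "concentration": rec.concentrations,
                "viability_pct": rec.viability_pct,
            }
        )
        for rec in drset.records
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# pipeline outputs

def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def write_outputs(
    directory: str | Path,
    run_report: dict,
    normalized_matrix: PeptideMatrix | None = None,
    qc_report: QCReport | None = None,
    cluster_labels: pd.Series | None = None,
    gap_curve: pd.DataFrame | None = None,
    differential_table: pd.DataFrame | None = None,
    outcome_tests: dict | None = None,
    lc50_table: pd.DataFrame | None = None,
) -> list[str]:
    """Write whichever pipeline products are supplied; return the manifest.

    Output is deterministic for identical inputs: JSON keys are sorted and
    the run report carries no timestamps.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest: list[str] = []

    def emit(name: str, writer) -> None:
        path = directory / name
        writer(path)
        manifest.append(name)

    if normalized_matrix is not None:
        emit(
            "normalized_matrix.tsv",
            lambda p: normalized_matrix.data.to_csv(p, sep="\t", index_label="peptide_id"),
        )
    if qc_report is not None:
        emit(
            "qc_report.csv",
            lambda p: qc_report.table.to_csv(p, index_label="sample_id"),
        )
    if cluster_labels is not None:
        emit(
            "cluster_labels.csv",
            lambda p: cluster_labels.rename("cluster").to_csv(p, index_label="sample_id"),
        )
    if gap_curve is not None:
        emit("gap_curve.csv", lambda p: gap_curve.to_csv(p, index_label="k"))
    if differential_table is not None:
        emit(
            "differential.tsv",
            lambda p: differential_table.to_csv(p, sep="\t", index_label="peptide_id"),
        )
    if outcome_tests is not None:
        emit("outcome_tests.json", lambda p: _json_dump(outcome_tests, p))
    if lc50_table is not None:
        emit("lc50.csv", lambda p: lc50_table.to_csv(p, index=False))

    report = dict(run_report)
    report["software_version"] = __version__
    report["manifest"] = manifest + ["run_report.json"]
    emit("run_report.json", lambda p: _json_dump(report, p))
    log.info("wrote %d artifacts to %s", len(manifest), directory)
    return manifest
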