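"""Core domain types for kinome peptide-microarray analysis.

The pipeline moves data through a fixed sequence of representations: raw
spot-level scans (:class:`ArrayScanSet`), a feature-by-sample matrix that is
tagged with its processing stage (:class:`PeptideMatrix`), and small result
containers for QC, clustering, statistics and dose-response readouts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: processing stages, in the only order transitions are allowed
STAGES = ("raw", "normalized", "collapsed", "filtered", "scaled")

N_REPLICATES = 3

VALID_GROUPS = ("AML", "NBM")


class ValidationError(ValueError):
    """Input violates a structural or domain invariant."""


@dataclass
class ArrayScanSet:
    """Spot-level intensities for a cohort of arrays.

    Each sample's array carries every peptide spotted in triplicate; ``fg``
    and ``bg`` hold foreground and local-background intensity for each
    (sample, peptide, replicate) spot.

    Parameters
    ----------
    samples : ordered sample identifiers
    peptides : ordered peptide identifiers (unique)
    fg, bg : float arrays of shape ``(n_samples, n_peptides, 3)``
    group : per-sample label, ``"AML"`` or ``"NBM"``
    """

    samples: list[str]
    peptides: list[str]
    fg: np.ndarray
    bg: np.ndarray
    group: list[str]

    def __post_init__(self) -> None:
        self.fg = np.asarray(self.fg, dtype=float)
        self.bg = np.asarray(self.bg, dtype=float)
        n_s, n_p = len(self.samples), len(self.peptides)
        expected = (n_s, n_p, N_REPLICATES)
        if self.fg.shape != expected or self.bg.shape != expected:
            raise ValidationError(
                f"intensity arrays must have shape {expected}; "
                f"got fg {self.fg.shape}, bg {self.bg.shape}"
            )
        if len(set(self.peptides)) != n_p:
            raise ValidationError("peptide identifiers must be unique")
        if len(set(self.samples)) != n_s:
            raise ValidationError("sample identifiers must be unique")
        if len(self.group) != n_s:
            raise ValidationError("one group label per sample required")
        bad = set(self.group) - set(VALID_GROUPS)
        if bad:
            raise ValidationError(f"unknown group labels: {sorted(bad)}")
        if np.any(self.fg < 0) or np.any(self.bg < 0):
            raise ValidationError("intensities must be non-negative")
        if not (np.isfinite(self.fg).all() and np.isfinite(self.bg).all()):
            raise ValidationError("intensities must be finite")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_peptides(self) -> int:
        return len(self.peptides)

    def sample_groups(self) -> dict[str, str]:
        return dict(zip(self.samples, self.group))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ArrayScanSet):
            return NotImplemented
        return (
            self.samples == other.samples
            and self.peptides == other.peptides
            and self.group == other.group
            and np.array_equal(self.fg, other.fg)
            and np.array_equal(self.bg, other.bg)
        )


@dataclass
class PeptideMatrix:
    """Feature-by-sample activation matrix with a processing-stage tag.

    ``data`` rows are features -- at the spot-level stages (``raw``,
    ``normalized``) a MultiIndex ``(peptide_id, replicate)``, afterwards a
    plain peptide index -- and columns are samples.  ``stage`` records where
    in the pipeline the values sit; transitions may only move forward through
    :data:`STAGES`.
    """

    data: pd.DataFrame
    stage: str
    log_applied: bool = False
    scaled: bool = False
    sample_groups: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValidationError(f"unknown stage {self.stage!r}")
        if self.stage in ("collapsed", "filtered", "scaled") and self.data.isna().any().any():
            raise ValidationError(f"missing values not allowed at stage {self.stage!r}")

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    def advance(self, new_stage: str, data: pd.DataFrame, **flags) -> "PeptideMatrix":
        """Return a copy at ``new_stage``, enforcing forward-only transitions."""
        if STAGES.index(new_stage) < STAGES.index(self.stage):
            raise ValidationError(
                f"cannot move from stage {self.stage!r} back to {new_stage!r}"
            )
        kwargs = dict(
            log_applied=self.log_applied,
            scaled=self.scaled,
            sample_groups=self.sample_groups,
        )
        kwargs.update(flags)
        return PeptideMatrix(data=data, stage=new_stage, **kwargs)

    def restrict_samples(self, keep: Sequence[str]) -> "PeptideMatrix":
        keep = [s for s in self.samples if s in set(keep)]
        return replace(self, data=self.data[keep])


@dataclass
class QCReport:
    """Per-sample triplicate-concordance decisions.

    ``table`` has one row per sample with columns ``r_squared`` and
    ``included``; a sample is included iff its concordance is at least
    ``threshold``.
    """

    table: pd.DataFrame
    threshold: float

    def __post_init__(self) -> None:
        ok = self.table["included"] == (self.table["r_squared"] >= self.threshold)
        if not ok.all():
            raise ValidationError("QC inclusion flags inconsistent with threshold")

    @property
    def included_samples(self) -> list[str]:
        return list(self.table.index[self.table["included"]])

    @property
    def excluded_samples(self) -> list[str]:
        return list(self.table.index[~self.table["included"]])


@dataclass
class ClinicalTable:
    """Per-sample clinical covariates and outcomes, indexed by sample id.

    Times are in months; event indicators are 0/1; ``sex`` is one of
    ``M``/``F``/``unknown`` (unknowns are preserved, never imputed).
    """

    COLUMNS = (
        "age", "sex", "source", "blast_pct", "wbc", "rbc", "plt",
        "relapse", "time_to_relapse", "death", "followup_time",
        "complete_response",
    )

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.data.columns)
        if missing:
            raise ValidationError(f"clinical table missing columns: {sorted(missing)}")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].tolist()
            raise ValidationError(f"duplicate sample ids: {dups}")
        if len(self.data) == 0:
            raise ValidationError("no records")
        for col in ("time_to_relapse", "followup_time"):
            vals = self.data[col].dropna()
            if (vals < 0).any():
                raise ValidationError(f"negative time in column {col!r}")
        for col in ("relapse", "death", "complete_response"):
            vals = self.data[col].dropna()
            if not vals.isin([0, 1]).all():
                raise ValidationError(f"non-binary indicator in column {col!r}")

    @property
    def samples(self) -> list[str]:
        return list(self.data.index)


@dataclass
class DoseResponseRecord:
    """One viability curve: ascending drug concentrations vs % viability."""

    sample: str
    drug: str
    concentrations: np.ndarray
    viability_pct: np.ndarray
    conc_unit: str = ""

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.viability_pct = np.asarray(self.viability_pct, dtype=float)
        if self.concentrations.shape != self.viability_pct.shape:
            raise ValidationError("concentration/viability length mismatch")
        if np.any(self.concentrations <= 0):
            raise ValidationError(
                f"non-positive concentration for {self.sample}/{self.drug}"
            )
        if np.any(np.diff(self.concentrations) <= 0):
            raise ValidationError(
                f"concentrations not strictly increasing for {self.sample}/{self.drug}"
            )
        if not np.isfinite(self.viability_pct).all():
            raise ValidationError(
                f"non-finite viability for {self.sample}/{self.drug}"
            )


@dataclass
class DoseResponseSet:
    """Collection of dose-response curves, one record per (sample, drug)."""

    records: list[DoseResponseRecord]

    def __post_init__(self) -> None:
        keys = [(r.sample, r.drug) for r in self.records]
        if len(set(keys)) != len(keys):
            raise ValidationError("duplicate (sample, drug) record")

    def by_drug(self) -> dict[str, list[DoseResponseRecord]]:
        out: dict[str, list[DoseResponseRecord]] = {}
        for rec in self.records:
            out.setdefault(rec.drug, []).append(rec)
        return out


@dataclass
class TestResult:
    """Generic statistical-test output: statistic, optional df, two-sided p."""

    statistic: float
    p_value: float
    method: str
    df: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValidationError(f"p-value {self.p_value} outside [0, 1]")

    def as_dict(self) -> dict:
        return {
            "statistic": float(self.statistic),
            "df": None if self.df is None else float(self.df),
            "p_value": float(self.p_value),
            "method": self.method,
        }


#: LC50 estimation outcomes
LC50_STATUSES = ("interpolated", "exact_50", "censored_above_max", "censored_below_min")


@dataclass
class LC50Result:
    """LC50 for one (sample, drug) curve.

    ``lc50`` is the interpolated concentration when the curve crosses 50%
    viability; for censored curves it holds the boundary concentration and
    ``status`` records the direction of censoring.
    """

    sample: str
    drug: str
    lc50: float
    status: str
    bracket: tuple[float, float] | None = None
    conc_min: float = np.nan
    conc_max: float = np.nan

    def __post_init__(self) -> None:
        if self.status not in LC50_STATUSES:
            raise ValidationError(f"unknown LC50 status {self.status!r}")
        if self.status == "interpolated":
            lo, hi = self.bracket
            if not (lo <= self.lc50 <= hi):
                raise ValidationError(
                    f"interpolated LC50 {self.lc50} outside bracket [{lo}, {hi}]"
                )


@dataclass
class ClusterResult:
    """Output of the clustering stage.

    ``linkage`` is a scipy-format merge table; ``labels`` maps each k in
    ``1..k_max`` to integer labels (1-based, numbered by first-member order);
    ``w``, ``gap`` and ``s`` are the per-k within-cluster dispersion, gap
    statistic and reference-spread terms; ``k_hat`` is the selected number of
    clusters.
    """

    samples: list[str]
    linkage: np.ndarray
    labels: dict[int, np.ndarray]
    w: np.ndarray
    gap: np.ndarray
    s: np.ndarray
    k_hat: int
    kept_peptides: list[str] = field(default_factory=list)

    def labels_at(self, k: int | None = None) -> pd.Series:
        k = self.k_hat if k is None else k
        return pd.Series(self.labels[k], index=self.samples, name="cluster")

    def cluster_sizes(self, k: int | None = None) -> dict[int, int]:
        lab = self.labels_at(k)
        return {int(c): int(n) for c, n in lab.value_counts().sort_index().items()}


def as_group_series(groups: Mapping[str, str] | pd.Series) -> pd.Series:
    """Normalize a sample->group mapping to a pandas Series."""
    if isinstance(groups, pd.Series):
        return groups
    return pd.Series(dict(groups))
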