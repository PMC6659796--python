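"""Synthetic AML kinome-array cohorts with known ground truth.

The generator emulates the statistical structure the analysis assumes: a
976-peptide array spotted in triplicate, lognormal spot intensities over a
lognormal background floor, a binary two-cluster activation pattern on a
subset of informative peptides, a handful of low-concordance (corrupt)
samples appended beyond the nominal cohort, CD34+ normal-bone-marrow (NBM)
control arrays drawn from the baseline, clinical covariates and censored
outcomes whose relapse probability differs by cluster, and sigmoid viability
curves whose true LC50 distributions differ by cluster by a configured fold.

Every draw is reproducible from ``SimConfig.seed``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    ArrayScanSet,
    ClinicalTable,
    DoseResponseRecord,
    DoseResponseSet,
    ValidationError,
)

#: drug concentration grids (log-spaced over the assay ranges);
#: mitoxantrone and amsacrine in ug/mL, etoposide in uM
DRUG_GRIDS: dict[str, np.ndarray] = {
    "mitoxantrone": np.logspace(-2, 1, 7),
    "etoposide": np.logspace(-2, 2, 9),
    "amsacrine": np.logspace(-2, 1, 7),
}

DRUG_UNITS = {"mitoxantrone": "ug/mL", "etoposide": "uM", "amsacrine": "ug/mL"}


def _default_folds() -> dict[str, float]:
    return {"mitoxantrone": 31.0, "etoposide": 31.0, "amsacrine": 104.0}


def _default_centers() -> dict[str, float]:
    # cluster-1 median true LC50, placed so that cluster-2 = center x fold
    # still sits inside the assay concentration range
    return {"mitoxantrone": 0.056, "etoposide": 0.178, "amsacrine": 0.056}


@dataclass
class SimConfig:
    """Cohort-generator parameters.

    Cohort composition defaults mirror the study design they emulate:
    96 evaluable AML samples plus 4 corrupt extras (100 arrays run), 4 NBM
    controls, 976 peptides of which 192 carry the two-cluster signal, cluster
    sizes 39/57, relapse probability 0.26 vs 0.47 per cluster, and median
    LC50 folds of 31/31/104 for mitoxantrone/etoposide/amsacrine.  Noise
    magnitudes (log-scale spreads) are generator choices, exposed here.
    """

    n_aml: int = 96
    n_corrupt_extra: int = 4
    n_nbm: int = 4
    n_peptides: int = 976
    n_informative: int = 192
    cluster_sizes: tuple[int, int] = (39, 57)
    relapse_prob: tuple[float, float] = (0.26, 0.47)

    # spot-level intensity model (log-scale parameters)
    intensity_scale: float = 500.0     # median peptide activity, arbitrary counts
    peptide_sdlog: float = 0.4         # spread of per-peptide baseline activity
    bio_sdlog: float = 0.3             # per-(sample, peptide) biological noise
    effect_size: float = 1.5           # cluster-1 vs cluster-2 log shift on informative peptides
    background_scale: float = 50.0
    background_sdlog: float = 0.3
    replicate_sdlog: float = 0.05      # triplicate spot noise (clean samples)
    corrupt_noise_multiplier: float = 20.0

    # clinical covariates (location, spread) and outcome rates
    age_mean: float = 8.3
    age_sd: float = 4.7
    blast_mean: float = 71.7
    blast_sd: float = 20.0
    wbc_mean: float = 29.9
    wbc_sd: float = 22.1
    rbc_mean: float = 4.4
    rbc_sd: float = 1.4
    plt_mean: float = 37.9
    plt_sd: float = 30.0
    male_frac: float = 0.656
    female_frac: float = 0.313         # remainder is unknown
    death_prob: float = 43 / 96
    cr_prob: float = 64 / 96
    relapse_time_mean: float = 12.0    # months, exponential
    relapse_censor_range: tuple[float, float] = (24.0, 60.0)
    death_time_mean: float = 24.0
    censor_time_range: tuple[float, float] = (36.0, 72.0)

    # chemosensitivity
    median_lc50_fold: dict[str, float] = field(default_factory=_default_folds)
    lc50_center: dict[str, float] = field(default_factory=_default_centers)
    lc50_sdlog10: float = 0.07
    hill_slope: float = 1.0
    viability_noise_pct: float = 2.0
    n_chemo_per_cluster: int = 5

    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.cluster_sizes) != self.n_aml:
            raise ValidationError(
                f"cluster sizes {self.cluster_sizes} must sum to n_aml={self.n_aml}"
            )
        if not all(0.0 <= p <= 1.0 for p in self.relapse_prob):
            raise ValidationError("relapse probabilities must lie in [0, 1]")
        if self.n_informative > self.n_peptides:
            raise ValidationError("n_informative exceeds n_peptides")
        if set(self.median_lc50_fold) != set(self.lc50_center):
            raise ValidationError("median_lc50_fold and lc50_center drugs differ")


@dataclass
class SyntheticTruth:
    """Ground truth behind one generated cohort."""

    labels: dict[str, int]                  # true cluster per AML sample (incl. corrupt)
    informative_up_c1: list[str]            # peptides shifted up in cluster-1
    informative_up_c2: list[str]
    corrupt_samples: list[str]
    nbm_samples: list[str]
    chemo_samples: list[str]
    true_lc50: dict[str, dict[str, float]]  # drug -> sample -> LC50
    relapse_prob: tuple[float, float]

    def __post_init__(self) -> None:
        if set(self.corrupt_samples) & set(self.nbm_samples):
            raise ValidationError("corrupt samples must be disjoint from NBM")
        if set(self.informative_up_c1) & set(self.informative_up_c2):
            raise ValidationError("informative directions must partition peptides")


def hill_viability(conc: np.ndarray, lc50: float, hill: float = 1.0) -> np.ndarray:
    """Sigmoid viability curve: 100 / (1 + (c / LC50)^h) percent."""
    conc = np.asarray(conc, dtype=float)
    return 100.0 / (1.0 + (conc / lc50) ** hill)


def _sample_ids(config: SimConfig) -> tuple[list[str], list[str]]:
    n_arrays = config.n_aml + config.n_corrupt_extra
    aml = [f"AML_{i + 1:03d}" for i in range(n_arrays)]
    nbm = [f"NBM_{i + 1:02d}" for i in range(config.n_nbm)]
    return aml, nbm


def generate_cohort(config: SimConfig) -> tuple[ArrayScanSet, ClinicalTable, SyntheticTruth]:
    """Generate one synthetic cohort: spot scans, clinical table, truth.

    Spot model: ``fg = bg + activity * replicate_noise`` with lognormal
    background and per-peptide lognormal baseline activity; informative
    peptides are shifted by +-effect_size/2 on the log scale according to
    cluster membership (NBM arrays carry no shift); corrupt samples use a
    replicate-noise multiplier large enough that triplicate concordance
    falls below the QC threshold.
    """
    rng = np.random.default_rng(config.seed)
    aml_ids, nbm_ids = _sample_ids(config)
    corrupt_ids = aml_ids[config.n_aml:]
    peptides = [f"pep_{i + 1:04d}" for i in range(config.n_peptides)]

    # cluster assignment: shuffled within the nominal cohort, proportional
    # draw for the corrupt extras
    base = np.concatenate(
        [np.ones(config.cluster_sizes[0], int), np.full(config.cluster_sizes[1], 2)]
    )
    labels = rng.permutation(base)
    p1 = config.cluster_sizes[0] / config.n_aml
    extra = rng.choice([1, 2], size=config.n_corrupt_extra, p=[p1, 1 - p1])
    labels = np.concatenate([labels, extra])
    label_map = dict(zip(aml_ids, (int(v) for v in labels)))

    # informative peptides and their directions (half up in each cluster)
    info_idx = rng.choice(config.n_peptides, size=config.n_informative, replace=False)
    directions = np.ones(config.n_informative)
    directions[config.n_informative // 2:] = -1.0
    directions = rng.permutation(directions)
    up_c1 = [peptides[i] for i, d in zip(info_idx, directions) if d > 0]
    up_c2 = [peptides[i] for i, d in zip(info_idx, directions) if d < 0]

    # log-scale activity
    mu_p = np.log(config.intensity_scale) + rng.normal(0.0, config.peptide_sdlog, config.n_peptides)
    n_arrays = len(aml_ids)
    n_total = n_arrays + config.n_nbm
    shift = np.zeros((n_total, config.n_peptides))
    sign = np.where(labels == 1, 1.0, -1.0)  # cluster-1 up for direction +1
    shift[:n_arrays, info_idx] = np.outer(sign, directions) * config.effect_size / 2.0

    log_act = mu_p[None, :] + shift + rng.normal(0.0, config.bio_sdlog, (n_total, config.n_peptides))
    activity = np.exp(log_act)

    rep_sd = np.full(n_total, config.replicate_sdlog)
    rep_sd[config.n_aml:n_arrays] *= config.corrupt_noise_multiplier
    rep_noise = np.exp(rng.normal(0.0, 1.0, (n_total, config.n_peptides, 3)) * rep_sd[:, None, None])
    spots = activity[:, :, None] * rep_noise

    bg = np.exp(rng.normal(np.log(config.background_scale), config.background_sdlog,
                           (n_total, config.n_peptides, 3)))
    fg = bg + spots

    scan = ArrayScanSet(
        samples=aml_ids + nbm_ids,
        peptides=peptides,
        fg=fg,
        bg=bg,
        group=["AML"] * n_arrays + ["NBM"] * config.n_nbm,
    )

    clinical = generate_clinical(config, aml_ids, labels, rng)

    # chemosensitivity subset: non-corrupt samples only, per cluster
    evaluable = np.array(aml_ids[: config.n_aml])
    eval_labels = labels[: config.n_aml]
    chemo_samples: list[str] = []
    for c in (1, 2):
        pool = evaluable[eval_labels == c]
        chemo_samples.extend(rng.choice(pool, size=config.n_chemo_per_cluster, replace=False))
    # cluster-2 true LC50s are the cluster-1 distribution scaled by the
    # configured fold: matched multiplier draws make the true median fold
    # exactly the configured value
    true_lc50: dict[str, dict[str, float]] = {}
    c1_samples = [s for s in chemo_samples if label_map[s] == 1]
    c2_samples = [s for s in chemo_samples if label_map[s] == 2]
    for drug, center in config.lc50_center.items():
        fold = config.median_lc50_fold[drug]
        mult = 10.0 ** rng.normal(0.0, config.lc50_sdlog10, max(len(c1_samples), len(c2_samples)))
        per_sample = {}
        for i, s in enumerate(c1_samples):
            per_sample[s] = float(center * mult[i])
        for i, s in enumerate(c2_samples):
            per_sample[s] = float(center * fold * mult[i])
        true_lc50[drug] = per_sample

    truth = SyntheticTruth(
        labels=label_map,
        informative_up_c1=up_c1,
        informative_up_c2=up_c2,
        corrupt_samples=list(corrupt_ids),
        nbm_samples=list(nbm_ids),
        chemo_samples=list(chemo_samples),
        true_lc50=true_lc50,
        relapse_prob=tuple(config.relapse_prob),
    )
    return scan, clinical, truth


def generate_clinical(
    config: SimConfig,
    sample_ids: list[str],
    labels: np.ndarray,
    rng: np.random.Generator,
) -> ClinicalTable:
    """Draw clinical covariates and censored outcomes for AML samples.

    Covariates are cluster-independent; relapse probability depends on the
    true cluster.  Event times are exponential, censoring times uniform.
    """
    n = len(sample_ids)
    labels = np.asarray(labels)
    age = np.clip(rng.normal(config.age_mean, config.age_sd, n), 0.1, 18.0)
    sex = rng.choice(
        ["M", "F", "unknown"],
        size=n,
        p=[config.male_frac, config.female_frac, 1 - config.male_frac - config.female_frac],
    )
    source = rng.choice(["PB", "BM"], size=n)
    blast = np.clip(rng.normal(config.blast_mean, config.blast_sd, n), 1.0, 100.0)
    wbc = np.clip(rng.normal(config.wbc_mean, config.wbc_sd, n), 0.5, None)
    rbc = np.clip(rng.normal(config.rbc_mean, config.rbc_sd, n), 0.5, None)
    plt = np.clip(rng.normal(config.plt_mean, config.plt_sd, n), 1.0, None)

    p_rel = np.where(labels == 1, config.relapse_prob[0], config.relapse_prob[1])
    relapse = (rng.uniform(size=n) < p_rel).astype(int)
    event_t = rng.exponential(config.relapse_time_mean, n)
    censor_t = rng.uniform(*config.relapse_censor_range, n)
    time_to_relapse = np.where(relapse == 1, event_t, censor_t)

    death = (rng.uniform(size=n) < config.death_prob).astype(int)
    death_t = rng.exponential(config.death_time_mean, n)
    fu_censor = rng.uniform(*config.censor_time_range, n)
    followup = np.where(death == 1, death_t, fu_censor)

    cr = (rng.uniform(size=n) < config.cr_prob).astype(int)

    df = pd.DataFrame(
        {
            "age": age,
            "sex": sex,
            "source": source,
            "blast_pct": blast,
            "wbc": wbc,
            "rbc": rbc,
            "plt": plt,
            "relapse": relapse,
            "time_to_relapse": time_to_relapse,
            "death": death,
            "followup_time": followup,
            "complete_response": cr,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return ClinicalTable(data=df)


def generate_dose_response(config: SimConfig, truth: SyntheticTruth) -> DoseResponseSet:
    """Evaluate sigmoid viability curves on the assay concentration grids.

    viability(c) = 100 / (1 + (c / LC50_true)^h) plus bounded uniform
    observation noise, clipped to [0, 100].
    """
    rng = np.random.default_rng([config.seed, 7])
    records = []
    for drug in sorted(truth.true_lc50):
        grid = DRUG_GRIDS[drug]
        for sample, lc50 in truth.true_lc50[drug].items():
            v = hill_viability(grid, lc50, config.hill_slope)
            noise = rng.uniform(-config.viability_noise_pct, config.viability_noise_pct, grid.shape)
            v = np.clip(v + noise, 0.0, 100.0)
            records.append(
                DoseResponseRecord(
                    sample=sample,
                    drug=drug,
                    concentrations=grid,
                    viability_pct=v,
                    conc_unit=DRUG_UNITS.get(drug, ""),
                )
            )
    return DoseResponseSet(records=records)


def export_truth(truth: SyntheticTruth, path: str | Path) -> None:
    """Serialize ground truth to JSON (lossless round-trip)."""
    Path(path).write_text(json.dumps(asdict(truth), indent=2, sort_keys=True) + "\n")


def load_truth(path: str | Path) -> SyntheticTruth:
    raw = json.loads(Path(path).read_text())
    raw["relapse_prob"] = tuple(raw["relapse_prob"])
    raw["labels"] = {k: int(v) for k, v in raw["labels"].items()}
    return SyntheticTruth(**raw)
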