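import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from kinarray import preprocess as pre
from kinarray.cluster import run_clustering
from kinarray.simulate import SimConfig, generate_cohort, generate_dose_response

settings.register_profile(
    "default", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_cohort():
    """One full-size synthetic cohort (seed 1) shared across tests."""
    cfg = SimConfig(seed=1)
    scan, clinical, truth = generate_cohort(cfg)
    return cfg, scan, clinical, truth


@pytest.fixture(scope="session")
def normalized_spots(default_cohort):
    """Background-subtracted, quantile-normalized spot-level matrix."""
    _, scan, _, _ = default_cohort
    return pre.quantile_normalize(pre.subtract_background(scan))


@pytest.fixture(scope="session")
def preprocessed(normalized_spots):
    """(collapsed matrix, QC report) for the shared cohort."""
    kept, report = pre.qc_filter_samples(normalized_spots)
    return pre.collapse_replicates(kept), report


@pytest.fixture(scope="session")
def cluster_outcome(preprocessed):
    """Clustering result on the shared cohort's AML samples."""
    collapsed, _ = preprocessed
    groups = collapsed.sample_groups or {}
    aml = [s for s in collapsed.samples if groups.get(s) == "AML"]
    return run_clustering(collapsed.restrict_samples(aml), seed=1)


@pytest.fixture(scope="session")
def dose_response(default_cohort):
    cfg, _, _, truth = default_cohort
    return generate_dose_response(cfg, truth)


@pytest.fixture
def small_config():
    """A miniature cohort configuration for fast structural tests."""
    return SimConfig(
        n_aml=8,
        n_corrupt_extra=2,
        n_nbm=2,
        n_peptides=20,
        n_informative=6,
        cluster_sizes=(4, 4),
        n_chemo_per_cluster=2,
        seed=3,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
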