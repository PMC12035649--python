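import pytest

from mpith.cluster import cluster_all
from mpith.nmf import extract_programs
from mpith.preprocess import normalize_for_nmf, qc_filter_cells, qc_filter_genes
from mpith.robust import ProgramSet, select_robust
from mpith.synthetic import default_cohort_config, simulate_cohort


@pytest.fixture(scope="session")
def cohort_world():
    """The default planted world: 8 samples x 300 cells, 3 shared programs."""
    cfg = default_cohort_config(seed=11)
    samples, truth = simulate_cohort(cfg)
    return cfg, samples, truth


@pytest.fixture(scope="session")
def qcd_samples(cohort_world):
    _, samples, _ = cohort_world
    out = []
    for s in samples:
        s = qc_filter_cells(s)
        s = qc_filter_genes(s)
        normalize_for_nmf(s)
        out.append(s)
    return out


@pytest.fixture(scope="session")
def program_pool(qcd_samples) -> ProgramSet:
    programs = []
    for s in qcd_samples:
        programs.extend(extract_programs(s, seed=0))
    return ProgramSet(programs)


@pytest.fixture(scope="session")
def robust_pool(program_pool) -> ProgramSet:
    return select_robust(program_pool)


@pytest.fixture(scope="session")
def meta_programs(robust_pool):
    return cluster_all(robust_pool)
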