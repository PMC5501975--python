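import numpy as np
import pytest

from mirmeta import CohortSimConfig, simulate_cohorts
from mirmeta.cohort_stats import cohort_gene_stats

#: the miR-21-5p mature sequence, used throughout as the query miRNA
MIR21 = "UAGCUUAUCAGACUGAUGUUGA"


@pytest.fixture(scope="session")
def mirna():
    return MIR21


def standard_run(seed: int, n_perm: int = 999):
    """The reference synthetic study: 3 cohorts, 500 genes, 5 planted
    targets (slope -1, miRNA shift +2, noise sd 1), 30+30 samples, 20
    matched.  Returns (cohorts, truth, pooled per-gene stats)."""
    configs = [
        CohortSimConfig(name=f"c{i + 1}", seed=seed * 101 + i) for i in range(3)
    ]
    cohorts, truth = simulate_cohorts(configs)
    stats = []
    root = np.random.SeedSequence(seed)
    for cohort, child in zip(cohorts, root.spawn(len(cohorts))):
        stats.extend(cohort_gene_stats(cohort, n_perm=n_perm, seed=child))
    return cohorts, truth, stats


@pytest.fixture(scope="session")
def reference_run():
    return standard_run(seed=1)
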