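import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import sdapower as sp

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_table(pop_sizes, genotypes, locus_names=None, ids=None):
    """Small-table helper: genotypes is (n, L, 2) list/array of allele codes."""
    alleles = np.asarray(genotypes, dtype=np.int64)
    n = alleles.shape[0]
    labels = []
    for pop, size in pop_sizes.items():
        labels.extend([pop] * size)
    assert len(labels) == n
    if ids is None:
        ids = [f"ind{i}" for i in range(n)]
    if locus_names is None:
        locus_names = [f"loc{j}" for j in range(alleles.shape[1])]
    return sp.GenotypeTable(
        individual_ids=ids,
        population_labels=labels,
        locus_names=locus_names,
        alleles=alleles,
    )


@pytest.fixture(scope="session")
def starling_table():
    """The default study conditions: 3 pops (30/32/32) x 29 loci."""
    table, truth = sp.simulate_starling_like(seed=7)
    return table, truth


@pytest.fixture
def two_pop_table():
    """Well-differentiated two-population toy (fixed alternative alleles at
    most loci plus one shared locus)."""
    rng = np.random.default_rng(3)
    n = 12
    geno_a = np.stack(
        [rng.choice([1, 2], size=(n, 5, 2), p=[0.9, 0.1])], axis=0
    )[0]
    geno_b = np.stack(
        [rng.choice([2, 3], size=(n, 5, 2), p=[0.1, 0.9])], axis=0
    )[0]
    return make_table(
        {"A": n, "B": n}, np.concatenate([geno_a, geno_b], axis=0)
    )
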