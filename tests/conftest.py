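import numpy as np
import pytest

from koaudit.core import CountMatrix
from koaudit.simulate import (
    scenario_config,
    simulate_annotation,
    simulate_counts,
    simulate_variants,
)

SMALL = dict(
    n_genes=600,
    n_chromosomes=2,
    chrom_length=20_000_000,
    region_start=4_000_000,
    region_end=10_000_000,
    n_cis_deregulated=40,
    signature_size=40,
    family_size=8,
)


@pytest.fixture(scope="session")
def small_gc_config():
    return scenario_config("GC", seed=101, **SMALL)


@pytest.fixture(scope="session")
def small_gc_annotation(small_gc_config):
    return simulate_annotation(small_gc_config)


@pytest.fixture(scope="session")
def small_gc_data(small_gc_config, small_gc_annotation):
    counts, truth = simulate_counts(small_gc_config, small_gc_annotation)
    return counts, truth


@pytest.fixture(scope="session")
def small_gc_variants(small_gc_config, small_gc_annotation):
    return simulate_variants(small_gc_config, small_gc_annotation)


@pytest.fixture()
def tiny_counts():
    rng = np.random.default_rng(0)
    counts = rng.poisson(50, size=(30, 4))
    genes = [f"g{i:03d}" for i in range(30)]
    samples = ["a1", "a2", "b1", "b2"]
    groups = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
    return CountMatrix(genes=genes, samples=samples, counts=counts,
                       groups=groups)
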