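import numpy as np
import pytest

from radmap import simcross


@pytest.fixture(scope="session")
def small_genome():
    """120 kb, two scaffolds, one modest repeat family, 5% genes."""
    return simcross.simulate_genome(
        n_scaffolds=2,
        scaffold_lengths=[70_000, 50_000],
        repeat_family_specs=[(300, 25, 0.02)],
        gene_density=0.05,
        seed=101,
    )


@pytest.fixture(scope="session")
def plain_genome():
    """60 kb, no repeats (round-trip alignment fixtures)."""
    return simcross.simulate_genome(
        n_scaffolds=2,
        scaffold_lengths=[35_000, 25_000],
        repeat_family_specs=[],
        gene_density=0.05,
        seed=202,
    )


@pytest.fixture(scope="session")
def small_cross(plain_genome):
    """SNP-only parents and a small progeny set over the plain genome."""
    parents = simcross.simulate_parents(
        plain_genome,
        het_rate_maternal=0.0003,
        het_rate_paternal=0.0037,
        snp_frac=1.0,
        repeat_insertions_per_mb=0.0,
        seed=7,
    )
    progeny = simcross.simulate_f1(parents, truth_cm_per_mb=30.0, n_progeny=8, seed=8)
    return parents, progeny


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
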