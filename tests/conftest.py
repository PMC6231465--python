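import numpy as np
import pytest

from milupop.genome_io import VariantTable
from milupop.simulate import SimConfig, simulate_genome, simulate_inbred_cohort


@pytest.fixture(scope="session")
def small_genome():
    """3 x 2 Mb genome with 500-kb density blocks (fast, all stages exercised)."""
    cfg = SimConfig(seed=7, n_scaffolds=3, scaffold_length=2_000_000,
                    block_mean_low_bp=500_000, block_mean_high_bp=500_000,
                    state_coverage_tol=0.05)
    return simulate_genome(cfg)


@pytest.fixture(scope="session")
def small_cohort():
    """4 x 5 Mb inbred cohort at F = 0.125 on a ~2-kb SNP lattice."""
    cfg = SimConfig(seed=13, n_scaffolds=4, scaffold_length=5_000_000, F=0.125)
    return simulate_inbred_cohort(cfg)


def make_table(pos, genotypes, samples=None, scaffold="scf1", qual=None,
               depth=None):
    """Hand-rolled single-scaffold VariantTable for small unit tests."""
    pos = np.asarray(pos, dtype=np.int64)
    g = np.asarray(genotypes, dtype=np.int8)
    if g.ndim == 1:
        g = g[:, None]
    samples = samples or [f"s{i+1}" for i in range(g.shape[1])]
    n = len(pos)
    return VariantTable(
        np.array([scaffold] * n, dtype=object), pos,
        np.asarray(qual, float) if qual is not None else np.full(n, np.nan),
        np.asarray(depth, float) if depth is not None else np.full(n, np.nan),
        g, samples)
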