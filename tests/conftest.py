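import numpy as np
import pytest

from islescan.genotypes import GenotypeMatrix
from islescan.simcohort import SimConfig, simulate_study


def make_gm(
    calls,
    pos=None,
    chrom=None,
    ref=None,
    alt=None,
    depth=None,
    gq=None,
    samples=None,
    spacing=1000,
):
    """Build a GenotypeMatrix from a (n_samples, n_sites) call array with
    sensible defaults for everything else."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    if samples is None:
        samples = [f"s{i + 1:02d}" for i in range(n)]
    if pos is None:
        pos = np.arange(1, m + 1) * spacing
    if chrom is None:
        chrom = np.full(m, "chr1", dtype=object)
    if ref is None:
        ref = np.full(m, "A", dtype=object)
    if alt is None:
        alt = np.full(m, "G", dtype=object)
    if depth is None:
        depth = np.full((n, m), 10, dtype=np.int32)
    if gq is None:
        gq = np.full((n, m), 99, dtype=np.int32)
    return GenotypeMatrix(
        samples=samples, chrom=np.asarray(chrom, dtype=object),
        pos=np.asarray(pos, dtype=np.int64), ref=np.asarray(ref, dtype=object),
        alt=np.asarray(alt, dtype=object), calls=calls, depth=depth, gq=gq,
    )


@pytest.fixture(scope="session")
def divergent_sim():
    """Two well-diverged islands, no causal loci; used by PCA/Fst tests."""
    cfg = SimConfig(
        n_sites=3000, n_chrom=2, chrom_length=3_000_000,
        island_divergence=0.2, n_causal=0, missing_rate=0.0, seed=7,
    )
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def causal_sim():
    """Planted case-vs-control differentiated loci on two islands."""
    cfg = SimConfig(
        n_sites=5000, n_chrom=2, chrom_length=5_000_000,
        island_divergence=0.05, n_causal=3, causal_delta=0.6,
        missing_rate=0.02, seed=11,
    )
    return simulate_study(cfg)
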