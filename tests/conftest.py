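import numpy as np
import pytest

from trapsil import SynthConfig, gen_genome
from trapsil.readproc import BarcodeScheme, revcomp


@pytest.fixture(scope="session")
def scheme():
    return BarcodeScheme()


@pytest.fixture(scope="session")
def small_cfg():
    return SynthConfig(
        genome_length=150_000,
        n_chromosomes=2,
        n_genes=10,
        gene_size_range=(4_000, 20_000),
        n_sites=80,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_bundle(small_cfg):
    return gen_genome(small_cfg)


def random_genome(rng: np.random.Generator, chrom_lengths: dict[str, int]) -> dict[str, str]:
    bases = np.array(list("ACGT"))
    return {c: "".join(bases[rng.integers(0, 4, size=n)]) for c, n in chrom_lengths.items()}


def brute_force_map(tag: str, genome: dict[str, str], max_mismatches: int):
    """Exhaustive minimum-Hamming scan over every window of both strands
    (numpy-vectorized but still a direct enumeration).  Returns
    (best_distance, sorted list of (chrom, pos, strand) hits at the best
    distance), with best_distance possibly exceeding max_mismatches."""
    k = len(tag)
    best_d, hits = k + 1, []
    for chrom, seq in genome.items():
        if len(seq) < k:
            continue
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        windows = np.lib.stride_tricks.sliding_window_view(arr, k)
        for strand, query in (("+", tag), ("-", revcomp(tag))):
            q = np.frombuffer(query.encode(), dtype=np.uint8)
            dists = (windows != q).sum(axis=1)
            m = int(dists.min())
            if m < best_d:
                best_d, hits = m, []
            if m == best_d:
                hits += [(chrom, int(p), strand) for p in np.flatnonzero(dists == m)]
    if best_d > max_mismatches:
        return best_d, []
    return best_d, sorted(set(hits))


def make_read(scheme: BarcodeScheme, barcode: str, vector: str, genomic: str) -> str:
    return scheme.primer_a + barcode + scheme.ltr[vector] + genomic + scheme.primer_b
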