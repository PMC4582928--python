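from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from divscan import GenotypeMatrix


def build_matrix(
    sites: list[list[tuple[int, int] | None]],
    positions=None,
    alleles=None,
    contig="chr1",
    sample_prefix="s",
) -> GenotypeMatrix:
    """Build a GenotypeMatrix from per-site genotype lists.

    ``sites[i][j]`` is the genotype of sample j at site i, as an allele
    index pair or None for missing.
    """
    n_sites = len(sites)
    n_samples = len(sites[0]) if n_sites else 0
    calls = np.full((n_sites, n_samples, 2), -1, dtype=np.int8)
    for i, site in enumerate(sites):
        for j, g in enumerate(site):
            if g is not None:
                calls[i, j] = g
    if positions is None:
        positions = np.arange(1, n_sites + 1) * 10
    if alleles is None:
        alleles = []
        for i, site in enumerate(sites):
            k = max((max(g) for g in site if g is not None), default=0) + 1
            alleles.append(tuple("ACGT"[: max(k, 2)]))
    return GenotypeMatrix(
        contig=contig,
        positions=np.asarray(positions, dtype=np.int64),
        alleles=alleles,
        calls=calls,
        samples=[f"{sample_prefix}{j}" for j in range(n_samples)],
    )


def random_instance(rng: np.random.Generator):
    """Small random two-population genotype site for oracle comparison."""
    nA = int(rng.integers(1, 7))
    nB = int(rng.integers(1, 7))
    k = int(rng.integers(2, 4))
    miss_rate = float(rng.choice([0.0, 0.1, 0.3]))

    def draw(n):
        out = []
        for _ in range(n):
            if rng.random() < miss_rate:
                out.append(None)
            else:
                out.append((int(rng.integers(0, k)), int(rng.integers(0, k))))
        return out

    return draw(nA), draw(nB), k


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
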