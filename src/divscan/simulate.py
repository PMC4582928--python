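"""Synthetic hybrid-zone genotype data with a known divergence structure.

Two diploid populations are simulated under a Balding–Nichols model: at
each site an ancestral frequency ``p`` is drawn uniformly, then each
population's frequency comes from ``Beta(p(1-F)/F, (1-p)(1-F)/F)`` so the
expected relative divergence at the site equals ``F``.  The per-site
``F`` follows a position-dependent profile — a low background plus a
peak decaying exponentially with recombination distance from a causative
site — which gives every pipeline stage a closed-form recovery target.

Sites are placed uniformly at random (without replacement) along the
contig to exercise window coverage with irregular spacing.  All
randomness flows from one seed; the same config yields a byte-identical
VCF.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .decay import RecombinationModel, bp_to_cM
from .genotype_io import GenotypeMatrix, write_vcf  # noqa: F401 (re-export)

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "divergence_profile",
    "simulate_pair",
    "expected_theta",
    "write_vcf",
    "write_truth",
]


@dataclass
class SimulationConfig:
    n_per_pop: int = 10
    n_sites: int = 50_000
    contig_length: int = 1_000_000
    contig: str = "sim1"
    ancestral_freq_range: tuple[float, float] = (0.05, 0.95)
    F_bg: float = 0.02
    F_pk: float = 0.9
    peak_center: int = 500_000
    lambda_cM: float = 0.5
    missing_rate: float = 0.0
    triallelic_fraction: float = 0.0
    recomb: RecombinationModel = field(default_factory=RecombinationModel)
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.ancestral_freq_range
        if not (0.0 < lo < hi < 1.0):
            raise ValueError("ancestral_freq_range must lie strictly inside (0,1)")
        if not (0.0 < self.F_bg <= self.F_pk <= 1.0):
            raise ValueError("need 0 < F_bg <= F_pk <= 1")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0,1)")
        if self.n_sites > self.contig_length:
            raise ValueError("n_sites cannot exceed contig_length")
        if self.n_per_pop < 1 or self.n_sites < 1:
            raise ValueError("n_per_pop and n_sites must be positive")
        if not (0.0 <= self.triallelic_fraction <= 1.0):
            raise ValueError("triallelic_fraction must be in [0,1]")
        if self.lambda_cM <= 0:
            raise ValueError("lambda_cM must be positive")


@dataclass
class SimulationTruth:
    """Generating values stored alongside every simulated dataset."""

    positions: np.ndarray  # 1-based
    p_ancestral: np.ndarray  # frequency of the reference allele
    p_popA: np.ndarray
    p_popB: np.ndarray
    F_target: np.ndarray


def divergence_profile(position, config: SimulationConfig) -> np.ndarray | float:
    """Target F at a position: background plus an exponentially decaying
    peak, ``F_bg + (F_pk - F_bg) * exp(-d_cM / lambda_cM)``."""
    config.validate()
    pos = np.asarray(position, dtype=np.int64)
    d = bp_to_cM(np.abs(pos - config.peak_center), config.recomb)
    out = config.F_bg + (config.F_pk - config.F_bg) * np.exp(
        -np.asarray(d) / config.lambda_cM
    )
    return float(out) if out.ndim == 0 else out


def _bn_frequencies(p: np.ndarray, F: np.ndarray, rng: np.random.Generator):
    """One Balding–Nichols draw per site: Beta with mean p, 'variance
    parameter' F."""
    scale = (1.0 - F) / F
    return rng.beta(p * scale, (1.0 - p) * scale)


def simulate_pair(config: SimulationConfig):
    """Simulate two populations; returns (GenotypeMatrix, SimulationTruth).

    Genotypes are HWE draws within each population from its realized
    frequency; genotypes are then masked missing independently at
    ``missing_rate``.  Deterministic under ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    S, n = config.n_sites, config.n_per_pop

    positions = np.sort(
        rng.choice(config.contig_length, size=S, replace=False).astype(np.int64) + 1
    )
    lo, hi = config.ancestral_freq_range
    p_anc = rng.uniform(lo, hi, size=S)
    F = np.asarray(divergence_profile(positions, config), dtype=np.float64)

    pA = _bn_frequencies(p_anc, F, rng)
    pB = _bn_frequencies(p_anc, F, rng)

    # allele 0 = reference with frequency p; HWE within population
    callsA = (rng.random((S, n, 2)) >= pA[:, None, None]).astype(np.int8)
    callsB = (rng.random((S, n, 2)) >= pB[:, None, None]).astype(np.int8)
    calls = np.concatenate([callsA, callsB], axis=1)

    alleles: list[tuple[str, ...]] = [("A", "T")] * S
    if config.triallelic_fraction > 0:
        n_tri = int(round(config.triallelic_fraction * S))
        tri_idx = rng.choice(S, size=n_tri, replace=False)
        for i in tri_idx:
            # split the alternate allele: each copy of allele 1 becomes
            # allele 1 or 2 with equal probability
            alt = calls[i] == 1
            split = rng.random(alt.shape) < 0.5
            calls[i][alt & split] = 2
            alleles[i] = ("A", "T", "G")

    if config.missing_rate > 0:
        miss = rng.random((S, calls.shape[1])) < config.missing_rate
        calls[miss] = -1

    sample_ids = [f"popA_{i:03d}" for i in range(n)] + [
        f"popB_{i:03d}" for i in range(n)
    ]
    G = GenotypeMatrix(
        contig=config.contig,
        positions=positions,
        alleles=alleles,
        calls=calls,
        samples=sample_ids,
    )
    truth = SimulationTruth(
        positions=positions, p_ancestral=p_anc, p_popA=pA, p_popB=pB, F_target=F
    )
    return G, truth


def expected_theta(
    config: SimulationConfig,
    region: tuple[int, int] | None = None,
    truth: SimulationTruth | None = None,
) -> float:
    """Estimand of the ratio-of-sums theta-hat implied by the F profile.

    Per site the expected numerator is ~ F * p(1-p) and the expected
    denominator ~ p(1-p), so the combined estimand is the p(1-p)-weighted
    average of F over the sites.  With ``truth`` the realized ancestral
    frequencies and positions are used; otherwise the profile is
    integrated uniformly over the region (weights cancel because p is
    drawn independently of position).
    """
    config.validate()
    if truth is not None:
        pos = truth.positions
        lo, hi = region if region is not None else (1, config.contig_length)
        sel = (pos >= lo) & (pos <= hi)
        if not sel.any():
            raise ValueError("no simulated sites inside region")
        w = truth.p_ancestral[sel] * (1.0 - truth.p_ancestral[sel])
        F = truth.F_target[sel]
        return float(np.sum(w * F) / np.sum(w))
    from scipy.integrate import quad

    lo, hi = region if region is not None else (1, config.contig_length)

    rate = config.recomb.cM_per_bp

    def f(x):  # continuous version of the profile for quadrature
        d = abs(x - config.peak_center) * rate
        return config.F_bg + (config.F_pk - config.F_bg) * np.exp(-d / config.lambda_cM)

    pts = [config.peak_center] if lo < config.peak_center < hi else None
    val, _ = quad(f, lo, hi, limit=500, points=pts)
    return float(val / (hi - lo))


def write_truth(truth: SimulationTruth, path) -> None:
    """Truth table TSV: pos, p_anc, p_popA, p_popB, F_target."""
    with open(path, "w") as fh:
        fh.write("pos\tp_anc\tp_popA\tp_popB\tF_target\n")
        for i in range(len(truth.positions)):
            fh.write(
                f"{truth.positions[i]}\t{truth.p_ancestral[i]:.8f}\t"
                f"{truth.p_popA[i]:.8f}\t{truth.p_popB[i]:.8f}\t"
                f"{truth.F_target[i]:.8f}\n"
            )
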