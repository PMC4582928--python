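"""Per-site divergence estimators and combining rules.

Relative divergence is the Weir & Cockerham (1984) two-population
random-effects estimator for diploid data: per site and per allele the
variance components *a* (among populations), *b* (among individuals
within populations) and *c* (within individuals) are computed from the
observed allele and heterozygote frequencies, summed over alleles, and
combined across sites as a ratio of sums — numerators and denominators
are summed separately and divided once.  Absolute divergence (d_xy) is
the probability that one allele drawn from each population differs,
``1 - sum_i x_i * y_i``, averaged over positions.

Negative per-site components are deliberately retained in the sums:
truncating them at zero would bias the ratio-of-sums estimate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np

from .genotype_io import GenotypeMatrix

__all__ = [
    "SiteComponents",
    "SiteDxy",
    "DivergenceEstimate",
    "BootstrapCI",
    "site_components",
    "site_dxy",
    "multilocus_theta",
    "mean_dxy",
    "combine_group",
    "bootstrap_ci",
]


@dataclass
class SiteComponents:
    """Per-site Weir–Cockerham variance components for one pair.

    Arrays are aligned with ``positions``; ``defined`` marks sites where
    both populations contributed at least one genotyped individual and
    the components are computable.  ``a``, ``b``, ``c`` are NaN at
    undefined sites and excluded from all sums.
    """

    contig: str
    positions: np.ndarray  # 1-based
    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    defined: np.ndarray  # bool
    n_genotyped_a: np.ndarray
    n_genotyped_b: np.ndarray

    @property
    def den(self) -> np.ndarray:
        return self.a + self.b + self.c

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    def theta_per_site(self) -> np.ndarray:
        """Per-site a/(a+b+c); NaN where the denominator is 0 or the
        site is undefined."""
        den = self.den
        out = np.full(self.n_sites, np.nan)
        ok = self.defined & (den != 0)
        out[ok] = self.a[ok] / den[ok]
        return out

    def subset(self, mask: np.ndarray) -> "SiteComponents":
        mask = np.asarray(mask, dtype=bool)
        return SiteComponents(
            self.contig,
            self.positions[mask],
            self.a[mask],
            self.b[mask],
            self.c[mask],
            self.defined[mask],
            self.n_genotyped_a[mask],
            self.n_genotyped_b[mask],
        )


@dataclass
class SiteDxy:
    """Per-site absolute divergence in [0, 1]."""

    contig: str
    positions: np.ndarray
    dxy: np.ndarray  # NaN where undefined
    defined: np.ndarray

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    def subset(self, mask: np.ndarray) -> "SiteDxy":
        mask = np.asarray(mask, dtype=bool)
        return SiteDxy(self.contig, self.positions[mask], self.dxy[mask], self.defined[mask])


@dataclass
class DivergenceEstimate:
    comparison_id: str
    theta: float  # NaN when undefined (zero summed denominator)
    dxy_mean: float
    n_positions: int

    @property
    def theta_defined(self) -> bool:
        return not np.isnan(self.theta)


@dataclass
class BootstrapCI:
    lower: float
    upper: float
    level: float
    n_reps: int
    seed: int


def _pop_counts(calls: np.ndarray, k_max: int):
    """Allele counts, heterozygote counts and genotyped-individual counts
    for one population.  ``calls``: (n_sites, n, 2) int8, -1 missing."""
    n_sites = calls.shape[0]
    genotyped = calls[:, :, 0] >= 0
    n_ind = genotyped.sum(axis=1).astype(np.float64)
    allele_counts = np.zeros((n_sites, k_max))
    het_counts = np.zeros((n_sites, k_max))
    for j in range(k_max):
        is_j = calls == j  # (sites, n, 2)
        allele_counts[:, j] = is_j.sum(axis=(1, 2))
        het_counts[:, j] = (is_j[:, :, 0] ^ is_j[:, :, 1]).sum(axis=1)
    return allele_counts, het_counts, n_ind


def site_components(
    G: GenotypeMatrix,
    popA: Sequence[str],
    popB: Sequence[str],
) -> SiteComponents:
    """Weir–Cockerham (1984) per-site components for two populations.

    Components are computed per allele from observed allele frequencies
    and observed heterozygosity, with per-site sample sizes taken from
    the non-missing calls only, then summed over alleles.  Sites where a
    population has no genotyped individual, or the average sample size
    does not exceed one, are flagged undefined.
    """
    ia, ib = G.sample_indices(popA), G.sample_indices(popB)
    if set(ia.tolist()) & set(ib.tolist()):
        raise ValueError("popA and popB overlap")
    k_max = max((len(a) for a in G.alleles), default=1)

    cntA, hetA, nA = _pop_counts(G.calls[:, ia, :], k_max)
    cntB, hetB, nB = _pop_counts(G.calls[:, ib, :], k_max)

    # average sample size n_bar, coefficient n_c (r = 2 populations)
    with np.errstate(divide="ignore", invalid="ignore"):
        n_tot = nA + nB
        n_bar = n_tot / 2.0
        n_c = n_tot - (nA**2 + nB**2) / n_tot

        pA = cntA / (2.0 * nA)[:, None]
        pB = cntB / (2.0 * nB)[:, None]
        p_bar = (cntA + cntB) / (2.0 * n_tot)[:, None]
        # s^2 = sum_i n_i (p_i - p_bar)^2 / ((r-1) n_bar)
        s2 = (
            nA[:, None] * (pA - p_bar) ** 2 + nB[:, None] * (pB - p_bar) ** 2
        ) / n_bar[:, None]
        h_bar = (hetA + hetB) / n_tot[:, None]

        nb = n_bar[:, None]
        ncc = n_c[:, None]
        pq = p_bar * (1.0 - p_bar)
        inner = pq - 0.5 * s2 - 0.25 * h_bar
        a = (nb / ncc) * (s2 - inner / (nb - 1.0))
        b = (nb / (nb - 1.0)) * (pq - 0.5 * s2 - (2.0 * nb - 1.0) / (4.0 * nb) * h_bar)
        c = 0.5 * h_bar

    defined = (nA >= 1) & (nB >= 1) & (n_bar > 1.0)
    # alleles absent from a site produce 0-valued terms; non-finite rows
    # only arise at undefined sites and are masked out
    a_sum = np.where(defined, np.where(np.isfinite(a), a, 0.0).sum(axis=1), np.nan)
    b_sum = np.where(defined, np.where(np.isfinite(b), b, 0.0).sum(axis=1), np.nan)
    c_sum = np.where(defined, np.where(np.isfinite(c), c, 0.0).sum(axis=1), np.nan)

    return SiteComponents(
        contig=G.contig,
        positions=G.positions.copy(),
        a=a_sum,
        b=b_sum,
        c=c_sum,
        defined=defined,
        n_genotyped_a=nA.astype(np.int64),
        n_genotyped_b=nB.astype(np.int64),
    )


def site_dxy(
    G: GenotypeMatrix,
    popA: Sequence[str],
    popB: Sequence[str],
) -> SiteDxy:
    """Per-site d_xy = 1 - sum_i x_i * y_i from sample allele frequencies."""
    ia, ib = G.sample_indices(popA), G.sample_indices(popB)
    if set(ia.tolist()) & set(ib.tolist()):
        raise ValueError("popA and popB overlap")
    k_max = max((len(a) for a in G.alleles), default=1)
    cntA, _, nA = _pop_counts(G.calls[:, ia, :], k_max)
    cntB, _, nB = _pop_counts(G.calls[:, ib, :], k_max)
    with np.errstate(divide="ignore", invalid="ignore"):
        x = cntA / (2.0 * nA)[:, None]
        y = cntB / (2.0 * nB)[:, None]
        d = 1.0 - np.sum(x * y, axis=1)
    defined = (nA >= 1) & (nB >= 1)
    d = np.where(defined, d, np.nan)
    return SiteDxy(contig=G.contig, positions=G.positions.copy(), dxy=d, defined=defined)


def multilocus_theta(
    components: SiteComponents, comparison_id: str = ""
) -> DivergenceEstimate:
    """Ratio-of-sums theta-hat over all defined sites.

    Monomorphic sites contribute 0/0 and therefore leave the estimate
    unchanged while still counting toward ``n_positions``.  A zero summed
    denominator yields ``theta = NaN`` (flagged, never silently 0).
    """
    d = components.defined
    n_positions = int(d.sum())
    num = float(np.nansum(components.a[d])) if n_positions else 0.0
    den = float(np.nansum(components.den[d])) if n_positions else 0.0
    theta = num / den if den != 0.0 else float("nan")
    return DivergenceEstimate(
        comparison_id=comparison_id,
        theta=theta,
        dxy_mean=float("nan"),
        n_positions=n_positions,
    )


def mean_dxy(values: SiteDxy) -> float:
    """Arithmetic mean of d_xy over defined positions (monomorphic
    positions contribute 0).  NaN if no position is defined."""
    d = values.defined
    if not d.any():
        return float("nan")
    return float(np.nanmean(values.dxy[d]))


def combine_group(
    per_comparison: Sequence[SiteComponents],
    per_comparison_dxy: Sequence[SiteDxy] | None = None,
    comparison_id: str = "",
) -> DivergenceEstimate:
    """Combine estimates across the member pairs of a comparison group.

    theta-hat: numerators and denominators summed over all sites of all
    member comparisons, divided once.  d_xy: mean across comparisons of
    the per-comparison means.
    """
    if not per_comparison:
        raise ValueError("need at least one comparison")
    num = den = 0.0
    n_positions = 0
    for comp in per_comparison:
        d = comp.defined
        if d.any():
            num += float(np.nansum(comp.a[d]))
            den += float(np.nansum(comp.den[d]))
            n_positions += int(d.sum())
    theta = num / den if den != 0.0 else float("nan")
    dxy = float("nan")
    if per_comparison_dxy is not None:
        means = [mean_dxy(v) for v in per_comparison_dxy]
        means = [m for m in means if not np.isnan(m)]
        if means:
            dxy = float(np.mean(means))
    return DivergenceEstimate(
        comparison_id=comparison_id, theta=theta, dxy_mean=dxy, n_positions=n_positions
    )


def bootstrap_ci(
    components: SiteComponents,
    statistic: Literal["theta", "dxy"] = "theta",
    dxy: SiteDxy | None = None,
    n_reps: int = 1000,
    level: float = 0.95,
    seed: int = 0,
    _batch: int = 200,
) -> BootstrapCI:
    """Percentile bootstrap CI, resampling positions with replacement.

    The resampling unit is the individual defined position (pooled across
    intervals by the caller).  Deterministic for a given seed.
    """
    if statistic == "dxy":
        if dxy is None:
            raise ValueError("dxy statistic requires dxy values")
        vals = dxy.dxy[dxy.defined]
        n = len(vals)
    else:
        d = components.defined
        a = np.nan_to_num(components.a[d])
        den = np.nan_to_num(components.den[d])
        n = len(a)
    if n < 2:
        raise ValueError("need at least 2 defined sites to bootstrap")
    rng = np.random.default_rng(seed)
    stats = np.empty(n_reps)
    for lo in range(0, n_reps, _batch):
        hi = min(lo + _batch, n_reps)
        idx = rng.integers(0, n, size=(hi - lo, n))
        if statistic == "theta":
            num_s = a[idx].sum(axis=1)
            den_s = den[idx].sum(axis=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                stats[lo:hi] = num_s / den_s
        else:
            stats[lo:hi] = vals[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lower, upper = np.nanquantile(stats, [alpha, 1.0 - alpha])
    return BootstrapCI(
        lower=float(lower), upper=float(upper), level=level, n_reps=n_reps, seed=seed
    )
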