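"""Independent brute-force oracles used by the test suite.

These deliberately avoid numpy vectorization and any code path from the
package under test: plain-Python, per-allele, per-population arithmetic
transcribed line by line from the published component definitions.
"""

from __future__ import annotations

from fractions import Fraction


def wc_components_oracle(pops: list[list[tuple[int, int] | None]]):
    """Variance components (a, b, c) for one site, summed over alleles.

    ``pops`` is a list of populations; each population is a list of
    diploid genotypes as ordered pairs of allele indices, or ``None`` for
    a missing genotype.  Returns ``None`` when fewer than two populations
    have data or the average sample size does not exceed one.
    """
    r = len(pops)
    genotyped = [[g for g in pop if g is not None] for pop in pops]
    n = [len(pop) for pop in genotyped]
    if any(ni < 1 for ni in n):
        return None
    n_bar = sum(n) / r
    if n_bar <= 1:
        return None
    n_c = (r * n_bar - sum(ni * ni for ni in n) / (r * n_bar)) / (r - 1)

    alleles = sorted({al for pop in genotyped for g in pop for al in g})
    a_tot = b_tot = c_tot = 0.0
    for allele in alleles:
        p = [
            sum((g[0] == allele) + (g[1] == allele) for g in pop) / (2 * ni)
            for pop, ni in zip(genotyped, n)
        ]
        h = [
            sum((g[0] == allele) != (g[1] == allele) for g in pop) / ni
            for pop, ni in zip(genotyped, n)
        ]
        p_bar = sum(ni * pi for ni, pi in zip(n, p)) / (r * n_bar)
        s2 = sum(ni * (pi - p_bar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * n_bar)
        h_bar = sum(ni * hi for ni, hi in zip(n, h)) / (r * n_bar)

        pq = p_bar * (1 - p_bar)
        a = (n_bar / n_c) * (
            s2 - (1 / (n_bar - 1)) * (pq - ((r - 1) / r) * s2 - h_bar / 4)
        )
        b = (n_bar / (n_bar - 1)) * (
            pq - ((r - 1) / r) * s2 - ((2 * n_bar - 1) / (4 * n_bar)) * h_bar
        )
        c = h_bar / 2
        a_tot += a
        b_tot += b
        c_tot += c
    return a_tot, b_tot, c_tot


def dxy_oracle(popA: list[tuple[int, int] | None], popB) -> float | None:
    """1 - sum_i x_i y_i from sample allele frequencies."""
    ga = [g for g in popA if g is not None]
    gb = [g for g in popB if g is not None]
    if not ga or not gb:
        return None
    alleles = sorted({al for g in ga + gb for al in g})
    total = Fraction(0)
    for allele in alleles:
        x = Fraction(sum((g[0] == allele) + (g[1] == allele) for g in ga), 2 * len(ga))
        y = Fraction(sum((g[0] == allele) + (g[1] == allele) for g in gb), 2 * len(gb))
        total += x * y
    return float(1 - total)
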