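"""Genotype, sample and region I/O plus per-pair site filters.

Coordinate conventions
----------------------
All external files (VCF, region tables) use 1-based, fully-closed
intervals.  Internally :class:`Region` stores 0-based half-open
``[start0, end0)`` coordinates; :class:`GenotypeMatrix` keeps the VCF's
1-based ``POS`` values untouched so written output round-trips exactly.

A diploid genotype is either fully called or missing: half-calls such as
``./A`` count as missing for the whole individual, because the
missingness filter counts *individuals* genotyped, not alleles.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "PHENOTYPE_CLASSES",
    "SampleMetadata",
    "GenotypeMatrix",
    "Region",
    "RegionSet",
    "read_sample_table",
    "read_region_table",
    "read_genotypes",
    "write_vcf",
    "filter_pair_missingness",
    "remove_invariant_sites",
    "subset_region",
    "apply_mask",
]

MISSING = -1

PHENOTYPE_CLASSES = ("postman", "rayed", "himera", "outgroup")


@dataclass(frozen=True)
class SampleMetadata:
    """One row of the sample table."""

    sample_id: str
    taxon: str
    hybrid_zone: str
    phenotype_class: str
    role: str = "ingroup"

    def __post_init__(self) -> None:
        if self.phenotype_class not in PHENOTYPE_CLASSES:
            raise ValueError(
                f"sample {self.sample_id!r}: phenotype_class must be one of "
                f"{PHENOTYPE_CLASSES}, got {self.phenotype_class!r}"
            )
        if self.role not in ("ingroup", "outgroup"):
            raise ValueError(
                f"sample {self.sample_id!r}: role must be ingroup/outgroup"
            )
        if self.role == "ingroup" and not (self.hybrid_zone and self.phenotype_class):
            raise ValueError(
                f"ingroup sample {self.sample_id!r} needs hybrid_zone and "
                "phenotype_class"
            )


@dataclass
class GenotypeMatrix:
    """Diploid genotype calls for one contig.

    ``calls`` has shape ``(n_sites, n_samples, 2)`` holding allele
    indices into ``alleles[site]`` (REF first); ``-1`` marks a missing
    genotype (both slots are then ``-1``).
    """

    contig: str
    positions: np.ndarray  # 1-based, strictly increasing
    alleles: list[tuple[str, ...]]
    calls: np.ndarray  # int8 (n_sites, n_samples, 2)
    samples: list[str]

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 3 or self.calls.shape[2] != 2:
            raise ValueError("calls must have shape (n_sites, n_samples, 2)")
        if self.calls.shape[0] != len(self.positions):
            raise ValueError("positions and calls disagree on site count")
        if len(self.alleles) != len(self.positions):
            raise ValueError("alleles and positions disagree on site count")
        if self.calls.shape[1] != len(self.samples):
            raise ValueError("samples and calls disagree on sample count")
        if len(self.positions) and np.any(np.diff(self.positions) <= 0):
            raise ValueError(f"positions on {self.contig} not strictly increasing")
        # normalize half-calls to fully missing
        half = (self.calls < 0).any(axis=2)
        self.calls[half] = MISSING
        for i, als in enumerate(self.alleles):
            k = len(als)
            site = self.calls[i]
            bad = site[site >= 0]
            if bad.size and bad.max() >= k:
                raise ValueError(
                    f"site {self.positions[i]} on {self.contig}: genotype indexes "
                    f"allele {int(bad.max())} but only {k} alleles are listed"
                )

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_indices(self, sample_ids: Sequence[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        missing = [s for s in sample_ids if s not in lookup]
        if missing:
            raise KeyError(f"samples not in matrix: {missing}")
        return np.array([lookup[s] for s in sample_ids], dtype=np.intp)

    def genotyped(self) -> np.ndarray:
        """Boolean (n_sites, n_samples): genotype fully called."""
        return self.calls[:, :, 0] >= 0


@dataclass(frozen=True)
class Region:
    """Named genomic interval, stored 0-based half-open."""

    name: str
    contig: str
    start0: int
    end0: int
    is_color_locus: bool = False
    is_functional: bool = False
    is_unlinked: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.start0 < self.end0):
            raise ValueError(f"region {self.name!r}: empty or negative interval")

    @classmethod
    def from_1based(cls, name, contig, start1, end1, **flags) -> "Region":
        return cls(name, contig, int(start1) - 1, int(end1), **flags)

    @property
    def start1(self) -> int:
        return self.start0 + 1

    @property
    def end1(self) -> int:
        return self.end0

    @property
    def length(self) -> int:
        return self.end0 - self.start0

    def contains_position(self, pos1) -> np.ndarray:
        pos1 = np.asarray(pos1)
        return (pos1 > self.start0) & (pos1 <= self.end0)


class RegionSet:
    """Collection of named regions with flag-based lookups."""

    def __init__(self, regions: Iterable[Region]):
        self.regions = list(regions)
        names = [r.name for r in self.regions]
        if len(set(names)) != len(names):
            raise ValueError("duplicate region names")
        self._by_name = {r.name: r for r in self.regions}
        self._validate()

    def _validate(self) -> None:
        func = [r for r in self.regions if r.is_functional]
        locus = [r for r in self.regions if r.is_color_locus]
        if func and locus:
            f, l = func[0], locus[0]
            if f.contig != l.contig or f.start0 < l.start0 or f.end0 > l.end0:
                raise ValueError(
                    f"functional region {f.name!r} not contained in color-locus "
                    f"region {l.name!r}"
                )

    def __getitem__(self, name: str) -> Region:
        return self._by_name[name]

    def __iter__(self):
        return iter(self.regions)

    def __len__(self) -> int:
        return len(self.regions)

    @property
    def unlinked(self) -> list[Region]:
        return [r for r in self.regions if r.is_unlinked]

    @property
    def functional(self) -> Region | None:
        for r in self.regions:
            if r.is_functional:
                return r
        return None

    @property
    def color_locus(self) -> Region | None:
        for r in self.regions:
            if r.is_color_locus:
                return r
        return None


def read_sample_table(path: str | os.PathLike) -> list[SampleMetadata]:
    """Read the TSV sample table (sample_id, taxon, hybrid_zone,
    phenotype_class, role)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"sample_id", "taxon", "hybrid_zone", "phenotype_class", "role"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sample table missing columns: {sorted(missing)}")
    samples = [
        SampleMetadata(
            sample_id=row.sample_id,
            taxon=row.taxon,
            hybrid_zone=row.hybrid_zone,
            phenotype_class=row.phenotype_class,
            role=row.role or "ingroup",
        )
        for row in df.itertuples()
    ]
    ids = [s.sample_id for s in samples]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample_id in sample table")
    return samples


def read_region_table(path: str | os.PathLike) -> RegionSet:
    """Read the TSV region table (name, contig, start, end, flags).

    ``start``/``end`` are 1-based inclusive; ``flags`` is a
    comma-separated subset of {color_locus, functional, unlinked}.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"name", "contig", "start", "end"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"region table missing columns: {sorted(missing)}")
    regions = []
    for row in df.itertuples():
        flags = {f.strip() for f in getattr(row, "flags", "").split(",") if f.strip()}
        unknown = flags - {"color_locus", "functional", "unlinked"}
        if unknown:
            raise ValueError(f"region {row.name!r}: unknown flags {sorted(unknown)}")
        regions.append(
            Region.from_1based(
                row.name,
                row.contig,
                int(row.start),
                int(row.end),
                is_color_locus="color_locus" in flags,
                is_functional="functional" in flags,
                is_unlinked="unlinked" in flags,
            )
        )
    return RegionSet(regions)


_NUCS = frozenset("ACGTN")


def _is_snp(ref: str, alts: Sequence[str]) -> bool:
    if len(ref) != 1 or ref.upper() not in _NUCS:
        return False
    for a in alts:
        if len(a) != 1 or a.upper() not in _NUCS or a == "*":
            return False
    return True


def read_genotypes(
    vcf_path: str | os.PathLike,
    samples: Sequence[SampleMetadata] | Sequence[str] | None = None,
) -> dict[str, GenotypeMatrix]:
    """Read a VCF into one :class:`GenotypeMatrix` per contig.

    Only SNP records are kept (indels and spanning deletions are dropped);
    multiallelic SNP records are retained as-is with all alleles.  Raises
    ``KeyError`` naming any requested sample absent from the VCF and
    ``ValueError`` (with the record index) on malformed records.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path), gts012=False)
    header_samples = list(vcf.samples)
    if samples is None:
        wanted = header_samples
    else:
        wanted = [s.sample_id if isinstance(s, SampleMetadata) else s for s in samples]
        absent = [s for s in wanted if s not in header_samples]
        if absent:
            raise KeyError(f"samples missing from VCF {vcf_path}: {absent}")
    col = np.array([header_samples.index(s) for s in wanted], dtype=np.intp)

    per_contig: dict[str, dict[str, list]] = {}
    for rec_idx, var in enumerate(vcf, start=1):
        try:
            alts = [a for a in (var.ALT or [])]
            if not _is_snp(var.REF, alts):
                continue
            gts = np.asarray(var.genotype.array(), dtype=np.int16)[:, :2]
        except Exception as exc:  # pragma: no cover - defensive
            raise ValueError(
                f"malformed VCF record #{rec_idx} in {vcf_path}: {exc}"
            ) from exc
        gts = gts[col]
        gts[(gts < 0).any(axis=1)] = MISSING
        store = per_contig.setdefault(
            var.CHROM, {"pos": [], "alleles": [], "calls": []}
        )
        store["pos"].append(var.POS)
        store["alleles"].append(tuple([var.REF] + alts))
        store["calls"].append(gts.astype(np.int8))
    vcf.close()

    out: dict[str, GenotypeMatrix] = {}
    for contig, store in per_contig.items():
        out[contig] = GenotypeMatrix(
            contig=contig,
            positions=np.array(store["pos"], dtype=np.int64),
            alleles=store["alleles"],
            calls=np.stack(store["calls"], axis=0)
            if store["calls"]
            else np.empty((0, len(wanted), 2), dtype=np.int8),
            samples=list(wanted),
        )
    return out


def write_vcf(
    G: GenotypeMatrix,
    path: str | os.PathLike,
    contig_length: int | None = None,
) -> None:
    """Write a minimal standards-compliant VCF v4.2 with GT fields.

    Missing genotypes become ``./.``; all genotypes are written unphased.
    An empty matrix yields a valid header-only file.
    """
    length = contig_length
    if length is None:
        length = int(G.positions[-1]) if G.n_sites else 1
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={G.contig},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(G.samples)
            + "\n"
        )
        for i in range(G.n_sites):
            als = G.alleles[i]
            alt = ",".join(als[1:]) if len(als) > 1 else "."
            cells = []
            for j in range(G.n_samples):
                a, b = G.calls[i, j]
                cells.append("./." if a < 0 else f"{a}/{b}")
            fh.write(
                f"{G.contig}\t{G.positions[i]}\t.\t{als[0]}\t{alt}\t.\t.\t.\tGT\t"
                + "\t".join(cells)
                + "\n"
            )


def filter_pair_missingness(
    G: GenotypeMatrix,
    popA: Sequence[str],
    popB: Sequence[str],
    threshold: float = 0.75,
) -> np.ndarray:
    """Site mask keeping positions where at least ``threshold`` of the
    individuals are genotyped in *each* of the two populations.

    The boundary passes: a site genotyped in exactly 75% of individuals of
    both populations is kept at the default threshold.
    """
    if not len(popA) or not len(popB):
        raise ValueError("populations must be non-empty")
    ia, ib = G.sample_indices(popA), G.sample_indices(popB)
    if set(ia) & set(ib):
        raise ValueError("popA and popB overlap")
    called = G.genotyped()
    fracA = called[:, ia].sum(axis=1) / len(ia)
    fracB = called[:, ib].sum(axis=1) / len(ib)
    return (fracA >= threshold) & (fracB >= threshold)


def remove_invariant_sites(G: GenotypeMatrix, samples: Sequence[str]) -> np.ndarray:
    """Site mask keeping positions with >=2 distinct observed alleles
    among the non-missing calls of ``samples``."""
    if not len(samples):
        raise ValueError("sample list must be non-empty")
    idx = G.sample_indices(samples)
    sub = G.calls[:, idx, :].reshape(G.n_sites, -1)
    mask = np.zeros(G.n_sites, dtype=bool)
    for i in range(G.n_sites):
        obs = np.unique(sub[i][sub[i] >= 0])
        mask[i] = obs.size >= 2
    return mask


def apply_mask(G: GenotypeMatrix, mask: np.ndarray) -> GenotypeMatrix:
    """New matrix restricted to masked sites (original coordinates kept)."""
    mask = np.asarray(mask, dtype=bool)
    return GenotypeMatrix(
        contig=G.contig,
        positions=G.positions[mask],
        alleles=[a for a, m in zip(G.alleles, mask) if m],
        calls=G.calls[mask],
        samples=list(G.samples),
    )


def subset_region(G: GenotypeMatrix, region: Region) -> GenotypeMatrix:
    """All and only the sites whose position lies inside ``region``.

    Region bounds are inclusive in the external 1-based convention, so a
    site at the region start coordinate is included.  An empty result is
    an empty matrix, not an error.
    """
    if region.contig != G.contig:
        raise ValueError(
            f"region {region.name!r} is on {region.contig}, matrix on {G.contig}"
        )
    return apply_mask(G, region.contains_position(G.positions))
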