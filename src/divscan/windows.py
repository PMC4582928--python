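"""Sliding-window divergence profiles and the comparison design.

Windows are anchored at the first base of the contig (external 1-based
coordinate 1), advance by ``step`` and are never truncated: only
full-size windows are emitted, so a contig shorter than one window size
yields none.  Window coverage is the fraction of genomic positions
inside the window that carry an estimate, with the window size in base
pairs as the denominator (switchable to the count of observed sites via
``coverage_denominator="sites"`` for sparse data).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np

from .divergence import SiteComponents, SiteDxy
from .genotype_io import SampleMetadata

__all__ = [
    "Window",
    "ComparisonSpec",
    "ComparisonDesign",
    "make_windows",
    "window_estimates",
    "enumerate_comparisons",
    "study_sample_table",
]

CATEGORIES = (
    "parapatric_within",
    "parapatric_between_species",
    "allopatric_postman_rayed",
    "allopatric_postman_postman",
    "allopatric_rayed_rayed",
)


@dataclass
class Window:
    """Half-open genomic interval [start0, end0) carrying estimates."""

    contig: str
    start0: int
    end0: int
    theta: float = float("nan")
    dxy_mean: float = float("nan")
    coverage: float = 0.0
    n_positions: int = 0
    # summed components, kept so group/region aggregation is exact
    sum_a: float = 0.0
    sum_den: float = 0.0

    @property
    def size(self) -> int:
        return self.end0 - self.start0

    @property
    def midpoint(self) -> float:
        """External 1-based midpoint, used for plotting and decay."""
        return (self.start0 + 1 + self.end0) / 2.0


@dataclass
class ComparisonSpec:
    """A named taxa pair (or group of pairs) to be compared."""

    comparison_id: str
    category: str
    popA: list[str]
    popB: list[str]
    taxonA: str = ""
    taxonB: str = ""

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if set(self.popA) & set(self.popB):
            raise ValueError(f"{self.comparison_id}: populations overlap")


@dataclass
class ComparisonDesign:
    """The full study design: 5 parapatric pairs and 3 allopatric groups."""

    parapatric: list[ComparisonSpec]
    allopatric: dict[str, list[ComparisonSpec]]

    @property
    def all_pairs(self) -> list[ComparisonSpec]:
        out = list(self.parapatric)
        for specs in self.allopatric.values():
            out.extend(specs)
        return out


def make_windows(
    contig_length: int,
    size: int = 15_000,
    step: int = 5_000,
    contig: str = "",
) -> list[Window]:
    """Full-size sliding windows over [1, contig_length].

    Count is ``floor((L - size)/step) + 1`` for ``L >= size``, else 0.
    """
    if not (size >= step > 0):
        raise ValueError("need size >= step > 0")
    windows = []
    start0 = 0
    while start0 + size <= contig_length:
        windows.append(Window(contig=contig, start0=start0, end0=start0 + size))
        start0 += step
    return windows


def window_estimates(
    components: SiteComponents,
    dxy: SiteDxy | None,
    windows: Sequence[Window],
    min_coverage: float = 0.20,
    coverage_denominator: Literal["bp", "sites"] = "bp",
) -> list[Window]:
    """Fill windows with ratio-of-sums theta-hat and mean d_xy.

    A window at exactly ``min_coverage`` passes ("at least"); windows
    below it are still emitted but carry NaN estimates.
    """
    pos = components.positions
    order = np.argsort(pos, kind="stable")
    pos = pos[order]
    defined = components.defined[order]
    a = np.nan_to_num(components.a[order])
    den = np.nan_to_num(components.den[order])
    a = np.where(defined, a, 0.0)
    den = np.where(defined, den, 0.0)
    if dxy is not None:
        if len(dxy.positions) != len(components.positions) or np.any(
            dxy.positions[order] != pos
        ):
            raise ValueError("components and dxy must cover the same positions")
        dvals = np.where(dxy.defined[order], np.nan_to_num(dxy.dxy[order]), 0.0)
        ddef = dxy.defined[order].astype(np.int64)
    # prefix sums for O(1) window aggregation
    csum_a = np.concatenate([[0.0], np.cumsum(a)])
    csum_den = np.concatenate([[0.0], np.cumsum(den)])
    csum_def = np.concatenate([[0], np.cumsum(defined.astype(np.int64))])
    if dxy is not None:
        csum_d = np.concatenate([[0.0], np.cumsum(dvals)])
        csum_dn = np.concatenate([[0], np.cumsum(ddef)])

    out = []
    for w in windows:
        lo = np.searchsorted(pos, w.start0 + 1, side="left")
        hi = np.searchsorted(pos, w.end0, side="right")
        n_def = int(csum_def[hi] - csum_def[lo])
        sum_a = float(csum_a[hi] - csum_a[lo])
        sum_den = float(csum_den[hi] - csum_den[lo])
        denom_bp = w.size if coverage_denominator == "bp" else max(hi - lo, 1)
        coverage = n_def / denom_bp
        theta = float("nan")
        dmean = float("nan")
        if coverage >= min_coverage and n_def > 0:
            theta = sum_a / sum_den if sum_den != 0.0 else float("nan")
            if dxy is not None:
                n_d = int(csum_dn[hi] - csum_dn[lo])
                if n_d > 0:
                    dmean = float(csum_d[hi] - csum_d[lo]) / n_d
        out.append(
            Window(
                contig=w.contig,
                start0=w.start0,
                end0=w.end0,
                theta=theta,
                dxy_mean=dmean,
                coverage=coverage,
                n_positions=n_def,
                sum_a=sum_a,
                sum_den=sum_den,
            )
        )
    return out


def _ingroup_taxa(samples: Sequence[SampleMetadata]):
    """Group ingroup samples by taxon -> (hybrid_zone, phenotype, ids)."""
    taxa: dict[str, dict] = {}
    for s in samples:
        if s.role != "ingroup":
            continue
        t = taxa.setdefault(
            s.taxon, {"zone": s.hybrid_zone, "phenotype": s.phenotype_class, "ids": []}
        )
        if t["zone"] != s.hybrid_zone or t["phenotype"] != s.phenotype_class:
            raise ValueError(
                f"taxon {s.taxon!r} has inconsistent hybrid_zone/phenotype_class"
            )
        t["ids"].append(s.sample_id)
    return taxa


def enumerate_comparisons(samples: Sequence[SampleMetadata]) -> ComparisonDesign:
    """Build the 5 parapatric comparisons and the allopatric groups.

    Expects 5 hybrid zones: 4 within-species zones (one of which pairs
    two postman taxa — those two are merged into a single race for the
    allopatric enumeration) and one between-species zone identified by
    its himera-class taxon.  The himera-zone taxa are excluded from all
    within-species comparisons.  Resulting allopatric group sizes are
    exactly 9 (postman vs rayed), 6 (postman vs postman) and
    3 (rayed vs rayed).
    """
    taxa = _ingroup_taxa(samples)
    zones: dict[str, list[str]] = {}
    for name, t in sorted(taxa.items()):
        zones.setdefault(t["zone"], []).append(name)
    if len(zones) != 5:
        raise ValueError(
            f"expected 5 hybrid zones, found {len(zones)}: {sorted(zones)}"
        )
    for zone, members in zones.items():
        if len(members) != 2:
            raise ValueError(
                f"hybrid zone {zone!r} must contain exactly 2 taxa, found {members}"
            )

    species_zones = [
        z
        for z, members in zones.items()
        if any(taxa[m]["phenotype"] == "himera" for m in members)
    ]
    if len(species_zones) != 1:
        raise ValueError(
            "expected exactly one between-species zone (one taxon of "
            f"phenotype_class 'himera'), found {species_zones}"
        )
    between_zone = species_zones[0]

    parapatric = []
    for zone in sorted(zones):
        t1, t2 = zones[zone]
        cat = (
            "parapatric_between_species"
            if zone == between_zone
            else "parapatric_within"
        )
        parapatric.append(
            ComparisonSpec(
                comparison_id=f"parapatric:{zone}",
                category=cat,
                popA=list(taxa[t1]["ids"]),
                popB=list(taxa[t2]["ids"]),
                taxonA=t1,
                taxonB=t2,
            )
        )

    # allopatric enumeration over within-species races, merging the
    # postman-postman zone's two taxa into one race
    within_zones = sorted(z for z in zones if z != between_zone)
    pp_zones = [
        z
        for z in within_zones
        if all(taxa[m]["phenotype"] == "postman" for m in zones[z])
    ]
    if len(pp_zones) != 1:
        raise ValueError(
            "expected exactly one postman-postman hybrid zone to merge, "
            f"found {pp_zones}"
        )
    races = []  # (race_name, zone, phenotype, ids)
    for zone in within_zones:
        if zone == pp_zones[0]:
            ids = [i for m in zones[zone] for i in taxa[m]["ids"]]
            races.append((f"{zone}_merged", zone, "postman", ids))
        else:
            for m in zones[zone]:
                races.append((m, zone, taxa[m]["phenotype"], list(taxa[m]["ids"])))

    groups: dict[str, list[ComparisonSpec]] = {
        "allopatric_postman_rayed": [],
        "allopatric_postman_postman": [],
        "allopatric_rayed_rayed": [],
    }
    for (ra, za, pa, ia), (rb, zb, pb, ib) in combinations(races, 2):
        if za == zb:
            continue  # parapatric, already covered
        if pa == pb == "postman":
            cat = "allopatric_postman_postman"
        elif pa == pb == "rayed":
            cat = "allopatric_rayed_rayed"
        else:
            cat = "allopatric_postman_rayed"
        groups[cat].append(
            ComparisonSpec(
                comparison_id=f"allopatric:{ra}|{rb}",
                category=cat,
                popA=ia,
                popB=ib,
                taxonA=ra,
                taxonB=rb,
            )
        )
    expected = {
        "allopatric_postman_rayed": 9,
        "allopatric_postman_postman": 6,
        "allopatric_rayed_rayed": 3,
    }
    for cat, n in expected.items():
        if len(groups[cat]) != n:
            raise ValueError(
                f"{cat}: expected {n} member pairs, enumerated {len(groups[cat])}"
            )
    return ComparisonDesign(parapatric=parapatric, allopatric=groups)


# sample counts per taxon in the study design (58 samples total);
# the per-zone split between the two races is not published, so the
# counts below split each zone's published total as evenly as possible.
_STUDY_DESIGN = [
    # taxon, zone, phenotype, role, n
    ("hydara_pan", "panama", "postman", "ingroup", 4),
    ("petiverana", "panama", "postman", "ingroup", 4),
    ("erato", "french_guiana", "rayed", "ingroup", 7),
    ("hydara_fg", "french_guiana", "postman", "ingroup", 6),
    ("emma", "peru", "rayed", "ingroup", 7),
    ("favorinus", "peru", "postman", "ingroup", 7),
    ("lativitta", "ecuador", "rayed", "ingroup", 5),
    ("notabilis", "ecuador", "postman", "ingroup", 5),
    ("himera", "loja", "himera", "ingroup", 5),
    ("cyrbia", "loja", "postman", "ingroup", 4),
    ("clysonymus", "", "outgroup", "outgroup", 2),
    ("telesiphe", "", "outgroup", "outgroup", 2),
]


def study_sample_table() -> list[SampleMetadata]:
    """Sample metadata matching the study's hybrid-zone design.

    Five hybrid zones (four within-species plus one between the
    incipient-species pair) and two outgroup taxa, 58 samples total.
    """
    out = []
    for taxon, zone, phen, role, n in _STUDY_DESIGN:
        for i in range(1, n + 1):
            out.append(
                SampleMetadata(
                    sample_id=f"{taxon}_{i:02d}",
                    taxon=taxon,
                    hybrid_zone=zone,
                    phenotype_class=phen,
                    role=role,
                )
            )
    return out
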