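"""Allele-of-origin hybrid detection from lineage marker sites.

Two designated species groups (in the motivating study, C3 species and
C3-C4 species) define *marker sites*: reference positions where every
member of group 1 has the same consensus base b1, every member of group
2 the same consensus base b2, and b1 != b2.  A putative hybrid is
excluded from its own group when markers are defined, and its read
pileup is then classified at each marker site:

* **both_alleles** — both marker bases supported by >= 40% of reads
  each (a hybrid expressing both parental alleles);
* **group1_allele / group2_allele** — one marker base supported by
  >= 90% of reads;
* **uncertain** — anything else (including sites where the reads show
  neither marker base, flagged separately, and uncovered sites).

The both-alleles test runs first: 40+40 <= 100 < 90+40 makes the
categories mutually exclusive except at degenerate fractions, where
hybrid evidence takes precedence.  Fractions are computed over the
total mapped depth at the site, other (non-marker) bases included.
A summary table with counts, proportions and the dominance split of
both-allele sites reproduces the structure of the study's hybrid table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from csphylo._seq import BASE_INDEX, BASES
from csphylo.consensus import DerivedSequence, GenePileup, PileupColumn

PURE_MIN = 0.90
HYBRID_MIN = 0.40

CAT_GROUP1 = "group1_allele"
CAT_GROUP2 = "group2_allele"
CAT_BOTH = "both_alleles"
CAT_UNCERTAIN = "uncertain"


@dataclass(frozen=True)
class MarkerSite:
    gene_id: str
    position: int  # 0-based on the reference CDS
    group1_base: str
    group2_base: str

    def __post_init__(self) -> None:
        if self.group1_base == self.group2_base:
            raise ValueError("marker bases must differ")
        if self.group1_base not in BASES or self.group2_base not in BASES:
            raise ValueError("marker bases must be upper-case A/C/G/T")


@dataclass
class MarkerClassification:
    site: MarkerSite
    n_group1: int
    n_group2: int
    n_other: int
    category: str
    dominant: str  # 'group1' / 'group2' / 'none'; defined for both_alleles
    no_coverage: bool = False
    neither_base: bool = False  # reads show neither marker base

    @property
    def depth(self) -> int:
        return self.n_group1 + self.n_group2 + self.n_other


def define_marker_sites(
    derived_by_species: dict[str, dict[str, DerivedSequence]],
    group1: list[str],
    group2: list[str],
    exclude: list[str] | None = None,
) -> list[MarkerSite]:
    """Scan jointly covered genes for group-diagnostic CS positions.

    ``exclude`` removes taxa (typically the query and its suspected
    second parent) from the groups before the consistency scan.  Sites
    where any group member is AS or UNS are skipped: ambiguous calls
    are not trusted as lineage evidence.
    """
    exclude = set(exclude or ())
    g1 = [s for s in group1 if s not in exclude]
    g2 = [s for s in group2 if s not in exclude]
    if not g1 or not g2:
        raise ValueError("a species group is empty after exclusions")
    members = g1 + g2
    shared_genes = sorted(
        set.intersection(*({g for g in derived_by_species[s]} for s in members))
    )
    markers: list[MarkerSite] = []
    for gid in shared_genes:
        seqs1 = [derived_by_species[s][gid] for s in g1]
        seqs2 = [derived_by_species[s][gid] for s in g2]
        cs_all = np.logical_and.reduce([d.cs_mask for d in seqs1 + seqs2])
        if not cs_all.any():
            continue
        arr1 = np.stack(
            [np.frombuffer(d.symbols.encode(), dtype=np.uint8) for d in seqs1]
        )
        arr2 = np.stack(
            [np.frombuffer(d.symbols.encode(), dtype=np.uint8) for d in seqs2]
        )
        consistent1 = (arr1 == arr1[0]).all(axis=0)
        consistent2 = (arr2 == arr2[0]).all(axis=0)
        hit = cs_all & consistent1 & consistent2 & (arr1[0] != arr2[0])
        for pos in np.nonzero(hit)[0]:
            markers.append(
                MarkerSite(gid, int(pos), chr(arr1[0, pos]), chr(arr2[0, pos]))
            )
    return markers


def classify_marker_site(
    column: PileupColumn | dict[str, int] | np.ndarray,
    marker: MarkerSite,
    pure_min: float = PURE_MIN,
    hybrid_min: float = HYBRID_MIN,
) -> MarkerClassification:
    """Assign the query's allele of origin at one marker site."""
    if isinstance(column, PileupColumn):
        vec = np.array([column.counts.get(b, 0) for b in BASES], dtype=np.int64)
    elif isinstance(column, dict):
        vec = np.array([column.get(b, 0) for b in BASES], dtype=np.int64)
    else:
        vec = np.asarray(column, dtype=np.int64)
    n1 = int(vec[BASE_INDEX[marker.group1_base]])
    n2 = int(vec[BASE_INDEX[marker.group2_base]])
    depth = int(vec.sum())
    other = depth - n1 - n2
    if depth == 0:
        return MarkerClassification(marker, 0, 0, 0, CAT_UNCERTAIN, "none",
                                    no_coverage=True)
    f1, f2 = n1 / depth, n2 / depth
    if f1 >= hybrid_min and f2 >= hybrid_min:
        dominant = "group1" if f1 > f2 else ("group2" if f2 > f1 else "none")
        return MarkerClassification(marker, n1, n2, other, CAT_BOTH, dominant)
    if f1 >= pure_min:
        return MarkerClassification(marker, n1, n2, other, CAT_GROUP1, "none")
    if f2 >= pure_min:
        return MarkerClassification(marker, n1, n2, other, CAT_GROUP2, "none")
    return MarkerClassification(
        marker, n1, n2, other, CAT_UNCERTAIN, "none", neither_base=(n1 + n2 == 0)
    )


def classify_sample(
    piles: dict[str, GenePileup],
    markers: list[MarkerSite],
    pure_min: float = PURE_MIN,
    hybrid_min: float = HYBRID_MIN,
) -> list[MarkerClassification]:
    """Classify a query sample's pileups at every marker site."""
    out = []
    for m in markers:
        pile = piles.get(m.gene_id)
        if pile is None:
            raise KeyError(f"no pileup for marker gene {m.gene_id!r}")
        out.append(
            classify_marker_site(pile.counts[m.position], m, pure_min, hybrid_min)
        )
    return out


def summarize_marker_profile(
    classifications: list[MarkerClassification],
) -> pd.DataFrame:
    """Category counts and proportions, both-allele sites split by dominance.

    Proportions are recomputed from the counts and sum to 1 over the
    four categories; the dominance split sums to the both-alleles
    proportion.
    """
    if not classifications:
        raise ValueError("no classifications to summarize")
    n = len(classifications)
    cats = [c.category for c in classifications]
    n_both = cats.count(CAT_BOTH)
    dom1 = sum(1 for c in classifications
               if c.category == CAT_BOTH and c.dominant == "group1")
    dom2 = sum(1 for c in classifications
               if c.category == CAT_BOTH and c.dominant == "group2")
    rows = [
        ("group1_allele", cats.count(CAT_GROUP1)),
        ("group2_allele", cats.count(CAT_GROUP2)),
        ("both_alleles", n_both),
        ("both_alleles_dominant_group1", dom1),
        ("both_alleles_dominant_group2", dom2),
        ("both_alleles_dominant_none", n_both - dom1 - dom2),
        ("uncertain", cats.count(CAT_UNCERTAIN)),
        ("uncertain_neither_marker_base",
         sum(1 for c in classifications if c.neither_base)),
    ]
    df = pd.DataFrame(rows, columns=["category", "n_sites"])
    df["proportion"] = df["n_sites"] / n
    return df
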