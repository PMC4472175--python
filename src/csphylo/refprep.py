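"""Paralog-aware reference preparation (m-CDS and s-CDS sets).

Cross-species read mapping is vulnerable to paralogous cross-mapping:
reads from one family member piling up on another inflate apparent
polymorphism and corrupt consensus calls.  The remedy implemented here
collapses a full CDS annotation into a *minimal* reference (m-CDS, the
longest member of each paralog group) and, more stringently, a
*singleton* reference (s-CDS, genes with no paralog at all).

Paralogy is decided from all-vs-all protein homology hits: a calibration
set of known paralog pairs fixes an E-value cutoff (the nearest-rank
upper 95th percentile of their E-values), pairs at or below the cutoff
become edges of an undirected graph, and paralog groups are its
connected components.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CdsRecord:
    """One reference coding sequence with an enforced reading frame."""

    gene_id: str
    sequence: str

    @property
    def length_nt(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class HomologyHit:
    """One directional protein homology hit (BLAST outfmt-6 style)."""

    query_id: str
    subject_id: str
    evalue: float
    bitscore: float = 0.0

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError("E-value must be non-negative")


@dataclass
class ParalogGroup:
    member_ids: frozenset[str]
    representative_id: str


def load_cds(records) -> list[CdsRecord]:
    """Validate raw (id, sequence) pairs; drop frame-broken entries.

    Sequences whose length is not a multiple of 3 cannot feed the codon
    machinery downstream and are dropped with a warning.
    """
    kept: list[CdsRecord] = []
    for gene_id, seq in records:
        seq = str(seq).upper()
        if len(seq) % 3 != 0:
            logger.warning(
                "dropping %s: length %d not divisible by 3", gene_id, len(seq)
            )
            continue
        kept.append(CdsRecord(gene_id, seq))
    return kept


def select_evalue_cutoff(
    known_paralog_evalues: list[float], percentile: float = 95.0
) -> float:
    """Nearest-rank upper percentile of known-paralog E-values.

    The cutoff is chosen to be at least as permissive (large) as the
    E-values of ``percentile`` percent of the known paralog pairs, so a
    graph built with it recovers essentially all of the calibration set.
    Nearest-rank (ceil(p/100 * n), 1-based) keeps the choice free of
    interpolation conventions.
    """
    if not known_paralog_evalues:
        raise ValueError("empty E-value list")
    if any(e < 0 for e in known_paralog_evalues):
        raise ValueError("E-values must be non-negative")
    vals = sorted(known_paralog_evalues)
    rank = max(1, math.ceil(percentile / 100.0 * len(vals)))
    return vals[rank - 1]


def build_paralog_groups(
    hits: list[HomologyHit],
    cutoff: float,
    gene_ids: list[str],
) -> list[ParalogGroup]:
    """Connected components of the thresholded homology graph.

    A pair (a, b) is joined when the smaller of its two directional
    E-values is <= cutoff (a pair is paralogous if either direction
    says so); self-hits are ignored.  Every gene with no qualifying
    edge forms a singleton group.  Representatives are chosen later,
    when sequence lengths are known (see :func:`build_reference`).
    """
    known = set(gene_ids)
    pair_eval: dict[tuple[str, str], float] = {}
    for h in hits:
        if h.query_id == h.subject_id:
            continue
        if h.query_id not in known or h.subject_id not in known:
            raise KeyError(
                f"homology hit references unknown gene: {h.query_id}/{h.subject_id}"
            )
        key = (min(h.query_id, h.subject_id), max(h.query_id, h.subject_id))
        e = pair_eval.get(key)
        pair_eval[key] = h.evalue if e is None else min(e, h.evalue)

    g = nx.Graph()
    g.add_nodes_from(gene_ids)
    g.add_edges_from(pair for pair, e in pair_eval.items() if e <= cutoff)
    groups = [
        ParalogGroup(frozenset(comp), representative_id=min(comp))
        for comp in nx.connected_components(g)
    ]
    groups.sort(key=lambda gr: min(gr.member_ids))
    return groups


def build_reference(
    groups: list[ParalogGroup],
    cds_set: list[CdsRecord],
    mode: str = "m-cds",
) -> list[CdsRecord]:
    """Select the mapping reference from paralog groups.

    m-CDS keeps one representative per group — the longest member, ties
    broken by lexicographically smallest gene_id.  s-CDS keeps only the
    singleton groups, i.e. genes without any paralog; s-CDS is therefore
    a subset of m-CDS.
    """
    if not groups:
        raise ValueError("empty group set")
    mode = mode.lower().replace("_", "-")
    if mode not in {"m-cds", "s-cds"}:
        raise ValueError(f"mode must be 'm-cds' or 's-cds', got {mode!r}")
    by_id = {r.gene_id: r for r in cds_set}
    covered = set()
    out: list[CdsRecord] = []
    for group in groups:
        members = sorted(group.member_ids)
        covered.update(members)
        if mode == "s-cds" and len(members) > 1:
            continue
        max_len = max(by_id[gid].length_nt for gid in members)
        rep = min(gid for gid in members if by_id[gid].length_nt == max_len)
        group.representative_id = rep
        out.append(by_id[rep])
    missing = set(by_id) - covered
    if missing:
        raise ValueError(f"groups do not cover the CDS set: missing {sorted(missing)[:5]}")
    out.sort(key=lambda r: r.gene_id)
    return out


# ---------------------------------------------------------------------------
# tabular I/O

def read_homology_tsv(path) -> list[HomologyHit]:
    """Read BLAST tabular (outfmt 6 style) hits.

    Accepts either the full 12-column layout (E-value in column 11,
    bitscore in column 12) or a minimal 4-column
    query/subject/evalue/bitscore file; lines starting with '#' are
    skipped.
    """
    hits: list[HomologyHit] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) >= 12:
                q, s, e, b = cols[0], cols[1], cols[10], cols[11]
            elif len(cols) >= 3:
                q, s, e = cols[0], cols[1], cols[2]
                b = cols[3] if len(cols) > 3 else "0"
            else:
                raise ValueError(f"malformed homology line: {line!r}")
            hits.append(HomologyHit(q, s, float(e), float(b)))
    return hits


def read_known_paralogs(path) -> list[tuple[str, str]]:
    """Two-column TSV of known paralog gene pairs."""
    pairs: list[tuple[str, str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            a, b = line.split("\t")[:2]
            pairs.append((a, b))
    return pairs
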