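"""Translated read mapping with decoy-calibrated score filtering.

Reads are placed on the reference CDS set in protein space: both the
read (six frames) and the reference (three forward frames, stops kept
as ``*``) are translated, exact 7-residue seed words anchor candidate
placements, and each candidate is rescored in nucleotide space as
matches minus mismatches over the ungapped aligned block.  This mapper
is a deliberately simple, fully scripted stand-in for BLAT's dnax/dnax
mode at desk scale; pre-computed BLAT PSL output can be ingested
instead via :func:`read_psl`.

The score cutoff separating trustworthy cross-species placements from
noise is calibrated empirically: the reference is shuffled preserving
its hexamer (k = 6) composition, the same reads are mapped against the
shuffled decoy, and the smallest integer cutoff is selected at which

    FDR(c) = #decoy reads with score >= c / #real reads with score >= c

drops below the requested bound (1% by default).  The realized ratio at
the selected cutoff is reported as q.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field

import numpy as np

from csphylo._seq import revcomp, translate_frame

logger = logging.getLogger(__name__)

SEED_WORD_AA = 7  # exact protein seed length
DEFAULT_MIN_SCORE = 18  # score floor below which alignments are discarded


@dataclass
class TranslatedAlignment:
    """One read placed on a CDS, in nucleotide coordinates."""

    read_id: str
    target_id: str
    score: int
    target_start: int  # 0-based, half-open span on the CDS
    target_end: int
    strand: str  # '+' read as given, '-' reverse complement aligned
    frame: int  # reference frame (0/1/2) of the seeding diagonal
    base_calls: list[tuple[int, str]] = field(default_factory=list)
    query_start: int = 0  # 0-based half-open, on the strand-oriented read
    query_end: int = 0

    @property
    def target_span(self) -> tuple[int, int]:
        return (self.target_start, self.target_end)


@dataclass
class ScoreCutoffResult:
    cutoff: int
    realized_fdr: float  # the q value: decoy/real passing-read ratio
    n_real_passing: int
    n_decoy_passing: int


class CutoffError(RuntimeError):
    """No score cutoff achieves the requested FDR bound."""


# ---------------------------------------------------------------------------
# k-let preserving decoy shuffle

def shuffle_sequence(seq: str, k: int = 6, rng: random.Random | None = None) -> str:
    """Shuffle one sequence preserving its k-mer multiset exactly.

    Implements the Euler-path shuffle on the (k-1)-mer De Bruijn
    multigraph: vertices are (k-1)-mers, each k-mer occurrence is an
    edge, and any Eulerian path from the original first (k-1)-mer to the
    original last one spells a sequence with the identical k-mer count
    vector (hence identical j-mer counts for all j <= k).  A uniform
    random arborescence toward the end vertex (sampled with Wilson's
    loop-erased random walks) fixes each vertex's last-exit edge; the
    remaining out-edges are permuted uniformly.
    """
    if len(seq) < k:
        raise ValueError(f"sequence length {len(seq)} shorter than k={k}")
    if rng is None:
        rng = random.Random()
    if len(seq) == k:
        return seq

    start = seq[: k - 1]
    end = seq[len(seq) - k + 1 :]
    out_edges: dict[str, list[str]] = {}
    for i in range(len(seq) - k + 1):
        u = seq[i : i + k - 1]
        v = seq[i + 1 : i + k]
        out_edges.setdefault(u, []).append(v)
        out_edges.setdefault(v, [])

    # Wilson's algorithm: random arborescence oriented toward `end`
    in_tree = {end}
    nxt: dict[str, str] = {}
    for u in out_edges:
        if not out_edges[u]:
            continue
        v = u
        while v not in in_tree:
            nxt[v] = rng.choice(out_edges[v])
            v = nxt[v]
        v = u
        while v not in in_tree:
            in_tree.add(v)
            v = nxt[v]

    # permute out-edges; the arborescence edge leaves each vertex last
    walk_edges: dict[str, list[str]] = {}
    for u, targets in out_edges.items():
        if not targets:
            continue
        pool = list(targets)
        if u != end:
            pool.remove(nxt[u])
        rng.shuffle(pool)
        if u != end:
            pool.append(nxt[u])
        walk_edges[u] = pool

    # walk the Eulerian path
    chunks = [start]
    u = start
    pos: dict[str, int] = {v: 0 for v in walk_edges}
    total = len(seq) - k + 1
    for _ in range(total):
        v = walk_edges[u][pos[u]]
        pos[u] += 1
        chunks.append(v[-1])
        u = v
    shuffled = "".join(chunks)
    assert len(shuffled) == len(seq)
    return shuffled


def shuffle_reference(
    reference: dict[str, str], k: int = 6, seed: int = 0
) -> dict[str, str]:
    """Independent k-let-preserving shuffle of every reference sequence."""
    rng = random.Random(seed)
    return {gid: shuffle_sequence(seq, k=k, rng=rng) for gid, seq in reference.items()}


# ---------------------------------------------------------------------------
# translated mapper

class TranslatedMapper:
    """Seeded protein-space mapper over a reference CDS set.

    The reference is indexed once (7-aa words of all three forward
    frames); each read is then translated in six frames, seeds are
    looked up, and every distinct (target, diagonal, strand) candidate
    is rescored in nucleotide space.  Only the unique best-scoring
    target is kept; exact score ties across different targets discard
    the read as ambiguous.
    """

    def __init__(self, reference: dict[str, str], min_score: int = DEFAULT_MIN_SCORE):
        self.reference = dict(reference)
        self.min_score = min_score
        self._index: dict[str, list[tuple[str, int]]] = {}
        for gid, seq in self.reference.items():
            for frame in range(3):
                prot = translate_frame(seq, frame)
                for i in range(len(prot) - SEED_WORD_AA + 1):
                    word = prot[i : i + SEED_WORD_AA]
                    if "X" in word:
                        continue
                    # diagonal: nt position on target of the word start
                    self._index.setdefault(word, []).append((gid, frame + 3 * i))

    def map_read(self, read_id: str, read_seq: str) -> TranslatedAlignment | None:
        read_seq = read_seq.upper()
        if any(c not in "ACGTN" for c in read_seq):
            raise ValueError(f"read {read_id}: non-ACGTN characters")
        if len(read_seq) < 3 * SEED_WORD_AA:
            return None

        candidates: set[tuple[str, int, str]] = set()
        for strand, seq in (("+", read_seq), ("-", revcomp(read_seq))):
            for frame in range(3):
                prot = translate_frame(seq, frame)
                for i in range(len(prot) - SEED_WORD_AA + 1):
                    word = prot[i : i + SEED_WORD_AA]
                    hits = self._index.get(word)
                    if not hits:
                        continue
                    read_nt = frame + 3 * i
                    for gid, t_nt in hits:
                        candidates.add((gid, t_nt - read_nt, strand))
        if not candidates:
            return None

        best: TranslatedAlignment | None = None
        best_key: tuple | None = None
        tied_targets: set[str] = set()
        for gid, diag, strand in candidates:
            aln = self._score_candidate(read_id, read_seq, gid, diag, strand)
            if aln is None:
                continue
            key = (-aln.score, aln.target_id, aln.target_start, aln.strand)
            if best is None or aln.score > best.score:
                best, best_key = aln, key
                tied_targets = {gid}
            elif aln.score == best.score:
                tied_targets.add(gid)
                if key < best_key:
                    best, best_key = aln, key
        if best is None or best.score < self.min_score:
            return None
        if len(tied_targets) > 1:
            return None  # ambiguous across targets
        return best

    def _score_candidate(
        self, read_id: str, read_seq: str, gid: str, diag: int, strand: str
    ) -> TranslatedAlignment | None:
        seq = read_seq if strand == "+" else revcomp(read_seq)
        target = self.reference[gid]
        t0 = max(0, diag)
        t1 = min(len(target), diag + len(seq))
        if t1 <= t0:
            return None
        score = 0
        calls: list[tuple[int, str]] = []
        for t in range(t0, t1):
            b = seq[t - diag]
            if b == target[t]:
                score += 1
            else:
                score -= 1
            if b != "N":
                calls.append((t, b))
        return TranslatedAlignment(
            read_id=read_id,
            target_id=gid,
            score=score,
            target_start=t0,
            target_end=t1,
            strand=strand,
            frame=t0 % 3,
            base_calls=calls,
            query_start=t0 - diag,
            query_end=t1 - diag,
        )

    def map_reads(self, reads) -> list[TranslatedAlignment]:
        """Map an iterable of (read_id, sequence)-like items; drop misses."""
        out = []
        for r in reads:
            rid, seq = (r.read_id, r.sequence) if hasattr(r, "read_id") else r
            aln = self.map_read(rid, seq)
            if aln is not None:
                out.append(aln)
        return out


def translated_map(
    read: tuple[str, str], reference: dict[str, str], min_score: int = DEFAULT_MIN_SCORE
) -> TranslatedAlignment | None:
    """One-shot convenience wrapper around :class:`TranslatedMapper`."""
    return TranslatedMapper(reference, min_score=min_score).map_read(*read)


# ---------------------------------------------------------------------------
# FDR-calibrated score cutoff

def choose_score_cutoff(
    real_scores,
    decoy_scores,
    fdr_max: float = 0.01,
) -> ScoreCutoffResult:
    """Smallest integer score cutoff with decoy/real passing ratio < fdr_max.

    Accepts alignment lists or bare score lists.  A valid cutoff must
    pass at least one real read (the vacuous pass-nothing solution is
    rejected); if no cutoff qualifies a :class:`CutoffError` is raised.
    """
    real = np.sort(np.asarray(_scores(real_scores), dtype=int))
    decoy = np.sort(np.asarray(_scores(decoy_scores), dtype=int))
    if real.size == 0:
        raise CutoffError("no real alignments to calibrate on")
    lo = int(min(real.min(), decoy.min())) if decoy.size else int(real.min())
    hi = int(real.max())
    for c in range(lo, hi + 1):
        n_real = int(real.size - np.searchsorted(real, c, side="left"))
        if n_real == 0:
            break
        n_decoy = int(decoy.size - np.searchsorted(decoy, c, side="left"))
        q = n_decoy / n_real
        if q < fdr_max:
            return ScoreCutoffResult(c, q, n_real, n_decoy)
    raise CutoffError(f"no cutoff achieves FDR < {fdr_max}")


def _scores(items) -> list[int]:
    return [it.score if hasattr(it, "score") else int(it) for it in items]


def filter_alignments(
    alignments: list[TranslatedAlignment], cutoff: int
) -> list[TranslatedAlignment]:
    return [a for a in alignments if a.score >= cutoff]


# ---------------------------------------------------------------------------
# PSL interchange (BLAT's 21-column format, 0-based half-open)

PSL_HEADER = (
    "psLayout version 3\n\n"
    "match\tmis- \trep. \tN's\tQ gap\tQ gap\tT gap\tT gap\tstrand\tQ        "
    "\tQ   \tQ    \tQ  \tT        \tT   \tT    \tT  \tblock\tblockSizes "
    "\tqStarts\t tStarts\n"
    + "-" * 159
    + "\n"
)


def write_psl(
    alignments: list[TranslatedAlignment],
    path,
    reads: dict[str, str],
    reference: dict[str, str],
    header: bool = False,
) -> None:
    """Write internal alignments as single-block 21-column PSL rows.

    Coordinates follow the PSL convention: qStart/qEnd on the forward
    query, tStart/tEnd 0-based half-open on the target, and qStarts on
    the reversed query for '-' strand rows.  Dialect note: read 'N's are
    tallied as misMatches (not nCount) so that the PSL score formula
    reproduces the internal match-minus-mismatch score exactly.
    """
    with open(path, "w") as fh:
        if header:
            fh.write(PSL_HEADER)
        for a in alignments:
            qsize = len(reads[a.read_id])
            tsize = len(reference[a.target_id])
            block = a.target_end - a.target_start
            match = (block + a.score) // 2
            mism = block - match
            if a.strand == "+":
                q_fwd0, q_fwd1 = a.query_start, a.query_end
            else:
                q_fwd0, q_fwd1 = qsize - a.query_end, qsize - a.query_start
            row = [
                match, mism, 0, 0, 0, 0, 0, 0, a.strand, a.read_id, qsize,
                q_fwd0, q_fwd1, a.target_id, tsize, a.target_start,
                a.target_end, 1, f"{block},", f"{a.query_start},",
                f"{a.target_start},",
            ]
            fh.write("\t".join(str(x) for x in row) + "\n")


def read_psl(path, reads: dict[str, str] | None = None) -> list[TranslatedAlignment]:
    """Parse a 21-column PSL file (with or without the psLayout header).

    The score is recomputed as matches + repMatches - misMatches -
    qNumInsert - tNumInsert.  When a read_id -> sequence dict is
    supplied, per-position base calls are reconstructed from the block
    lists (qStarts are interpreted on the reversed query for '-' rows,
    per the PSL specification); 'N' calls are excluded.
    """
    out: list[TranslatedAlignment] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or not line[0].isdigit():
                continue  # psLayout header / separator lines
            cols = line.split("\t")
            if len(cols) != 21:
                raise ValueError(
                    f"{path}:{lineno}: expected 21 PSL columns, got {len(cols)}"
                )
            (match, mism, rep, _ncount, q_ins, _qb, t_ins, _tb) = map(int, cols[:8])
            strand = cols[8][0]
            qname, qsize = cols[9], int(cols[10])
            tname, tsize = cols[13], int(cols[14])
            tstart, tend = int(cols[15]), int(cols[16])
            nblocks = int(cols[17])
            sizes = [int(x) for x in cols[18].rstrip(",").split(",")]
            qstarts = [int(x) for x in cols[19].rstrip(",").split(",")]
            tstarts = [int(x) for x in cols[20].rstrip(",").split(",")]
            if not (len(sizes) == len(qstarts) == len(tstarts) == nblocks):
                raise ValueError(f"{path}:{lineno}: block list lengths disagree")
            if tend > tsize or any(ts + bs > tsize for ts, bs in zip(tstarts, sizes)):
                raise ValueError(f"{path}:{lineno}: coordinates exceed target size")
            score = match + rep - mism - q_ins - t_ins
            calls: list[tuple[int, str]] = []
            if reads is not None and qname in reads:
                oriented = reads[qname] if strand == "+" else revcomp(reads[qname])
                for bs, qs, ts in zip(sizes, qstarts, tstarts):
                    for i in range(bs):
                        b = oriented[qs + i]
                        if b != "N":
                            calls.append((ts + i, b))
            out.append(
                TranslatedAlignment(
                    read_id=qname,
                    target_id=tname,
                    score=score,
                    target_start=tstart,
                    target_end=tend,
                    strand=strand,
                    frame=tstart % 3,
                    base_calls=calls,
                    query_start=qstarts[0],
                    query_end=qstarts[-1] + sizes[-1],
                )
            )
    return out


# ---------------------------------------------------------------------------
# paired-end concordance

@dataclass
class PairStats:
    frac_mate_mapped: float  # mapped reads whose mate is also mapped / mapped reads
    frac_same_target: float  # both-mapped pairs on one reference / both-mapped pairs
    n_mapped: int
    n_pairs_both_mapped: int
    same_target_defined: bool = True


def pair_stats(
    alignments: list[TranslatedAlignment],
    mate_of: dict[str, str],
) -> PairStats:
    """Concordance of paired reads among filtered alignments.

    ``mate_of`` maps each read id to its mate's id (both directions).
    The first fraction counts mapped reads whose mate also mapped, over
    all mapped reads belonging to pairs; the second counts, among pairs
    with both mates mapped, those mapped to the same reference sequence.
    """
    if not mate_of:
        raise ValueError("pair_stats requires paired-end pairing information")
    target_of = {a.read_id: a.target_id for a in alignments}
    mapped = [rid for rid in target_of if rid in mate_of]
    if not mapped:
        return PairStats(0.0, 0.0, 0, 0, same_target_defined=False)
    both = [rid for rid in mapped if mate_of[rid] in target_of]
    frac1 = len(both) / len(mapped)
    pairs = {frozenset((rid, mate_of[rid])) for rid in both}
    if not pairs:
        logger.info("no pair has both mates mapped; concordance undefined")
        return PairStats(frac1, 0.0, len(mapped), 0, same_target_defined=False)
    same = sum(1 for p in pairs if len({target_of[r] for r in p}) == 1)
    return PairStats(frac1, same / len(pairs), len(mapped), len(pairs))
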