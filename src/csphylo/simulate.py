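"""Synthetic data generation with known ground truth.

Produces every input the pipeline consumes — a reference CDS set
(optionally with diverged paralog families), species sequences evolved
along a known tree, single- or paired-end reads with uniform base
errors, and 1:1 two-haplotype hybrids — while recording the truth needed
to verify each downstream stage: true per-species sequences, the true
tree, read origins, paralog families and hybrid parentage.

The generator is deliberately simple where the pipeline is insensitive
to realism: substitutions are Jukes-Cantor per site with no indels
(reads either map or do not), read starts are uniform over each gene,
qualities are constant, and open reading frames are kept intact by
resampling any codon that a mutation would turn into a stop.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from csphylo._seq import BASES, STOP_CODONS
from csphylo.refprep import CdsRecord

_NONSTOP_CODONS = sorted(
    a + b + c
    for a in BASES
    for b in BASES
    for c in BASES
    if a + b + c not in STOP_CODONS
)


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic run.

    Defaults emulate a short-read transcriptome experiment on a small
    clade: 80 nt reads (the paired libraries of the motivating datasets
    ran 75-90 nt, single-end ones 100 nt), 1% uniform base error, and
    enough depth that the >=10-read consensus rule is comfortably met.
    """

    n_genes: int = 20
    gene_length_nt: int = 300
    tree: str | None = None  # newick with branch lengths (expected subs/site)
    substitution_model: str = "JC69"
    read_length_nt: int = 80
    mean_depth: float = 20.0
    error_rate: float = 0.01
    paired: bool = False
    insert_size: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if self.gene_length_nt % 3 != 0:
            raise ValueError("gene_length_nt must be a multiple of 3")
        if not (0 <= self.error_rate < 0.25):
            raise ValueError("error_rate must lie in [0, 0.25)")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if self.read_length_nt > self.gene_length_nt:
            raise ValueError("read_length_nt may not exceed gene_length_nt")
        if self.paired and self.insert_size > self.gene_length_nt:
            raise ValueError("insert_size may not exceed gene_length_nt")


@dataclass
class ReadOrigin:
    read_id: str
    species: str
    gene_id: str
    haplotype: int  # 0 for pure species; 0/1 for hybrid haplotypes
    start: int  # 0-based start on the source gene
    strand: str  # '+' or '-'
    mate_id: str | None = None


@dataclass
class GroundTruth:
    """Everything the tests need to verify the pipeline against."""

    species_sequences: dict[str, dict[str, object]] = field(default_factory=dict)
    tree: str | None = None
    hybrid_parents: dict[str, tuple[str, str]] = field(default_factory=dict)
    paralog_groups: dict[str, list[str]] = field(default_factory=dict)
    read_origins: list[ReadOrigin] = field(default_factory=list)


# ---------------------------------------------------------------------------
# encoding helpers

def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    out = np.empty(len(seq), dtype=np.uint8)
    for i, b in enumerate(BASES):
        out[arr == ord(b)] = i
    return out


def _decode(arr: np.ndarray) -> str:
    lut = np.frombuffer("ACGT".encode(), dtype=np.uint8)
    return lut[arr].tobytes().decode()


def _mutate_jc(arr: np.ndarray, p_sub: float, rng: np.random.Generator) -> np.ndarray:
    """One round of per-site JC substitution at probability p_sub.

    Frames are kept clean: codons mutated into stops have their mutated
    positions redrawn (still to a base different from the parent's, so
    the per-site substitution count is unaffected).
    """
    out = arr.copy()
    hit = rng.random(arr.size) < p_sub
    idx = np.nonzero(hit)[0]
    if idx.size:
        out[idx] = (arr[idx] + rng.integers(1, 4, size=idx.size)) % 4
        _fix_stops(out, arr, idx, rng)
    return out


def _fix_stops(out: np.ndarray, parent: np.ndarray, mutated: np.ndarray,
               rng: np.random.Generator) -> None:
    stop_arrs = [_encode(c) for c in sorted(STOP_CODONS)]
    codon_starts = {int(i) - int(i) % 3 for i in mutated}
    for cs in codon_starts:
        guard = 0
        while any(np.array_equal(out[cs : cs + 3], s) for s in stop_arrs):
            for pos in mutated[(mutated >= cs) & (mutated < cs + 3)]:
                out[pos] = (parent[pos] + rng.integers(1, 4)) % 4
            guard += 1
            if guard > 100:  # pragma: no cover - unreachable, safety net
                raise RuntimeError("stop-codon resampling did not converge")


# ---------------------------------------------------------------------------
# reference simulation

def simulate_reference(
    config: SimulationConfig,
    n_paralog_families: int = 0,
    family_size: int = 2,
    divergence: float = 0.3,
) -> tuple[list[CdsRecord], dict[str, list[str]]]:
    """Draw a frame-clean reference CDS set, optionally with paralog families.

    Each gene starts with ATG and contains no in-frame stop codon.  When
    paralog families are requested, the first ``n_paralog_families``
    genes act as family ancestors and ``family_size - 1`` copies each,
    diverged at roughly ``divergence`` of their sites, are appended.
    Returns the records plus the family map (ancestor -> all members,
    ancestor included); the map is empty when no families are requested.
    """
    rng = np.random.default_rng(config.seed)
    n_codons = config.gene_length_nt // 3 - 1
    records: list[CdsRecord] = []
    for g in range(config.n_genes):
        codons = rng.choice(_NONSTOP_CODONS, size=n_codons)
        records.append(CdsRecord(f"GENE{g + 1:04d}", "ATG" + "".join(codons)))

    families: dict[str, list[str]] = {}
    for f in range(min(n_paralog_families, config.n_genes)):
        ancestor = records[f]
        members = [ancestor.gene_id]
        parent = _encode(ancestor.sequence)
        for c in range(1, family_size):
            child = parent.copy()
            # leave the ATG intact so copies are themselves valid CDS
            tail = _mutate_jc(parent[3:], divergence, rng)
            child[3:] = tail
            gid = f"{ancestor.gene_id}p{c}"
            records.append(CdsRecord(gid, _decode(child)))
            members.append(gid)
        families[ancestor.gene_id] = members
    return records, families


# ---------------------------------------------------------------------------
# evolution along a tree

def evolve_along_tree(
    reference: list[CdsRecord] | dict[str, str],
    tree: str,
    model: str = "JC69",
    seed: int = 0,
) -> dict[str, dict[str, str]]:
    """Evolve the reference down a newick tree, one JC process per site.

    Branch lengths are expected substitutions per site; the per-branch
    substitution probability is the JC closed form
    ``p = 3/4 * (1 - exp(-4 b / 3))``.  Returns, for every leaf label,
    a gene_id -> sequence dict of full-length species sequences.
    """
    if model.upper() not in {"JC", "JC69", "JUKES-CANTOR"}:
        raise ValueError(f"unknown substitution model: {model!r}")
    if isinstance(reference, dict):
        genes = list(reference.items())
    else:
        genes = [(r.gene_id, r.sequence) for r in reference]
    gene_ids = [g for g, _ in genes]
    lengths = [len(s) for _, s in genes]
    bounds = np.cumsum([0] + lengths)
    root = _encode("".join(s for _, s in genes))

    t = dendropy.Tree.get(data=tree, schema="newick")
    labels = [lf.taxon.label for lf in t.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        raise ValueError("tree leaf labels must be unique")

    rng = np.random.default_rng(seed)
    leaf_seqs: dict[str, dict[str, str]] = {}
    stack: list[tuple[object, np.ndarray]] = [(t.seed_node, root)]
    while stack:
        node, seq = stack.pop()
        b = node.edge.length or 0.0
        if b < 0 or not np.isfinite(b):
            raise ValueError("branch lengths must be finite and non-negative")
        if b > 0:
            p = 0.75 * (1.0 - np.exp(-4.0 * b / 3.0))
            seq = _mutate_jc(seq, p, rng)
        if node.is_leaf():
            full = seq
            leaf_seqs[node.taxon.label] = {
                gid: _decode(full[bounds[i] : bounds[i + 1]])
                for i, gid in enumerate(gene_ids)
            }
        else:
            for child in node.child_nodes():
                stack.append((child, seq))
    return leaf_seqs


# ---------------------------------------------------------------------------
# hybrids

def make_hybrid(
    parent_a: dict[str, str],
    parent_b: dict[str, str],
    label: str,
) -> dict[str, tuple[str, str]]:
    """Combine two parental gene sets into a two-haplotype hybrid species.

    The returned mapping carries both parental haplotypes per gene; read
    simulation samples them 1:1.  ``label`` is only used in error text —
    callers register the hybrid under it in their species dict.
    """
    if set(parent_a) != set(parent_b):
        raise ValueError(f"hybrid {label!r}: parents carry different gene sets")
    return {g: (parent_a[g], parent_b[g]) for g in parent_a}


# ---------------------------------------------------------------------------
# read simulation

@dataclass
class SimRead:
    read_id: str
    sequence: str


def simulate_reads(
    species_sequences: dict[str, object],
    config: SimulationConfig,
    species: str = "sample",
    rng: np.random.Generator | None = None,
    depth_multipliers: dict[str, float] | None = None,
) -> tuple[list[SimRead], list[ReadOrigin]]:
    """Simulate an RNA-Seq library from one species' gene set.

    ``species_sequences`` maps gene_id to either a sequence (pure
    species) or a 2-tuple of haplotype sequences (hybrid; each
    read/fragment picks a haplotype with probability 1/2).  Per-gene
    read counts are Poisson with mean ``mean_depth * L / read_length``
    (fragment counts are half that in paired mode, so nucleotide depth
    is comparable); base errors are uniform substitutions at
    ``error_rate``.  ``depth_multipliers`` scales individual genes'
    expected depth, which is how low-coverage genes for the retention
    filter are produced.
    """
    if not species_sequences:
        raise ValueError("no input sequences to simulate reads from")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    L_read = config.read_length_nt
    reads: list[SimRead] = []
    origins: list[ReadOrigin] = []
    for gene_id in sorted(species_sequences):
        entry = species_sequences[gene_id]
        haplotypes = entry if isinstance(entry, tuple) else (entry,)
        L = len(haplotypes[0])
        mult = 1.0 if depth_multipliers is None else depth_multipliers.get(gene_id, 1.0)
        mean_reads = config.mean_depth * mult * L / L_read
        if config.paired:
            n_frag = rng.poisson(mean_reads / 2.0)
            span = config.insert_size
        else:
            n_frag = rng.poisson(mean_reads)
            span = L_read
        for i in range(n_frag):
            hap = int(rng.integers(len(haplotypes)))
            src = haplotypes[hap]
            start = int(rng.integers(0, L - span + 1))
            if config.paired:
                rid1 = f"{species}|{gene_id}|{i}/1"
                rid2 = f"{species}|{gene_id}|{i}/2"
                fwd = src[start : start + L_read]
                rev = _revcomp(src[start + span - L_read : start + span])
                reads.append(SimRead(rid1, _with_errors(fwd, config.error_rate, rng)))
                reads.append(SimRead(rid2, _with_errors(rev, config.error_rate, rng)))
                origins.append(ReadOrigin(rid1, species, gene_id, hap, start, "+", rid2))
                origins.append(
                    ReadOrigin(rid2, species, gene_id, hap,
                               start + span - L_read, "-", rid1)
                )
            else:
                rid = f"{species}|{gene_id}|{i}"
                frag = src[start : start + L_read]
                reads.append(SimRead(rid, _with_errors(frag, config.error_rate, rng)))
                origins.append(ReadOrigin(rid, species, gene_id, hap, start, "+"))
    return reads, origins


def _revcomp(seq: str) -> str:
    from csphylo._seq import revcomp

    return revcomp(seq)


def _with_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = _encode(seq)
    hit = rng.random(arr.size) < rate
    idx = np.nonzero(hit)[0]
    if idx.size:
        arr[idx] = (arr[idx] + rng.integers(1, 4, size=idx.size)) % 4
    return _decode(arr)
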