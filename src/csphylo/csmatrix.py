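"""Codon-wise intersection of consensus sites into a supermatrix.

A reference codon enters the matrix only when all three of its
positions are consensus sites in *every* sample and its gene passes the
10% CS-coverage retention filter in every sample.  Because all derived
sequences share the reference coordinate system, retained codons are
directly column-comparable across samples and no multiple sequence
alignment is needed; they are concatenated in (gene_id, codon index)
order.  Each matrix column carries its codon position (1/2/3), which is
exported as partitions for downstream partitioned ML/Bayesian inference
(the motivating analyses ran GTR+GAMMA+I).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from csphylo.consensus import DerivedSequence

logger = logging.getLogger(__name__)


@dataclass
class CsMatrix:
    taxa: list[str]
    characters: list[str]  # per-taxon concatenated upper-case rows
    provenance: list[tuple[str, int]]  # per codon: (gene_id, codon index)
    partition_map: np.ndarray  # per column: codon position 1/2/3

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_columns(self) -> int:
        return len(self.characters[0]) if self.characters else 0

    def row(self, taxon: str) -> str:
        return self.characters[self.taxa.index(taxon)]


class EmptyMatrixError(RuntimeError):
    """No codon survived the cross-sample CS intersection."""


def build_cs_matrix(
    derived_by_sample: dict[str, dict[str, DerivedSequence]],
) -> CsMatrix:
    """Intersect CS codons across samples and concatenate them.

    ``derived_by_sample`` maps sample label -> (gene_id -> derived
    sequence), all against the same reference.  Genes must be retained
    (>= 10% CS coverage) in every sample; codons must be CS at all three
    positions in every sample.  Raises :class:`EmptyMatrixError` with
    per-gene diagnostics when nothing survives.
    """
    if len(derived_by_sample) < 2:
        raise ValueError("need at least two samples to intersect")
    samples = sorted(derived_by_sample)
    gene_sets = [
        {g for g, d in derived_by_sample[s].items() if d.retained} for s in samples
    ]
    genes = sorted(set.intersection(*gene_sets))

    rows: dict[str, list[str]] = {s: [] for s in samples}
    provenance: list[tuple[str, int]] = []
    dropped: dict[str, int] = {}
    for gid in genes:
        per_sample = [derived_by_sample[s][gid] for s in samples]
        L = len(per_sample[0].symbols)
        if any(len(d.symbols) != L for d in per_sample):
            raise ValueError(f"gene {gid}: derived lengths differ between samples")
        joint_cs = np.logical_and.reduce([d.cs_mask for d in per_sample])
        codon_ok = joint_cs[: L - L % 3].reshape(-1, 3).all(axis=1)
        kept = np.nonzero(codon_ok)[0]
        dropped[gid] = int(codon_ok.size - kept.size)
        for j in kept:
            provenance.append((gid, int(j)))
            for s, d in zip(samples, per_sample):
                rows[s].append(d.symbols[3 * j : 3 * j + 3])
    if not provenance:
        detail = ", ".join(f"{g}: 0/{dropped[g] or '?'} codons" for g in genes[:10])
        raise EmptyMatrixError(
            "no codon is CS in all samples"
            + (f" (first genes: {detail})" if genes else " (no gene retained in all samples)")
        )
    characters = ["".join(rows[s]) for s in samples]
    partition_map = np.tile([1, 2, 3], len(provenance))
    return CsMatrix(samples, characters, provenance, partition_map)


def codon_position_submatrix(matrix: CsMatrix, position: int) -> CsMatrix:
    """Columns of one codon position (1, 2 or 3), order preserved."""
    if position not in (1, 2, 3):
        raise ValueError("codon position must be 1, 2 or 3")
    keep = np.nonzero(matrix.partition_map == position)[0]
    chars = ["".join(row[i] for i in keep) for row in matrix.characters]
    return CsMatrix(
        list(matrix.taxa),
        chars,
        list(matrix.provenance),
        np.full(keep.size, position),
    )


# ---------------------------------------------------------------------------
# export

def sanitize_labels(taxa: list[str]) -> dict[str, str]:
    """PHYLIP/NEXUS-safe labels; the mapping is logged when it renames."""
    mapping = {}
    seen = set()
    for t in taxa:
        clean = re.sub(r"[\s,;:()\[\]]+", "_", t)
        base, i = clean, 1
        while clean in seen:
            i += 1
            clean = f"{base}_{i}"
        seen.add(clean)
        mapping[t] = clean
        if clean != t:
            logger.warning("taxon label %r sanitized to %r", t, clean)
    return mapping


def write_matrix(
    matrix: CsMatrix,
    path,
    fmt: str = "relaxed-phylip",
    partition_path=None,
    partition_style: str = "none",
) -> None:
    """Write the matrix (relaxed PHYLIP, FASTA or NEXUS) plus partitions.

    ``partition_style='raxml'`` writes ``DNA, codonN = N-L\\3`` lines to
    ``partition_path``; ``'nexus-sets'`` appends a SETS block (NEXUS
    output only).  Output is byte-stable for a fixed matrix.
    """
    labels = sanitize_labels(matrix.taxa)
    L = matrix.n_columns
    lines: list[str] = []
    if fmt == "relaxed-phylip":
        lines.append(f"{matrix.n_taxa} {L}")
        for t, row in zip(matrix.taxa, matrix.characters):
            lines.append(f"{labels[t]} {row}")
    elif fmt == "fasta":
        for t, row in zip(matrix.taxa, matrix.characters):
            lines.append(f">{labels[t]}")
            lines.append(row)
    elif fmt == "nexus":
        lines += [
            "#NEXUS",
            "BEGIN DATA;",
            f"    DIMENSIONS NTAX={matrix.n_taxa} NCHAR={L};",
            "    FORMAT DATATYPE=DNA MISSING=? GAP=-;",
            "    MATRIX",
        ]
        for t, row in zip(matrix.taxa, matrix.characters):
            lines.append(f"    {labels[t]} {row}")
        lines += ["    ;", "END;"]
        if partition_style == "nexus-sets":
            lines += ["BEGIN SETS;"]
            for p in (1, 2, 3):
                lines.append(f"    CHARSET codon{p} = {p}-{L}\\3;")
            lines += ["END;"]
    else:
        raise ValueError(f"unknown format {fmt!r}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")

    if partition_style == "raxml":
        if partition_path is None:
            raise ValueError("raxml partition_style requires partition_path")
        with open(partition_path, "w") as fh:
            for p in (1, 2, 3):
                fh.write(f"DNA, codon{p} = {p}-{L}\\3\n")


def read_fasta_matrix(path) -> CsMatrix:
    """Re-read a FASTA matrix written by :func:`write_matrix`.

    Provenance is not stored in FASTA; the returned matrix carries an
    empty provenance list and the standard 1/2/3 partition cycle.
    """
    from Bio import SeqIO

    taxa, chars = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        taxa.append(rec.id)
        chars.append(str(rec.seq).upper())
    if not taxa:
        raise ValueError(f"no sequences in {path}")
    L = len(chars[0])
    if any(len(c) != L for c in chars):
        raise ValueError("rows of unequal length")
    return CsMatrix(taxa, chars, [], np.tile([1, 2, 3], L // 3)[:L])


def provenance_table(matrix: CsMatrix) -> pd.DataFrame:
    """Column provenance TSV: column (1-based), gene, codon, position."""
    rows = []
    for j, (gid, codon) in enumerate(matrix.provenance):
        for p in (1, 2, 3):
            rows.append((3 * j + p, gid, codon, p))
    return pd.DataFrame(rows, columns=["column", "gene_id", "codon_index", "codon_position"])
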