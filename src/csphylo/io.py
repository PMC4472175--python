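"""FASTA/FASTQ plumbing shared by the CLI and tests (Biopython-backed)."""

from __future__ import annotations

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def read_fasta(path) -> dict[str, str]:
    """FASTA -> ordered {id: upper-case sequence}."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        out[rec.id] = str(rec.seq).upper()
    return out


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fastq(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fastq")}


def write_fastq(reads, path, quality: int = 40) -> None:
    """Write (read_id, sequence) items with a constant Phred+33 quality."""
    with open(path, "w") as fh:
        for r in reads:
            rid, seq = (r.read_id, r.sequence) if hasattr(r, "read_id") else r
            fh.write(f"@{rid}\n{seq}\n+\n{chr(33 + quality) * len(seq)}\n")
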