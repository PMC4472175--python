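"""Small shared sequence helpers (translation, complement, codon sets)."""

from __future__ import annotations

from Bio.Data import CodonTable

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

_standard = CodonTable.unambiguous_dna_by_id[1]
CODON_TO_AA: dict[str, str] = dict(_standard.forward_table)
for _stop in _standard.stop_codons:
    CODON_TO_AA[_stop] = "*"
STOP_CODONS = frozenset(_standard.stop_codons)

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def translate_frame(seq: str, frame: int) -> str:
    """Translate one forward frame; codons with N (or short tails) become 'X'.

    Stop codons are kept as '*' so that out-of-frame reference peptides
    remain matchable by exact seed words.
    """
    aa = []
    get = CODON_TO_AA.get
    for i in range(frame, len(seq) - 2, 3):
        aa.append(get(seq[i : i + 3], "X"))
    return "".join(aa)


def kmer_counts(seq: str, k: int) -> dict[str, int]:
    counts: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        w = seq[i : i + k]
        counts[w] = counts.get(w, 0) + 1
    return counts
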