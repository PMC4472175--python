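"""Shared test helpers."""

import numpy as np

from csphylo.consensus import GenePileup, derive_sequence


def derived_from_symbols(gene_id, symbols, retained=True):
    """Construct a DerivedSequence carrying exactly these symbols."""
    counts = np.zeros((len(symbols), 4), dtype=np.int64)
    for i, s in enumerate(symbols):
        if s == "-":
            continue
        counts[i, "ACGT".index(s.upper())] = 20 if s.isupper() else 5
    d = derive_sequence(GenePileup(gene_id, counts), min_cs_cover=0.0)
    assert d.symbols == symbols
    d.retained = retained
    return d
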