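"""Per-site consensus calling on read pileups (CS/AS/UNS).

Every filtered alignment contributes its base calls to a per-gene
pileup of A/C/G/T counts.  Each reference position is then classified:

* **CS** (consensus site, upper-case base): depth >= 10 and the most
  frequent base carries >= 80% of the mapped reads;
* **UNS** (uncovered site, ``-``): no read maps to the position;
* **AS** (ambiguous site, lower-case base): covered but failing the CS
  rule; the symbol is the lower-case majority base, alphabetically
  first among ties.

Genes are retained for matrix building only when CS positions cover at
least 10% of the CDS length — a guard against spurious fragments and
reference/sample ORF mismatch.  Depth counts A/C/G/T calls only: read
'N's and gapped positions contribute nothing.  Overlapping mates are
counted as two independent observations.  Coordinates are 0-based
internally and 1-based in the tabular output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from csphylo._seq import BASE_INDEX, BASES

MIN_DEPTH = 10
MIN_AGREE = 0.80
MIN_CS_COVER = 0.10

CATEGORY_CS = "CS"
CATEGORY_AS = "AS"
CATEGORY_UNS = "UNS"


@dataclass
class PileupColumn:
    gene_id: str
    position: int  # 0-based on the reference CDS
    counts: dict[str, int]

    @property
    def depth(self) -> int:
        return sum(self.counts.values())


@dataclass
class SiteCall:
    category: str
    symbol: str
    depth: int
    agreement_fraction: float


@dataclass
class GenePileup:
    gene_id: str
    counts: np.ndarray  # (L, 4) int array, columns in A,C,G,T order

    @property
    def length(self) -> int:
        return self.counts.shape[0]

    def column(self, position: int) -> PileupColumn:
        return PileupColumn(
            self.gene_id,
            position,
            {b: int(self.counts[position, i]) for b, i in BASE_INDEX.items()},
        )


@dataclass
class DerivedSequence:
    """Per-gene derived sequence: one symbol per reference position."""

    gene_id: str
    symbols: str  # upper-case CS, lower-case AS, '-' UNS
    depths: np.ndarray
    agreement: np.ndarray  # max-base fraction; NaN at depth 0
    cs_cover: float
    retained: bool

    @property
    def categories(self) -> np.ndarray:
        cats = np.full(len(self.symbols), CATEGORY_AS, dtype=object)
        arr = np.frombuffer(self.symbols.encode(), dtype=np.uint8)
        cats[(arr >= ord("A")) & (arr <= ord("Z"))] = CATEGORY_CS
        cats[arr == ord("-")] = CATEGORY_UNS
        return cats

    @property
    def cs_mask(self) -> np.ndarray:
        arr = np.frombuffer(self.symbols.encode(), dtype=np.uint8)
        return (arr >= ord("A")) & (arr <= ord("Z"))

    def site_call(self, position: int) -> SiteCall:
        sym = self.symbols[position]
        cat = CATEGORY_UNS if sym == "-" else (CATEGORY_CS if sym.isupper() else CATEGORY_AS)
        agree = self.agreement[position]
        return SiteCall(cat, sym, int(self.depths[position]),
                        float(agree) if np.isfinite(agree) else 0.0)


def build_pileup(alignments, reference: dict[str, str]) -> dict[str, GenePileup]:
    """Accumulate base calls of filtered alignments into per-gene pileups.

    Every gene of the reference gets a pileup (all-zero when nothing
    maps); an alignment to a target absent from the reference is an
    error.
    """
    piles = {
        gid: GenePileup(gid, np.zeros((len(seq), 4), dtype=np.int64))
        for gid, seq in reference.items()
    }
    for a in alignments:
        pile = piles.get(a.target_id)
        if pile is None:
            raise KeyError(f"alignment targets unknown gene {a.target_id!r}")
        counts = pile.counts
        for pos, base in a.base_calls:
            idx = BASE_INDEX.get(base)
            if idx is None:
                continue  # N / ambiguity codes carry no evidence
            if not 0 <= pos < counts.shape[0]:
                raise IndexError(
                    f"alignment position {pos} outside {a.target_id} "
                    f"(length {counts.shape[0]})"
                )
            counts[pos, idx] += 1
    return piles


def classify_site(
    column: PileupColumn | dict[str, int] | np.ndarray,
    min_depth: int = MIN_DEPTH,
    min_agree: float = MIN_AGREE,
) -> SiteCall:
    """Classify one pileup column by the CS/AS/UNS rule."""
    if isinstance(column, PileupColumn):
        vec = np.array([column.counts.get(b, 0) for b in BASES], dtype=np.int64)
    elif isinstance(column, dict):
        vec = np.array([column.get(b, 0) for b in BASES], dtype=np.int64)
    else:
        vec = np.asarray(column, dtype=np.int64)
    if (vec < 0).any():
        raise ValueError("negative base counts")
    depth = int(vec.sum())
    if depth == 0:
        return SiteCall(CATEGORY_UNS, "-", 0, 0.0)
    top = int(np.argmax(vec))  # argmax takes the first maximum: alphabetical tie-break
    agree = vec[top] / depth
    if depth >= min_depth and agree >= min_agree:
        return SiteCall(CATEGORY_CS, BASES[top], depth, float(agree))
    return SiteCall(CATEGORY_AS, BASES[top].lower(), depth, float(agree))


def derive_sequence(
    pileup: GenePileup,
    min_depth: int = MIN_DEPTH,
    min_agree: float = MIN_AGREE,
    min_cs_cover: float = MIN_CS_COVER,
) -> DerivedSequence:
    """Vectorised CS/AS/UNS calling over a whole gene.

    Equivalent to :func:`classify_site` at every position (asserted by
    the test suite); also computes the CS coverage fraction and the
    retention flag.
    """
    counts = pileup.counts
    if (counts < 0).any():
        raise ValueError("negative base counts")
    depth = counts.sum(axis=1)
    top = counts.argmax(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        agree = np.where(depth > 0, counts.max(axis=1) / np.maximum(depth, 1), np.nan)
    is_cs = (depth >= min_depth) & (np.nan_to_num(agree) >= min_agree)
    is_uns = depth == 0

    base_arr = np.frombuffer(BASES.encode(), dtype=np.uint8)
    lower_arr = np.frombuffer(BASES.lower().encode(), dtype=np.uint8)
    syms = lower_arr[top].copy()
    syms[is_cs] = base_arr[top[is_cs]]
    syms[is_uns] = ord("-")
    symbols = syms.tobytes().decode()

    cs_cover = float(is_cs.sum() / counts.shape[0])
    return DerivedSequence(
        gene_id=pileup.gene_id,
        symbols=symbols,
        depths=depth,
        agreement=agree,
        cs_cover=cs_cover,
        retained=cs_cover >= min_cs_cover,
    )


def derive_all(
    piles: dict[str, GenePileup],
    min_depth: int = MIN_DEPTH,
    min_agree: float = MIN_AGREE,
    min_cs_cover: float = MIN_CS_COVER,
) -> dict[str, DerivedSequence]:
    return {
        gid: derive_sequence(p, min_depth, min_agree, min_cs_cover)
        for gid, p in piles.items()
    }


def pool_pileups(pileup_sets: list[dict[str, GenePileup]]) -> dict[str, GenePileup]:
    """Element-wise sum of per-library pileups against one reference.

    Pooling raises depth at shallow sites, so positions below the depth
    threshold in each library alone can become CS in the pool; the
    classification is re-applied to the pooled counts by the caller.
    """
    if not pileup_sets:
        raise ValueError("nothing to pool")
    first = pileup_sets[0]
    genes = set(first)
    for other in pileup_sets[1:]:
        if set(other) != genes or any(
            other[g].length != first[g].length for g in genes
        ):
            raise ValueError("pileups were built against different references")
    return {
        g: GenePileup(g, np.sum([ps[g].counts for ps in pileup_sets], axis=0))
        for g in genes
    }


def consistency_report(
    derived_a: dict[str, DerivedSequence],
    derived_b: dict[str, DerivedSequence],
) -> tuple[pd.DataFrame, float]:
    """Cross-library concordance of CS calls (e.g. juvenile vs mature leaf).

    Per gene, over positions that are CS in both libraries, the fraction
    with identical consensus base; genes with no jointly-CS position are
    reported with NaN and excluded from the overall mean.
    """
    rows = []
    for gid in sorted(set(derived_a) & set(derived_b)):
        a, b = derived_a[gid], derived_b[gid]
        if len(a.symbols) != len(b.symbols):
            raise ValueError(f"gene {gid}: derived lengths differ")
        joint = a.cs_mask & b.cs_mask
        n_joint = int(joint.sum())
        if n_joint == 0:
            rows.append((gid, 0, np.nan))
            continue
        sa = np.frombuffer(a.symbols.encode(), dtype=np.uint8)[joint]
        sb = np.frombuffer(b.symbols.encode(), dtype=np.uint8)[joint]
        rows.append((gid, n_joint, float((sa == sb).mean())))
    df = pd.DataFrame(rows, columns=["gene_id", "n_joint_cs", "identical_fraction"])
    mean = float(df["identical_fraction"].dropna().mean()) if len(df) else float("nan")
    return df, mean


def pileup_table(piles: dict[str, GenePileup], **thresholds) -> pd.DataFrame:
    """Human-readable pileup TSV: gene, 1-based position, counts, call."""
    rows = []
    for gid in sorted(piles):
        p = piles[gid]
        derived = derive_sequence(p, **thresholds)
        for i in range(p.length):
            a, c, g, t = (int(x) for x in p.counts[i])
            rows.append((gid, i + 1, a, c, g, t, a + c + g + t, derived.symbols[i]))
    return pd.DataFrame(
        rows, columns=["gene_id", "pos", "A", "C", "G", "T", "depth", "call"]
    )
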