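"""Distance-based tree building and comparison for internal checks.

The supermatrix itself is meant for external partitioned ML/Bayesian
inference; this module provides just enough phylogenetics to verify
matrix quality in-process: Jukes-Cantor distances from the CS matrix,
a standard neighbor-joining reconstruction, and the Robinson-Foulds
bipartition distance between trees.  JC rather than GTR keeps the
distance closed-form and dependency-free — adequate for topology smoke
tests on simulated data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import dendropy
import numpy as np

from csphylo.csmatrix import CsMatrix

logger = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    taxa: list[str]
    values: np.ndarray  # symmetric, zero diagonal

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.taxa), len(self.taxa)):
            raise ValueError("matrix shape does not match taxa")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0):
            raise ValueError("diagonal must be zero")
        if (v < 0).any() or not np.isfinite(v).all():
            raise ValueError("distances must be finite and non-negative")
        self.values = v


class SaturationError(ValueError):
    """Observed p-distance >= 0.75: the JC transform is undefined."""


def p_distance(matrix: CsMatrix) -> DistanceMatrix:
    """Pairwise mismatch fraction over all matrix columns."""
    if matrix.n_taxa < 2 or matrix.n_columns == 0:
        raise ValueError("need >= 2 taxa and >= 1 column")
    rows = [np.frombuffer(r.encode(), dtype=np.uint8) for r in matrix.characters]
    n = len(rows)
    d = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        d[i, j] = d[j, i] = float((rows[i] != rows[j]).mean())
    return DistanceMatrix(list(matrix.taxa), d)


def jc_distance(matrix: CsMatrix) -> DistanceMatrix:
    """Jukes-Cantor distance d = -(3/4) ln(1 - 4p/3) from the CS matrix."""
    pd_ = p_distance(matrix)
    p = pd_.values
    if (p >= 0.75).any():
        worst = p.max()
        raise SaturationError(f"p-distance {worst:.3f} >= 0.75, JC distance undefined")
    d = -0.75 * np.log1p(-4.0 * p / 3.0)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(pd_.taxa), d)


# ---------------------------------------------------------------------------
# neighbor joining

def neighbor_joining(dist: DistanceMatrix) -> str:
    """Saitou-Nei neighbor joining; returns an unrooted newick string.

    Uses the Q criterion with Studier-Keppler distance updates; ties in
    Q are broken deterministically on the (i, j) index pair.  Negative
    branch-length estimates are clamped to zero with a log note.
    """
    n = len(dist.taxa)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    d = dist.values.astype(float).copy()
    nodes: list[str] = [_quote(t) for t in dist.taxa]
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        totals = sub.sum(axis=1)
        best = None
        for ai, aj in combinations(range(m), 2):
            q = (m - 2) * sub[ai, aj] - totals[ai] - totals[aj]
            key = (q, active[ai], active[aj])
            if best is None or key < best:
                best = key
                pick = (ai, aj)
        ai, aj = pick
        i, j = active[ai], active[aj]
        dij = sub[ai, aj]
        li = 0.5 * dij + (totals[ai] - totals[aj]) / (2 * (m - 2))
        lj = dij - li
        li, lj = _clamp(li), _clamp(lj)
        new = d.shape[0]
        d = np.pad(d, ((0, 1), (0, 1)))
        for ak in range(m):
            k = active[ak]
            if k in (i, j):
                continue
            d[new, k] = d[k, new] = 0.5 * (sub[ai, ak] + sub[aj, ak] - dij)
        nodes.append(f"({nodes[i]}:{li:.6f},{nodes[j]}:{lj:.6f})")
        active = [k for k in active if k not in (i, j)] + [new]

    i, j, k = active
    # three-point formulas for the final star resolution
    li = _clamp(0.5 * (d[i, j] + d[i, k] - d[j, k]))
    lj = _clamp(0.5 * (d[i, j] + d[j, k] - d[i, k]))
    lk = _clamp(0.5 * (d[i, k] + d[j, k] - d[i, j]))
    return f"({nodes[i]}:{li:.6f},{nodes[j]}:{lj:.6f},{nodes[k]}:{lk:.6f});"


def _clamp(x: float) -> float:
    if x < 0:
        logger.info("negative branch length %.6f clamped to 0", x)
        return 0.0
    return float(x)


def _quote(label: str) -> str:
    if any(c in label for c in " (),;:[]'"):
        return "'" + label.replace("'", "''") + "'"
    return label


# ---------------------------------------------------------------------------
# Robinson-Foulds

def _bipartitions(newick: str, leaf_set: frozenset[str]) -> set[frozenset[str]]:
    tree = dendropy.Tree.get(data=newick, schema="newick")
    leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    if leaves != leaf_set:
        raise ValueError("trees have different leaf sets")
    anchor = min(leaf_set)
    splits: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node is tree.seed_node:
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if len(side) <= 1 or len(side) >= len(leaf_set) - 1:
            continue  # trivial split
        if anchor in side:
            side = leaf_set - side
        splits.add(side)
    return splits


def rf_distance(newick_a: str, newick_b: str) -> int:
    """Robinson-Foulds distance: bipartitions present in exactly one tree."""
    ta = dendropy.Tree.get(data=newick_a, schema="newick")
    leaf_set = frozenset(lf.taxon.label for lf in ta.leaf_node_iter())
    sa = _bipartitions(newick_a, leaf_set)
    sb = _bipartitions(newick_b, leaf_set)
    return len(sa ^ sb)


def write_distance_tsv(dist: DistanceMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("taxon\t" + "\t".join(dist.taxa) + "\n")
        for t, row in zip(dist.taxa, dist.values):
            fh.write(t + "\t" + "\t".join(f"{x:.6f}" for x in row) + "\n")
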