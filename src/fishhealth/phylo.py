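"""Distance phylogenetics for short aligned sequences.

Pairwise identity and p-distance exclude, per pair, any site where either
sequence has a gap or an N (pairwise rather than complete deletion, which
keeps short alignments informative). The Jukes-Cantor model corrects the
observed proportion of differing sites p into an expected substitutions/site
distance d = -(3/4) ln(1 - 4p/3), diverging at the saturation point
p = 3/4. Trees are built with the classical Saitou-Nei neighbor-joining
algorithm and supported by nonparametric bootstrap over alignment columns.

Determinism contract: NJ ties on the Q criterion are broken by the lowest
(row, column) index pair in current matrix order, and negative branch
lengths are clamped to zero with a logged warning.
"""

from __future__ import annotations

import logging
import math

import numpy as np

from .errors import InsufficientDataError, SaturationError, ValidationError
from .model import AlignedSequences, DistanceMatrix, TreeNode, bipartitions

log = logging.getLogger(__name__)

_ACGT = np.frombuffer(b"ACGT", dtype="S1").astype("U1")


def _encode(seqs: AlignedSequences) -> tuple[np.ndarray, np.ndarray]:
    """Character matrix and per-site validity mask (unambiguous bases only)."""
    m = seqs.matrix()
    valid = np.isin(m, _ACGT)
    return m, valid


def pairwise_stats(
    seqs: AlignedSequences,
) -> dict[tuple[str, str], tuple[float, float]]:
    """Per-pair (identity %, p-distance) with pairwise gap/N exclusion.

    Pairs with zero comparable sites are omitted (with a warning).
    """
    if len(seqs) < 2:
        raise InsufficientDataError("pairwise stats need at least 2 sequences")
    m, valid = _encode(seqs)
    ids = seqs.ids
    out: dict[tuple[str, str], tuple[float, float]] = {}
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            both = valid[i] & valid[j]
            n_valid = int(both.sum())
            if n_valid == 0:
                log.warning("pair (%s, %s): no comparable sites; omitted",
                            ids[i], ids[j])
                continue
            matches = int((m[i][both] == m[j][both]).sum())
            identity = 100.0 * matches / n_valid
            out[(ids[i], ids[j])] = (identity, 1.0 - matches / n_valid)
    return out


def jukes_cantor(p: float) -> float:
    """Jukes-Cantor distance d = -(3/4) ln(1 - 4p/3) for p in [0, 0.75)."""
    if p < 0:
        raise ValidationError("p-distance must be nonnegative")
    if p >= 0.75:
        raise SaturationError(
            f"p-distance {p} at or beyond saturation (0.75); JC distance undefined"
        )
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def jc_distance_matrix(seqs: AlignedSequences) -> DistanceMatrix:
    """Jukes-Cantor distance matrix from pairwise p-distances."""
    ids = seqs.ids
    stats = pairwise_stats(seqs)
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            key = (ids[i], ids[j])
            if key not in stats:
                raise SaturationError(
                    f"pair {key}: no comparable sites; distance undefined"
                )
            _, p = stats[key]
            d[i, j] = d[j, i] = jukes_cantor(p)
    return DistanceMatrix(ids, d)


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining; returns an unrooted tree represented
    with a trifurcating root (for 3+ taxa)."""
    n = len(dm.labels)
    if n < 3:
        raise InsufficientDataError("neighbor joining needs at least 3 taxa")
    nodes: list[TreeNode] = [TreeNode(name=lab) for lab in dm.labels]
    d = dm.d.copy()

    def clamp(x: float, where: str) -> float:
        if x < 0:
            log.warning("negative branch length %.4g at %s clamped to 0", x, where)
            return 0.0
        return x

    while len(nodes) > 3:
        r = len(nodes)
        row_sums = d.sum(axis=1)
        # Q(i, j) = (r - 2) d(i, j) - R_i - R_j; ties -> lowest (i, j) pair
        best, best_q = None, math.inf
        for i in range(r):
            for j in range(i + 1, r):
                q = (r - 2) * d[i, j] - row_sums[i] - row_sums[j]
                if q < best_q - 1e-12:
                    best_q, best = q, (i, j)
        i, j = best
        li = 0.5 * d[i, j] + (row_sums[i] - row_sums[j]) / (2 * (r - 2))
        lj = d[i, j] - li
        li = clamp(li, f"join({nodes[i].name or 'internal'})")
        lj = clamp(lj, f"join({nodes[j].name or 'internal'})")
        nodes[i].length, nodes[j].length = li, lj
        new = TreeNode(children=[nodes[i], nodes[j]])
        new_d = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(r) if k not in (i, j)]
        d2 = np.zeros((r - 1, r - 1))
        d2[:-1, :-1] = d[np.ix_(keep, keep)]
        d2[-1, :-1] = d2[:-1, -1] = new_d[keep]
        d = d2
        nodes = [nodes[k] for k in keep] + [new]

    # resolve the final three-node star with the three-point formulas
    a, b, c = nodes
    la = 0.5 * (d[0, 1] + d[0, 2] - d[1, 2])
    lb = 0.5 * (d[0, 1] + d[1, 2] - d[0, 2])
    lc = 0.5 * (d[0, 2] + d[1, 2] - d[0, 1])
    a.length = clamp(la, "final star")
    b.length = clamp(lb, "final star")
    c.length = clamp(lc, "final star")
    return TreeNode(children=[a, b, c])


def bootstrap_support(
    seqs: AlignedSequences, replicates: int = 1000, seed: int = 0
) -> TreeNode:
    """NJ tree with integer bootstrap percentages on internal nodes.

    Alignment columns are resampled with replacement; each replicate is
    rebuilt with JC + NJ, and the support of each internal bipartition of
    the point-estimate tree is the percentage of successful replicates
    containing it. Replicates with a saturated or incomparable pair are
    skipped and counted (warning above 5% skipped).
    """
    if len(seqs) < 4:
        raise InsufficientDataError("bootstrap support needs at least 4 taxa")
    if replicates < 1:
        raise ValidationError("replicates must be >= 1")
    tree = neighbor_joining(jc_distance_matrix(seqs))
    target_splits = {split: 0 for split in bipartitions(tree)}

    m, valid = _encode(seqs)
    ids = seqs.ids
    nseq, length = m.shape
    # per-pair per-site difference and validity masks, computed once
    pair_idx = [(i, j) for i in range(nseq) for j in range(i + 1, nseq)]
    diff = np.stack([(m[i] != m[j]) for i, j in pair_idx])
    both = np.stack([valid[i] & valid[j] for i, j in pair_idx])

    rng = np.random.default_rng(seed)
    skipped = 0
    successes = 0
    for _ in range(replicates):
        cols = rng.integers(0, length, size=length)
        n_valid = both[:, cols].sum(axis=1)
        n_diff = (diff & both)[:, cols].sum(axis=1)
        if np.any(n_valid == 0):
            skipped += 1
            continue
        p = n_diff / n_valid
        if np.any(p >= 0.75):
            skipped += 1
            continue
        d = np.zeros((nseq, nseq))
        dvals = -0.75 * np.log1p(-4.0 * p / 3.0)
        for (i, j), val in zip(pair_idx, dvals):
            d[i, j] = d[j, i] = val
        rep_tree = neighbor_joining(DistanceMatrix(ids, d))
        rep_splits = bipartitions(rep_tree)
        for split in target_splits:
            if split in rep_splits:
                target_splits[split] += 1
        successes += 1
    if skipped > 0.05 * replicates:
        log.warning("%d of %d bootstrap replicates skipped (saturation)",
                    skipped, replicates)
    if successes == 0:
        raise SaturationError("all bootstrap replicates were saturated")

    all_leaves = frozenset(tree.leaf_names())
    anchor = min(all_leaves)

    def annotate(node: TreeNode, is_root: bool) -> frozenset[str]:
        if node.is_leaf:
            return frozenset([node.name])
        below = frozenset().union(*(annotate(c, False) for c in node.children))
        if not is_root and 1 < len(below) < len(all_leaves) - 1:
            side = below if anchor not in below else all_leaves - below
            node.support = round(100.0 * target_splits[side] / successes)
        return below

    annotate(tree, True)
    return tree
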