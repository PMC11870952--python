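"""Liver histopathology scoring: occurrence rates, severity bins, clustering.

Lesions are scored 0 (absent) to 3 (severe) per specimen in ten categories.
Mean scores are binned into severity classes absent / mild / moderate /
severe with boundaries at 0.45, 1.45 and 2.45 — the midpoints of the gaps
the conventional 0.0-0.4 / 0.5-1.4 / 1.5-2.4 / 2.5+ ranges leave, so the
mapping is total on [0, inf). Specimen lesion profiles are clustered
agglomeratively on Euclidean distance (complete linkage by default) for
heatmap ordering.
"""

from __future__ import annotations

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .errors import InsufficientDataError, ValidationError
from .model import LESION_CATEGORIES, HistoProfile, TreeNode

SEVERITY_BOUNDS = {  # label -> [lower, upper)
    "absent": (0.0, 0.45),
    "mild": (0.45, 1.45),
    "moderate": (1.45, 2.45),
    "severe": (2.45, float("inf")),
}


def bin_severity(score: float) -> str:
    """Map a (possibly fractional, e.g. averaged) score to its severity bin."""
    if score < 0:
        raise ValidationError("severity score must be nonnegative")
    for label, (lo, hi) in SEVERITY_BOUNDS.items():
        if lo <= score < hi:
            return label
    raise AssertionError("unreachable: bins partition [0, inf)")


def occurrence_percentages(profiles: list[HistoProfile]) -> dict[str, float]:
    """Percent of specimens with score >= 1, per lesion category."""
    if not profiles:
        raise InsufficientDataError("no histology profiles")
    n = len(profiles)
    return {
        cat: 100.0 * sum(1 for p in profiles if p.scores[cat] >= 1) / n
        for cat in LESION_CATEGORIES
    }


def distance_matrix(profiles: list[HistoProfile]) -> np.ndarray:
    """Pairwise Euclidean distances over the 10 score dimensions."""
    X = np.vstack([p.vector() for p in profiles])
    return squareform(pdist(X, metric="euclidean"))


def cluster_profiles(
    profiles: list[HistoProfile], k: int = 2, method: str = "complete"
) -> tuple[list[int], np.ndarray, np.ndarray]:
    """Agglomerative clustering of lesion profiles.

    Returns (leaf order for heatmap rows, scipy linkage matrix, cluster
    labels 1..k from cutting the dendrogram at k clusters).
    """
    if len(profiles) < 2:
        raise InsufficientDataError("clustering needs at least 2 profiles")
    if k > len(profiles):
        raise ValidationError(f"k={k} exceeds number of profiles {len(profiles)}")
    X = np.vstack([p.vector() for p in profiles])
    Z = hierarchy.linkage(pdist(X, metric="euclidean"), method=method)
    order = hierarchy.leaves_list(Z).tolist()
    labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    return order, Z, labels


def dendrogram_tree(profiles: list[HistoProfile], Z: np.ndarray) -> TreeNode:
    """Convert a scipy linkage matrix into a newick-serializable tree.

    Branch lengths are merge-height differences, so leaf depths equal the
    cophenetic heights of the dendrogram.
    """
    root, nodes = hierarchy.to_tree(Z, rd=True)

    def convert(node, parent_height: float) -> TreeNode:
        height = node.dist
        if node.is_leaf():
            return TreeNode(name=profiles[node.id].specimen_id,
                            length=parent_height)
        return TreeNode(
            length=parent_height - height,
            children=[convert(node.left, height), convert(node.right, height)],
        )

    tree = convert(root, root.dist)
    tree.length = None
    return tree
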