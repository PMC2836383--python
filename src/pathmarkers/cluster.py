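"""Unsupervised hierarchical clustering of encoded samples.

Samples encoded by top-pathway activity levels are clustered
agglomeratively (class labels unused), the merge tree is exportable as
Newick for standard dendrogram / unrooted-tree viewers, and a two-group cut
at the root summarises how well the unsupervised structure recovers the
clinical classes (the "14 of 16" style purity statement).

Determinism: samples are reordered lexicographically by id before distances
are computed, so the output is invariant to input order; remaining ties in
merge heights are then resolved identically on every run.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .classify import FeatureSet

__all__ = [
    "SampleTree",
    "hierarchical_cluster",
    "two_group_purity",
    "newick_string",
    "export_newick",
    "merge_table",
]


@dataclass
class SampleTree:
    """Binary agglomerative merge tree over samples.

    ``linkage`` is a scipy linkage matrix; rows merge clusters at
    non-decreasing heights.  ``sample_ids`` gives the leaf order used when
    the linkage was computed (lexicographic).
    """

    linkage: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        if len(self.sample_ids) < 2:
            raise ValueError("a sample tree needs >= 2 leaves")
        if self.linkage.shape != (len(self.sample_ids) - 1, 4):
            raise ValueError("linkage matrix does not match the leaf count")

    @property
    def n_leaves(self) -> int:
        return len(self.sample_ids)


def hierarchical_cluster(
    features: FeatureSet,
    distance: Literal["euclidean", "correlation"] = "euclidean",
    linkage: Literal["average", "complete", "single"] = "average",
    standardize: bool = True,
) -> SampleTree:
    """Agglomerative clustering of the samples x features matrix.

    ``standardize`` z-scores each feature column first (over all samples)
    so large-mean pathways do not dominate the metric; constant columns are
    left centred at zero.  Undefined feature values are rejected by the
    :class:`FeatureSet` contract before we get here, but re-checked.
    """
    order = sorted(range(len(features.sample_ids)), key=lambda i: features.sample_ids[i])
    ids = [features.sample_ids[i] for i in order]
    X = features.matrix.to_numpy(dtype=float)[order]
    if not np.isfinite(X).all():
        raise ValueError(
            "undefined feature values present; impute or exclude them first"
        )
    if standardize:
        mu = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        sd = np.where(sd == 0, 1.0, sd)
        X = (X - mu) / sd
    d = pdist(X, metric=distance)
    if np.isnan(d).any():  # correlation distance on constant rows
        raise ValueError(
            "correlation distance undefined for constant sample vectors"
        )
    Z = hierarchy.linkage(d, method=linkage)
    return SampleTree(Z, ids)


@dataclass
class PuritySummary:
    cluster_sizes: list[int]
    composition: list[dict[str, int]]   # per cluster: class label -> count
    majority_counts: list[int]

    def __str__(self) -> str:
        parts = []
        for size, comp, maj in zip(
            self.cluster_sizes, self.composition, self.majority_counts
        ):
            detail = ", ".join(f"{k}={v}" for k, v in sorted(comp.items()))
            parts.append(f"cluster of {size} ({detail}; majority {maj})")
        return "; ".join(parts)


def two_group_purity(tree: SampleTree, labels: dict[str, str]) -> PuritySummary:
    """Cut the tree into two clusters at the root and report per-cluster
    class composition and majority counts.

    Degenerate trees whose root cut yields a single group (all merges at
    one height) report the global composition as one cluster.
    """
    assignment = hierarchy.fcluster(tree.linkage, t=2, criterion="maxclust")
    summary_sizes: list[int] = []
    composition: list[dict[str, int]] = []
    majority: list[int] = []
    for cl in sorted(set(assignment)):
        members = [s for s, a in zip(tree.sample_ids, assignment) if a == cl]
        comp: dict[str, int] = {}
        for s in members:
            comp[labels[s]] = comp.get(labels[s], 0) + 1
        summary_sizes.append(len(members))
        composition.append(comp)
        majority.append(max(comp.values()))
    return PuritySummary(summary_sizes, composition, majority)


# ---------------------------------------------------------------------------
# Newick export
# ---------------------------------------------------------------------------

_NEWICK_UNSAFE = set(" \t()[]:;,'\"")


def _quote(name: str) -> str:
    if any(ch in _NEWICK_UNSAFE for ch in name):
        return "'" + name.replace("'", "''") + "'"
    return name


def newick_string(tree: SampleTree) -> str:
    """Render the merge tree as Newick with branch lengths.

    A node's branch length is its parent's merge height minus its own
    (leaves sit at height 0), so root-to-leaf path lengths reproduce the
    merge heights exactly.
    """
    root = hierarchy.to_tree(tree.linkage)

    def render(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{_quote(tree.sample_ids[node.id])}:{length:.12g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:.12g}"

    left = render(root.left, root.dist)
    right = render(root.right, root.dist)
    return f"({left},{right});"


def export_newick(tree: SampleTree, path: str | Path) -> None:
    Path(path).write_text(newick_string(tree) + "\n")


def merge_table(tree: SampleTree) -> pd.DataFrame:
    """Linkage as a plain table (child ids, merge height, cluster size) for
    external dendrogram plotting."""
    Z = tree.linkage
    return pd.DataFrame(
        {
            "child_a": Z[:, 0].astype(int),
            "child_b": Z[:, 1].astype(int),
            "height": Z[:, 2],
            "n_members": Z[:, 3].astype(int),
        }
    )
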