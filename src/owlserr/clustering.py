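"""Max-normalized species feature vectors and UPGMA dendrograms.

Each species is summarised at one vane position by its mean inclination
angle, mean tip-displacement angle and mean serration length.  Every
parameter column is normalized to its maximum (the species with the highest
value sits at 1), Euclidean distances are computed over the normalized
3-vectors, and a hierarchical binary cluster tree is built with unweighted
average linkage (UPGMA).

Merge heights are stored as the linkage distance itself (not halved);
Newick branch lengths are height differences between a node and its parent.
Ties in the minimum inter-cluster distance are broken by the
lexicographically smallest pair of cluster leaf-name tuples, so trees are
deterministic across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .synthetic import PARAMETERS

__all__ = [
    "DendrogramNode",
    "Dendrogram",
    "species_parameter_means",
    "normalize_parameter_means",
    "euclidean_distances",
    "upgma",
    "activity_bipartition",
]


def species_parameter_means(dataset: pd.DataFrame, position: float) -> pd.DataFrame:
    """Species x parameter table of mean values at one vane position.

    Row order follows first appearance in the dataset (the study species
    order for generated tables).
    """
    cell = dataset[dataset["position"] == position]
    if cell.empty:
        raise ValueError(f"dataset has no measurements at position {position}")
    means = cell.groupby("species", sort=False)[list(PARAMETERS)].mean()
    means.columns.name = "parameter"
    return means


def normalize_parameter_means(means: pd.DataFrame) -> pd.DataFrame:
    """Divide every parameter column by its maximum.

    The species with the highest value of a parameter is set at exactly 1;
    all entries land in (0, 1].  Non-positive or missing means are rejected.
    """
    if means.isna().any().any():
        bad = means.index[means.isna().any(axis=1)].tolist()
        raise ValueError(f"missing mean values for species {bad}")
    if not (means > 0).all().all():
        raise ValueError("all means must be strictly positive before normalization")
    return means / means.max(axis=0)


def euclidean_distances(features: pd.DataFrame) -> pd.DataFrame:
    """Symmetric zero-diagonal Euclidean distance matrix over feature rows."""
    if features.isna().any().any():
        raise ValueError("feature matrix has missing cells")
    d = squareform(pdist(features.to_numpy(), metric="euclidean"))
    return pd.DataFrame(d, index=features.index, columns=features.index)


@dataclass(frozen=True)
class DendrogramNode:
    """Binary tree node; leaves carry a name, internal nodes a merge height."""

    name: str | None = None
    height: float = 0.0
    left: "DendrogramNode | None" = None
    right: "DendrogramNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.left is None

    def leaves(self) -> tuple[str, ...]:
        if self.is_leaf:
            return (self.name,)
        return self.left.leaves() + self.right.leaves()


@dataclass(frozen=True)
class Dendrogram:
    """Rooted binary ultrametric tree over species with merge heights."""

    root: DendrogramNode

    def leaves(self) -> tuple[str, ...]:
        return self.root.leaves()

    def merge_heights(self) -> list[float]:
        """Internal-node heights in merge order (non-decreasing on metric input)."""
        heights = []

        def walk(node: DendrogramNode) -> None:
            if not node.is_leaf:
                walk(node.left)
                walk(node.right)
                heights.append(node.height)

        walk(self.root)
        return sorted(heights)

    def cophenetic_distance(self, a: str, b: str) -> float:
        """Merge height of the smallest cluster containing both leaves."""
        if a == b:
            return 0.0

        def find(node: DendrogramNode) -> float | None:
            lv = node.leaves()
            if a not in lv or b not in lv:
                return None
            if not node.is_leaf:
                for child in (node.left, node.right):
                    h = find(child)
                    if h is not None:
                        return h
            return node.height

        h = find(self.root)
        if h is None:
            raise KeyError(f"leaves {a!r}, {b!r} not both in tree")
        return h

    def to_newick(self) -> str:
        """Newick string; branch lengths are parent-child height differences."""

        def fmt(node: DendrogramNode, parent_height: float) -> str:
            bl = parent_height - node.height
            if node.is_leaf:
                return f"{node.name}:{bl:.10g}"
            inner = ",".join(fmt(c, node.height) for c in (node.left, node.right))
            return f"({inner}):{bl:.10g}"

        root = self.root
        if root.is_leaf:
            return f"{root.name}:0;"
        inner = ",".join(fmt(c, root.height) for c in (root.left, root.right))
        return f"({inner});"


def _validate_distance_matrix(dist: pd.DataFrame) -> np.ndarray:
    d = dist.to_numpy(dtype=float)
    if d.shape[0] != d.shape[1] or d.shape[0] < 2:
        raise ValueError("distance matrix must be square with n >= 2")
    if list(dist.index) != list(dist.columns):
        raise ValueError("distance matrix index and columns must match")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    if not np.allclose(np.diag(d), 0.0):
        raise ValueError("distance matrix diagonal must be zero")
    return d


def upgma(dist: pd.DataFrame) -> Dendrogram:
    """Unweighted average-linkage (UPGMA) hierarchical clustering.

    At each step the pair of clusters with the smallest unweighted average
    of the original pairwise distances (over all cross pairs of leaves) is
    merged; the merge height is that average distance.  Ties are broken by
    the lexicographically smallest pair of sorted leaf-name tuples.
    """
    d = _validate_distance_matrix(dist)
    labels = [str(x) for x in dist.index]
    index_of = {name: i for i, name in enumerate(labels)}
    clusters: list[tuple[tuple[str, ...], DendrogramNode]] = [
        ((name,), DendrogramNode(name=name)) for name in labels
    ]

    def avg_dist(a: tuple[str, ...], b: tuple[str, ...]) -> float:
        rows = [index_of[x] for x in a]
        cols = [index_of[x] for x in b]
        return float(d[np.ix_(rows, cols)].mean())

    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                li, lj = clusters[i][0], clusters[j][0]
                key_i, key_j = tuple(sorted(li)), tuple(sorted(lj))
                pair_key = min(key_i, key_j), max(key_i, key_j)
                cand = (avg_dist(li, lj), pair_key, i, j)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        height, _, i, j = best
        (leaves_i, node_i), (leaves_j, node_j) = clusters[i], clusters[j]
        # deterministic child order: lexicographically smaller leaf set left
        if tuple(sorted(leaves_j)) < tuple(sorted(leaves_i)):
            node_i, node_j = node_j, node_i
            leaves_i, leaves_j = leaves_j, leaves_i
        merged = DendrogramNode(height=height, left=node_i, right=node_j)
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append((leaves_i + leaves_j, merged))
    return Dendrogram(root=clusters[0][1])


def activity_bipartition(tree: Dendrogram, species_table) -> bool:
    """True iff the root split separates nocturnal from diurnal exactly.

    The root's two subtrees must partition the leaves into {all nocturnal
    species} and {all diurnal species}.  A tree over a single activity
    class cannot bipartition (one side would be empty) and returns False.
    """
    activity = {sp.name: sp.activity for sp in species_table}
    unknown = set(tree.leaves()) - set(activity)
    if unknown:
        raise KeyError(f"tree leaves not in species table: {sorted(unknown)}")
    root = tree.root
    if root.is_leaf:
        return False
    sides = [set(root.left.leaves()), set(root.right.leaves())]
    acts = [{activity[s] for s in side} for side in sides]
    return (acts[0] == {"nocturnal"} and acts[1] == {"diurnal"}) or (
        acts[0] == {"diurnal"} and acts[1] == {"nocturnal"}
    )
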