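"""Feature merging, scaling, Ward clustering and cluster-count selection.

The morphology similarity matrix and the directed synapse-count matrix are
concatenated row-wise into one feature matrix per neuron, min-max scaled
into [0, 1], and hierarchically clustered with Ward's method (squared
Euclidean joining cost).  The number of groups is chosen from the profile
of Ward joining costs: the elbow where the differential of the joining
cost is largest — merging below that count is expensive, above it cheap.

Joining-cost convention: the cost of a merge is the increase in total
within-cluster sum of squared distances,

    dESS(A, B) = |A||B| / (|A| + |B|) * ||centroid_A - centroid_B||^2,

i.e. the square of the scipy Ward linkage height divided by two.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .connectivity import ConnectivityMatrix
from .nblast import SimilarityMatrix

__all__ = [
    "MergedFeatureMatrix",
    "Dendrogram",
    "GroupAssignment",
    "merge_features",
    "minmax_scale",
    "ward_linkage",
    "joining_cost_profile",
    "select_k",
    "cut",
]


@dataclass
class MergedFeatureMatrix:
    """Per-neuron feature rows: similarity block then connectivity block(s).

    ``column_blocks`` maps block name -> (start, stop) column span.
    """

    neuron_ids: list[str]
    features: np.ndarray
    column_blocks: dict[str, tuple[int, int]]

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.shape[0] != len(self.neuron_ids):
            raise ValueError("row count != number of neurons")
        if not np.isfinite(self.features).all():
            raise ValueError("non-finite feature values")


@dataclass
class Dendrogram:
    """Ward merge sequence.

    ``merges`` rows are (cluster_a, cluster_b, joining_cost, new_size)
    following scipy linkage indexing (leaves 0..n-1, merge m creates
    cluster n+m).  ``linkage`` is the scipy matrix (heights =
    sqrt(2 * joining_cost)) kept for cutting and plotting.
    """

    neuron_ids: list[str]
    merges: np.ndarray
    linkage: np.ndarray

    @property
    def n_leaves(self) -> int:
        return len(self.neuron_ids)

    @property
    def joining_costs(self) -> np.ndarray:
        return self.merges[:, 2]

    def leaf_order(self) -> list[int]:
        return hierarchy.leaves_list(self.linkage).tolist()

    def to_newick(self) -> str:
        """Newick string; leaf names are neuron ids, branch lengths are the
        drop in joining cost from parent merge to child merge (cost scale)."""
        n = self.n_leaves
        costs = self.joining_costs

        def node(i: int, parent_cost: float) -> str:
            if i < n:
                name = str(self.neuron_ids[i]).replace(" ", "_")
                return f"{name}:{parent_cost:.6g}"
            m = i - n
            a, b = int(self.merges[m, 0]), int(self.merges[m, 1])
            inner = f"({node(a, costs[m])},{node(b, costs[m])})"
            return f"{inner}:{max(parent_cost - costs[m], 0.0):.6g}"

        m = n - 2  # last merge row; its cluster index is 2n-2 (the root)
        a, b = int(self.merges[m, 0]), int(self.merges[m, 1])
        return f"({node(a, costs[m])},{node(b, costs[m])});"

    def to_merge_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.merges, columns=["cluster_a", "cluster_b", "joining_cost", "new_size"]
        ).astype({"cluster_a": int, "cluster_b": int, "new_size": int})


@dataclass
class GroupAssignment:
    """neuron_id -> group index (1..k), numbered by dendrogram leaf order."""

    neuron_ids: list[str]
    labels: np.ndarray
    k: int
    hemisphere: str = "right"
    modalities: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        present = sorted(set(self.labels.tolist()))
        if present != list(range(1, self.k + 1)):
            raise ValueError(f"labels must be contiguous 1..{self.k}, got {present}")

    def labels_for(self, ids: list[str]) -> np.ndarray:
        index = dict(zip(self.neuron_ids, self.labels))
        missing = [i for i in ids if i not in index]
        if missing:
            raise KeyError(f"neurons without a group label: {missing}")
        return np.array([index[i] for i in ids], dtype=np.int64)

    def members(self, group: int) -> list[str]:
        return [i for i, g in zip(self.neuron_ids, self.labels) if g == group]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "neuron_id": self.neuron_ids,
                "group": self.labels,
                "modality": [self.modalities.get(int(g), "") for g in self.labels],
            }
        )


def merge_features(
    similarity: SimilarityMatrix,
    conn: ConnectivityMatrix,
    mode: str = "out",
) -> MergedFeatureMatrix:
    """Concatenate similarity rows with connectivity rows per neuron.

    ``mode`` selects the connectivity block: outgoing counts (``out``,
    default), incoming (``in``) or both.  Neuron id order must match
    exactly; no silent reindexing.
    """
    if list(similarity.neuron_ids) != list(conn.neuron_ids):
        raise ValueError("similarity and connectivity neuron id order mismatch")
    n = len(similarity.neuron_ids)
    blocks: list[tuple[str, np.ndarray]] = [("similarity", similarity.values)]
    if mode == "out":
        blocks.append(("conn_out", conn.counts.astype(float)))
    elif mode == "in":
        blocks.append(("conn_in", conn.counts.T.astype(float)))
    elif mode == "both":
        blocks.append(("conn_out", conn.counts.astype(float)))
        blocks.append(("conn_in", conn.counts.T.astype(float)))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    spans, cols, start = {}, [], 0
    for name, arr in blocks:
        spans[name] = (start, start + arr.shape[1])
        start += arr.shape[1]
        cols.append(arr)
    return MergedFeatureMatrix(
        list(similarity.neuron_ids), np.hstack(cols), spans
    )


def minmax_scale(m: MergedFeatureMatrix, scope: str = "per_block") -> MergedFeatureMatrix:
    """Min-max scale features into [0, 1].

    ``scope`` is ``per_block`` (default: each labelled column block scaled
    by its own min/max so similarity and raw synapse counts end up at
    comparable scale), ``global`` or ``per_column``.  A constant scope maps
    to all zeros.
    """

    def scale(x: np.ndarray) -> np.ndarray:
        lo, hi = x.min(), x.max()
        return np.zeros_like(x) if hi == lo else (x - lo) / (hi - lo)

    f = m.features.copy()
    if scope == "global":
        f = scale(f)
    elif scope == "per_block":
        for start, stop in m.column_blocks.values():
            f[:, start:stop] = scale(f[:, start:stop])
    elif scope == "per_column":
        for j in range(f.shape[1]):
            f[:, j] = scale(f[:, j])
    else:
        raise ValueError(f"unknown scope {scope!r}")
    return MergedFeatureMatrix(list(m.neuron_ids), f, dict(m.column_blocks))


def ward_linkage(features: MergedFeatureMatrix) -> Dendrogram:
    """Agglomerative Ward clustering of the scaled feature rows.

    Uses Euclidean distance (the only metric for which Ward's objective is
    defined).  Joining costs are reported as dESS.
    """
    x = features.features
    if x.shape[0] < 2:
        raise ValueError("need at least 2 neurons to cluster")
    if not np.isfinite(x).all():
        raise ValueError("non-finite features")
    Z = hierarchy.linkage(x, method="ward")
    merges = Z.copy()
    merges[:, 2] = Z[:, 2] ** 2 / 2.0  # scipy height -> dESS joining cost
    return Dendrogram(list(features.neuron_ids), merges, Z)


def joining_cost_profile(d: Dendrogram) -> list[tuple[int, float]]:
    """J(k) for k = 1..n-1: the cost of the merge that reduces k+1 clusters
    to k.  Nonincreasing in k by Ward monotonicity."""
    costs = d.joining_costs
    n = d.n_leaves
    return [(k, float(costs[n - 1 - k])) for k in range(1, n)]


def select_k(
    profile: list[tuple[int, float]],
    k_min: int = 2,
    k_max: int = 12,
    criterion: str = "relative",
) -> int:
    """Pick the cluster count at the joining-cost elbow.

    With the default ``relative`` criterion, k* is the argmax over k in
    [k_min, k_max] of the differential of the joining cost relative to the
    cost just after the drop, D(k) / J(k) = J(k-1)/J(k) - 1: the count
    below which merging becomes expensive and above which it is cheap.
    The relative form is used because Ward joining costs between true
    groups grow with the sizes of the clusters being merged, so the raw
    differential D(k) = J(k-1) - J(k) (available as ``criterion=
    "absolute"``) peaks at small k whenever group sizes are unequal,
    regardless of where the elbow is.  Ties go to the smallest k.
    """
    J = dict(profile)
    n = len(profile) + 1
    if k_max >= n:
        warnings.warn(f"k_max={k_max} >= n={n}; clipping to {n - 1}", stacklevel=2)
        k_max = n - 1
    k_min = max(k_min, 2)
    if k_min > k_max:
        raise ValueError(f"empty k range [{k_min}, {k_max}]")
    best_k, best_d = None, -np.inf
    for k in range(k_min, k_max + 1):
        dk = J[k - 1] - J[k]
        if criterion == "relative":
            dk = dk / J[k] if J[k] > 0 else (np.inf if dk > 0 else 0.0)
        elif criterion != "absolute":
            raise ValueError(f"unknown criterion {criterion!r}")
        if dk > best_d:
            best_k, best_d = k, dk
    return int(best_k)


def cut(d: Dendrogram, k: int, hemisphere: str = "right") -> GroupAssignment:
    """Partition into the k clusters present after the first n-k merges.

    Group indices are assigned 1..k by dendrogram left-to-right leaf order.
    """
    n = d.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    raw = hierarchy.cut_tree(d.linkage, n_clusters=k).ravel()
    order = d.leaf_order()
    relabel: dict[int, int] = {}
    for leaf in order:
        if raw[leaf] not in relabel:
            relabel[raw[leaf]] = len(relabel) + 1
    labels = np.array([relabel[c] for c in raw], dtype=np.int64)
    return GroupAssignment(list(d.neuron_ids), labels, k=k, hemisphere=hemisphere)
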