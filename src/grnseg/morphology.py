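"""Skeleton -> dotprops conversion and point-cloud composites.

NBLAST does not consume skeletons directly: each arbor is resampled to
points roughly evenly spaced along the cable, and each point carries a unit
tangent vector estimated as the first principal axis of its k nearest
resampled neighbours.  Tangent sign is arbitrary; scoring uses the absolute
dot product.

Group composites are concatenated point clouds of the member dotprops.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .skeleton_io import NeuronSkeleton

__all__ = ["DotProps", "to_dotprops", "merge_dotprops"]


@dataclass
class DotProps:
    """Resampled point cloud with unit tangent vectors.

    ``points`` is ``(n, 3)`` in micrometres; ``tangents`` is ``(n, 3)`` with
    each row of Euclidean norm 1.
    """

    neuron_id: str
    points: np.ndarray
    tangents: np.ndarray
    subsample_seed: int | None = None

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        self.tangents = np.atleast_2d(np.asarray(self.tangents, dtype=float))
        if self.points.shape != self.tangents.shape or self.points.shape[1] != 3:
            raise ValueError("points and tangents must both be (n, 3)")
        if self.n_points < 1:
            raise ValueError("dotprops needs at least one point")
        if not np.isfinite(self.points).all():
            raise ValueError("non-finite points")
        norms = np.linalg.norm(self.tangents, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("tangents must be unit vectors")

    @property
    def n_points(self) -> int:
        return self.points.shape[0]


def _segments(skeleton: NeuronSkeleton) -> list[np.ndarray]:
    """Split the tree into unbranched paths (root/branch point -> branch
    point/leaf), each returned as an (m, 3) coordinate array."""
    edges = skeleton.edges()
    children: dict[int, list[int]] = {}
    for child, parent in edges:
        children.setdefault(int(parent), []).append(int(child))
    index = {int(nid): i for i, nid in enumerate(skeleton.node_ids)}
    root = index[skeleton.root]
    paths = []
    # walk from every segment start (root or branch point) to the next
    # branch point or leaf
    starts = [root]
    seen = set()
    while starts:
        s = starts.pop(0)
        if s in seen:
            continue
        seen.add(s)
        for c0 in sorted(children.get(s, [])):
            path = [s, c0]
            node = c0
            while len(children.get(node, [])) == 1:
                node = children[node][0]
                path.append(node)
            paths.append(skeleton.coords[np.asarray(path)])
            if len(children.get(node, [])) > 1:
                starts.append(node)
    return paths


def _resample_path(path: np.ndarray, spacing: float) -> np.ndarray:
    """Resample a polyline to points ~``spacing`` apart (endpoints kept)."""
    seg = np.linalg.norm(np.diff(path, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1]
    if total == 0:
        return path[:1]
    n = max(int(round(total / spacing)) + 1, 2)
    t = np.linspace(0.0, total, n)
    return np.column_stack([np.interp(t, arc, path[:, k]) for k in range(3)])


def to_dotprops(
    skeleton: NeuronSkeleton,
    spacing: float = 1.0,
    k_neighbors: int = 5,
    allow_single_point: bool = False,
) -> DotProps:
    """Convert a skeleton to its NBLAST point/tangent representation.

    Parameters
    ----------
    spacing
        Target distance between resampled points along each branch, µm.
    k_neighbors
        Neighbourhood size for the principal-axis tangent fit (>= 2).
    allow_single_point
        Accept single-node skeletons (tangent defaults to +x).
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if k_neighbors < 2:
        raise ValueError("k_neighbors must be >= 2")
    paths = _segments(skeleton)
    if not paths:
        if not allow_single_point:
            raise ValueError(f"{skeleton.neuron_id}: degenerate skeleton (single node)")
        return DotProps(
            skeleton.neuron_id, skeleton.coords[:1], np.array([[1.0, 0.0, 0.0]])
        )
    if skeleton.cable_length() < spacing:
        # whole arbor shorter than one sample: one point on its only edge
        pts = np.vstack(paths)
        mid = pts.mean(axis=0, keepdims=True)
        d = paths[0][-1] - paths[0][0]
        tangent = (d / np.linalg.norm(d)).reshape(1, 3)
        return DotProps(skeleton.neuron_id, mid, tangent)
    points = np.vstack([_resample_path(p, spacing) for p in paths])
    tangents = _knn_tangents(points, k_neighbors)
    return DotProps(skeleton.neuron_id, points, tangents)


def _knn_tangents(points: np.ndarray, k: int) -> np.ndarray:
    """First principal axis of each point's k nearest neighbours (incl. self)."""
    n = len(points)
    k = min(k, n)
    tree = cKDTree(points)
    _, idx = tree.query(points, k=k)
    if k == 1:
        idx = idx[:, None]
    nbrs = points[idx]                             # (n, k, 3)
    centred = nbrs - nbrs.mean(axis=1, keepdims=True)
    cov = np.einsum("nki,nkj->nij", centred, centred) / k
    _, vecs = np.linalg.eigh(cov)                  # ascending eigenvalues
    tang = vecs[:, :, -1]
    norms = np.linalg.norm(tang, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return tang / norms


def merge_dotprops(
    members: list[DotProps],
    max_points: int | None = None,
    seed: int = 0,
    neuron_id: str = "composite",
) -> DotProps:
    """Concatenate member dotprops into one composite cloud.

    With ``max_points`` set, a uniform random subsample of that size is
    drawn with a fixed seed, recorded on the output (``subsample_seed``).
    """
    if not members:
        raise ValueError("merge_dotprops needs at least one member")
    points = np.vstack([m.points for m in members])
    tangents = np.vstack([m.tangents for m in members])
    sub_seed = None
    if max_points is not None and len(points) > max_points:
        rng = np.random.default_rng(seed)
        keep = np.sort(rng.choice(len(points), size=max_points, replace=False))
        points, tangents = points[keep], tangents[keep]
        sub_seed = seed
    return DotProps(neuron_id, points, tangents, subsample_seed=sub_seed)
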