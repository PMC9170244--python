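"""NBLAST-style morphological similarity scoring.

For a query point cloud Q scored against a target T, every query point i is
matched to its nearest target point j(i); the raw score is

    S(Q, T) = sum_i f(||p_i - q_j(i)||, |u_i . v_j(i)|)

where f is a score function of nearest-neighbour distance d (µm) and the
absolute tangent dot product.  Normalised scores divide by the query's
self-score S(Q, Q); the symmetric mean score averages both directions and
is what the clustering and modality assignment consume.

Two score functions are provided: a parametric exponential kernel
f(d, a) = a * exp(-d / sigma) (default, sigma = 3 µm), and a binned
log-odds lookup table in the published NBLAST score-matrix format, loadable
from TSV, which takes precedence when supplied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .morphology import DotProps

__all__ = [
    "ExpScore",
    "TableScore",
    "read_score_table",
    "raw_score",
    "normalized_score",
    "mean_score",
    "all_by_all",
    "SimilarityMatrix",
]


@dataclass(frozen=True)
class ExpScore:
    """Parametric kernel f(d, a) = a * exp(-d / sigma); f(0, 1) = 1."""

    sigma: float = 3.0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")

    def __call__(self, dist: np.ndarray, adot: np.ndarray) -> np.ndarray:
        return np.asarray(adot) * np.exp(-np.asarray(dist) / self.sigma)


@dataclass(frozen=True)
class TableScore:
    """Binned log-odds score table over (distance, |dot|) cells.

    ``dist_edges`` are the interior/upper bin edges starting at 0; bins are
    half-open [lo, hi) and distances beyond the last edge fall in the last
    bin.  ``dot_edges`` likewise partition [0, 1].  ``values`` has shape
    (n_dist_bins, n_dot_bins).
    """

    dist_edges: np.ndarray
    dot_edges: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "dist_edges", np.asarray(self.dist_edges, float))
        object.__setattr__(self, "dot_edges", np.asarray(self.dot_edges, float))
        object.__setattr__(self, "values", np.asarray(self.values, float))
        nd = len(self.dist_edges)
        na = len(self.dot_edges)
        if self.values.shape != (nd, na):
            raise ValueError(
                f"values shape {self.values.shape} != ({nd}, {na})"
            )
        if (np.diff(self.dist_edges) <= 0).any() or (np.diff(self.dot_edges) <= 0).any():
            raise ValueError("bin edges must be strictly increasing")

    def __call__(self, dist: np.ndarray, adot: np.ndarray) -> np.ndarray:
        di = np.searchsorted(self.dist_edges, dist, side="right")
        ai = np.searchsorted(self.dot_edges, adot, side="right")
        di = np.minimum(di, len(self.dist_edges) - 1)
        ai = np.minimum(ai, len(self.dot_edges) - 1)
        return self.values[di, ai]


def read_score_table(path: str | Path) -> TableScore:
    """Load a trained NBLAST score matrix from TSV.

    Rows are distance bins labelled ``(lo,hi]`` (µm), columns |dot| bins;
    the first column holds the row labels.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)

    def upper(label: str) -> float:
        hi = label.strip("([])").split(",")[1]
        return np.inf if hi in ("Inf", "inf") else float(hi)

    dist_edges = np.array([upper(r) for r in df.index])
    dot_edges = np.array([upper(c) for c in df.columns])
    # an infinite last edge is implied by "beyond last edge -> last bin"
    dist_edges[-1] = min(dist_edges[-1], np.finfo(float).max)
    dot_edges[-1] = min(dot_edges[-1], 1.0)
    return TableScore(dist_edges, dot_edges, df.to_numpy(float))


def _match(query: DotProps, target: DotProps, tree: cKDTree | None = None):
    tree = tree or cKDTree(target.points)
    dist, idx = tree.query(query.points, k=1)
    adot = np.abs(np.einsum("ij,ij->i", query.tangents, target.tangents[idx]))
    return dist, np.clip(adot, 0.0, 1.0)


def raw_score(query: DotProps, target: DotProps, f=None) -> float:
    """Sum of f(d, |dot|) over nearest-target matches of every query point."""
    f = f or ExpScore()
    dist, adot = _match(query, target)
    return float(f(dist, adot).sum())


def normalized_score(query: DotProps, target: DotProps, f=None) -> float:
    """raw_score(query, target) / raw_score(query, query); self-score is 1."""
    f = f or ExpScore()
    self_score = raw_score(query, query, f)
    if self_score == 0:
        raise ZeroDivisionError(f"{query.neuron_id}: zero self-score")
    return raw_score(query, target, f) / self_score


def mean_score(a: DotProps, b: DotProps, f=None) -> float:
    """Symmetric similarity: mean of the two normalised directions."""
    f = f or ExpScore()
    return 0.5 * (normalized_score(a, b, f) + normalized_score(b, a, f))


@dataclass
class SimilarityMatrix:
    """All-by-all symmetric normalised NBLAST scores; diagonal exactly 1."""

    neuron_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.neuron_ids)
        if self.values.shape != (n, n):
            raise ValueError("similarity matrix shape mismatch")
        if not np.isfinite(self.values).all():
            raise ValueError("non-finite similarity values")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.neuron_ids, columns=self.neuron_ids)


def all_by_all(neurons: list[DotProps], f=None) -> SimilarityMatrix:
    """Mean-score similarity matrix over a list of dotprops.

    Equivalent to looped :func:`mean_score` calls but batched: each
    neuron's KD-tree is queried once with the stacked points of all other
    neurons.
    """
    f = f or ExpScore()
    if len(neurons) < 2:
        raise ValueError("all_by_all needs at least 2 neurons")
    ids = [n.neuron_id for n in neurons]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate neuron ids")
    n = len(neurons)
    sizes = np.array([d.n_points for d in neurons])
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    all_pts = np.vstack([d.points for d in neurons])
    all_tan = np.vstack([d.tangents for d in neurons])

    self_scores = np.array([raw_score(d, d, f) for d in neurons])
    raw = np.empty((n, n))
    for t, target in enumerate(neurons):
        tree = cKDTree(target.points)
        dist, idx = tree.query(all_pts, k=1)
        adot = np.clip(
            np.abs(np.einsum("ij,ij->i", all_tan, target.tangents[idx])), 0.0, 1.0
        )
        scores = f(dist, adot)
        for q in range(n):
            raw[q, t] = scores[offsets[q] : offsets[q + 1]].sum()
    norm = raw / self_scores[:, None]          # normalised query->target
    values = 0.5 * (norm + norm.T)
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(ids, values)
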