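"""Directed synapse-count matrices and connectivity statistics.

Builds the all-by-all synapse-count matrix for a cohort of neurons,
per-neuron synapse statistics (total pre/post sites, input received from
within the cohort), and group-level block sums with within/between synapse
fractions — the quantities used to ask whether sensory axons synapse
mostly onto axons of their own modality group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .skeleton_io import SynapseTable

logger = logging.getLogger(__name__)

__all__ = [
    "ConnectivityMatrix",
    "GroupConnectivitySummary",
    "build_matrix",
    "totals_from_table",
    "neuron_stats",
    "group_block_sums",
    "threshold_edges",
]


@dataclass
class ConnectivityMatrix:
    """counts[i, j] = number of synapses from neuron i onto neuron j."""

    neuron_ids: list[str]
    counts: np.ndarray
    n_dropped_rows: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        n = len(self.neuron_ids)
        if self.counts.shape != (n, n):
            raise ValueError("connectivity matrix shape mismatch")
        if (self.counts < 0).any():
            raise ValueError("negative synapse counts")
        if np.diagonal(self.counts).any():
            raise ValueError("autapses on the diagonal; exclude them upstream")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.neuron_ids, columns=self.neuron_ids)


def build_matrix(
    table: SynapseTable, neuron_ids: list[str], drop_unknown: bool = False
) -> ConnectivityMatrix:
    """Aggregate a synapse table into a directed count matrix.

    Rows whose pre or post neuron is outside ``neuron_ids`` raise unless
    ``drop_unknown`` is set, in which case they are excluded from the
    matrix (their number is logged and recorded on the result); use
    :func:`totals_from_table` to retain them in per-neuron totals.
    """
    index = {nid: i for i, nid in enumerate(neuron_ids)}
    if len(index) != len(neuron_ids):
        raise ValueError("duplicate neuron ids")
    counts = np.zeros((len(neuron_ids), len(neuron_ids)), dtype=np.int64)
    dropped = 0
    for pre, post, cnt in table.rows[["pre_id", "post_id", "count"]].itertuples(
        index=False
    ):
        if pre not in index or post not in index:
            if not drop_unknown:
                unknown = pre if pre not in index else post
                raise KeyError(f"synapse row references unknown neuron {unknown!r}")
            dropped += 1
            continue
        counts[index[pre], index[post]] += cnt
    if dropped:
        logger.info("build_matrix: dropped %d rows outside the cohort", dropped)
    return ConnectivityMatrix(list(neuron_ids), counts, n_dropped_rows=dropped)


def totals_from_table(table: SynapseTable) -> pd.DataFrame:
    """Per-neuron presynaptic/postsynaptic totals over *all* table rows,
    including partners outside any later cohort restriction."""
    pre = table.rows.groupby("pre_id")["count"].sum()
    post = table.rows.groupby("post_id")["count"].sum()
    ids = sorted(set(pre.index) | set(post.index))
    return pd.DataFrame(
        {
            "neuron_id": ids,
            "n_pre": [int(pre.get(i, 0)) for i in ids],
            "n_post": [int(post.get(i, 0)) for i in ids],
        }
    )


def neuron_stats(
    matrix: ConnectivityMatrix, totals: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, dict]:
    """Per-neuron synapse statistics and their cohort means / standard errors.

    ``totals`` is the (neuron_id, n_pre, n_post) table of total synaptic
    site counts including non-cohort partners.  Without it, totals default
    to the matrix's own row/column sums — then every input fraction is 1 by
    construction, which is flagged in the summary.

    Returns a per-neuron DataFrame (n_presyn_sites, n_postsyn_sites,
    postsyn_from_cohort, input_fraction_from_cohort) and a summary dict of
    means and standard errors.
    """
    ids = matrix.neuron_ids
    col_sums = matrix.counts.sum(axis=0)
    row_sums = matrix.counts.sum(axis=1)
    totals_default = totals is None
    if totals_default:
        n_pre, n_post = row_sums, col_sums
    else:
        t = totals.set_index("neuron_id")
        missing = [i for i in ids if i not in t.index]
        if missing:
            raise KeyError(f"totals missing neurons: {missing}")
        n_pre = t.loc[ids, "n_pre"].to_numpy(np.int64)
        n_post = t.loc[ids, "n_post"].to_numpy(np.int64)
        low = n_post < col_sums
        if low.any():
            bad = [ids[i] for i in np.flatnonzero(low)]
            raise ValueError(
                f"totals below in-cohort synapse sums for neurons: {bad}"
            )
    frac = np.divide(
        col_sums, n_post, out=np.zeros(len(ids), dtype=float), where=n_post > 0
    )
    df = pd.DataFrame(
        {
            "neuron_id": ids,
            "n_presyn_sites": n_pre,
            "n_postsyn_sites": n_post,
            "postsyn_from_cohort": col_sums,
            "input_fraction_from_cohort": frac,
        }
    )

    def _mean_se(x: np.ndarray) -> tuple[float, float]:
        x = np.asarray(x, dtype=float)
        se = float(x.std(ddof=1) / np.sqrt(len(x))) if len(x) > 1 else 0.0
        return float(x.mean()), se

    summary: dict = {"totals_defaulted_to_matrix_sums": totals_default}
    for key, col in (
        ("n_presyn_sites", n_pre),
        ("n_postsyn_sites", n_post),
        ("input_fraction_from_cohort", frac),
    ):
        m, se = _mean_se(col)
        summary[f"mean_{key}"] = m
        summary[f"se_{key}"] = se
    return df, summary


@dataclass
class GroupConnectivitySummary:
    """k x k synapse block sums plus within/between fractions.

    ``block_sums[g, h]`` counts synapses from group g onto group h.
    Fractions are synapse-weighted (share of summed synapses); the
    edge-weighted variants (share of nonzero neuron-pair connections) are
    reported alongside under ``*_edges``.
    """

    group_labels: list[int]
    block_sums: np.ndarray
    total: int
    within_fraction: float
    between_fraction: float
    within_fraction_edges: float
    between_fraction_edges: float

    def to_dict(self) -> dict:
        return {
            "group_labels": list(self.group_labels),
            "block_sums": self.block_sums.tolist(),
            "total": self.total,
            "within_fraction": self.within_fraction,
            "between_fraction": self.between_fraction,
            "within_fraction_edges": self.within_fraction_edges,
            "between_fraction_edges": self.between_fraction_edges,
        }


def group_block_sums(matrix: ConnectivityMatrix, assignment) -> GroupConnectivitySummary:
    """Sum synapses within and between groups of a partition.

    ``assignment`` is a :class:`~grnseg.clustering.GroupAssignment` (or any
    object with a ``labels_for(ids)`` method returning integer labels).
    """
    labels = np.asarray(assignment.labels_for(matrix.neuron_ids))
    groups = sorted(set(labels.tolist()))
    gidx = {g: i for i, g in enumerate(groups)}
    k = len(groups)
    block = np.zeros((k, k), dtype=np.int64)
    edges = np.zeros((k, k), dtype=np.int64)
    li = np.array([gidx[g] for g in labels])
    np.add.at(block, (li[:, None], li[None, :]), matrix.counts)
    np.add.at(edges, (li[:, None], li[None, :]), (matrix.counts > 0).astype(np.int64))
    total = int(block.sum())
    n_edges = int(edges.sum())
    within = int(np.trace(block))
    within_e = int(np.trace(edges))
    wf = within / total if total else 0.0
    wfe = within_e / n_edges if n_edges else 0.0
    return GroupConnectivitySummary(
        group_labels=groups,
        block_sums=block,
        total=total,
        within_fraction=wf,
        between_fraction=1.0 - wf if total else 0.0,
        within_fraction_edges=wfe,
        between_fraction_edges=1.0 - wfe if n_edges else 0.0,
    )


def threshold_edges(matrix: ConnectivityMatrix, min_synapses: int) -> ConnectivityMatrix:
    """Keep only high-confidence connections of >= ``min_synapses`` synapses;
    weaker entries are zeroed, neuron order unchanged."""
    if min_synapses < 1:
        raise ValueError("min_synapses must be >= 1")
    counts = np.where(matrix.counts >= min_synapses, matrix.counts, 0)
    return ConnectivityMatrix(list(matrix.neuron_ids), counts)
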