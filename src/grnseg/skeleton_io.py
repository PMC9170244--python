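"""Read, validate and write neuron skeletons and synapse tables.

This module is the pipeline's only contact with files holding biological
data.  Skeletons travel as SWC (the community standard: seven whitespace
separated columns ``id type x y z radius parent``, ``#`` comments), synapse
tables and per-neuron totals as plain CSV.  All coordinates are converted to
micrometres at read time and stay in micrometres everywhere downstream.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "NeuronSkeleton",
    "SynapseTable",
    "SkeletonError",
    "read_swc",
    "write_swc",
    "read_synapse_table",
    "read_totals",
    "read_manifest",
]


class SkeletonError(ValueError):
    """Raised when a skeleton or synapse table violates its invariants."""


@dataclass
class NeuronSkeleton:
    """A rooted tree of 3-D nodes reconstructed from EM.

    Parameters
    ----------
    neuron_id
        Identity of the neuron; by convention the SWC filename stem.
    node_ids
        Integer node identifiers, arbitrary but unique.
    parent_ids
        Parent node id per node; ``-1`` marks the root.
    coords
        ``(n, 3)`` float array of x, y, z positions in micrometres.
    radii
        Per-node radius in micrometres (``nan`` when unknown).
    labels
        SWC structure labels; carried through but ignored by the pipeline.
    """

    neuron_id: str
    node_ids: np.ndarray
    parent_ids: np.ndarray
    coords: np.ndarray
    radii: np.ndarray
    labels: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.node_ids = np.asarray(self.node_ids, dtype=np.int64)
        self.parent_ids = np.asarray(self.parent_ids, dtype=np.int64)
        self.coords = np.asarray(self.coords, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if not self.name:
            self.name = self.neuron_id
        self.validate()

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def root(self) -> int:
        """Node id of the root (soma or tract-entry node)."""
        return int(self.node_ids[self.parent_ids == -1][0])

    def validate(self) -> None:
        """Check the tree invariants; raise :class:`SkeletonError` if broken."""
        n = len(self.node_ids)
        if n == 0:
            raise SkeletonError(f"{self.neuron_id}: empty skeleton")
        if len(np.unique(self.node_ids)) != n:
            raise SkeletonError(f"{self.neuron_id}: duplicate node ids")
        if not np.isfinite(self.coords).all():
            raise SkeletonError(f"{self.neuron_id}: non-finite coordinates")
        roots = np.flatnonzero(self.parent_ids == -1)
        if len(roots) == 0:
            raise SkeletonError(f"{self.neuron_id}: no root (broken tree)")
        if len(roots) > 1:
            raise SkeletonError(f"{self.neuron_id}: multiple roots")
        known = set(self.node_ids.tolist())
        for pid in self.parent_ids:
            if pid != -1 and int(pid) not in known:
                raise SkeletonError(
                    f"{self.neuron_id}: parent {int(pid)} not present (broken tree)"
                )
        # cycle check: every node must reach the root
        index = {int(nid): i for i, nid in enumerate(self.node_ids)}
        for i in range(n):
            seen = set()
            j = i
            while self.parent_ids[j] != -1:
                if j in seen:
                    raise SkeletonError(f"{self.neuron_id}: cycle detected")
                seen.add(j)
                j = index[int(self.parent_ids[j])]

    def edges(self) -> np.ndarray:
        """Return ``(n_edges, 2)`` array of (child_index, parent_index) rows."""
        index = {int(nid): i for i, nid in enumerate(self.node_ids)}
        out = [
            (i, index[int(pid)])
            for i, pid in enumerate(self.parent_ids)
            if pid != -1
        ]
        return np.asarray(out, dtype=np.int64).reshape(-1, 2)

    def cable_length(self) -> float:
        """Total cable length in micrometres."""
        e = self.edges()
        if len(e) == 0:
            return 0.0
        d = self.coords[e[:, 0]] - self.coords[e[:, 1]]
        return float(np.linalg.norm(d, axis=1).sum())


@dataclass
class SynapseTable:
    """Directed synapse rows (pre id, post id, count, optional x/y/z in µm)."""

    rows: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        df = self.rows
        if len(df) == 0:
            self.rows = pd.DataFrame(
                columns=["pre_id", "post_id", "count", "x", "y", "z"]
            )
            return
        df = df.copy()
        df["pre_id"] = df["pre_id"].astype(str)
        df["post_id"] = df["post_id"].astype(str)
        if "count" not in df.columns:
            df["count"] = 1
        df["count"] = df["count"].astype(np.int64)
        for c in ("x", "y", "z"):
            if c not in df.columns:
                df[c] = np.nan
        if (df["count"] < 1).any():
            bad = df.index[df["count"] < 1][0]
            raise SkeletonError(f"synapse row {bad}: count < 1")
        self.rows = df[["pre_id", "post_id", "count", "x", "y", "z"]].reset_index(
            drop=True
        )

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def total(self) -> int:
        return int(self.rows["count"].sum())

    def neuron_ids(self) -> list[str]:
        """All neuron ids appearing as pre or post, sorted."""
        return sorted(set(self.rows["pre_id"]) | set(self.rows["post_id"]))


def read_swc(path: str | Path, unit: str = "um", neuron_id: str | None = None) -> NeuronSkeleton:
    """Read one skeleton from an SWC file.

    Parameters
    ----------
    path
        SWC file with seven whitespace-separated columns per data line.
    unit
        ``"um"`` (default) or ``"nm"``; nanometre coordinates (and radii)
        are divided by 1000 so the returned skeleton is in micrometres.
    neuron_id
        Overrides the default identity (the filename stem).
    """
    path = Path(path)
    if unit not in ("um", "nm", "µm"):
        raise ValueError(f"unknown unit {unit!r}; expected 'nm' or 'um'")
    scale = 1e-3 if unit == "nm" else 1.0
    node_ids, labels, xyz, radii, parents = [], [], [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 7:
                raise SkeletonError(
                    f"{path.name}:{lineno}: expected 7 columns, got {len(parts)}"
                )
            try:
                nid = int(parts[0])
                lab = int(parts[1])
                x, y, z, r = (float(v) for v in parts[2:6])
                pid = int(parts[6])
            except ValueError as exc:
                raise SkeletonError(
                    f"{path.name}:{lineno}: non-numeric field ({exc})"
                ) from None
            node_ids.append(nid)
            labels.append(lab)
            xyz.append((x * scale, y * scale, z * scale))
            radii.append(r * scale)
            parents.append(pid)
    if not node_ids:
        raise SkeletonError(f"{path.name}: no data lines")
    return NeuronSkeleton(
        neuron_id=neuron_id or path.stem,
        node_ids=np.asarray(node_ids),
        parent_ids=np.asarray(parents),
        coords=np.asarray(xyz),
        radii=np.asarray(radii),
        labels=np.asarray(labels),
    )


def write_swc(skeleton: NeuronSkeleton, path: str | Path) -> None:
    """Write a validated skeleton as standard 7-column SWC (root parent −1)."""
    skeleton.validate()
    buf = io.StringIO()
    buf.write(f"# {skeleton.neuron_id}\n")
    buf.write("# id type x y z radius parent\n")
    for nid, lab, (x, y, z), r, pid in zip(
        skeleton.node_ids,
        skeleton.labels,
        skeleton.coords,
        skeleton.radii,
        skeleton.parent_ids,
    ):
        rr = 0.0 if np.isnan(r) else r
        buf.write(f"{nid} {lab} {x:.6f} {y:.6f} {z:.6f} {rr:.6f} {pid}\n")
    Path(path).write_text(buf.getvalue())


def read_synapse_table(path: str | Path, allow_autapses: bool = False) -> SynapseTable:
    """Read a directed synapse table from CSV.

    The header must name the pre/post id columns (``pre_id``/``post_id``;
    the CATMAID-style aliases ``pre``, ``post``, ``presynaptic``,
    ``postsynaptic`` are accepted).  A missing ``count`` column means one
    synapse per row.  Autapse rows (pre == post) are rejected unless
    ``allow_autapses`` is set.
    """
    df = pd.read_csv(path, dtype={0: str})
    rename = {}
    for cands, target in (
        (("pre_id", "pre", "presynaptic", "pre_neuron_id"), "pre_id"),
        (("post_id", "post", "postsynaptic", "post_neuron_id"), "post_id"),
        (("count", "n", "n_synapses", "weight"), "count"),
    ):
        for c in cands:
            if c in df.columns:
                rename[c] = target
                break
    df = df.rename(columns=rename)
    if "pre_id" not in df.columns or "post_id" not in df.columns:
        raise SkeletonError(
            f"{path}: header must name pre/post id columns, got {list(df.columns)}"
        )
    table = SynapseTable(df)
    if not allow_autapses:
        auto = table.rows["pre_id"] == table.rows["post_id"]
        if auto.any():
            i = int(table.rows.index[auto][0])
            pre = table.rows.loc[i, "pre_id"]
            raise SkeletonError(
                f"{path}: row {i} is an autapse ({pre} -> {pre}); "
                "pass allow_autapses=True to keep it"
            )
    return table


def write_synapse_table(table: SynapseTable, path: str | Path) -> None:
    """Write a synapse table as CSV (drops all-empty coordinate columns)."""
    df = table.rows
    if df[["x", "y", "z"]].isna().all().all():
        df = df[["pre_id", "post_id", "count"]]
    df.to_csv(path, index=False, float_format="%.6f")


def read_totals(path: str | Path) -> pd.DataFrame:
    """Read the per-neuron totals CSV (neuron_id, n_pre, n_post).

    Totals include partners outside the analysed cohort, so they can exceed
    the in-matrix synapse sums but never fall below them.
    """
    df = pd.read_csv(path, dtype={"neuron_id": str})
    df = df.rename(columns={"n_presyn_sites": "n_pre", "n_postsyn_sites": "n_post"})
    missing = {"neuron_id", "n_pre", "n_post"} - set(df.columns)
    if missing:
        raise SkeletonError(f"{path}: totals CSV missing columns {sorted(missing)}")
    if (df[["n_pre", "n_post"]] < 0).any().any():
        raise SkeletonError(f"{path}: negative totals")
    return df[["neuron_id", "n_pre", "n_post"]].astype(
        {"n_pre": np.int64, "n_post": np.int64}
    )


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a plain-text manifest mapping filename -> neuron id -> hemisphere."""
    df = pd.read_csv(path, dtype=str)
    need = {"filename", "neuron_id"}
    if not need <= set(df.columns):
        raise SkeletonError(f"{path}: manifest needs columns {sorted(need)}")
    if "hemisphere" not in df.columns:
        df["hemisphere"] = "right"
    return df[["filename", "neuron_id", "hemisphere"]]
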