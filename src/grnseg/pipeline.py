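"""End-to-end orchestration: skeletons + synapses -> groups + modalities.

`cluster_cohort` is the in-memory pipeline (dotprops -> NBLAST all-by-all
-> merge with connectivity -> min-max scale -> Ward -> elbow k-selection
-> cut); `run_pipeline` wraps it with file I/O, template-based modality
assignment, connectivity summaries at each requested synapse threshold,
and a run manifest, for the command-line front end.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .assignment import TemplateLibrary, assign_modalities
from .clustering import (
    Dendrogram,
    GroupAssignment,
    MergedFeatureMatrix,
    cut,
    joining_cost_profile,
    merge_features,
    minmax_scale,
    select_k,
    ward_linkage,
)
from .connectivity import (
    ConnectivityMatrix,
    build_matrix,
    group_block_sums,
    neuron_stats,
    threshold_edges,
)
from .morphology import DotProps, to_dotprops
from .nblast import ExpScore, SimilarityMatrix, all_by_all, read_score_table
from .skeleton_io import read_swc, read_synapse_table, read_totals

__all__ = ["RunConfig", "PipelineResult", "cluster_cohort", "run_pipeline"]


@dataclass
class PipelineResult:
    similarity: SimilarityMatrix
    connectivity: ConnectivityMatrix
    merged: MergedFeatureMatrix
    scaled: MergedFeatureMatrix
    dendrogram: Dendrogram
    profile: list[tuple[int, float]]
    k: int
    k_fixed_by_user: bool
    assignment: GroupAssignment


def cluster_cohort(
    dotprops: list[DotProps],
    conn: ConnectivityMatrix,
    score_fn=None,
    merge_mode: str = "out",
    scale_scope: str = "per_block",
    k: int | None = None,
    k_min: int = 2,
    k_max: int = 12,
    hemisphere: str = "right",
) -> PipelineResult:
    """Cluster a cohort from its dotprops and synapse-count matrix."""
    score_fn = score_fn or ExpScore()
    sim = all_by_all(dotprops, score_fn)
    if list(sim.neuron_ids) != list(conn.neuron_ids):
        raise ValueError("dotprops and connectivity neuron order mismatch")
    merged = merge_features(sim, conn, mode=merge_mode)
    scaled = minmax_scale(merged, scope=scale_scope)
    dend = ward_linkage(scaled)
    profile = joining_cost_profile(dend)
    fixed = k is not None
    k_star = k if fixed else select_k(profile, k_min=k_min, k_max=k_max)
    assign = cut(dend, k_star, hemisphere=hemisphere)
    return PipelineResult(
        sim, conn, merged, scaled, dend, profile, k_star, fixed, assign
    )


@dataclass
class RunConfig:
    """File-based run configuration (see ``grnseg run --help``)."""

    skeleton_dir: str
    synapse_csv: str
    output_dir: str
    totals_csv: str | None = None
    template_dir: str | None = None
    unit: str = "um"
    spacing: float = 1.0
    k_neighbors: int = 5
    sigma: float = 3.0
    score_table: str | None = None
    merge_mode: str = "out"
    scale_scope: str = "per_block"
    k: int | None = None
    k_min: int = 2
    k_max: int = 12
    thresholds: list[int] = field(default_factory=lambda: [1, 5])
    hemisphere: str = "right"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_templates(template_dir: Path, spacing: float, k_neighbors: int) -> TemplateLibrary:
    """Template library from a directory of SWCs plus a labels.csv manifest
    (columns filename, template_id, class_label)."""
    manifest = pd.read_csv(template_dir / "labels.csv", dtype=str)
    entries = []
    for fn, tid, cls in manifest[["filename", "template_id", "class_label"]].itertuples(
        index=False
    ):
        sk = read_swc(template_dir / fn, neuron_id=tid)
        entries.append((tid, cls, to_dotprops(sk, spacing=spacing, k_neighbors=k_neighbors)))
    return TemplateLibrary(entries)


def run_pipeline(config: RunConfig) -> dict:
    """Run the full pipeline from files and write all outputs.

    Writes similarity/connectivity/merged CSVs, the Newick dendrogram and
    joining-cost profile, group assignments, modality calls, per-neuron
    stats, group connectivity summaries at each threshold, and a
    run-manifest JSON; returns the run report as a dict.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    skel_dir = Path(config.skeleton_dir)
    paths = sorted(skel_dir.glob("*.swc"))
    if not paths:
        raise FileNotFoundError(f"[skeleton_io] no SWC files in {skel_dir}")
    skeletons = [read_swc(p, unit=config.unit) for p in paths]
    ids = [s.neuron_id for s in skeletons]
    dotprops = [
        to_dotprops(s, spacing=config.spacing, k_neighbors=config.k_neighbors)
        for s in skeletons
    ]

    table = read_synapse_table(config.synapse_csv)
    conn = build_matrix(table, ids, drop_unknown=True)
    totals = read_totals(config.totals_csv) if config.totals_csv else None

    score_fn = (
        read_score_table(config.score_table)
        if config.score_table
        else ExpScore(sigma=config.sigma)
    )
    res = cluster_cohort(
        dotprops,
        conn,
        score_fn=score_fn,
        merge_mode=config.merge_mode,
        scale_scope=config.scale_scope,
        k=config.k,
        k_min=config.k_min,
        k_max=config.k_max,
        hemisphere=config.hemisphere,
    )

    res.similarity.to_frame().to_csv(out / "similarity.csv")
    res.connectivity.to_frame().to_csv(out / "connectivity.csv")
    pd.DataFrame(res.scaled.features, index=ids).to_csv(out / "merged_scaled.csv")
    (out / "dendrogram.nwk").write_text(res.dendrogram.to_newick() + "\n")
    pd.DataFrame(res.profile, columns=["k", "joining_cost"]).to_csv(
        out / "joining_costs.csv", index=False
    )

    calls = []
    if config.template_dir:
        library = _load_templates(
            Path(config.template_dir), config.spacing, config.k_neighbors
        )
        dp_map = {d.neuron_id: d for d in dotprops}
        calls = assign_modalities(res.assignment, dp_map, library, score_fn)
        res.assignment.modalities.update(
            {c.group_index: c.class_label for c in calls}
        )
    res.assignment.to_frame().to_csv(out / "assignments.csv", index=False)
    (out / "modality_calls.json").write_text(
        json.dumps([c.to_dict() for c in calls], indent=2) + "\n"
    )

    stats_df, stats_summary = neuron_stats(res.connectivity, totals)
    stats_df.to_csv(out / "neuron_stats.csv", index=False)

    summaries = {}
    for t in config.thresholds:
        mat = threshold_edges(res.connectivity, t) if t > 1 else res.connectivity
        summaries[str(t)] = group_block_sums(mat, res.assignment).to_dict()
    (out / "group_summary.json").write_text(
        json.dumps({"thresholds": summaries, "neuron_stats": stats_summary}, indent=2)
        + "\n"
    )

    inputs = {str(p): _sha256(p) for p in paths}
    inputs[str(config.synapse_csv)] = _sha256(Path(config.synapse_csv))
    if config.totals_csv:
        inputs[str(config.totals_csv)] = _sha256(Path(config.totals_csv))
    report = {
        "version": __version__,
        "n_neurons": len(ids),
        "k": res.k,
        "k_fixed_by_user": res.k_fixed_by_user,
        "within_fraction": summaries[str(config.thresholds[0])]["within_fraction"],
        "summaries": summaries,
        "neuron_stats": stats_summary,
        "modality_calls": [c.to_dict() for c in calls],
        "dropped_synapse_rows": conn.n_dropped_rows,
        "parameters": {
            k: v for k, v in vars(config).items() if not k.startswith("_")
        },
        "input_checksums": inputs,
    }
    (out / "run_manifest.json").write_text(json.dumps(report, indent=2) + "\n")
    return report
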