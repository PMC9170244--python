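"""Synthetic gustatory-axon cohorts with known ground truth.

Emulates the anatomy this pipeline is built for: several tens of sensory
axons per hemisphere entering the brain through a common nerve tract,
terminating in group-specific spatial zones with branched arbors, and a
directed synapse graph with strong within-group and weak between-group
connectivity blocks.  Everything downstream of manual EM reconstruction
can therefore be exercised end-to-end with a known partition.

Sampling model
--------------
* Geometry: each neuron grows from ``tract_entry`` as a biased random walk
  to its group's ``zone_center``, then a recursive binary arbor of depth
  ``branch_depth`` whose branch targets scatter around the zone centre
  with s.d. ``zone_spread``.
* Connectivity: each ordered neuron pair (i, j), i != j, is connected with
  probability ``p_within`` (same group) or ``p_between`` (different
  groups); a connected pair carries ``1 + Poisson(lambda - 1)`` synapses
  (zero-truncated, so "connected" always means >= 1).
* Totals: per-neuron site totals add Poisson non-cohort partners
  (``external_input_rate`` postsynaptic, ``external_output_rate``
  presynaptic) to the realized cohort sums.

One :func:`numpy.random.default_rng` stream is consumed in a fixed order —
neuron geometry, template geometry, edges (ordered pairs in id order),
totals — so a seed pins every output byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .assignment import TemplateLibrary
from .morphology import to_dotprops
from .skeleton_io import NeuronSkeleton, SynapseTable

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "GeneratedData",
    "generate",
    "preset_labellar",
    "expected_block_totals",
    "build_template_library",
]

#: default taste-class label per group (distinct labels so assignment
#: accuracy against ground truth is well defined)
DEFAULT_CLASSES = ("bitter-medial", "bitter-lateral", "low-salt", "sugar",
                   "high-salt", "water")


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic cohort; see the module docstring."""

    n_groups: int
    group_sizes: list[int]
    zone_centers: np.ndarray            # (n_groups, 3), µm
    zone_spread: float = 4.0            # µm
    tract_entry: tuple[float, float, float] = (0.0, -70.0, 0.0)
    branch_depth: int = 3
    branch_length_mean: float = 6.0     # µm
    p_within: float = 0.5
    p_between: float = 0.1
    lambda_within: float = 6.6          # mean synapses per connected within pair
    lambda_between: float = 1.95
    external_input_rate: float = 102.7  # mean non-cohort postsynaptic sites
    external_output_rate: float = 109.7
    seed: int = 0
    class_labels: tuple[str, ...] = DEFAULT_CLASSES

    def __post_init__(self) -> None:
        self.zone_centers = np.asarray(self.zone_centers, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.n_groups < 1 or len(self.group_sizes) != self.n_groups:
            raise ValueError("group_sizes must have n_groups entries")
        if min(self.group_sizes) < 1:
            raise ValueError("group sizes must be >= 1")
        if self.zone_centers.shape != (self.n_groups, 3):
            raise ValueError("zone_centers must be (n_groups, 3)")
        d = np.linalg.norm(
            self.zone_centers[:, None] - self.zone_centers[None, :], axis=-1
        )
        if (d[np.triu_indices(self.n_groups, 1)] == 0).any():
            raise ValueError("zone centers must be pairwise distinct")
        for p in (self.p_within, self.p_between):
            if not 0.0 <= p <= 1.0:
                raise ValueError("connection probabilities must be in [0, 1]")
        for lam in (self.lambda_within, self.lambda_between):
            if lam < 1.0:
                raise ValueError("lambda must be >= 1 (zero-truncated Poisson mean)")
        if self.external_input_rate < 0 or self.external_output_rate < 0:
            raise ValueError("external rates must be >= 0")
        if self.zone_spread <= 0 or self.branch_length_mean <= 0:
            raise ValueError("lengths must be positive")
        if self.n_groups < 2 and self.p_between > 0 and self.p_within == 0:
            raise ValueError(
                "single group with only between-group edges requested: "
                "no edges can be realized"
            )
        if len(self.class_labels) < self.n_groups:
            raise ValueError("need a class label per group")

    @property
    def n_neurons(self) -> int:
        return int(sum(self.group_sizes))


@dataclass
class GroundTruth:
    """Planted partition and realized synapse block totals."""

    neuron_to_group: dict[str, int]
    group_to_class: dict[int, str]
    within_total: int
    between_total: int

    def labels_for(self, ids: list[str]) -> np.ndarray:
        return np.array([self.neuron_to_group[i] for i in ids], dtype=np.int64)


@dataclass
class GeneratedData:
    config: SyntheticConfig
    skeletons: list[NeuronSkeleton]
    synapses: SynapseTable
    totals: pd.DataFrame                  # neuron_id, n_pre, n_post
    truth: GroundTruth
    template_skeletons: list[tuple[str, str, NeuronSkeleton]] = field(
        default_factory=list
    )  # (template_id, class_label, skeleton)


def _grow(rng: np.random.Generator, neuron_id: str, entry: np.ndarray,
          center: np.ndarray, spread: float, depth: int,
          branch_len: float) -> NeuronSkeleton:
    """One axon: tract walk from entry toward the zone, then a binary arbor."""
    coords = [np.asarray(entry, float)]
    parents = [-1]

    def add(point: np.ndarray, parent_idx: int) -> int:
        coords.append(point)
        parents.append(parent_idx)
        return len(coords) - 1

    # main tract: biased walk until within one spread of the zone centre
    step = max(branch_len / 2.0, 1.0)
    cur, cur_idx = coords[0], 0
    while np.linalg.norm(center - cur) > spread:
        direction = center - cur
        direction = direction / np.linalg.norm(direction)
        direction = direction + rng.normal(0.0, 0.15, 3)
        direction /= np.linalg.norm(direction)
        cur = cur + direction * min(step, np.linalg.norm(center - cur))
        cur_idx = add(cur, cur_idx)

    def branch(start_idx: int, level: int) -> None:
        if level == 0:
            return
        for _ in range(2):
            target = center + rng.normal(0.0, spread, 3)
            start = coords[start_idx]
            tip = start_idx
            for frac in (1 / 3, 2 / 3, 1.0):
                jitter = rng.normal(0.0, 0.3, 3) if frac < 1.0 else 0.0
                tip = add(start + (target - start) * frac + jitter, tip)
            branch(tip, level - 1)

    branch(cur_idx, depth)
    n = len(coords)
    return NeuronSkeleton(
        neuron_id=neuron_id,
        node_ids=np.arange(1, n + 1),
        parent_ids=np.array([p + 1 if p >= 0 else -1 for p in parents]),
        coords=np.asarray(coords),
        radii=np.full(n, 0.1),
        labels=np.full(n, 2),  # SWC axon
    )


def _leaf_coords(skeleton: NeuronSkeleton) -> np.ndarray:
    """Coordinates of terminal nodes (synapse placement sites)."""
    has_child = np.isin(skeleton.node_ids, skeleton.parent_ids)
    leaves = skeleton.coords[~has_child]
    return leaves if len(leaves) else skeleton.coords[-1:]


def generate(config: SyntheticConfig) -> GeneratedData:
    """Draw one synthetic cohort; same seed -> byte-identical outputs."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    entry = np.asarray(config.tract_entry, float)

    ids: list[str] = []
    groups: list[int] = []
    for g, size in enumerate(config.group_sizes, start=1):
        for _ in range(size):
            ids.append(f"grn_{len(ids) + 1:03d}")
            groups.append(g)

    skeletons = [
        _grow(rng, nid, entry, config.zone_centers[g - 1], config.zone_spread,
              config.branch_depth, config.branch_length_mean)
        for nid, g in zip(ids, groups)
    ]

    template_skeletons = []
    for g in range(1, config.n_groups + 1):
        cls = config.class_labels[g - 1]
        tmpl = _grow(rng, f"template_{cls}", entry, config.zone_centers[g - 1],
                     config.zone_spread, config.branch_depth,
                     config.branch_length_mean)
        template_skeletons.append((f"template_{cls}", cls, tmpl))

    leaves = {s.neuron_id: _leaf_coords(s) for s in skeletons}
    rows = []
    within_total = between_total = 0
    n = len(ids)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            same = groups[i] == groups[j]
            p = config.p_within if same else config.p_between
            lam = config.lambda_within if same else config.lambda_between
            if rng.random() < p:
                count = 1 + int(rng.poisson(lam - 1.0))
                site = leaves[ids[i]][int(rng.integers(len(leaves[ids[i]])))]
                rows.append((ids[i], ids[j], count, *np.round(site, 6)))
                if same:
                    within_total += count
                else:
                    between_total += count

    synapses = SynapseTable(
        pd.DataFrame(rows, columns=["pre_id", "post_id", "count", "x", "y", "z"])
    )
    pre_sums = {i: 0 for i in ids}
    post_sums = {i: 0 for i in ids}
    for pre, post, cnt, *_ in rows:
        pre_sums[pre] += cnt
        post_sums[post] += cnt
    totals = pd.DataFrame(
        {
            "neuron_id": ids,
            "n_pre": [
                pre_sums[i] + int(rng.poisson(config.external_output_rate))
                for i in ids
            ],
            "n_post": [
                post_sums[i] + int(rng.poisson(config.external_input_rate))
                for i in ids
            ],
        }
    )
    truth = GroundTruth(
        neuron_to_group=dict(zip(ids, groups)),
        group_to_class={
            g: config.class_labels[g - 1] for g in range(1, config.n_groups + 1)
        },
        within_total=within_total,
        between_total=between_total,
    )
    return GeneratedData(config, skeletons, synapses, totals, truth,
                         template_skeletons)


def build_template_library(
    template_skeletons: list[tuple[str, str, NeuronSkeleton]],
    spacing: float = 1.0,
    k_neighbors: int = 5,
) -> TemplateLibrary:
    """Dotprops template library from generated (or loaded) template skeletons."""
    return TemplateLibrary(
        [
            (tid, cls, to_dotprops(sk, spacing=spacing, k_neighbors=k_neighbors))
            for tid, cls, sk in template_skeletons
        ]
    )


# six zone centres in a ~100 µm field, pairwise >= ~39 µm apart --
# discrete termination zones well separated relative to the arbor spread
_PRESET_ZONES = np.array(
    [
        [40.0, 10.0, 0.0],
        [15.0, 42.0, 8.0],
        [-25.0, 38.0, -6.0],
        [-42.0, 5.0, 6.0],
        [-18.0, -35.0, -4.0],
        [25.0, -35.0, 5.0],
    ]
)


def preset_labellar(seed: int = 0) -> SyntheticConfig:
    """The study-scale preset: 87 axons in six groups of 7-23.

    Rate parameters are chosen so the analytic expectations match the
    study-scale statistics this generator emulates: a synapse-weighted
    within-group fraction of ~0.79, ~175 presynaptic and ~168 postsynaptic
    sites per neuron, and a mean within-cohort input fraction of ~0.39.
    """
    return SyntheticConfig(
        n_groups=6,
        group_sizes=[7, 10, 12, 15, 20, 23],
        zone_centers=_PRESET_ZONES.copy(),
        seed=seed,
    )


def write_generated(data: GeneratedData, outdir) -> None:
    """Write a generated cohort to disk in the pipeline's input layout:
    ``skeletons/*.swc``, ``synapses.csv``, ``totals.csv``, ``truth.json``,
    ``templates/*.swc`` + ``templates/labels.csv``."""
    import json
    from pathlib import Path

    from .skeleton_io import write_swc, write_synapse_table

    outdir = Path(outdir)
    (outdir / "skeletons").mkdir(parents=True, exist_ok=True)
    (outdir / "templates").mkdir(parents=True, exist_ok=True)
    for sk in data.skeletons:
        write_swc(sk, outdir / "skeletons" / f"{sk.neuron_id}.swc")
    write_synapse_table(data.synapses, outdir / "synapses.csv")
    data.totals.to_csv(outdir / "totals.csv", index=False)
    rows = []
    for tid, cls, sk in data.template_skeletons:
        fn = f"{tid}.swc"
        write_swc(sk, outdir / "templates" / fn)
        rows.append((fn, tid, cls))
    pd.DataFrame(rows, columns=["filename", "template_id", "class_label"]).to_csv(
        outdir / "templates" / "labels.csv", index=False
    )
    truth = {
        "neuron_to_group": data.truth.neuron_to_group,
        "group_to_class": data.truth.group_to_class,
        "within_total": data.truth.within_total,
        "between_total": data.truth.between_total,
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=2) + "\n")


def _trunc_pois_moments(lam: float, threshold: int) -> tuple[float, float]:
    """E[T 1{T>=t}] and E[T^2 1{T>=t}] for T = 1 + Poisson(lam - 1)."""
    mu = lam - 1.0
    sf = lambda m: float(stats.poisson.sf(m - 1, mu)) if mu > 0 else float(m <= 0)
    t = threshold
    m1 = sf(t - 1) + mu * sf(t - 2)
    m2 = sf(t - 1) + 3 * mu * sf(t - 2) + mu * mu * sf(t - 3)
    return m1, m2


def expected_block_totals(config: SyntheticConfig, threshold: int = 1) -> dict:
    """Analytic expectation (and delta-method SE) of the synapse-weighted
    within-group fraction after keeping only edges of >= ``threshold``
    synapses.  Serves as the oracle for generator calibration tests."""
    sizes = np.asarray(config.group_sizes)
    n = sizes.sum()
    n_within_pairs = int((sizes * (sizes - 1)).sum())
    n_between_pairs = int(n * (n - 1)) - n_within_pairs

    def block(p: float, lam: float, n_pairs: int) -> tuple[float, float]:
        m1, m2 = _trunc_pois_moments(lam, threshold)
        mean = n_pairs * p * m1
        var = n_pairs * (p * m2 - (p * m1) ** 2)
        return mean, var

    ew, vw = block(config.p_within, config.lambda_within, n_within_pairs)
    eb, vb = block(config.p_between, config.lambda_between, n_between_pairs)
    total = ew + eb
    frac = ew / total if total else 0.0
    se = np.sqrt(eb * eb * vw + ew * ew * vb) / total**2 if total else 0.0
    return {
        "expected_within": ew,
        "expected_between": eb,
        "within_fraction": frac,
        "se_within_fraction": float(se),
    }
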