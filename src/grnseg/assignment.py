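"""Taste-modality assignment of clusters against a labelled template library.

Each cluster's member dotprops are merged into a composite point cloud and
scored (symmetric mean NBLAST score) against every template in a library
of labelled projection patterns — e.g. bitter (Gr66a), sugar (Gr64f),
water (Ppk28) and low-salt (Ir94e) reference arbors registered to the same
space.  The cluster is named after its top hit; per-class mean scores are
reported alongside for libraries with several exemplars per class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .clustering import GroupAssignment
from .morphology import DotProps, merge_dotprops
from .nblast import mean_score

__all__ = ["TemplateLibrary", "ModalityCall", "assign_modalities"]


@dataclass
class TemplateLibrary:
    """Labelled reference dotprops, at least one per taste class."""

    entries: list[tuple[str, str, DotProps]]  # (template_id, class_label, dotprops)

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("template library is empty")
        ids = [t for t, _, _ in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate template ids")

    @property
    def class_labels(self) -> list[str]:
        return sorted({c for _, c, _ in self.entries})


@dataclass
class ModalityCall:
    """One cluster's best match in the template library."""

    group_index: int
    top_template_id: str
    top_score: float
    class_label: str
    per_class_mean_scores: dict[str, float] = field(default_factory=dict)
    tie: bool = False

    def to_dict(self) -> dict:
        return {
            "group_index": self.group_index,
            "top_template_id": self.top_template_id,
            "top_score": self.top_score,
            "class_label": self.class_label,
            "per_class_mean_scores": self.per_class_mean_scores,
            "tie": self.tie,
        }


def assign_modalities(
    groups: GroupAssignment,
    neuron_dotprops: dict[str, DotProps],
    library: TemplateLibrary,
    f=None,
    max_composite_points: int | None = None,
) -> list[ModalityCall]:
    """Label every cluster with the taste class of its top template hit.

    For each group a composite cloud is built from the member dotprops and
    scored against every template with the symmetric mean score; the call
    records the top template, its class, and per-class mean scores.  Ties
    on the top score go to the lexicographically smallest template id and
    are flagged.
    """
    calls = []
    for g in range(1, groups.k + 1):
        members = groups.members(g)
        if not members:
            raise ValueError(f"group {g} is empty")
        composite = merge_dotprops(
            [neuron_dotprops[m] for m in members],
            max_points=max_composite_points,
            neuron_id=f"group{g}_composite",
        )
        scores = {
            tid: mean_score(composite, dp, f) for tid, _, dp in library.entries
        }
        top = max(scores.values())
        winners = sorted(t for t, s in scores.items() if s == top)
        top_id = winners[0]
        top_class = next(c for t, c, _ in library.entries if t == top_id)
        per_class: dict[str, list[float]] = {}
        for tid, cls, _ in library.entries:
            per_class.setdefault(cls, []).append(scores[tid])
        calls.append(
            ModalityCall(
                group_index=g,
                top_template_id=top_id,
                top_score=float(top),
                class_label=top_class,
                per_class_mean_scores={
                    c: float(sum(v) / len(v)) for c, v in per_class.items()
                },
                tie=len(winners) > 1,
            )
        )
    return calls
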