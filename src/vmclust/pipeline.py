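"""The two-step valgus-moment waveform clustering pipeline.

Step 1 (shape): window each trial to early stance, resample to the
common grid, encode as direction-change signs, build the Euclidean
distance matrix, cluster with Ward.D2, scan the C-Index over a range of
cluster counts, select a count, and assign each resulting cluster one of
the six shape labels from its aggregate profile (or a manual override).

Step 2 (magnitude): within each shape group, cluster the body-mass-
normalized (Nm/kg) curves the same way, choose the 2-4 sub-cluster
solution with the lowest C-Index, and rank sub-clusters into
small/medium/large magnitude classes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .hierarchical import ClusterAssignment, Linkage, cut_tree, ward2_linkage
from .labeling import (
    MagnitudeLabel,
    ShapeLabel,
    classify_magnitude,
    classify_shape,
    profile_cluster,
)
from .preprocess import WindowSpec, preprocess_cohort
from .shape_encoding import distance_matrix, encode
from .trial_io import Cohort, LabeledTrial
from .validity import CIndexScan, c_index, scan_k, select_k


@dataclass
class PipelineConfig:
    """Tunable parameters of the two-step pipeline."""

    window: WindowSpec = field(default_factory=WindowSpec)
    ties: str = "zero"              # encoder tie policy
    k_min: int = 2
    k_max: int = 50
    c_threshold: float = 0.05
    selection_rule: str = "threshold"
    k_fixed: int | None = None      # bypass C-Index selection (sensitivity analysis)
    sub_k_min: int = 2
    sub_k_max: int = 4
    early_fraction: float = 0.5
    prominence_min: float = 0.2
    shape_overrides: dict[int, ShapeLabel] | None = None


@dataclass
class MagnitudeStep:
    """Sub-clustering outcome for one shape group."""

    shape: ShapeLabel
    trial_ids: list[str]
    k_sub: int
    sub_labels: np.ndarray
    magnitude_labels: list[MagnitudeLabel]
    c_values: dict[int, float]


@dataclass
class PipelineResult:
    """Everything the two-step pipeline produced, for audit and export."""

    labeled: list[LabeledTrial]
    shape_linkage: Linkage
    shape_scan: CIndexScan
    shape_assignment: ClusterAssignment
    cluster_shapes: dict[int, ShapeLabel]
    magnitude_steps: dict[ShapeLabel, MagnitudeStep]
    grid_length: int

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {
                "grid_length": self.grid_length,
                "shape_k": self.shape_assignment.k,
                "shape_rule_used": self.shape_scan.rule_used,
                "c_index_scan": {
                    int(k): (None if np.isnan(c) else c)
                    for k, c in zip(self.shape_scan.k_values, self.shape_scan.c_values)
                },
                "cluster_shapes": {int(c): s.value for c, s in self.cluster_shapes.items()},
                "shape_linkage": json.loads(self.shape_linkage.to_json()),
                "magnitude": {
                    s.value: {
                        "k_sub": step.k_sub,
                        "c_values": step.c_values,
                        "labels": [m.value for m in step.magnitude_labels],
                    }
                    for s, step in self.magnitude_steps.items()
                },
                "assignments": [
                    {
                        "trial_id": a.trial_id,
                        "shape": a.shape.value,
                        "magnitude": a.magnitude.value if a.magnitude else None,
                        "shape_cluster": a.shape_cluster,
                        "sub_cluster": a.sub_cluster,
                    }
                    for a in self.labeled
                ],
            },
            indent=2,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload


def _sub_cluster_group(
    shape: ShapeLabel,
    ids: list[str],
    curves: np.ndarray,
    config: PipelineConfig,
) -> MagnitudeStep:
    """Magnitude sub-clustering of one shape group's Nm/kg curves.

    The sub-cluster count with the lowest defined C-Index wins.  Groups
    too small (or too degenerate) to sub-cluster collapse to a single
    sub-cluster labeled medium.
    """
    m = len(ids)
    fallback = MagnitudeStep(
        shape=shape,
        trial_ids=ids,
        k_sub=1,
        sub_labels=np.zeros(m, dtype=int),
        magnitude_labels=[MagnitudeLabel.MEDIUM],
        c_values={},
    )
    if m < 3:
        return fallback
    dm = distance_matrix(curves, ids)
    link = ward2_linkage(dm)
    c_values: dict[int, float] = {}
    assignments: dict[int, ClusterAssignment] = {}
    for k in range(config.sub_k_min, min(config.sub_k_max, m - 1) + 1):
        assignment = cut_tree(link, k, ids)
        try:
            c_values[k] = c_index(dm, assignment)
        except Exception:
            continue
        assignments[k] = assignment
    if not c_values:
        return fallback
    # lowest C-Index wins; exact ties go to the finer partition, since the
    # sub-cluster step exists to differentiate magnitudes and equal C means
    # both solutions separate equally well
    k_best = min(c_values, key=lambda k: (c_values[k], -k))
    assignment = assignments[k_best]
    profiles = [profile_cluster(curves[assignment.members(c)]) for c in range(k_best)]
    mags = classify_magnitude(profiles)
    return MagnitudeStep(
        shape=shape,
        trial_ids=ids,
        k_sub=k_best,
        sub_labels=assignment.labels,
        magnitude_labels=mags,
        c_values=c_values,
    )


def run_pipeline(cohort: Cohort, config: PipelineConfig | None = None) -> PipelineResult:
    """Run the full two-step cluster analysis on a cohort."""
    config = config or PipelineConfig()
    trials = list(cohort)
    if len(trials) < 3:
        raise ValidationError("pipeline needs at least 3 trials")

    ids, curves = preprocess_cohort(cohort, config.window)
    encoded = np.vstack([encode(c, ties=config.ties) for c in curves]).astype(float)

    dm_shape = distance_matrix(encoded, ids)
    link = ward2_linkage(dm_shape)
    k_max = min(config.k_max, len(ids) - 1)
    scan = scan_k(dm_shape, link, config.k_min, k_max)
    if config.k_fixed is not None:
        k = config.k_fixed
        scan.chosen_k, scan.rule_used = k, "fixed"
    else:
        k = select_k(scan, threshold=config.c_threshold, rule=config.selection_rule)
    assignment = cut_tree(link, k, ids)

    overrides = config.shape_overrides or {}
    cluster_shapes: dict[int, ShapeLabel] = {}
    for c in range(k):
        if c in overrides:
            cluster_shapes[c] = overrides[c]
            continue
        members = assignment.members(c)
        profile = profile_cluster(curves[members])
        cluster_shapes[c] = classify_shape(
            profile, early_fraction=config.early_fraction, prominence_min=config.prominence_min
        )

    # group trials by assigned shape for the magnitude step
    id_to_index = {tid: i for i, tid in enumerate(ids)}
    shape_groups: dict[ShapeLabel, list[str]] = {}
    for tid, cluster in zip(ids, assignment.labels):
        shape_groups.setdefault(cluster_shapes[int(cluster)], []).append(tid)

    magnitude_steps: dict[ShapeLabel, MagnitudeStep] = {}
    trial_magnitude: dict[str, MagnitudeLabel] = {}
    trial_sub: dict[str, int] = {}
    for shape, group_ids in shape_groups.items():
        group_curves = curves[[id_to_index[t] for t in group_ids]]
        step = _sub_cluster_group(shape, group_ids, group_curves, config)
        magnitude_steps[shape] = step
        for tid, sub in zip(group_ids, step.sub_labels):
            trial_magnitude[tid] = step.magnitude_labels[int(sub)]
            trial_sub[tid] = int(sub)

    labeled = [
        LabeledTrial(
            trial_id=tid,
            shape=cluster_shapes[int(cluster)],
            magnitude=trial_magnitude[tid],
            shape_cluster=int(cluster),
            sub_cluster=trial_sub[tid],
        )
        for tid, cluster in zip(ids, assignment.labels)
    ]
    return PipelineResult(
        labeled=labeled,
        shape_linkage=link,
        shape_scan=scan,
        shape_assignment=assignment,
        cluster_shapes=cluster_shapes,
        magnitude_steps=magnitude_steps,
        grid_length=curves.shape[1],
    )
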