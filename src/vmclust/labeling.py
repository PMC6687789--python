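"""Semantic labels for shape clusters and magnitude sub-clusters.

The visual-inspection step of the original clustering workflow — looking
at aggregate cluster curves and calling them "early peak", "upslope",
"small", "large", ... — is replaced here by documented quantitative
rules operating on a :class:`ClusterProfile`, with a manual-override path
for cases the rules cannot settle.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np

from .errors import UnclassifiableShapeError, ValidationError


class ShapeLabel(str, Enum):
    """The six waveform shape families of the early-stance valgus moment."""

    EARLY_PEAK = "early_peak"
    PEAK = "peak"
    UPSLOPE = "upslope"
    DOWNSLOPE = "downslope"
    TROUGH = "trough"
    EARLY_TROUGH = "early_trough"


class MagnitudeLabel(str, Enum):
    """Magnitude class of a sub-cluster (body-mass-normalized scale)."""

    SMALL = "small"
    MEDIUM = "medium"
    LARGE = "large"


@dataclass
class ClusterProfile:
    """Computable summary of a cluster's aggregate curve.

    ``apex_index`` locates the sample deviating most from the chord that
    joins the curve's endpoints; ``apex_sign`` is the sign of that
    deviation (+1 bump, -1 dip, 0 flat); ``prominence`` is the absolute
    apex deviation relative to the curve's value range.
    """

    mean_curve: np.ndarray
    apex_index: int
    apex_sign: int
    net_change: float
    prominence: float


def profile_cluster(member_curves: Sequence[np.ndarray]) -> ClusterProfile:
    """Profile a cluster from its member curves (equal-length, common grid)."""
    curves = [np.asarray(c, dtype=float) for c in member_curves]
    if not curves:
        raise ValidationError("cannot profile an empty cluster")
    lengths = {len(c) for c in curves}
    if len(lengths) != 1:
        raise ValidationError(f"member curves have unequal lengths: {sorted(lengths)}")
    mean = np.mean(curves, axis=0)
    chord = np.linspace(mean[0], mean[-1], len(mean))
    dev = mean - chord
    apex = int(np.argmax(np.abs(dev)))
    value_range = float(mean.max() - mean.min())
    prominence = float(abs(dev[apex]) / value_range) if value_range > 0 else 0.0
    return ClusterProfile(
        mean_curve=mean,
        apex_index=apex,
        apex_sign=int(np.sign(dev[apex])),
        net_change=float(mean[-1] - mean[0]),
        prominence=prominence,
    )


def classify_shape(
    profile: ClusterProfile,
    early_fraction: float = 0.5,
    prominence_min: float = 0.2,
) -> ShapeLabel:
    """Assign one of the six shape families to a cluster profile.

    A profile with a prominent interior apex (``prominence >=
    prominence_min``) is a bump: positive apexes are peaks, negative
    apexes troughs, and the EARLY_* variant applies when the apex falls
    within the first ``early_fraction`` of the analysis window.
    Non-prominent profiles are slopes classified by the sign of their
    net change.  A flat profile with no apex and no net change is
    unclassifiable and must be resolved by manual override.
    """
    n = len(profile.mean_curve)
    early = profile.apex_index <= early_fraction * (n - 1)
    if profile.prominence >= prominence_min and profile.apex_sign > 0:
        return ShapeLabel.EARLY_PEAK if early else ShapeLabel.PEAK
    if profile.prominence >= prominence_min and profile.apex_sign < 0:
        return ShapeLabel.EARLY_TROUGH if early else ShapeLabel.TROUGH
    if profile.net_change > 0:
        return ShapeLabel.UPSLOPE
    if profile.net_change < 0:
        return ShapeLabel.DOWNSLOPE
    raise UnclassifiableShapeError(
        "flat profile with no prominent apex and zero net change; "
        "provide a manual override for this cluster"
    )


#: How ranked sub-clusters map to magnitude names, by sub-cluster count.
#: Ranks are ascending in mean absolute magnitude.  With four sub-clusters
#: the two lowest ranks are both called small (documented convention).
_MAGNITUDE_MAPS = {
    2: [MagnitudeLabel.SMALL, MagnitudeLabel.LARGE],
    3: [MagnitudeLabel.SMALL, MagnitudeLabel.MEDIUM, MagnitudeLabel.LARGE],
    4: [MagnitudeLabel.SMALL, MagnitudeLabel.SMALL, MagnitudeLabel.MEDIUM, MagnitudeLabel.LARGE],
}


def classify_magnitude(subcluster_profiles: Sequence[ClusterProfile]) -> list[MagnitudeLabel]:
    """Label 2-4 magnitude sub-clusters as small/medium/large.

    Sub-clusters are ranked by the mean absolute value of their aggregate
    Nm/kg curve; ties are broken by peak absolute value, then by input
    position.  The returned list is aligned with the input order.
    """
    k = len(subcluster_profiles)
    if k not in _MAGNITUDE_MAPS:
        raise ValidationError(f"magnitude classification needs 2-4 sub-clusters, got {k}")
    keys = [
        (float(np.mean(np.abs(p.mean_curve))), float(np.max(np.abs(p.mean_curve))), i)
        for i, p in enumerate(subcluster_profiles)
    ]
    order = sorted(range(k), key=lambda i: keys[i])
    labels: list[MagnitudeLabel] = [MagnitudeLabel.SMALL] * k
    for rank, idx in enumerate(order):
        labels[idx] = _MAGNITUDE_MAPS[k][rank]
    return labels


def read_overrides(path) -> dict[int, ShapeLabel]:
    """Read a manual shape-override file (two-column CSV: cluster_id,label)."""
    out: dict[int, ShapeLabel] = {}
    valid = {s.value for s in ShapeLabel}
    with open(path, newline="") as fh:
        for i, row in enumerate(csv.reader(fh)):
            if not row or (i == 0 and row[0].strip().lower() == "cluster_id"):
                continue
            if len(row) < 2:
                raise ValidationError(f"{path}: override row {i + 1} needs cluster_id,label")
            label = row[1].strip().lower()
            if label not in valid:
                raise ValidationError(
                    f"{path}: unknown shape label {row[1]!r} (valid: {sorted(valid)})"
                )
            out[int(row[0])] = ShapeLabel(label)
    return out
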