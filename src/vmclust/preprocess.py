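"""Windowing, resampling and body-mass normalization of moment curves.

Each trial is reduced to the early weight-acceptance part of stance (the
first 30% by default, where ACL injuries occur), every windowed series is
linearly interpolated onto a common grid whose length is the longest
windowed series plus two frames, and curves are divided by body mass to
give Nm/kg.  Linear interpolation is used deliberately: splines can
overshoot and manufacture spurious direction changes that would corrupt
the downstream sign encoding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .trial_io import Cohort, Trial


@dataclass
class WindowSpec:
    """Configuration of the windowing/resampling step.

    ``stance_fraction`` is the leading fraction of stance retained (window
    length rounds up, so the window never undershoots the fraction).
    ``target_length_rule`` is ``"max_plus_2"`` (common grid = longest
    windowed series + 2 frames) or ``"fixed"`` with ``fixed_length`` set.
    """

    stance_fraction: float = 0.30
    target_length_rule: str = "max_plus_2"
    fixed_length: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.stance_fraction <= 1:
            raise ValidationError(f"stance_fraction must be in (0, 1], got {self.stance_fraction}")
        if self.target_length_rule not in ("max_plus_2", "fixed"):
            raise ValidationError(f"unknown target_length_rule {self.target_length_rule!r}")
        if self.target_length_rule == "fixed" and (self.fixed_length is None or self.fixed_length < 2):
            raise ValidationError("fixed rule requires fixed_length >= 2")


@dataclass
class NormalizedCurve:
    """A windowed, resampled, mass-normalized curve on the common grid."""

    trial_id: str
    grid: np.ndarray
    values_nm_per_kg: np.ndarray


def window_trial(trial: Trial, spec: WindowSpec) -> np.ndarray:
    """Return the first ``ceil(stance_fraction * n_frames)`` samples, unmodified."""
    n = math.ceil(spec.stance_fraction * trial.n_frames)
    if n < 3:
        raise ValidationError(
            f"trial {trial.trial_id!r}: window of {n} samples is too short (need >= 3)"
        )
    return trial.values[:n].copy()


def common_length(windowed: Sequence[np.ndarray], spec: WindowSpec) -> int:
    """Common grid length for a collection of windowed series."""
    windowed = list(windowed)
    if not windowed:
        raise ValidationError("common_length of an empty collection is undefined")
    if spec.target_length_rule == "fixed":
        return int(spec.fixed_length)  # type: ignore[arg-type]
    return max(len(w) for w in windowed) + 2


def resample(series: np.ndarray, target_length: int) -> np.ndarray:
    """Piecewise-linear resampling onto ``target_length`` equally spaced points.

    The new grid spans the original first and last samples, which are
    preserved exactly; interior points are linear interpolants.
    """
    series = np.asarray(series, dtype=float)
    if len(series) < 2:
        raise ValidationError("cannot resample a series shorter than 2 samples")
    if target_length < 2:
        raise ValidationError(f"target_length must be >= 2, got {target_length}")
    old = np.linspace(0.0, 1.0, len(series))
    new = np.linspace(0.0, 1.0, target_length)
    return np.interp(new, old, series)


def normalize_by_mass(series: np.ndarray, mass_kg: float) -> np.ndarray:
    """Convert Nm to Nm/kg by elementwise division by body mass."""
    if mass_kg <= 0:
        raise ValidationError(f"mass must be positive, got {mass_kg}")
    return np.asarray(series, dtype=float) / mass_kg


def preprocess_cohort(cohort: Cohort, spec: WindowSpec | None = None):
    """Window, resample and normalize every trial of a cohort.

    Order of operations is fixed: window first, then derive the common
    length from the windowed series, then resample, then normalize.
    Returns ``(ids, curves)`` where ``curves`` is an (n_trials, L) array
    of Nm/kg values on the shared grid.
    """
    spec = spec or WindowSpec()
    trials = list(cohort)
    if not trials:
        raise ValidationError("cannot preprocess an empty cohort")
    windowed = [window_trial(t, spec) for t in trials]
    L = common_length(windowed, spec)
    curves = np.vstack(
        [normalize_by_mass(resample(w, L), t.body_mass_kg) for w, t in zip(windowed, trials)]
    )
    ids = [t.trial_id for t in trials]
    return ids, curves
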