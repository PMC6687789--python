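"""Synthetic stance-phase valgus-moment trial generator.

Emulates the six waveform families seen in early-stance knee valgus
moment data — early peaks, peaks, upslopes, downslopes, early troughs,
troughs — as parametric templates on the stance-fraction axis: bumps are
Gaussian, monotone slopes are logistic ramps.  Each trial is a template
scaled by a magnitude-class multiplier (Nm/kg), corrupted with smooth
additive noise, sampled at a random raw length, and converted to Nm with
a per-athlete body mass.  Ground-truth shape and magnitude labels are
recorded so recovery by the clustering pipeline can be scored.

Noise is autocorrelated (moving-average-filtered white noise) rather
than white: the shape encoder differences the curve, and white noise
would shred the sign structure in a way filtered inverse-dynamics
signals never do.

Default group sizes and shape frequencies mirror the packaged reference
cohort tables; magnitude-class frequencies default to the per-shape
splits of the shape-by-magnitude table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .labeling import MagnitudeLabel, ShapeLabel
from .trial_io import Cohort, Trial

GroupKey = tuple[str, str]  # (sex, phase)


@dataclass(frozen=True)
class ShapeTemplate:
    """Parametric template of one waveform family on the stance axis.

    For bump families, ``apex_center``/``apex_width`` are the Gaussian
    centre and width as stance fractions and ``sign`` the bump polarity.
    For monotone families the logistic ramp is centred at ``apex_center``
    with steepness scale ``apex_width``; ``sign`` +1 rises, -1 falls.
    """

    family: ShapeLabel
    kind: str  # "bump" | "ramp"
    apex_center: float
    apex_width: float
    sign: int

    def curve(self, t: np.ndarray) -> np.ndarray:
        """Unit-amplitude template evaluated at stance fractions ``t``."""
        if self.kind == "bump":
            return self.sign * np.exp(-((t - self.apex_center) ** 2) / (2 * self.apex_width**2))
        if self.kind == "ramp":
            ramp = 1.0 / (1.0 + np.exp(-(t - self.apex_center) / self.apex_width))
            return ramp if self.sign > 0 else 1.0 - ramp
        raise ValidationError(f"unknown template kind {self.kind!r}")


#: Early apexes sit at 10% of stance (within the first quarter, matching
#: the injury-relevant timing); late apexes at 24% so they still fall
#: inside a 30% analysis window.  Ramps switch around 15% of stance.
DEFAULT_TEMPLATES: dict[ShapeLabel, ShapeTemplate] = {
    ShapeLabel.EARLY_PEAK: ShapeTemplate(ShapeLabel.EARLY_PEAK, "bump", 0.10, 0.06, +1),
    ShapeLabel.PEAK: ShapeTemplate(ShapeLabel.PEAK, "bump", 0.24, 0.08, +1),
    ShapeLabel.EARLY_TROUGH: ShapeTemplate(ShapeLabel.EARLY_TROUGH, "bump", 0.10, 0.06, -1),
    ShapeLabel.TROUGH: ShapeTemplate(ShapeLabel.TROUGH, "bump", 0.24, 0.08, -1),
    ShapeLabel.UPSLOPE: ShapeTemplate(ShapeLabel.UPSLOPE, "ramp", 0.15, 0.05, +1),
    ShapeLabel.DOWNSLOPE: ShapeTemplate(ShapeLabel.DOWNSLOPE, "ramp", 0.15, 0.05, -1),
}

#: Magnitude multipliers in Nm/kg.  Bump-peak and slope families carry two
#: classes, trough families three, mirroring the reference cohort's 14
#: sub-clusters; adjacent classes are separated by at least 2x.
DEFAULT_MAGNITUDES: dict[ShapeLabel, dict[MagnitudeLabel, float]] = {
    ShapeLabel.EARLY_PEAK: {MagnitudeLabel.SMALL: 0.5, MagnitudeLabel.LARGE: 1.0},
    ShapeLabel.PEAK: {MagnitudeLabel.SMALL: 0.5, MagnitudeLabel.LARGE: 1.0},
    ShapeLabel.UPSLOPE: {MagnitudeLabel.SMALL: 0.5, MagnitudeLabel.LARGE: 1.0},
    ShapeLabel.DOWNSLOPE: {MagnitudeLabel.SMALL: 0.5, MagnitudeLabel.LARGE: 1.0},
    ShapeLabel.TROUGH: {MagnitudeLabel.SMALL: 0.4, MagnitudeLabel.MEDIUM: 0.8, MagnitudeLabel.LARGE: 1.6},
    ShapeLabel.EARLY_TROUGH: {MagnitudeLabel.SMALL: 0.4, MagnitudeLabel.MEDIUM: 0.8, MagnitudeLabel.LARGE: 1.6},
}

#: Body mass (mean, sd) in kg per (sex, phase), emulating a youth cohort
#: at baseline and its adolescent follow-up; draws are truncated at 25 kg.
DEFAULT_MASS_PARAMS: dict[GroupKey, tuple[float, float]] = {
    ("boy", "1"): (40.2, 8.1),
    ("girl", "1"): (41.8, 9.4),
    ("boy", "2"): (74.9, 16.5),
    ("girl", "2"): (64.0, 10.3),
}


def _default_group_sizes() -> dict[GroupKey, int]:
    from .datasets import load_shape_counts

    t = load_shape_counts()
    return {g: int(n) for g, n in zip(t.row_labels, t.row_totals)}


def _default_shape_freqs() -> dict[GroupKey, dict[ShapeLabel, float]]:
    from .datasets import load_shape_counts

    t = load_shape_counts()
    out: dict[GroupKey, dict[ShapeLabel, float]] = {}
    for g, row in zip(t.row_labels, t.counts):
        total = row.sum()
        out[g] = {ShapeLabel(s): c / total for s, c in zip(t.col_labels, row)}
    return out


def _default_magnitude_freqs() -> dict[ShapeLabel, dict[MagnitudeLabel, float]]:
    from .datasets import load_shape_magnitude_counts

    t = load_shape_magnitude_counts()
    pooled = t.counts.sum(axis=0)
    by_shape: dict[ShapeLabel, dict[MagnitudeLabel, int]] = {}
    for (s, m), c in zip(t.col_labels, pooled):
        by_shape.setdefault(ShapeLabel(s), {})[MagnitudeLabel(m)] = int(c)
    return {
        s: {m: c / sum(d.values()) for m, c in d.items()} for s, d in by_shape.items()
    }


@dataclass
class GeneratorConfig:
    """Study conditions for synthetic cohort generation.

    Leave ``group_sizes``/``shape_freqs``/``magnitude_freqs`` as None to
    use the reference-cohort defaults.  ``noise_sd`` is the Nm/kg
    standard deviation of the smooth additive noise (default 0.04, i.e.
    10% of the smallest magnitude multiplier); ``noise_corr_frames`` its
    moving-average correlation length in raw frames.
    """

    group_sizes: Mapping[GroupKey, int] | None = None
    shape_freqs: Mapping[GroupKey, Mapping[ShapeLabel, float]] | None = None
    magnitude_freqs: Mapping[ShapeLabel, Mapping[MagnitudeLabel, float]] | None = None
    magnitude_multipliers: Mapping[ShapeLabel, Mapping[MagnitudeLabel, float]] = field(
        default_factory=lambda: DEFAULT_MAGNITUDES
    )
    templates: Mapping[ShapeLabel, ShapeTemplate] = field(
        default_factory=lambda: DEFAULT_TEMPLATES
    )
    mass_params: Mapping[GroupKey, tuple[float, float]] = field(
        default_factory=lambda: DEFAULT_MASS_PARAMS
    )
    noise_sd: float = 0.04
    noise_corr_frames: int = 5
    length_range: tuple[int, int] = (80, 120)
    trials_per_athlete: int = 20
    seed: int = 0

    def resolved_group_sizes(self) -> dict[GroupKey, int]:
        gs = dict(self.group_sizes) if self.group_sizes is not None else _default_group_sizes()
        if any(n < 0 for n in gs.values()):
            raise ValidationError("group sizes must be non-negative")
        return gs

    def resolved_shape_freqs(self) -> dict[GroupKey, dict[ShapeLabel, float]]:
        sf = (
            {g: dict(v) for g, v in self.shape_freqs.items()}
            if self.shape_freqs is not None
            else _default_shape_freqs()
        )
        for g, v in sf.items():
            if abs(sum(v.values()) - 1.0) > 1e-9:
                raise ValidationError(f"shape frequencies for group {g} must sum to 1")
        return sf

    def resolved_magnitude_freqs(self) -> dict[ShapeLabel, dict[MagnitudeLabel, float]]:
        if self.magnitude_freqs is not None:
            mf = {s: dict(v) for s, v in self.magnitude_freqs.items()}
        else:
            mf = _default_magnitude_freqs()
        for s, v in mf.items():
            if abs(sum(v.values()) - 1.0) > 1e-9:
                raise ValidationError(f"magnitude frequencies for shape {s} must sum to 1")
        return mf


@dataclass
class SyntheticCohort:
    """A generated cohort plus its ground-truth labels."""

    cohort: Cohort
    truth: pd.DataFrame  # columns: trial_id, shape, magnitude

    def truth_shapes(self) -> dict[str, ShapeLabel]:
        return {r.trial_id: ShapeLabel(r.shape) for r in self.truth.itertuples()}

    def truth_magnitudes(self) -> dict[str, MagnitudeLabel]:
        return {r.trial_id: MagnitudeLabel(r.magnitude) for r in self.truth.itertuples()}


def _smooth_noise(n: int, sd: float, corr: int, rng: np.random.Generator) -> np.ndarray:
    if sd == 0:
        return np.zeros(n)
    white = rng.normal(size=n + corr - 1)
    kernel = np.ones(corr) / corr
    smoothed = np.convolve(white, kernel, mode="valid")
    # MA(corr) of unit white noise has sd 1/sqrt(corr)
    return smoothed * (sd * np.sqrt(corr))


def generate_trial(
    template: ShapeTemplate,
    magnitude: MagnitudeLabel,
    config: GeneratorConfig,
    rng: np.random.Generator,
    trial_id: str = "synthetic_0",
    athlete_id: str = "athlete_0",
    sex: str = "boy",
    phase: str = "1",
    mass_kg: float | None = None,
) -> Trial:
    """Generate one trial from a template and magnitude class.

    The curve covers the full stance phase (the analysis window later
    takes its leading fraction); values are in Nm (= Nm/kg curve times
    body mass).
    """
    lo, hi = config.length_range
    n = int(rng.integers(lo, hi + 1))
    if mass_kg is None:
        mean, sd = config.mass_params.get((sex, phase), (55.0, 10.0))
        mass_kg = float(max(25.0, rng.normal(mean, sd)))
    multiplier = config.magnitude_multipliers[template.family][magnitude]
    t = np.linspace(0.0, 1.0, n)
    nm_per_kg = multiplier * template.curve(t) + _smooth_noise(
        n, config.noise_sd, config.noise_corr_frames, rng
    )
    return Trial(
        trial_id=trial_id,
        athlete_id=athlete_id,
        sex=sex,
        phase=phase,
        body_mass_kg=mass_kg,
        values=nm_per_kg * mass_kg,
    )


def generate_cohort(config: GeneratorConfig | None = None) -> SyntheticCohort:
    """Generate a labeled cohort under the configured study conditions.

    Per-group totals are exact; shape and magnitude labels within each
    group are multinomial draws from the configured frequency vectors.
    Athletes are blocks of ``trials_per_athlete`` consecutive trials
    sharing one body mass.  Fully reproducible under ``config.seed``.
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.seed)
    group_sizes = config.resolved_group_sizes()
    shape_freqs = config.resolved_shape_freqs()
    magnitude_freqs = config.resolved_magnitude_freqs()

    trials: list[Trial] = []
    truth_rows: list[dict] = []
    for (sex, phase), n_group in group_sizes.items():
        freqs = shape_freqs[(sex, phase)]
        shapes = list(freqs)
        counts = rng.multinomial(n_group, [freqs[s] for s in shapes])
        labels: list[ShapeLabel] = [s for s, c in zip(shapes, counts) for _ in range(c)]
        rng.shuffle(labels)  # interleave families across athletes
        athlete_masses: dict[str, float] = {}
        for i, shape in enumerate(labels):
            mf = magnitude_freqs[shape]
            mags = list(mf)
            magnitude = mags[
                int(rng.choice(len(mags), p=[mf[m] for m in mags]))
            ]
            athlete_id = f"{sex}{phase}_a{i // config.trials_per_athlete:03d}"
            if athlete_id not in athlete_masses:
                mean, sd = config.mass_params.get((sex, phase), (55.0, 10.0))
                athlete_masses[athlete_id] = float(max(25.0, rng.normal(mean, sd)))
            trial = generate_trial(
                config.templates[shape],
                magnitude,
                config,
                rng,
                trial_id=f"{sex}{phase}_t{i:05d}",
                athlete_id=athlete_id,
                sex=sex,
                phase=phase,
                mass_kg=athlete_masses[athlete_id],
            )
            trials.append(trial)
            truth_rows.append(
                {"trial_id": trial.trial_id, "shape": shape.value, "magnitude": magnitude.value}
            )
    return SyntheticCohort(cohort=Cohort(trials), truth=pd.DataFrame(truth_rows))
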