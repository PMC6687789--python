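"""Reading and writing stance-phase moment trials and pipeline results.

The canonical on-disk trial format is a long (tidy) CSV with one row per
recorded frame:

    trial_id, athlete_id, sex, phase, mass_kg, frame, value_nm

``frame`` is a 0-based contiguous index within each trial and ``value_nm``
the joint moment sample in newton-metres.  Motion-analysis exports are
trivially reshaped to this layout, and it supports trials of unequal
length, which a wide one-column-per-frame table would not.  Extra columns
are tolerated and ignored, so condition or task metadata can ride along.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError
from .labeling import MagnitudeLabel, ShapeLabel

REQUIRED_COLUMNS = ("trial_id", "athlete_id", "sex", "phase", "mass_kg", "frame", "value_nm")

#: Minimum number of frames for a trial to survive windowing + differencing.
MIN_FRAMES = 4


@dataclass
class Trial:
    """One recorded stance-phase moment time series with metadata.

    ``values`` holds the raw moment samples in Nm, ordered by frame; the
    stance phase is assumed to be exactly the provided sample range.
    """

    trial_id: str
    athlete_id: str
    sex: str
    phase: str
    body_mass_kg: float
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValidationError(f"trial {self.trial_id!r}: values must be 1-D")
        if self.body_mass_kg <= 0:
            raise ValidationError(
                f"trial {self.trial_id!r}: body mass must be positive, got {self.body_mass_kg}"
            )
        if self.n_frames < MIN_FRAMES:
            raise ValidationError(
                f"trial {self.trial_id!r}: needs >= {MIN_FRAMES} frames, got {self.n_frames}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError(f"trial {self.trial_id!r}: values contain missing/non-finite entries")

    @property
    def n_frames(self) -> int:
        return len(self.values)

    @property
    def group(self) -> str:
        """Group key used by the frequency statistics (sex and phase)."""
        return f"{self.sex}_{self.phase}"


@dataclass
class Cohort:
    """A collection of trials with unique ids."""

    trials: list[Trial] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [t.trial_id for t in self.trials]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate trial ids in cohort: {dupes}")

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)

    @property
    def groups(self) -> list[tuple[str, str]]:
        """(sex, phase) combinations in order of first appearance."""
        seen: dict[tuple[str, str], None] = {}
        for t in self.trials:
            seen.setdefault((t.sex, t.phase), None)
        return list(seen)


@dataclass
class LabeledTrial:
    """A trial annotated by the two-step pipeline."""

    trial_id: str
    shape: ShapeLabel
    magnitude: MagnitudeLabel | None
    shape_cluster: int
    sub_cluster: int


def read_trials(path) -> Cohort:
    """Read a long-CSV trial file into a :class:`Cohort`.

    Frames within each trial must form a contiguous 0-based run and mass
    must be constant per trial.  Malformed rows are reported with their
    1-based line number in the file.
    """
    df = pd.read_csv(path, dtype={"trial_id": str, "athlete_id": str, "sex": str, "phase": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")

    bad = df.index[df[list(REQUIRED_COLUMNS)].isna().any(axis=1)]
    if len(bad):
        lines = ", ".join(str(i + 2) for i in bad[:10])  # +2: header + 0-based index
        raise FormatError(f"{path}: malformed rows with missing fields at line(s) {lines}")

    trials: list[Trial] = []
    for trial_id, sub in df.groupby("trial_id", sort=False):
        frames = sub["frame"].to_numpy()
        dup = sub[sub.duplicated("frame", keep=False)]
        if len(dup):
            f = int(dup["frame"].iloc[0])
            raise ValidationError(
                f"trial {trial_id!r}: duplicate rows for frame {f} "
                f"(line {int(dup.index[0]) + 2})"
            )
        order = np.argsort(frames, kind="stable")
        frames = frames[order]
        if not np.array_equal(frames, np.arange(len(frames))):
            raise ValidationError(f"trial {trial_id!r}: frames are not a contiguous 0-based run")
        masses = sub["mass_kg"].unique()
        if len(masses) != 1:
            raise ValidationError(f"trial {trial_id!r}: inconsistent mass values {sorted(masses)}")
        trials.append(
            Trial(
                trial_id=str(trial_id),
                athlete_id=str(sub["athlete_id"].iloc[0]),
                sex=str(sub["sex"].iloc[0]),
                phase=str(sub["phase"].iloc[0]),
                body_mass_kg=float(masses[0]),
                values=sub["value_nm"].to_numpy(dtype=float)[order],
            )
        )
    return Cohort(trials)


def write_trials(cohort: Cohort, path) -> None:
    """Write a cohort in the long-CSV trial format (17 significant digits)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(REQUIRED_COLUMNS)
        for t in cohort:
            for frame, v in enumerate(t.values):
                w.writerow(
                    [t.trial_id, t.athlete_id, t.sex, t.phase,
                     f"{t.body_mass_kg:.17g}", frame, f"{v:.17g}"]
                )


RESULT_COLUMNS = ("trial_id", "shape", "magnitude", "shape_cluster", "sub_cluster")


def write_results(assignments: Sequence[LabeledTrial], path) -> None:
    """Write pipeline label assignments as CSV, one record per trial.

    Refuses an empty collection: an empty results file would be
    indistinguishable from a failed run.
    """
    assignments = list(assignments)
    if not assignments:
        raise ValidationError("refusing to write an empty results file")
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(RESULT_COLUMNS)
        for a in assignments:
            w.writerow(
                [a.trial_id, a.shape.value,
                 a.magnitude.value if a.magnitude is not None else "",
                 a.shape_cluster, a.sub_cluster]
            )


def read_results(path) -> list[LabeledTrial]:
    """Read back a results CSV written by :func:`write_results`."""
    out: list[LabeledTrial] = []
    with open(path, newline="") as fh:
        r = csv.DictReader(fh)
        if r.fieldnames is None or any(c not in r.fieldnames for c in RESULT_COLUMNS):
            raise FormatError(f"{path}: not a results file (expected columns {RESULT_COLUMNS})")
        for row in r:
            out.append(
                LabeledTrial(
                    trial_id=row["trial_id"],
                    shape=ShapeLabel(row["shape"]),
                    magnitude=MagnitudeLabel(row["magnitude"]) if row["magnitude"] else None,
                    shape_cluster=int(row["shape_cluster"]),
                    sub_cluster=int(row["sub_cluster"]),
                )
            )
    return out
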