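"""Direction-change encoding of curves and Euclidean distance matrices.

A curve of length L is reduced to the signs of its lagged differences: a
ternary sequence of length L-1 whose entries say whether each sample rose
(+1), fell (-1) or tied (0) relative to the previous frame.  The encoding
discards all amplitude information — it is invariant to positive scaling
and to offsets — which is exactly what makes the first clustering step a
*shape* classification.  Ties are encoded as 0 because interpolation can
create exactly-equal neighbours; a flag maps them to +1 instead for
sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .errors import ValidationError


@dataclass
class EncodedWaveform:
    """Ternary (-1/0/+1) direction-change signature of one curve."""

    trial_id: str
    signs: np.ndarray


@dataclass
class DistanceMatrix:
    """Symmetric non-negative dissimilarity matrix over named items."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.ids):
            raise ValidationError("distance matrix must be square and match ids")
        if not np.allclose(v, v.T):
            raise ValidationError("distance matrix must be symmetric")
        if np.any(v < 0) or not np.allclose(np.diag(v), 0):
            raise ValidationError("distances must be non-negative with a zero diagonal")
        self.values = v

    @property
    def n(self) -> int:
        return len(self.ids)

    def to_csv(self, path) -> None:
        """Export as a square CSV with an id header row/column."""
        import csv

        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["id", *self.ids])
            for i, row in enumerate(self.values):
                w.writerow([self.ids[i], *(f"{x:.17g}" for x in row)])


def encode(curve: Sequence[float], ties: str = "zero") -> np.ndarray:
    """Encode a curve as the signs of its first differences.

    ``signs[k] = sign(curve[k+1] - curve[k])`` with sign(0) = 0 under the
    default tie policy, or +1 under ``ties="up"``.
    """
    curve = np.asarray(curve, dtype=float)
    if curve.ndim != 1 or len(curve) < 2:
        raise ValidationError("encoding needs a 1-D curve of length >= 2")
    d = np.diff(curve)
    signs = np.sign(d)
    if ties == "up":
        signs[d == 0] = 1.0
    elif ties != "zero":
        raise ValidationError(f"unknown tie policy {ties!r}")
    return signs.astype(np.int8)


def distance_matrix(items: Sequence[Sequence[float]], ids: Sequence[str] | None = None) -> DistanceMatrix:
    """Pairwise Euclidean distance matrix over equal-length sequences."""
    items = [np.asarray(x, dtype=float) for x in items]
    if len(items) < 2:
        raise ValidationError("distance matrix needs at least 2 items")
    if ids is None:
        ids = [str(i) for i in range(len(items))]
    ids = list(ids)
    if len(ids) != len(items):
        raise ValidationError("ids and items differ in length")
    lengths = {len(x) for x in items}
    if len(lengths) != 1:
        offenders = [ids[i] for i, x in enumerate(items) if len(x) != len(items[0])]
        raise ValidationError(f"ragged item lengths {sorted(lengths)}; offending items: {offenders}")
    d = squareform(pdist(np.vstack(items), metric="euclidean"))
    return DistanceMatrix(ids=ids, values=d)
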