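"""Packaged reference frequency tables.

These are the observed trial counts of shape clusters (and shape-by-
magnitude sub-clusters) of the knee valgus moment, by sex and study
phase, from a published two-phase cohort of youth soccer and team
handball athletes performing a change-of-direction task (phase 1:
pre-adolescence, phase 2: five-year follow-up in adolescence).  They let
the frequency statistics be exercised and documented without access to
any raw motion-capture data, and they provide realistic default shape
frequencies for the synthetic generator.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .frequency import ContingencyTable

_GROUP_ORDER = [("boy", "1"), ("girl", "1"), ("boy", "2"), ("girl", "2")]


def _load(name: str, category_cols: list[str]) -> ContingencyTable:
    with resources.files("vmclust.data").joinpath(name).open() as fh:
        df = pd.read_csv(fh, dtype={"sex": str, "phase": str})
    rows: dict = {}
    cols: dict = {}
    for _, r in df.iterrows():
        rows.setdefault((r["sex"], r["phase"]), len(rows))
        key = tuple(r[c] for c in category_cols)
        cols.setdefault(key if len(key) > 1 else key[0], len(cols))
    import numpy as np

    counts = np.zeros((len(rows), len(cols)), dtype=np.int64)
    for _, r in df.iterrows():
        key = tuple(r[c] for c in category_cols)
        counts[rows[(r["sex"], r["phase"])], cols[key if len(key) > 1 else key[0]]] = r["count"]
    return ContingencyTable(row_labels=list(rows), col_labels=list(cols), counts=counts)


def load_shape_counts() -> ContingencyTable:
    """Observed counts of the six shape clusters by sex and phase (4 x 6)."""
    return _load("cohort_shape_counts.csv", ["shape"])


def load_shape_magnitude_counts() -> ContingencyTable:
    """Observed counts of the 14 shape-by-magnitude sub-clusters (4 x 14)."""
    return _load("cohort_shape_magnitude_counts.csv", ["shape", "magnitude"])
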