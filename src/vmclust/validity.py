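"""C-Index cluster validity and selection of the number of clusters.

The C-Index (Hubert-Levin) compares the sum of within-cluster pairwise
distances S_w against the best and worst conceivable sums over the same
number of pairs:

    C = (S_w - S_min) / (S_max - S_min)

where, for n_w within-cluster pairs, S_min and S_max are the sums of the
n_w smallest and largest distances among *all* pairs.  C lies in [0, 1];
0 means the within-cluster pairs are exactly the globally closest pairs
(perfect separation), lower is better.  The index is undefined for a
single cluster, for an all-singleton partition, and when every pairwise
distance is equal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import UndefinedIndexError, ValidationError
from .hierarchical import ClusterAssignment, Linkage, cut_tree
from .shape_encoding import DistanceMatrix


@dataclass
class CIndexScan:
    """C-Index evaluated over a range of cluster counts.

    ``c_values`` is aligned with ``k_values``; undefined entries are NaN.
    ``chosen_k`` and ``rule_used`` are filled in by :func:`select_k`.
    """

    k_values: np.ndarray
    c_values: np.ndarray
    chosen_k: int | None = None
    rule_used: str | None = None

    def to_csv(self, path) -> None:
        """Export the (k, C) scan for plotting."""
        import csv

        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["k", "c_index"])
            for k, c in zip(self.k_values, self.c_values):
                w.writerow([int(k), "" if np.isnan(c) else f"{c:.17g}"])


def _pair_arrays(dm: DistanceMatrix):
    iu = np.triu_indices(dm.n, 1)
    return iu, dm.values[iu]


def _c_from_masks(dists: np.ndarray, within: np.ndarray, sorted_prefix: np.ndarray) -> float:
    n_w = int(within.sum())
    n_pairs = len(dists)
    if n_w == 0:
        raise UndefinedIndexError("no within-cluster pair (all-singleton partition)")
    if n_w == n_pairs:
        raise UndefinedIndexError("all pairs are within-cluster (single cluster)")
    s_w = float(dists[within].sum())
    s_min = float(sorted_prefix[n_w])
    s_max = float(sorted_prefix[n_pairs] - sorted_prefix[n_pairs - n_w])
    if s_max == s_min:
        raise UndefinedIndexError("all pairwise distances are equal; C-Index undefined")
    # clamp float-summation dust so C stays in [0, 1]
    return min(1.0, max(0.0, (s_w - s_min) / (s_max - s_min)))


def c_index(dm: DistanceMatrix, assignment: ClusterAssignment) -> float:
    """Hubert-Levin C-Index of a partition over a distance matrix."""
    if len(assignment.labels) != dm.n:
        raise ValidationError("assignment does not match distance matrix size")
    iu, dists = _pair_arrays(dm)
    within = assignment.labels[iu[0]] == assignment.labels[iu[1]]
    prefix = np.concatenate([[0.0], np.cumsum(np.sort(dists))])
    return _c_from_masks(dists, within, prefix)


def scan_k(dm: DistanceMatrix, linkage: Linkage, k_min: int = 2, k_max: int = 50) -> CIndexScan:
    """Evaluate the C-Index on tree cuts for every k in [k_min, k_max].

    Cluster counts for which the index is undefined (e.g. the
    all-singleton cut) are recorded as NaN rather than dropped, so the
    scan stays aligned with the requested range.
    """
    if not 2 <= k_min <= k_max <= linkage.n_leaves:
        raise ValidationError(
            f"need 2 <= k_min <= k_max <= {linkage.n_leaves}, got [{k_min}, {k_max}]"
        )
    iu, dists = _pair_arrays(dm)
    prefix = np.concatenate([[0.0], np.cumsum(np.sort(dists))])
    ks = np.arange(k_min, k_max + 1)
    cs = np.full(len(ks), np.nan)
    for idx, k in enumerate(ks):
        labels = cut_tree(linkage, int(k)).labels
        within = labels[iu[0]] == labels[iu[1]]
        try:
            cs[idx] = _c_from_masks(dists, within, prefix)
        except UndefinedIndexError:
            pass
    return CIndexScan(k_values=ks, c_values=cs)


def select_k(scan: CIndexScan, threshold: float = 0.05, rule: str = "threshold") -> int:
    """Choose the number of clusters from a C-Index scan.

    ``threshold`` rule: the smallest k whose C-Index is <= threshold
    (the comparison is inclusive).  ``elbow`` rule: the k maximizing the
    discrete second difference of the C-Index curve (first maximum;
    smaller k wins ties).  If the threshold rule finds no qualifying k,
    the argmin of the scan is returned and flagged as a fallback.
    """
    defined = ~np.isnan(scan.c_values)
    if not defined.any():
        raise ValidationError("scan contains no defined C-Index values")
    ks, cs = scan.k_values[defined], scan.c_values[defined]

    if rule == "threshold":
        hits = np.flatnonzero(cs <= threshold)
        if len(hits):
            scan.chosen_k, scan.rule_used = int(ks[hits[0]]), "threshold"
        else:
            scan.chosen_k, scan.rule_used = int(ks[np.argmin(cs)]), "argmin-fallback"
    elif rule == "elbow":
        if len(cs) < 3:
            scan.chosen_k, scan.rule_used = int(ks[np.argmin(cs)]), "argmin-fallback"
        else:
            second_diff = cs[:-2] - 2 * cs[1:-1] + cs[2:]
            scan.chosen_k = int(ks[1 + int(np.argmax(second_diff))])
            scan.rule_used = "elbow"
    else:
        raise ValidationError(f"unknown selection rule {rule!r}")
    return scan.chosen_k
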