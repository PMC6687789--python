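"""Agglomerative Ward.D2 clustering over an arbitrary dissimilarity matrix.

This is the Murtagh-Legendre "Ward.D2" formulation: the minimum-variance
(Ward) criterion applied to the *input* dissimilarities by running the
Lance-Williams recurrence on their squares and reporting merge heights on
the original (square-rooted) scale.  On Euclidean point distances it
coincides with classical Ward clustering of the points.

The implementation is generic over any valid dissimilarity matrix so the
same code drives both pipeline steps (encoded-shape distances and Nm/kg
magnitude distances).  When two merge candidates tie exactly on the
criterion, the pair with the lexicographically smallest (smaller node id,
larger node id) wins, making the output independent of input order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .shape_encoding import DistanceMatrix


@dataclass
class Linkage:
    """A merge tree in scipy convention.

    ``merges`` has one row per agglomeration: (left node, right node,
    height, size of the new cluster).  Leaves are nodes 0..n-1; the merge
    at row t creates node n + t.
    """

    merges: np.ndarray
    n_leaves: int

    def __post_init__(self) -> None:
        m = np.asarray(self.merges, dtype=float)
        if m.shape != (self.n_leaves - 1, 4):
            raise ValidationError(
                f"linkage needs {self.n_leaves - 1} merges of 4 fields, got {m.shape}"
            )
        self.merges = m

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    def to_json(self, path=None) -> str:
        """Serialize the merge list for audit/replication."""
        payload = json.dumps(
            {
                "n_leaves": self.n_leaves,
                "merges": [
                    {"left": int(a), "right": int(b), "height": h, "size": int(s)}
                    for a, b, h, s in self.merges
                ],
            },
            indent=2,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload


@dataclass
class ClusterAssignment:
    """A flat partition of items into k clusters.

    Label indices are assigned in order of first appearance over ``ids``.
    """

    ids: list[str]
    labels: np.ndarray
    k: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.labels) != len(self.ids):
            raise ValidationError("labels and ids differ in length")
        if len(np.unique(self.labels)) != self.k:
            raise ValidationError(f"expected exactly {self.k} distinct labels")

    def members(self, label: int) -> np.ndarray:
        return np.flatnonzero(self.labels == label)


def ward2_linkage(dm: DistanceMatrix) -> Linkage:
    """Build the Ward.D2 merge tree for a dissimilarity matrix."""
    n = dm.n
    if n < 2:
        raise ValidationError("clustering needs at least 2 items")
    # Lance-Williams recurrence runs on squared dissimilarities; merge
    # heights are reported on the original scale.
    d2 = dm.values.astype(float) ** 2
    np.fill_diagonal(d2, np.inf)
    size = np.ones(n)
    node = np.arange(n)          # current node id living in each slot
    alive = np.ones(n, dtype=bool)
    merges = np.empty((n - 1, 4))

    for step in range(n - 1):
        flat = np.argmin(d2)
        best = d2.flat[flat]
        # exact ties: prefer the lexicographically smallest node pair
        ti, tj = np.nonzero(d2 == best)
        pairs = sorted(
            (tuple(sorted((node[a], node[b]))), a, b) for a, b in zip(ti, tj) if a < b
        )
        _, i, j = pairs[0]

        merges[step] = (node[i], node[j], np.sqrt(best), size[i] + size[j])

        si, sj = size[i], size[j]
        k = alive.copy()
        k[[i, j]] = False
        sk = size[k]
        d2_new = ((si + sk) * d2[i, k] + (sj + sk) * d2[j, k] - sk * best) / (si + sj + sk)
        # merged cluster takes slot i; slot j dies
        d2[i, k] = d2_new
        d2[k, i] = d2_new
        d2[j, :] = np.inf
        d2[:, j] = np.inf
        d2[i, i] = np.inf
        size[i] = si + sj
        node[i] = n + step
        alive[j] = False

    return Linkage(merges=merges, n_leaves=n)


def cut_tree(linkage: Linkage, k: int, ids: list[str] | None = None) -> ClusterAssignment:
    """Cut the merge tree into k clusters (undo the last k-1 merges)."""
    n = linkage.n_leaves
    if not 1 <= k <= n:
        raise ValidationError(f"k must be in [1, {n}], got {k}")
    if ids is None:
        ids = [str(i) for i in range(n)]
    parent = np.arange(2 * n - 1)

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for t in range(n - k):
        a, b, _, _ = linkage.merges[t]
        new = n + t
        parent[find(int(a))] = new
        parent[find(int(b))] = new

    roots = [find(i) for i in range(n)]
    relabel: dict[int, int] = {}
    labels = np.empty(n, dtype=int)
    for i, r in enumerate(roots):
        labels[i] = relabel.setdefault(r, len(relabel))
    return ClusterAssignment(ids=list(ids), labels=labels, k=k)
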