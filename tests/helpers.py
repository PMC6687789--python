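"""Shared independent oracles for the test suite."""

import numpy as np

from vmclust import ClusterAssignment


def assign_labels(labels):
    labels = np.asarray(labels)
    return ClusterAssignment(
        ids=[str(i) for i in range(len(labels))],
        labels=labels,
        k=len(np.unique(labels)),
    )


def brute_force_c_index(d, labels):
    """Independent C-Index oracle: explicit sort of all pairwise distances."""
    n = len(labels)
    pairs = [(d[i, j], labels[i] == labels[j]) for i in range(n) for j in range(i + 1, n)]
    within = [p for p, w in pairs if w]
    n_w = len(within)
    all_sorted = sorted(p for p, _ in pairs)
    s_w, s_min, s_max = sum(within), sum(all_sorted[:n_w]), sum(all_sorted[-n_w:])
    return (s_w - s_min) / (s_max - s_min)
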