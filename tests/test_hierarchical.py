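"""Ward.D2 linkage and tree cutting."""

import itertools

import numpy as np
import pytest
from scipy.cluster.hierarchy import cut_tree as sp_cut
from scipy.cluster.hierarchy import linkage as sp_linkage
from scipy.spatial.distance import pdist

from vmclust import DistanceMatrix, ValidationError, cut_tree, distance_matrix, ward2_linkage


def _points_dm(pts):
    return distance_matrix(np.atleast_2d(pts), [str(i) for i in range(len(pts))])


def test_two_items_merge_at_their_distance():
    dm = DistanceMatrix(ids=["a", "b"], values=np.array([[0.0, 3.7], [3.7, 0.0]]))
    link = ward2_linkage(dm)
    assert link.merges.shape == (1, 4)
    assert link.merges[0, 2] == pytest.approx(3.7)
    assert link.merges[0, 3] == 2


def test_clear_one_dimensional_bipartition():
    """Cutting at k=2 isolates {0, 0.1, 0.2} from {10, 10.1}.

    Checked against exhaustive enumeration of every bipartition by total
    within-cluster sum of squared deviations from the centroid.
    """
    x = np.array([0.0, 0.1, 0.2, 10.0, 10.1])
    best, best_ss = None, np.inf
    for size in range(1, 5):
        for left in itertools.combinations(range(5), size):
            right = [i for i in range(5) if i not in left]
            ss = sum(np.sum((x[list(g)] - x[list(g)].mean()) ** 2) for g in (left, right))
            if ss < best_ss:
                best_ss, best = ss, frozenset(map(frozenset, (set(left), set(right))))
    link = ward2_linkage(_points_dm(x[:, None]))
    labels = cut_tree(link, 2).labels
    got = frozenset(
        frozenset(np.flatnonzero(labels == c).tolist()) for c in np.unique(labels)
    )
    assert got == best == frozenset({frozenset({0, 1, 2}), frozenset({3, 4})})


@pytest.mark.parametrize("seed", range(10))
def test_matches_reference_ward_implementation(seed):
    """Partitions at every k agree with scipy's Ward linkage on random points."""
    rng = np.random.default_rng(seed)
    pts = rng.normal(size=(8, 3))
    link = ward2_linkage(_points_dm(pts))
    ref = sp_linkage(pdist(pts), method="ward")
    np.testing.assert_allclose(np.sort(link.heights), np.sort(ref[:, 2]), rtol=1e-8)
    for k in range(1, 9):
        ours = cut_tree(link, k).labels
        theirs = sp_cut(ref, n_clusters=k).ravel()
        # agreement up to label renaming
        assert len({(a, b) for a, b in zip(ours, theirs)}) == k


@pytest.mark.parametrize("seed", range(5))
def test_no_height_inversions(seed):
    pts = np.random.default_rng(seed).normal(size=(12, 4))
    link = ward2_linkage(_points_dm(pts))
    assert np.all(np.diff(link.heights) >= -1e-12)


@pytest.mark.parametrize("seed", range(5))
def test_cuts_are_nested(seed):
    """The k-cluster partition refines the (k-1)-cluster partition."""
    pts = np.random.default_rng(seed).normal(size=(10, 2))
    link = ward2_linkage(_points_dm(pts))
    for k in range(2, 11):
        fine = cut_tree(link, k).labels
        coarse = cut_tree(link, k - 1).labels
        # each fine cluster maps into exactly one coarse cluster
        mapping = {}
        for f, c in zip(fine, coarse):
            assert mapping.setdefault(f, c) == c


def test_permutation_invariance():
    rng = np.random.default_rng(7)
    pts = rng.normal(size=(9, 3))
    perm = rng.permutation(9)
    link_a = ward2_linkage(_points_dm(pts))
    link_b = ward2_linkage(_points_dm(pts[perm]))
    for k in (2, 3, 4):
        la = cut_tree(link_a, k).labels
        lb = cut_tree(link_b, k).labels
        # compare partitions as sets of index sets
        part_a = frozenset(frozenset(np.flatnonzero(la == c).tolist()) for c in range(k))
        part_b = frozenset(
            frozenset(perm[np.flatnonzero(lb == c)].tolist()) for c in range(k)
        )
        assert part_a == part_b


def test_cut_extremes_and_bounds():
    pts = np.arange(6.0)[:, None]
    link = ward2_linkage(_points_dm(pts))
    assert cut_tree(link, 1).labels.tolist() == [0] * 6
    assert sorted(cut_tree(link, 6).labels.tolist()) == list(range(6))
    with pytest.raises(ValidationError):
        cut_tree(link, 0)
    with pytest.raises(ValidationError):
        cut_tree(link, 7)


def test_labels_in_first_appearance_order():
    x = np.array([10.0, 0.0, 10.1, 0.1])[:, None]
    labels = cut_tree(ward2_linkage(_points_dm(x)), 2).labels
    assert labels.tolist() == [0, 1, 0, 1]


def test_rejects_invalid_matrix():
    with pytest.raises(ValidationError):
        DistanceMatrix(ids=["a", "b"], values=np.array([[0.0, 1.0], [2.0, 0.0]]))
    with pytest.raises(ValidationError):
        DistanceMatrix(ids=["a", "b"], values=np.array([[0.0, -1.0], [-1.0, 0.0]]))


def test_sizes_telescope(balanced_cohort):
    from vmclust import encode, preprocess_cohort

    ids, curves = preprocess_cohort(balanced_cohort.cohort)
    enc = np.vstack([encode(c) for c in curves[:40]]).astype(float)
    link = ward2_linkage(distance_matrix(enc, ids[:40]))
    assert link.merges[-1, 3] == 40
    assert link.merges.shape == (39, 4)
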