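"""Feature-space distances, neighbor joining, subclass purity."""

import io

import numpy as np
import pytest
from skbio import TreeNode
from skbio import DistanceMatrix as SkbioDM
from skbio.tree import nj as skbio_nj

from pdekit.errors import InputError
from pdekit.motifs import SpacerProfile
from pdekit.phylo import (
    DistanceMatrix,
    cluster_purity,
    nj_tree,
    profile_distance_matrix,
    spacer_distance,
)
from pdekit.pipeline import classification_tree, classify_records

from _oracles import best_ls_topology, random_additive_matrix, skbio_split_set


def _profile(s2, s3, s4, s5, length):
    return SpacerProfile((1, s2, s3, s4, s5, 1), length)


def test_spacer_distance_basics():
    a = _profile(37, 30, 69, 36, 285)
    assert spacer_distance(a, a) == 0.0
    b = _profile(27, 30, 69, 36, 285)
    assert spacer_distance(a, b, length_weight=0.0) == 10.0
    c = _profile(27, 30, 69, 36, 265)
    assert spacer_distance(a, c, length_weight=0.1) == pytest.approx(12.0)


def test_spacer_distance_symmetry_over_random_profiles(rng):
    for _ in range(50):
        a = _profile(*rng.integers(1, 80, size=4), int(rng.integers(100, 400)))
        b = _profile(*rng.integers(1, 80, size=4), int(rng.integers(100, 400)))
        assert spacer_distance(a, b) == pytest.approx(spacer_distance(b, a))
        assert spacer_distance(a, b) >= 0


def test_distance_matrix_validation():
    with pytest.raises(InputError):
        DistanceMatrix(("a", "b"), np.array([[0.0, 1.0], [2.0, 0.0]]))
    with pytest.raises(InputError):
        DistanceMatrix(("a", "b"), np.array([[1.0, 0.0], [0.0, 0.0]]))
    with pytest.raises(InputError):
        nj_tree(DistanceMatrix(("a", "b"), np.zeros((2, 2))))


def test_nj_recovers_four_taxon_additive_topology():
    # additive matrix for ((A,B),(C,D)) with internal branch 2
    labels = ("A", "B", "C", "D")
    d = np.array(
        [
            [0.0, 3.0, 7.0, 8.0],
            [3.0, 0.0, 8.0, 9.0],
            [7.0, 8.0, 0.0, 5.0],
            [8.0, 9.0, 5.0, 0.0],
        ]
    )
    tree = nj_tree(DistanceMatrix(labels, d))
    got = skbio_split_set(tree, list(labels))
    want = best_ls_topology(list(labels), d)
    assert got == want == frozenset({frozenset({"C", "D"})})


def test_three_taxon_closed_form_branch_lengths():
    labels = ("a", "b", "c")
    d = np.array([[0.0, 5.0, 9.0], [5.0, 0.0, 10.0], [9.0, 10.0, 0.0]])
    tree = nj_tree(DistanceMatrix(labels, d))
    lengths = {t.name: t.length for t in tree.tips()}
    assert lengths["a"] == pytest.approx((5 + 9 - 10) / 2)
    assert lengths["b"] == pytest.approx((5 + 10 - 9) / 2)
    assert lengths["c"] == pytest.approx((9 + 10 - 5) / 2)


def test_nj_matches_bruteforce_on_random_additive_matrices(rng):
    for n in (4, 5, 6):
        for _ in range(5):
            labels = [f"t{i}" for i in range(n)]
            want_splits, d = random_additive_matrix(rng, labels)
            tree = nj_tree(DistanceMatrix(tuple(labels), d))
            assert skbio_split_set(tree, labels) == want_splits
            assert best_ls_topology(labels, d) == want_splits


def test_nj_recovers_topology_up_to_eight_taxa(rng):
    for n in (7, 8):
        for _ in range(5):
            labels = [f"t{i}" for i in range(n)]
            want_splits, d = random_additive_matrix(rng, labels)
            tree = nj_tree(DistanceMatrix(tuple(labels), d))
            assert skbio_split_set(tree, labels) == want_splits


def test_nj_agrees_with_skbio_on_additive_matrices(rng):
    labels = [f"t{i}" for i in range(7)]
    _, d = random_additive_matrix(rng, labels)
    ours = nj_tree(DistanceMatrix(tuple(labels), d))
    theirs = skbio_nj(SkbioDM(d, ids=labels))
    assert skbio_split_set(ours, labels) == skbio_split_set(theirs, labels)


def test_ultrametric_two_cluster_bipartition_present():
    labels = ("a1", "a2", "a3", "b1", "b2", "b3")
    d = np.full((6, 6), 10.0)
    d[:3, :3] = 1.0
    d[3:, 3:] = 1.0
    np.fill_diagonal(d, 0.0)
    tree = nj_tree(DistanceMatrix(labels, d))
    splits = skbio_split_set(tree, list(labels))
    assert frozenset({"b1", "b2", "b3"}) in splits


def test_newick_round_trip():
    labels = ("A", "B", "C", "D", "E")
    rng = np.random.default_rng(3)
    _, d = random_additive_matrix(rng, list(labels))
    tree = nj_tree(DistanceMatrix(labels, d))
    text = str(tree)
    back = TreeNode.read(io.StringIO(text))
    assert skbio_split_set(back, list(labels)) == skbio_split_set(tree, list(labels))
    assert {t.name for t in back.tips()} == set(labels)


def test_cluster_purity_cases():
    labels = ("a1", "a2", "b1", "b2")
    d = np.array(
        [
            [0.0, 1.0, 9.0, 9.0],
            [1.0, 0.0, 9.0, 9.0],
            [9.0, 9.0, 0.0, 1.0],
            [9.0, 9.0, 1.0, 0.0],
        ]
    )
    tree = nj_tree(DistanceMatrix(labels, d))
    assert cluster_purity(tree, {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}) == 1.0
    # single subclass present: vacuously pure
    assert cluster_purity(tree, {l: "A" for l in labels}) == 1.0
    with pytest.raises(InputError):
        cluster_purity(tree, {"a1": "A"})


def test_planted_label_error_breaks_purity():
    profiles = {}
    labels = {}
    rng = np.random.default_rng(5)
    for lab, (s2, s4, s5, ln) in {
        "A": (37, 69, 36, 285), "B": (17, 62, 21, 243), "C": (14, 28, 12, 183),
    }.items():
        for i in range(4):
            name = f"{lab}{i}"
            profiles[name] = _profile(
                s2 + int(rng.integers(0, 2)), 30, s4, s5, ln
            )
            labels[name] = lab
    # one "B" sequence actually carries subclass-A spacings
    profiles["B0"] = _profile(37, 30, 69, 36, 285)
    tree = nj_tree(profile_distance_matrix(profiles))
    assert cluster_purity(tree, labels) < 1.0


def test_default_benchmark_fixture_is_pure(benchmark60):
    records, truth = benchmark60
    _, profiles, labels = classify_records(records)
    assert len(profiles) == 60
    tree, purity = classification_tree(profiles, labels)
    assert purity == 1.0
    # labels used for purity must agree with the planted truth
    planted = dict(zip(truth["id"], truth["label"]))
    assert labels == planted
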