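"""UPGMA clustering, threshold cut, and the homogeneity re-clustering check."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from skbio import DistanceMatrix

from codonbin import (
    CodonUsageClusterer,
    CodonUsageVector,
    build_distance_matrix,
    cut_at_threshold,
    homogeneity_check,
    upgma,
)

from tests_oracles import naive_average_linkage, random_distance_matrix

settings.register_profile("ci", max_examples=40, deadline=None, derandomize=True)
settings.load_profile("ci")


def test_upgma_matches_hand_computation():
    dm = DistanceMatrix([[0, 0.02, 0.10], [0.02, 0, 0.06], [0.10, 0.06, 0]], ids=list("ABC"))
    tree = upgma(dm)
    assert tree.heights == pytest.approx([0.02, 0.08], abs=1e-15)


def test_upgma_equal_distances_merge_at_same_height():
    c = 0.05
    dm = DistanceMatrix(np.full((3, 3), c) - c * np.eye(3), ids=list("XYZ"))
    assert upgma(dm).heights == pytest.approx([c, c], abs=1e-15)


def test_upgma_heights_match_naive_oracle_on_random_matrices():
    rng = np.random.default_rng(12345)
    for _ in range(200):
        n = int(rng.integers(3, 9))
        dm = random_distance_matrix(rng, n)
        Z = upgma(dm)
        assert np.allclose(
            np.sort(Z.heights), np.sort(naive_average_linkage(dm.data)), atol=1e-12, rtol=0
        )


def test_upgma_heights_are_monotone_on_random_matrix():
    rng = np.random.default_rng(8)
    tree = upgma(random_distance_matrix(rng, 8))
    assert np.all(np.diff(tree.heights) >= -1e-15)


def test_cut_semantics_on_hand_tree():
    dm = DistanceMatrix([[0, 0.02, 0.10], [0.02, 0, 0.06], [0.10, 0.06, 0]], ids=list("ABC"))
    tree = upgma(dm)
    g = cut_at_threshold(tree, 0.04)
    assert sorted(g.groups.values()) == [["A", "B"], ["C"]]
    assert cut_at_threshold(tree, 0.0).n_groups == 3  # below all heights
    assert cut_at_threshold(tree, 1.0).n_groups == 1  # above all heights


@given(st.integers(0, 2**31 - 1), st.floats(0.0, 1.5))
def test_cut_always_returns_a_partition(seed, threshold):
    rng = np.random.default_rng(seed)
    dm = random_distance_matrix(rng, int(rng.integers(2, 10)))
    g = cut_at_threshold(upgma(dm), threshold)
    members = sorted(m for grp in g.groups.values() for m in grp)
    assert members == sorted(dm.ids)  # union = leaves, no duplicates


def test_within_group_cophenetic_bounded_by_threshold():
    rng = np.random.default_rng(5)
    dm = random_distance_matrix(rng, 9)
    tree = upgma(dm)
    g = cut_at_threshold(tree, 0.05)
    coph = tree.cophenetic()
    for members in g.groups.values():
        for a in members:
            for b in members:
                assert coph[a, b] <= 0.05 + 1e-12


def test_distance_matrix_contract():
    rng = np.random.default_rng(2)
    profiles = [CodonUsageVector(f"p{i}", rng.integers(1, 30, 61)) for i in range(3)]
    dm = build_distance_matrix(profiles)
    assert dm.shape == (3, 3)
    assert np.allclose(dm.data, dm.data.T)
    assert np.all(np.diag(dm.data) == 0)
    twin = CodonUsageVector("p0", profiles[0].counts)
    with pytest.raises(ValueError, match="duplicate"):
        build_distance_matrix([profiles[0], twin])


def test_identical_profiles_have_zero_offdiagonal():
    counts = np.full(61, 4)
    dm = build_distance_matrix(
        [CodonUsageVector("a", counts), CodonUsageVector("b", counts)]
    )
    assert dm["a", "b"] == 0.0


def test_homogeneity_check_groups_contigs_with_their_species(rng):
    """Queries sampled deeply from one species re-cluster into one group."""
    base_p = [np.random.default_rng(100 + i).dirichlet(np.full(61, 2.0)) for i in range(6)]
    bases = [
        CodonUsageVector(f"base{i}", np.random.default_rng(200 + i).multinomial(8000, p))
        for i, p in enumerate(base_p)
    ]
    queries = [
        CodonUsageVector(f"ctg{i}", np.random.default_rng(300 + i).multinomial(20000, base_p[0]))
        for i in range(4)
    ]
    rep = homogeneity_check(bases, queries, threshold=0.04)
    assert rep.queries_in_single_group
    assert rep.min_cross_distance < 0.04  # contigs sit inside their species group


def test_homogeneity_check_rejects_id_collisions():
    a = CodonUsageVector("x", np.full(61, 3))
    b = CodonUsageVector("x", np.full(61, 4))
    with pytest.raises(ValueError, match="collision"):
        homogeneity_check([a], [b])


def test_singleton_query_far_from_everything_stays_singleton():
    rng = np.random.default_rng(9)
    bases = [CodonUsageVector(f"b{i}", rng.multinomial(9000, rng.dirichlet(np.full(61, 1.0)))) for i in range(4)]
    lone = CodonUsageVector("lone", np.eye(61, dtype=int)[0] * 1000)
    rep = homogeneity_check(bases, [lone], threshold=0.04)
    assert rep.grouping.group_sizes[rep.grouping.assignment["lone"]] == 1


class TestClusterer:
    def test_fit_exposes_sklearn_attributes(self, small_profiles):
        est = CodonUsageClusterer(threshold=0.04).fit(small_profiles)
        assert est.labels_.shape == (len(small_profiles),)
        assert est.n_groups_ == len(set(est.labels_) - {-1})
        assert est.get_params()["threshold"] == 0.04

    def test_shallow_clones_reported_unclustered(self, small_profiles):
        tiny = CodonUsageVector("tiny", np.eye(61, dtype=int)[0] * 10)
        est = CodonUsageClusterer(min_internal_codons=100).fit(small_profiles + [tiny])
        assert est.grouping_.unclustered == ("tiny",)
        assert est.labels_[-1] == -1
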