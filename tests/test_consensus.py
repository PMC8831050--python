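import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from updrs.consensus import (ClusterEnsemble, Partition, align_labels,
                             build_coassociation, build_hypergraph,
                             cspa_partition, hgpa_partition, majority_vote)
from updrs.evaluate import adjusted_rand_index

from conftest import random_ensemble


def brute_force_coassociation(ensemble):
    n = ensemble.n_rows
    S = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            S[i, j] = np.mean([p.labels[i] == p.labels[j] for p in ensemble.partitions])
    return S


def exhaustive_min_cut(hypergraph, lo, hi):
    """Minimum hyperedge cut over all bipartitions within size bounds."""
    n = hypergraph.n_vertices
    best = np.inf
    for size in range(lo, hi + 1):
        if not lo <= n - size <= hi:
            continue
        for left in itertools.combinations(range(n), size):
            if 0 not in left:  # fix vertex 0 on the left: halves the search
                continue
            left_set = set(left)
            cut = sum(
                1 for e in hypergraph.hyperedges
                if any(v in left_set for v in e) and any(v not in left_set for v in e)
            )
            best = min(best, cut)
    return best


class TestCoassociation:
    def test_unanimous_ensemble_gives_binary_matrix(self):
        p = Partition(np.array([0, 0, 1, 1]), 2, "p")
        ens = ClusterEnsemble([p, p, p])
        S = build_coassociation(ens)
        expected = (p.labels[:, None] == p.labels[None, :]).astype(float)
        np.testing.assert_array_equal(S, expected)

    def test_half_agreement_pairs(self):
        ens = ClusterEnsemble([
            Partition(np.array([0, 0, 1, 1]), 2, "AABB"),
            Partition(np.array([0, 1, 0, 1]), 2, "ABAB"),
        ])
        S = build_coassociation(ens)
        assert S[0, 1] == 0.5
        assert S[0, 2] == 0.5
        assert S[0, 3] == 0.0
        assert S[2, 3] == 0.5
        np.testing.assert_array_equal(S.diagonal(), 1.0)

    def test_matches_brute_force_on_random_ensembles(self, rng):
        for _ in range(100):
            ens = random_ensemble(rng, n_rows=int(rng.integers(3, 11)),
                                  n_partitions=int(rng.integers(2, 6)))
            np.testing.assert_array_equal(build_coassociation(ens),
                                          brute_force_coassociation(ens))


class TestCspa:
    def test_recovers_unanimous_partition(self):
        p = Partition(np.array([0, 0, 0, 1, 1, 2, 2, 2]), 3, "p")
        ens = ClusterEnsemble([p, p, p])
        out = cspa_partition(build_coassociation(ens), target_k=3)
        assert adjusted_rand_index(out, p) == pytest.approx(1.0)

    def test_two_perfect_blocks(self):
        S = np.zeros((6, 6))
        S[:3, :3] = 1.0
        S[3:, 3:] = 1.0
        out = cspa_partition(S, target_k=2)
        assert len(set(out.labels[:3])) == 1
        assert len(set(out.labels[3:])) == 1
        assert out.labels[0] != out.labels[3]

    def test_outvotes_noisy_minority_member(self, rng):
        majority = Partition(np.repeat([0, 1], 4), 2, "maj")
        noisy = Partition(rng.integers(0, 2, 8), 2, "noise")
        ens = ClusterEnsemble([majority, majority, majority, noisy])
        out = cspa_partition(build_coassociation(ens), target_k=2)
        ari_out = adjusted_rand_index(out, majority)
        ari_noisy = adjusted_rand_index(noisy, majority)
        assert ari_out >= ari_noisy

    def test_target_k_out_of_range(self):
        with pytest.raises(ValueError):
            cspa_partition(np.eye(4), target_k=5)


class TestHypergraph:
    def test_edge_count_and_membership(self):
        ens = ClusterEnsemble([
            Partition(np.array([0, 0, 1, 1, 2, 2]), 3, "a"),
            Partition(np.array([0, 1, 1, 2, 2, 0]), 3, "b"),
        ])
        H = build_hypergraph(ens)
        assert len(H.hyperedges) == 6
        assert [set(e) for e in H.hyperedges[:3]] == [{0, 1}, {2, 3}, {4, 5}]

    def test_partition_edges_cover_rows_disjointly(self, rng):
        ens = random_ensemble(rng, n_rows=12, n_partitions=3)
        H = build_hypergraph(ens)
        # each partition contributes consecutive edges covering all rows
        start = 0
        for part in ens.partitions:
            n_edges = len([c for c in part.clusters() if len(c)])
            covered = np.concatenate(H.hyperedges[start:start + n_edges])
            assert sorted(covered) == list(range(12))
            start += n_edges

    def test_empty_clusters_dropped(self):
        ens = ClusterEnsemble([
            Partition(np.array([0, 0, 2, 2]), 4, "sparse"),  # clusters 1, 3 empty
            Partition(np.array([0, 1, 0, 1]), 2, "b"),
        ])
        H = build_hypergraph(ens)
        assert len(H.hyperedges) == 4


class TestHgpa:
    def test_zero_cut_optimum_recovered(self):
        p = Partition(np.array([0, 0, 0, 1, 1, 1]), 2, "p")
        ens = ClusterEnsemble([p, p, p])
        out = hgpa_partition(build_hypergraph(ens), target_k=2, seed=0)
        assert adjusted_rand_index(out, p) == pytest.approx(1.0)

    def test_cut_never_beats_exhaustive_minimum(self, rng):
        for trial in range(10):
            n = int(rng.integers(6, 13))
            ens = random_ensemble(rng, n_rows=n, n_partitions=int(rng.integers(2, 5)))
            H = build_hypergraph(ens)
            tol = 0.2
            lo = max(int(np.floor((1 - tol) * n / 2)), 1)
            hi = int(np.ceil((1 + tol) * n / 2))
            out = hgpa_partition(H, target_k=2, imbalance_tolerance=tol,
                                 n_restarts=20, seed=trial)
            left = set(np.flatnonzero(out.labels == out.labels[0]).tolist())
            cut = sum(1 for e in H.hyperedges
                      if any(v in left for v in e) and any(v not in left for v in e))
            assert cut >= exhaustive_min_cut(H, lo, hi)

    def test_balance_constraint_respected(self, rng):
        ens = random_ensemble(rng, n_rows=30, n_partitions=3)
        out = hgpa_partition(build_hypergraph(ens), target_k=3,
                             imbalance_tolerance=0.2, seed=1)
        sizes = np.bincount(out.labels, minlength=3)
        assert sizes.min() >= np.floor(0.8 * 10)
        assert sizes.max() <= np.ceil(1.2 * 10)

    def test_infeasible_target_k_rejected(self):
        p = Partition(np.array([0, 0, 1]), 2, "p")
        ens = ClusterEnsemble([p, p])
        # more parts than vertices: every part needs at least one vertex
        with pytest.raises(ValueError, match="infeasible"):
            hgpa_partition(build_hypergraph(ens), target_k=4, imbalance_tolerance=0.0)

    def test_deterministic_given_seed(self, rng):
        ens = random_ensemble(rng, n_rows=20, n_partitions=3)
        H = build_hypergraph(ens)
        a = hgpa_partition(H, target_k=2, seed=3)
        b = hgpa_partition(H, target_k=2, seed=3)
        np.testing.assert_array_equal(a.labels, b.labels)


class TestAlignLabels:
    def test_permutation_inverse_recovered(self):
        ref = Partition(np.array([0, 0, 1, 1, 2, 2]), 3, "ref")
        perm = Partition(np.array([2, 2, 0, 0, 1, 1]), 3, "perm")
        out = align_labels(ref, perm)
        np.testing.assert_array_equal(out.labels, ref.labels)

    def test_self_alignment_is_identity(self, rng):
        labels = rng.integers(0, 3, 15)
        p = Partition(labels, 3, "p")
        np.testing.assert_array_equal(align_labels(p, p).labels, labels)

    def test_one_disagreement_against_exhaustive_search(self):
        ref = Partition(np.array([0, 0, 0, 1, 1]), 2, "ref")
        other = Partition(np.array([1, 1, 1, 0, 1]), 2, "other")
        aligned = align_labels(ref, other)
        overlap = (aligned.labels == ref.labels).sum()
        best = max(
            (np.array([m[l] for l in other.labels]) == ref.labels).sum()
            for m in ({0: 0, 1: 1}, {0: 1, 1: 0})
        )
        assert overlap == best == 4

    def test_surplus_clusters_get_fresh_labels(self):
        ref = Partition(np.array([0, 0, 1, 1]), 2, "ref")
        other = Partition(np.array([0, 1, 2, 2]), 3, "other")
        aligned = align_labels(ref, other)
        assert set(aligned.labels) <= {0, 1, 2}
        assert aligned.k >= 3


class TestMajorityVote:
    def test_two_against_one_worked_example(self):
        """Four patients, three clusterers; the first patient is put in
        cluster A by two algorithms and cluster B by the third, so the
        majority assigns it cluster A."""
        A, B = 0, 1
        alg1 = Partition(np.array([A, A, B, B]), 2, "alg1")
        alg2 = Partition(np.array([A, B, A, B]), 2, "alg2")
        alg3 = Partition(np.array([B, B, A, B]), 2, "alg3")
        out = majority_vote(ClusterEnsemble([alg1, alg2, alg3]))
        assert out.labels[0] == A

    def test_unanimity_returns_the_partition(self):
        p = Partition(np.array([0, 1, 2, 0, 1, 2]), 3, "p")
        out = majority_vote(ClusterEnsemble([p, p, p]))
        np.testing.assert_array_equal(out.labels, p.labels)

    def test_matches_per_row_tally_oracle(self):
        """Three partitions of 12 rows, each dissenting on one distinct
        row: the 2-vote majority must win on every row (label alignment
        is the identity because the partitions agree on 11/12 rows)."""
        base = np.repeat([0, 1], 6)
        parts = []
        for b in range(3):
            labels = base.copy()
            labels[4 * b] = 1 - labels[4 * b]
            parts.append(Partition(labels, 2, f"p{b}"))
        out = majority_vote(ClusterEnsemble(parts))
        stacked = np.stack([p.labels for p in parts])
        expected = np.array([np.bincount(stacked[:, i], minlength=2).argmax()
                             for i in range(12)])
        # consensus labels are meaningful up to renaming only
        assert adjusted_rand_index(out, Partition(expected, 2, "tally")) == pytest.approx(1.0)


class TestConsensusInvariants:
    @pytest.mark.parametrize("method", ["voting", "cspa", "hgpa"])
    def test_consensus_of_identical_partitions_is_that_partition(self, method):
        p = Partition(np.array([0, 0, 0, 1, 1, 1, 2, 2, 2]), 3, "p")
        ens = ClusterEnsemble([p, p, p, p], target_k=3)
        out = _run(method, ens)
        assert adjusted_rand_index(out, p) == pytest.approx(1.0)

    @pytest.mark.parametrize("method", ["voting", "cspa", "hgpa"])
    def test_label_permutation_invariance(self, rng, method):
        for _ in range(15):
            ens = random_ensemble(rng, n_rows=12, n_partitions=3)
            out1 = _run(method, ens)
            permuted = []
            for p in ens.partitions:
                perm = rng.permutation(p.k)
                permuted.append(Partition(perm[p.labels], p.k, p.source))
            out2 = _run(method, ClusterEnsemble(permuted, target_k=ens.target_k))
            assert adjusted_rand_index(out1, out2) == pytest.approx(1.0)

    def test_single_partition_ensemble_rejected(self):
        p = Partition(np.array([0, 1]), 2, "p")
        with pytest.raises(ValueError):
            ClusterEnsemble([p])

    def test_mismatched_row_sets_rejected(self):
        with pytest.raises(ValueError):
            ClusterEnsemble([Partition(np.array([0, 1]), 2, "a"),
                             Partition(np.array([0, 1, 0]), 2, "b")])

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_default_target_k_is_median_member_k(self, seed):
        rng = np.random.default_rng(seed)
        ks = rng.integers(2, 6, size=3)
        parts = [Partition(rng.integers(0, k, 10), int(k), "p") for k in ks]
        ens = ClusterEnsemble(parts)
        assert ens.target_k == int(np.median(ks))


def _run(method, ens):
    if method == "voting":
        return majority_vote(ens)
    if method == "cspa":
        return cspa_partition(build_coassociation(ens), ens.target_k, seed=0)
    return hgpa_partition(build_hypergraph(ens), ens.target_k, seed=0)
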