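"""Multilayer modularity, generalized Louvain, entropy, and partition selection."""

import numpy as np
import pytest

from fcsubspace.community import (
    MultiSubjectLouvain,
    MultiSubjectPartition,
    build_multilayer_modularity,
    community_sizes,
    louvain_maximize,
    match_partitions,
    modularity_value,
    normalized_entropy,
    select_optimal_partition,
    sweep_parameter_space,
)
from fcsubspace.connectivity import pearson_fc
from fcsubspace.synthetic import CohortParams, generate_cohort

from oracles import exhaustive_max_modularity


def _random_layers(rng, r, s, lo=-0.5, hi=1.0):
    layers = []
    for _ in range(s):
        w = rng.uniform(lo, hi, (r, r))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 1.0)
        layers.append(w)
    return layers


class TestStructure:
    def test_hand_written_supra_matrix_r2_s2(self):
        w1 = np.array([[1.0, 0.4], [0.4, 1.0]])
        w2 = np.array([[1.0, -0.2], [-0.2, 1.0]])
        st = build_multilayer_modularity([w1, w2], gamma=0.1, omega=0.3)
        expected = np.array(
            [
                [0.0, 0.3, 0.3, 0.0],
                [0.3, 0.0, 0.0, 0.3],
                [0.3, 0.0, 0.0, -0.3],
                [0.0, 0.3, -0.3, 0.0],
            ]
        )
        # hand layout: unit order (layer0 node0, layer0 node1, layer1 node0, layer1 node1)
        hand = np.zeros((4, 4))
        hand[0, 1] = hand[1, 0] = 0.4 - 0.1
        hand[2, 3] = hand[3, 2] = -0.2 - 0.1
        hand[0, 2] = hand[2, 0] = hand[1, 3] = hand[3, 1] = 0.3
        np.testing.assert_allclose(st.to_sparse().toarray(), hand, atol=1e-12)
        del expected

    def test_gamma_equal_to_offdiagonal_zeroes_intra(self):
        w = np.full((3, 3), 0.25)
        np.fill_diagonal(w, 1.0)
        st = build_multilayer_modularity([w], gamma=0.25, omega=0.0)
        np.testing.assert_allclose(st.intra(0), 0.0, atol=1e-15)

    def test_zero_coupling_block_diagonal(self):
        rng = np.random.default_rng(0)
        layers = _random_layers(rng, 4, 3)
        st = build_multilayer_modularity(layers, gamma=0.2, omega=0.0)
        a = st.to_sparse().toarray()
        for s in range(3):
            for t in range(3):
                if s != t:
                    assert np.all(a[4 * s : 4 * s + 4, 4 * t : 4 * t + 4] == 0)

    def test_asymmetric_layer_rejected(self):
        w = np.array([[1.0, 0.5], [0.2, 1.0]])
        with pytest.raises(ValueError):
            build_multilayer_modularity([w], 0.0, 0.0)


class TestModularityValue:
    def test_all_singletons_zero(self):
        rng = np.random.default_rng(1)
        st = build_multilayer_modularity(_random_layers(rng, 4, 2), 0.1, 0.2)
        labels = np.arange(8).reshape(4, 2)
        assert modularity_value(labels, st) == pytest.approx(0.0)

    def test_all_in_one_hand_sum(self):
        w1 = np.array([[1.0, 0.4], [0.4, 1.0]])
        w2 = np.array([[1.0, -0.2], [-0.2, 1.0]])
        st = build_multilayer_modularity([w1, w2], gamma=0.1, omega=0.3)
        labels = np.zeros((2, 2), dtype=int)
        # intra: 2*(0.4-0.1) + 2*(-0.2-0.1); inter: 2*0.3 per node over 1 layer pair
        hand = 2 * 0.3 + 2 * (-0.3) + 2 * 0.3 * 2
        assert modularity_value(labels, st) == pytest.approx(hand)

    def test_omega_increase_raises_q_with_cross_layer_agreement(self):
        rng = np.random.default_rng(2)
        layers = _random_layers(rng, 4, 3)
        labels = np.tile(np.array([[0], [0], [1], [1]]), (1, 3))
        q1 = modularity_value(labels, build_multilayer_modularity(layers, 0.1, 0.2))
        q2 = modularity_value(labels, build_multilayer_modularity(layers, 0.1, 0.5))
        assert q2 > q1


class TestLouvain:
    def test_two_cliques_recovered_across_layers(self):
        w = np.zeros((6, 6))
        w[:3, :3] = 0.9
        w[3:, 3:] = 0.9
        np.fill_diagonal(w, 1.0)
        st = build_multilayer_modularity([w, w], gamma=0.1, omega=0.1)
        part = louvain_maximize(st, n_restarts=5, seed=0)
        assert part.community_count == 2
        for j in range(2):
            assert len(set(part.labels[:3, j])) == 1
            assert len(set(part.labels[3:, j])) == 1
        np.testing.assert_array_equal(part.labels[:, 0], part.labels[:, 1])

    @pytest.mark.parametrize("r, s, seed", [(3, 3, 10), (5, 2, 11), (3, 3, 12)])
    def test_matches_exhaustive_enumeration(self, r, s, seed):
        rng = np.random.default_rng(seed)
        layers = _random_layers(rng, r, s)
        st = build_multilayer_modularity(
            layers, gamma=float(rng.uniform(-0.2, 0.5)), omega=float(rng.uniform(0, 0.5))
        )
        part = louvain_maximize(st, n_restarts=30, seed=seed)
        oracle = exhaustive_max_modularity(st.to_sparse().toarray())
        assert part.Q == pytest.approx(oracle, abs=1e-9)

    def test_resolution_sweep_counts_nondecreasing(self):
        rng = np.random.default_rng(3)
        layers = _random_layers(rng, 6, 2, lo=-0.3)
        counts = [
            louvain_maximize(build_multilayer_modularity(layers, g, 0.2), 10, 3).community_count
            for g in (-0.5, -0.1, 0.3, 0.6, 0.9)
        ]
        assert counts == sorted(counts)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(4)
        layers = _random_layers(rng, 8, 3)
        st = build_multilayer_modularity(layers, 0.2, 0.1)
        p1 = louvain_maximize(st, 5, 42)
        p2 = louvain_maximize(st, 5, 42)
        np.testing.assert_array_equal(p1.labels, p2.labels)
        assert p1.Q == p2.Q

    def test_large_omega_forces_agreement_small_omega_decouples(self):
        rng = np.random.default_rng(5)
        layers = _random_layers(rng, 8, 4)
        strong = louvain_maximize(build_multilayer_modularity(layers, 0.2, 50.0), 5, 0)
        assert strong.averaged_entropy == pytest.approx(0.0, abs=1e-12)
        # at omega=0 each layer solves its own single-layer problem
        decoupled = louvain_maximize(build_multilayer_modularity(layers, 0.2, 0.0), 10, 0)
        for j, w in enumerate(layers):
            solo = louvain_maximize(build_multilayer_modularity([w], 0.2, 0.0), 10, j)
            assert modularity_value(decoupled.labels[:, j : j + 1], build_multilayer_modularity([w], 0.2, 0.0)) == pytest.approx(solo.Q, abs=1e-9)

    def test_estimator_front_end(self):
        rng = np.random.default_rng(6)
        layers = _random_layers(rng, 6, 3)
        est = MultiSubjectLouvain(gamma=0.2, omega=0.1, n_restarts=3, random_state=1).fit(layers)
        assert est.labels_.shape == (6, 3)
        assert np.isfinite(est.Q_)
        assert 0 <= est.averaged_entropy_ <= 1


class TestEntropy:
    def test_identical_labels_zero(self):
        labels = np.tile(np.array([[0], [1], [1], [2]]), (1, 5))
        h, avg = normalized_entropy(labels)
        np.testing.assert_allclose(h, 0.0)
        assert avg == 0.0

    def test_even_split_maximal(self):
        # S=4 subjects, node split evenly over the K=2 communities present
        labels = np.array([[0, 0, 1, 1], [0, 1, 0, 1]])
        h, _ = normalized_entropy(labels)
        assert h[0] == pytest.approx(1.0)
        assert h[1] == pytest.approx(1.0)

    def test_bounds_always_hold(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            labels = rng.integers(0, 5, (12, 6))
            h, avg = normalized_entropy(labels)
            assert np.all(h >= 0) and np.all(h <= 1)
            assert avg == pytest.approx(h.mean())


@pytest.fixture()
def layers():
    rng = np.random.default_rng(8)
    return _random_layers(rng, 8, 3)


class TestSweepAndSelection:
    def test_bookkeeping_and_mane(self, layers):
        sweep = sweep_parameter_space(layers, n_samples=10, seed=1)
        assert len(sweep.samples) == 10
        assert sweep.mane == pytest.approx(
            np.mean([s["averaged_entropy"] for s in sweep.samples])
        )

    def test_deterministic(self, layers):
        s1 = sweep_parameter_space(layers, n_samples=12, seed=5)
        s2 = sweep_parameter_space(layers, n_samples=12, seed=5)
        assert [a["gamma"] for a in s1.samples] == [a["gamma"] for a in s2.samples]
        assert s1.mane == s2.mane

    def test_collapsed_ranges(self, layers):
        sweep = sweep_parameter_space(
            layers, n_samples=10, gamma_range=(0.3, 0.3), omega_range=(0.1, 0.1), seed=2
        )
        assert all(s["gamma"] == 0.3 and s["omega"] == 0.1 for s in sweep.samples)

    def _partition(self, gamma, omega, entropy, count=4, q=1.0, singleton=False):
        labels = np.tile(np.arange(count).repeat(2)[:, None], (1, 3))
        part = MultiSubjectPartition(
            labels=labels, gamma=gamma, omega=omega, Q=q,
            node_entropy=np.full(labels.shape[0], entropy),
            averaged_entropy=entropy, community_count=count,
        )
        return {
            "gamma": gamma, "omega": omega, "averaged_entropy": entropy,
            "community_count": count, "has_singleton": singleton, "partition": part,
        }

    def test_minimum_gamma_preferred(self):
        from fcsubspace.community import SweepResult

        sweep = SweepResult(
            samples=[self._partition(0.3, 0.5, 0.10), self._partition(0.1, 0.5, 0.10)],
            mane=0.10,
        )
        assert select_optimal_partition(sweep, 0.02, None).gamma == 0.1

    def test_maximum_omega_breaks_gamma_ties(self):
        from fcsubspace.community import SweepResult

        sweep = SweepResult(
            samples=[self._partition(0.1, 0.5, 0.10), self._partition(0.1, 1.5, 0.10)],
            mane=0.10,
        )
        assert select_optimal_partition(sweep, 0.02, None).omega == 1.5

    def test_singletons_and_entropy_window_filtered(self):
        from fcsubspace.community import SweepResult

        good = self._partition(0.5, 0.5, 0.10)
        singleton = self._partition(0.1, 0.5, 0.10, singleton=True)
        far = self._partition(0.05, 0.5, 0.50)
        sweep = SweepResult(samples=[good, singleton, far], mane=0.10)
        assert select_optimal_partition(sweep, 0.02, None).gamma == 0.5

    def test_empty_candidates_raise(self):
        from fcsubspace.community import SweepResult

        sweep = SweepResult(samples=[self._partition(0.1, 0.5, 0.5)], mane=0.0)
        with pytest.raises(ValueError, match="tolerance"):
            select_optimal_partition(sweep, 0.02, None)


class TestSizesAndMatching:
    def test_sizes_rows_sum_to_r(self):
        labels = np.array([[0, 0], [0, 1], [1, 1], [1, 0], [2, 2], [2, 2]])
        sizes = community_sizes(labels)
        assert sizes.shape == (2, 3)
        np.testing.assert_array_equal(sizes.sum(axis=1), [6, 6])
        np.testing.assert_array_equal(sizes[0], [2, 2, 2])

    def test_identical_labels_identical_rows(self):
        labels = np.tile(np.array([[0], [0], [0], [1], [1], [1]]), (1, 4))
        sizes = community_sizes(labels)
        assert np.all(sizes == sizes[0])
        np.testing.assert_array_equal(sizes[0], [3, 3])

    def test_relabeled_partition_perfect_match(self):
        # each node has a strict modal label so the consensus is unambiguous
        rng = np.random.default_rng(9)
        base = rng.integers(0, 4, 20)
        labels = np.tile(base[:, None], (1, 5))
        flip = rng.random((20, 5)) < 0.15
        labels[flip] = (labels[flip] + 1) % 4
        relabeled = (labels + 2) % 4
        res = match_partitions(labels, relabeled)
        assert res["ari"] == pytest.approx(1.0)
        assert res["matched_fraction"] == pytest.approx(1.0)

    def test_independent_labels_near_zero_ari(self):
        rng = np.random.default_rng(10)
        res = match_partitions(rng.integers(0, 5, 100), rng.integers(0, 5, 100))
        assert abs(res["ari"]) < 0.1

    def test_merged_community_reported(self):
        base = np.repeat([0, 1, 2], 4)
        merged = np.repeat([0, 0, 1], 4)  # communities 0 and 1 merged
        res = match_partitions(base, merged)
        mapped = set(res["mapping"].values())
        assert len(res["mapping"]) == 2  # only two labels available on the right
        assert mapped == {0, 1}


class TestRecoveryOnGenerator:
    def test_selected_partition_recovers_base_communities(self):
        params = CohortParams(
            n_rois=24, n_timepoints=240, n_subjects_per_group=(10, 10), n_communities=4,
            common_strength=0.0, intra_community_corr=0.6, node_reassign_prob=0.1, seed=34,
        )
        cohort_a, _, truth = generate_cohort(params)
        fcs = [pearson_fc(s.values).values for s in cohort_a.subjects]
        # restricted (gamma, omega) subset sized for this toy cohort
        sweep = sweep_parameter_space(
            fcs, n_samples=300, gamma_range=(0.1, 0.7), omega_range=(0.0, 0.5), seed=7
        )
        part = select_optimal_partition(sweep, 0.02, (4, 12))
        res = match_partitions(part.labels, truth.base_partition["A"])
        assert res["ari"] >= 0.8
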