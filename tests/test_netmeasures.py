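"""Signed modularity, participation coefficients, fluctuation magnitudes.

Q* and the Louvain maximizer are checked against an independent
direct-summation oracle and exhaustive enumeration of all set partitions
on networks of up to 8 nodes.
"""

import numpy as np
import pytest

from conftest import qstar_reference, set_partitions, two_cliques
from segint.netmeasures import (fluctuation_magnitude, louvain_qstar,
                                measure_series, participation, qstar,
                                temporal_participation)


def random_signed(n, seed, p_neg=0.3):
    rng = np.random.default_rng(seed)
    w = rng.normal(size=(n, n))
    w[rng.random((n, n)) < p_neg] *= -1
    w = (w + w.T) / 2
    np.fill_diagonal(w, 0.0)
    return w


class TestQstar:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_direct_summation_oracle(self, seed):
        w = random_signed(6, seed)
        rng = np.random.default_rng(seed + 50)
        labels = rng.integers(0, 3, size=6)
        assert np.isclose(qstar(w, labels), qstar_reference(w, labels),
                          atol=1e-12)

    def test_two_clique_graph_against_oracle(self):
        w, labels = two_cliques()
        assert np.isclose(qstar(w, labels), qstar_reference(w, labels),
                          atol=1e-12)

    def test_single_community_partition_scores_zero(self):
        for seed in range(3):
            w = random_signed(7, seed)
            assert abs(qstar(w, np.zeros(7, int))) < 1e-12

    def test_sign_flip_exchanges_terms(self):
        """For -w the positive/negative parts swap; check numerically
        against the oracle rather than against w's value."""
        w = random_signed(6, 3)
        labels = np.array([0, 0, 1, 1, 2, 2])
        assert np.isclose(qstar(-w, labels), qstar_reference(-w, labels),
                          atol=1e-12)

    def test_gamma_scales_null_terms_only(self):
        w = np.abs(random_signed(6, 4))
        np.fill_diagonal(w, 0.0)
        labels = np.array([0, 0, 0, 1, 1, 1])
        vp = w.sum()
        sp = w.sum(axis=1)
        same = labels[:, None] == labels[None, :]
        for gamma in (0.5, 1.0, 2.0):
            expected = (w[same].sum()
                        - gamma * np.outer(sp, sp)[same].sum() / vp) / vp
            assert np.isclose(qstar(w, labels, gamma=gamma), expected,
                              atol=1e-12)

    def test_all_negative_rejected(self):
        w = -np.abs(random_signed(5, 0))
        np.fill_diagonal(w, 0.0)
        with pytest.raises(ValueError, match="positive"):
            qstar(w, np.zeros(5, int))


class TestLouvain:
    def exhaustive_best(self, w):
        best, best_labels = -np.inf, None
        for labels in set_partitions(w.shape[0]):
            q = qstar_reference(w, labels)
            if q > best:
                best, best_labels = q, labels
        return best, best_labels

    @pytest.mark.parametrize("seed", range(4))
    def test_reaches_exhaustive_optimum_on_small_networks(self, seed):
        w = random_signed(7, seed + 10)
        best, _ = self.exhaustive_best(w)
        _, q = louvain_qstar(w, n_restarts=100, seed=seed)
        assert q >= best - 1e-9

    def test_anticorrelated_blocks_recovered(self):
        w = np.full((8, 8), -0.5)
        w[:4, :4] = 1.0
        w[4:, 4:] = 1.0
        np.fill_diagonal(w, 0.0)
        labels, q = louvain_qstar(w, seed=0)
        assert len(np.unique(labels[:4])) == 1
        assert len(np.unique(labels[4:])) == 1
        assert labels[0] != labels[4]
        best, _ = self.exhaustive_best(w)
        assert q >= best - 1e-9

    def test_returned_q_is_consistent_with_qstar(self):
        w = random_signed(8, 2)
        labels, q = louvain_qstar(w, seed=1)
        assert np.isclose(q, qstar(w, labels), atol=1e-10)


class TestParticipation:
    def test_all_weight_in_own_community_gives_zero(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 2.0
        pc, _ = participation(w, np.array([0, 0, 1, 1]))
        assert pc[0] == 0.0

    def test_even_split_across_two_communities(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1.0
        w[0, 2] = w[2, 0] = 1.0
        pc, _ = participation(w, np.array([0, 1, 2]))
        assert np.isclose(pc[0], 0.5)

    def test_three_one_split(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 3.0
        w[0, 2] = w[2, 0] = 1.0
        pc, _ = participation(w, np.array([0, 1, 2]))
        assert np.isclose(pc[0], 1 - (9 + 1) / 16)

    def test_zero_positive_strength_warns_and_scores_zero(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = -1.0
        w[1, 2] = w[2, 1] = 1.0
        with pytest.warns(RuntimeWarning, match="zero positive"):
            pc, _ = participation(w, np.zeros(3, int))
        assert pc[0] == 0.0

    def test_bounds(self):
        for seed in range(5):
            w = random_signed(10, seed)
            labels = np.random.default_rng(seed).integers(0, 4, 10)
            pc, mean = participation(w, labels)
            n_c = len(np.unique(labels))
            assert np.all(pc >= 0.0)
            assert np.all(pc <= 1 - 1 / n_c + 1e-12)
            assert np.isclose(mean, pc.mean())


class TestTemporalParticipation:
    def test_constant_partition_reduces_to_pc(self):
        mats = [random_signed(6, s) for s in range(4)]
        labels = np.array([0, 0, 1, 1, 2, 2])
        tpc, _ = temporal_participation(mats, [labels] * 4)
        for t, w in enumerate(mats):
            pc, _ = participation(w, labels)
            assert np.allclose(tpc[t], pc, atol=1e-12)

    def test_single_window_equals_pc(self):
        w = random_signed(5, 7)
        labels = np.array([0, 1, 0, 1, 0])
        tpc, _ = temporal_participation([w], [labels])
        pc, _ = participation(w, labels)
        assert np.allclose(tpc[0], pc, atol=1e-12)

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(0)
        mats = [random_signed(5, s + 20) for s in range(3)]
        parts = [rng.integers(0, 3, 5) for _ in range(3)]
        with np.testing.suppress_warnings() as sup:
            sup.filter(RuntimeWarning)
            tpc, mean_tpc = temporal_participation(mats, parts)
        T = 3
        for t in range(T):
            wp = np.where(mats[t] > 0, mats[t], 0.0)
            for i in range(5):
                kappa = wp[i].sum()
                if kappa == 0:
                    assert tpc[t, i] == 0.0
                    continue
                total = 0.0
                for u in range(T):
                    for c in np.unique(parts[u]):
                        k_ic = wp[i, parts[u] == c].sum()
                        total += (k_ic / kappa) ** 2
                assert np.isclose(tpc[t, i], 1 - total / T, atol=1e-12)
        assert np.allclose(mean_tpc, tpc.mean(axis=1))


class TestMeasureSeries:
    def test_series_lengths_match_window_count(self):
        mats = [random_signed(8, s) for s in range(5)]
        series = measure_series(mats, seed=0, n_restarts=10)
        assert len(series.mean_pc) == len(series.mean_tpc) \
            == len(series.qstar) == 5

    def test_frozen_fc_has_zero_fluctuation_with_fixed_seed(self):
        w = random_signed(8, 3)
        series = measure_series([w.copy() for _ in range(4)], seed=5,
                                n_restarts=20)
        mag = fluctuation_magnitude(series)
        assert mag.sd_mean_pc == 0.0
        assert mag.sd_qstar == 0.0

    def test_segregated_integrated_alternation_tracked_by_mean_pc(self):
        """Block-diagonal (segregated) vs uniform (integrated) windows."""
        seg = np.full((8, 8), -0.2)
        seg[:4, :4] = 1.0
        seg[4:, 4:] = 1.0
        np.fill_diagonal(seg, 0.0)
        # integrated: strong positive between-block ties, with a few
        # negative pairs anchoring the same two-community partition
        integ = np.full((8, 8), 0.9)
        integ[:4, :4] = 1.0
        integ[4:, 4:] = 1.0
        for i in range(4):
            integ[i, i + 4] = integ[i + 4, i] = -0.5
        np.fill_diagonal(integ, 0.0)
        mats = [seg, integ, seg, integ]
        series = measure_series(mats, seed=2, n_restarts=20)
        assert series.mean_pc[1] > series.mean_pc[0]
        assert series.mean_pc[3] > series.mean_pc[2]
        assert series.qstar[0] > series.qstar[1]


class TestFluctuationMagnitude:
    def test_constant_series_zero(self):
        mats = [random_signed(6, 1)] * 3
        series = measure_series(mats, seed=0, n_restarts=5)
        assert fluctuation_magnitude(series).sd_mean_pc == 0.0

    def test_binary_series_sample_sd(self):
        from segint.netmeasures import MeasureSeries
        s = MeasureSeries(mean_pc=np.array([0.0, 1.0]),
                          mean_tpc=np.array([0.0, 1.0]),
                          qstar=np.array([0.0, 2.0]), partitions=[])
        mag = fluctuation_magnitude(s)
        assert np.isclose(mag.sd_mean_pc, np.sqrt(0.5))
        assert np.isclose(mag.sd_qstar, np.sqrt(2.0))

    def test_scale_equivariance(self):
        from segint.netmeasures import MeasureSeries
        rng = np.random.default_rng(4)
        x = rng.random(10)
        a = 3.7
        s1 = MeasureSeries(x, x, x, [])
        s2 = MeasureSeries(a * x, a * x, a * x, [])
        assert np.isclose(fluctuation_magnitude(s2).sd_mean_pc,
                          a * fluctuation_magnitude(s1).sd_mean_pc)
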