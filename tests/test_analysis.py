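import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.linalg import subspace_angles

import robustbmi as rb
from robustbmi.analysis import (
    DirectionalCountTable,
    count_table_for_electrode,
    subspace_basis,
)


def _brute_force_mi(table):
    """Independent double-sum oracle: I = sum p log2 p/(px py)."""
    p = table / table.sum()
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mi = 0.0
    for j in range(p.shape[0]):
        for k in range(p.shape[1]):
            if p[j, k] > 0:
                mi += p[j, k] * np.log2(p[j, k] / (px[j] * py[k]))
    return mi


class TestDiscretize:
    @pytest.mark.parametrize("count,category", [
        (0, 0), (4, 4), (5, 5), (7, 5), (100, 5)])
    def test_five_plus_capping(self, count, category):
        assert rb.discretize_counts(np.array([count]))[0] == category

    def test_cap_is_250_hz_instantaneous_in_20ms(self):
        # 5 spikes / 0.020 s = 250 Hz: the category boundary expressed
        # as an instantaneous rate
        assert 5 / 0.020 == 250.0


class TestMutualInformation:
    def test_independence_gives_zero(self):
        table = DirectionalCountTable(np.full((4, 6), 10.0), 20.0)
        assert rb.mutual_information(table) == 0.0

    def test_deterministic_categories_give_log2_d_bits(self):
        # 4 directions, each emitting its own distinct category,
        # uniformly: H(Y)=2 bits, H(Y|X)=0
        table = np.zeros((4, 6))
        for j in range(4):
            table[j, j] = 25.0
        mi = rb.mutual_information(DirectionalCountTable(table, 20.0))
        assert np.isclose(mi, 2.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_brute_force_on_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        D = int(rng.integers(2, 5))
        table = rng.integers(0, 20, size=(D, 6)).astype(float)
        table[rng.integers(0, D), :] += 1  # ensure non-empty
        mi = rb.mutual_information(DirectionalCountTable(table, 20.0))
        assert abs(mi - _brute_force_mi(table)) < 1e-12
        assert mi <= np.log2(D) + 1e-12

    def test_empty_table_raises(self):
        with pytest.raises(ValueError):
            rb.mutual_information(
                DirectionalCountTable(np.zeros((3, 6)), 20.0))


class TestRanking:
    def test_dead_electrode_ranks_last(self, small_corpus):
        import dataclasses
        corpus, tuning = small_corpus
        # rebuild one day with electrode 0 silenced
        cond = rb.RecordingConditionSpec.identity(tuning.n_electrodes)
        eg = cond.electrode_gain.copy()
        eg[0] = 0.0
        cond = dataclasses.replace(cond, electrode_gain=eg)
        rng = np.random.default_rng(0)
        trials = []
        for tr in corpus.day_trials(0):
            spikes = rb.emit_counts(tr.kin, tuning, cond, rng)
            trials.append(dataclasses.replace(tr, spikes=spikes))
        ranking = rb.rank_electrodes(trials)
        last_electrode, last_mi = ranking[-1]
        assert last_electrode == 0
        assert last_mi == 0.0

    def test_strong_tuning_outranks_weak(self):
        # two-electrode population: strongly tuned vs untuned; the tuned
        # one must rank first in nearly all seeded corpora
        wins = 0
        for seed in range(40):
            tuning = rb.TuningModel(
                baseline_rate=np.array([15.0, 15.0]),
                modulation_depth=np.array([1.5, 0.0]),
                preferred_direction=np.array([[1.0, 0.0], [0.0, 1.0]]),
                position_gain=np.zeros(2))
            corpus, _ = rb.generate_corpus(
                1, 32, n_electrodes=2, seed=seed,
                drift=rb.DriftProcess.none(), tuning=tuning)
            ranking = rb.rank_electrodes(corpus.day_trials(0))
            wins += ranking[0][0] == 0
        assert wins >= 38

    def test_ranking_deterministic(self, small_corpus):
        corpus, _ = small_corpus
        trials = corpus.day_trials(0)
        assert rb.rank_electrodes(trials) == rb.rank_electrodes(trials)


class TestDropElectrodes:
    def test_identity_at_zero_and_total_at_e(self, small_corpus):
        corpus, _ = small_corpus
        counts = next(corpus.iter_trials()).spikes
        ranking = list(range(counts.n_electrodes))
        assert np.array_equal(
            rb.drop_electrodes(counts, ranking, 0).counts, counts.counts)
        assert rb.drop_electrodes(counts, ranking,
                                  counts.n_electrodes).counts.sum() == 0

    def test_exactly_k_rows_zeroed_and_idempotent(self, small_corpus):
        corpus, _ = small_corpus
        trials = corpus.day_trials(0)
        ranking = rb.rank_electrodes(trials)
        counts = trials[0].spikes
        k = 4
        once = rb.drop_electrodes(counts, ranking, k)
        twice = rb.drop_electrodes(once, ranking, k)
        dropped = {e for e, _ in ranking[:k]}
        for e in range(counts.n_electrodes):
            if e in dropped:
                assert once.counts[e].sum() == 0
            else:
                assert np.array_equal(once.counts[e], counts.counts[e])
        assert np.array_equal(once.counts, twice.counts)

    def test_k_out_of_range_raises(self, small_corpus):
        corpus, _ = small_corpus
        counts = next(corpus.iter_trials()).spikes
        with pytest.raises(ValueError):
            rb.drop_electrodes(counts, list(range(16)), 17)


class TestSubspaces:
    def test_recovers_planted_two_plane(self):
        rng = np.random.default_rng(0)
        E = 12
        basis = np.linalg.qr(rng.normal(size=(E, 2)))[0]
        latent = rng.normal(size=(2, 500))
        Y = basis @ latent
        sb = subspace_basis(Y, np.zeros(E), K=2)
        # projector difference vanishes when the span is recovered
        P_true = basis @ basis.T
        P_hat = sb.V @ sb.V.T
        assert np.abs(P_true - P_hat).max() < 1e-8
        assert np.all(np.diff(sb.eigenvalues) <= 1e-12)

    def test_basis_orthonormal(self, small_corpus):
        corpus, _ = small_corpus
        Y = np.concatenate(
            [t.spikes.counts for t in corpus.day_trials(0)],
            axis=1).astype(float)
        sb = subspace_basis(Y, Y.mean(axis=1), K=5)
        assert np.abs(sb.V.T @ sb.V - np.eye(5)).max() < 1e-10

    def test_angle_closed_forms(self):
        e = np.eye(4)
        b1 = rb.SubspaceBasis(e[:, :1], 0)
        b2 = rb.SubspaceBasis(e[:, 1:2], 1)
        assert np.isclose(rb.min_principal_angle(b1, b2), np.pi / 2)
        assert rb.min_principal_angle(b1, b1) == 0.0
        b12 = rb.SubspaceBasis(e[:, :2], 0)
        b23 = rb.SubspaceBasis(e[:, 1:3], 1)
        assert np.isclose(rb.min_principal_angle(b12, b23), 0.0,
                          atol=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_scipy_and_is_symmetric(self, seed):
        rng = np.random.default_rng(seed)
        E, K = 8, 3
        A = np.linalg.qr(rng.normal(size=(E, K)))[0]
        B = np.linalg.qr(rng.normal(size=(E, K)))[0]
        ba, bb = rb.SubspaceBasis(A, 0), rb.SubspaceBasis(B, 1)
        mine = rb.min_principal_angle(ba, bb)
        ref = subspace_angles(A, B).min()
        assert abs(mine - ref) < 1e-10
        assert abs(mine - rb.min_principal_angle(bb, ba)) < 1e-12
        assert 0.0 <= mine <= np.pi / 2 + 1e-12

    def test_zero_drift_days_match_split_half_angle(self):
        # without drift, the across-day angle is indistinguishable from a
        # within-day split-half angle
        corpus, _ = rb.generate_corpus(2, 60, n_electrodes=16, seed=4,
                                       drift=rb.DriftProcess.none())
        act = {d: np.concatenate([t.spikes.counts
                                  for t in corpus.day_trials(d)],
                                 axis=1).astype(float)
               for d in (0, 1)}
        means = (act[0].mean(axis=1) + act[1].mean(axis=1)) / 2
        across = rb.min_principal_angle(
            subspace_basis(act[0], means, K=4),
            subspace_basis(act[1], means, K=4))
        half = act[0].shape[1] // 2
        within = rb.min_principal_angle(
            subspace_basis(act[0][:, :half], means, K=4),
            subspace_basis(act[0][:, half:], means, K=4))
        assert abs(across - within) < max(3 * within, 0.1)


class TestBehavioralSimilarity:
    def test_self_similarity_is_one(self, small_corpus):
        corpus, _ = small_corpus
        trials = corpus.day_trials(0)
        assert np.isclose(rb.behavioral_similarity(trials, trials), 1.0)

    def test_concatenated_window_is_10400_ms(self, small_corpus):
        from robustbmi.analysis import _avg_velocity_traces
        corpus, _ = small_corpus
        traces, bin_width = _avg_velocity_traces(
            corpus.day_trials(0), 700.0, 600.0)
        assert traces.shape[1] * bin_width == 10_400.0

    def test_high_similarity_across_neural_drift(self, drifting_corpus):
        corpus, _ = drifting_corpus
        sim = rb.behavioral_similarity(corpus.day_trials(0),
                                       corpus.day_trials(4))
        assert sim > 0.97
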