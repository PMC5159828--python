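import dataclasses

import numpy as np
import pytest

import robustbmi as rb
from robustbmi.training import (
    TrainingSequence,
    _cg,
    batch_gradient,
    batch_loss,
    build_training_sequences,
    gauss_newton_vector_product,
)


@pytest.fixture(scope="module")
def norm():
    return rb.NormalizationSpec(position_scale=[10.0, 10.0],
                                velocity_scale=[25.0, 25.0])


@pytest.fixture(scope="module")
def tiny_sequence():
    rng = np.random.default_rng(12)
    return TrainingSequence(
        counts=rng.integers(0, 4, size=(3, 12)),
        targets=rng.normal(scale=0.3, size=(2, 12)),
        seed_end=4, day_index=0, start_trial=0)


class TestSequenceConstruction:
    def test_window_counts(self, small_corpus, norm):
        corpus, _ = small_corpus
        trials = corpus.day_trials(0)
        assert len(build_training_sequences(trials[:5], norm)) == 1
        assert len(build_training_sequences(trials[:9], norm)) == 5

    def test_too_few_trials_warns_and_returns_empty(self, small_corpus,
                                                    norm):
        corpus, _ = small_corpus
        with pytest.warns(UserWarning):
            out = build_training_sequences(corpus.day_trials(0)[:4], norm)
        assert out == []

    def test_every_trial_after_first_two_is_learned_from(self,
                                                         small_corpus,
                                                         norm):
        corpus, _ = small_corpus
        trials = corpus.day_trials(0)[:12]
        seqs = build_training_sequences(trials, norm)
        learned = set()
        for s in seqs:
            learned.update(range(s.start_trial + 2, s.start_trial + 5))
        assert learned == set(range(2, 12))

    def test_seed_and_learn_spans_partition_sequence(self, small_corpus,
                                                     norm):
        corpus, _ = small_corpus
        seqs = build_training_sequences(corpus.day_trials(0)[:6], norm)
        for s in seqs:
            lo, hi = s.learn_span
            assert lo == s.seed_end and hi == s.n_bins
            assert 0 < s.seed_end < s.n_bins


class TestPerturbCounts:
    def test_zero_sigma_is_identity(self, tiny_sequence):
        out = rb.perturb_counts(tiny_sequence.counts,
                                rb.PerturbationSpec.none(),
                                np.random.default_rng(0))
        assert np.array_equal(out, tiny_sequence.counts)

    def test_totals_bounded_and_nonnegative(self):
        rng = np.random.default_rng(1)
        counts = rng.integers(0, 3, size=(8, 60))
        totals = counts.sum(axis=1)
        spec = rb.PerturbationSpec(sigma_trial=0.2, sigma_electrode=0.8)
        for _ in range(50):
            out = rb.perturb_counts(counts, spec, rng)
            assert (out >= 0).all()
            assert np.all(out.sum(axis=1) <= 2 * totals)

    def test_zero_count_electrodes_untouched(self):
        counts = np.zeros((4, 30), dtype=int)
        counts[1, 5] = 3
        out = rb.perturb_counts(counts, rb.PerturbationSpec(0.5, 0.5),
                                np.random.default_rng(2))
        assert out[0].sum() == out[2].sum() == out[3].sum() == 0

    def test_mean_preservation_at_reference_sigmas(self):
        # sigma_trial 0.045, sigma_electrode 0.3: over many draws the
        # mean perturbed total stays within 2 SE of the true total
        rng = np.random.default_rng(3)
        counts = rng.integers(0, 3, size=(1, 200))
        n = counts.sum()
        spec = rb.PerturbationSpec(sigma_trial=0.045, sigma_electrode=0.3)
        draws = np.array([
            rb.perturb_counts(counts, spec, rng).sum()
            for _ in range(10_000)])
        se = draws.std() / np.sqrt(draws.size)
        assert abs(draws.mean() - n) < 2 * se


class TestLossAndGradient:
    def test_perfect_targets_give_zero_loss(self, tiny_mrnn,
                                            tiny_sequence):
        z = rb.run(tiny_mrnn, tiny_sequence.counts)
        seq = dataclasses.replace(tiny_sequence, targets=z)
        assert batch_loss(tiny_mrnn, [seq]) < 1e-24

    def test_fresh_net_loss_is_target_power(self, tiny_sequence):
        params = rb.init_mrnn(4, 4, 3, 2, rb.InitSpec(seed=0))
        loss = batch_loss(params, [tiny_sequence])
        t = tiny_sequence.targets[:, tiny_sequence.seed_end:]
        assert np.isclose(loss, (t ** 2).mean())

    def test_loss_ignores_seed_span_targets(self, tiny_mrnn,
                                            tiny_sequence):
        t2 = tiny_sequence.targets.copy()
        t2[:, :tiny_sequence.seed_end] = 99.0
        seq2 = dataclasses.replace(tiny_sequence, targets=t2)
        assert batch_loss(tiny_mrnn, [seq2]) \
            == batch_loss(tiny_mrnn, [tiny_sequence])

    def test_gradient_matches_finite_differences(self, tiny_mrnn,
                                                 tiny_sequence):
        g = batch_gradient(tiny_mrnn, [tiny_sequence])
        v0 = tiny_mrnn.to_vector()
        eps = 1e-6
        idx = np.random.default_rng(0).choice(v0.size, size=40,
                                              replace=False)
        fd = np.empty(idx.size)
        for j, i in enumerate(idx):
            vp, vm = v0.copy(), v0.copy()
            vp[i] += eps
            vm[i] -= eps
            fd[j] = (batch_loss(tiny_mrnn.with_vector(vp),
                                [tiny_sequence])
                     - batch_loss(tiny_mrnn.with_vector(vm),
                                  [tiny_sequence])) / (2 * eps)
        denom = max(np.abs(fd).max(), 1e-12)
        assert np.abs(g[idx] - fd).max() / denom < 1e-5

    def test_readout_gradient_closed_form(self, tiny_mrnn,
                                          tiny_sequence):
        # for the linear readout, dL/dW_o = (2/(M n)) sum_t e_t r_t^T
        from robustbmi.training import _Batch, _forward
        batch = _Batch([tiny_sequence])
        cache = _forward(tiny_mrnn, batch)
        e = 2.0 * (cache.Z - batch.targets) * batch.mask[None, :, :] \
            / (2 * batch.n_learn)
        expected = sum(e[:, t, :] @ cache.r[t + 1].T
                       for t in range(batch.mask.shape[0]))
        g = batch_gradient(tiny_mrnn, [tiny_sequence])
        N, F, E, M = tiny_mrnn.dims
        off = N * F + F * E + F * N + N
        gW = g[off:off + M * N].reshape(M, N)
        assert np.allclose(gW, expected, atol=1e-12)

    def test_zero_error_gives_zero_gradient(self, tiny_mrnn,
                                            tiny_sequence):
        z = rb.run(tiny_mrnn, tiny_sequence.counts)
        seq = dataclasses.replace(tiny_sequence, targets=z)
        assert np.abs(batch_gradient(tiny_mrnn, [seq])).max() < 1e-12


class TestGaussNewton:
    def test_zero_vector_maps_to_zero(self, tiny_mrnn, tiny_sequence):
        v = np.zeros(tiny_mrnn.n_params)
        assert np.all(gauss_newton_vector_product(
            tiny_mrnn, [tiny_sequence], v) == 0)

    def test_operator_symmetry(self, tiny_mrnn, tiny_sequence):
        rng = np.random.default_rng(7)
        v1 = rng.normal(size=tiny_mrnn.n_params)
        v2 = rng.normal(size=tiny_mrnn.n_params)
        Gv1 = gauss_newton_vector_product(tiny_mrnn, [tiny_sequence], v1)
        Gv2 = gauss_newton_vector_product(tiny_mrnn, [tiny_sequence], v2)
        lhs, rhs = v2 @ Gv1, v1 @ Gv2
        assert abs(lhs - rhs) / max(abs(lhs), 1e-12) < 1e-8

    def test_positive_semidefinite(self, tiny_mrnn, tiny_sequence):
        rng = np.random.default_rng(8)
        for _ in range(5):
            v = rng.normal(size=tiny_mrnn.n_params)
            Gv = gauss_newton_vector_product(tiny_mrnn, [tiny_sequence], v)
            assert v @ Gv >= -1e-10

    def test_large_damping_dominates(self, tiny_mrnn, tiny_sequence):
        rng = np.random.default_rng(9)
        v = rng.normal(size=tiny_mrnn.n_params)
        lam = 1e8
        out = gauss_newton_vector_product(tiny_mrnn, [tiny_sequence], v,
                                          lam=lam)
        assert np.allclose(out / lam, v, rtol=1e-4)

    def test_cg_solves_spd_system(self):
        rng = np.random.default_rng(10)
        A = rng.normal(size=(20, 20))
        A = A @ A.T + 0.5 * np.eye(20)
        b = rng.normal(size=20)
        x = _cg(lambda p: A @ p, b, max_iters=100, tol=1e-12)
        assert np.allclose(A @ x, b, atol=1e-6)


class TestHFTraining:
    def test_returned_snapshot_no_worse_than_init_and_loss_drops(
            self, small_corpus):
        corpus, _ = small_corpus
        cfg = rb.HFConfig(total_steps=12, max_cg_iters=8,
                          snapshot_interval=4, seed=0)
        params, snapshots, history = rb.hf_train(
            corpus, cfg, rb.PerturbationSpec.none(), "velocity",
            n_units=16)
        losses = {s: l for s, l, _ in snapshots}
        best = min(losses.values())
        assert best <= losses[0]
        # substantial optimization progress on a learnable corpus
        assert best < 0.5 * losses[0]
        assert all(np.isfinite(h["loss"]) for h in history)

    def test_minibatch_covers_every_training_day(self, drifting_corpus):
        corpus, _ = drifting_corpus
        cfg = rb.HFConfig(total_steps=3, max_cg_iters=4,
                          snapshot_interval=3, minibatch_fraction=0.05,
                          seed=1)
        _, _, history = rb.hf_train(corpus, cfg,
                                    rb.PerturbationSpec.none(),
                                    "velocity", n_units=8)
        from robustbmi.training import _sample_minibatch, \
            build_training_sequences
        norm = rb.fit_normalization(corpus)
        per_day = {d: build_training_sequences(t, norm, "velocity")
                   for d, t in corpus.days}
        rng = np.random.default_rng(0)
        batch = _sample_minibatch(per_day, 0.05, rng)
        assert {s.day_index for s in batch} == set(corpus.day_indices)

    def test_decoder_pair_differs_and_shares_normalization(
            self, small_corpus):
        corpus, _ = small_corpus
        cfg = rb.HFConfig(total_steps=4, max_cg_iters=4,
                          snapshot_interval=2, seed=3)
        pos, vel, norm = rb.train_decoder_pair(corpus, cfg,
                                               rb.PerturbationSpec.none(),
                                               n_units=12)
        assert pos.dims[3] == vel.dims[3] == 2
        assert not np.array_equal(pos.to_vector(), vel.to_vector())

    def test_warm_start_resumes_from_given_weights(self, small_corpus):
        corpus, _ = small_corpus
        cfg = rb.HFConfig(total_steps=3, max_cg_iters=4,
                          snapshot_interval=3, seed=4)
        first, _, _ = rb.hf_train(corpus, cfg, rb.PerturbationSpec.none(),
                                  "velocity", n_units=12)
        _, snaps, _ = rb.hf_train(corpus, cfg, rb.PerturbationSpec.none(),
                                  "velocity", init_params=first)
        # the step-0 snapshot carries the warm-start weights
        assert np.array_equal(snaps[0][2].to_vector(), first.to_vector())
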