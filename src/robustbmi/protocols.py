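"""The three robustness experiment protocols, run on synthetic corpora.

* ``protocol_training_size_sweep`` — offline: train velocity decoders on
  increasing numbers of days (added by looking further back in time) and
  measure held-out decode accuracy on a later test day.
* ``protocol_electrode_drop`` — closed loop: zero the k most informative
  electrodes (mutual-information ranking, no retraining) and compare a
  multiday augmented MRNN against a same-day FIT-KF.
* ``protocol_stale_training`` — closed loop: withhold a gap of recent
  days from training and compare the multiday MRNN against FIT Long
  (same pooled data), FIT Old (last pre-gap day) and FIT Sameday.

All protocols are deterministic given their seed and return tidy
DataFrames.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .analysis import drop_electrodes, rank_electrodes
from .datamodel import NormalizationSpec, SessionCorpus
from .kalman import KFParams, fit_fit_kf, kf_decode
from .mrnn import MRNNParams, run as mrnn_run
from .simulate import (
    FeedbackUserModel,
    KFCursorDecoder,
    MRNNCursorDecoder,
    TaskConfig,
    calibrate_output_gain,
    decode_accuracy_r2,
    run_block,
    targets_per_minute,
)
from .synthetic import TuningModel
from .training import (
    HFConfig,
    PerturbationSpec,
    SEED_TRIALS,
    hf_train,
    train_decoder_pair,
)

__all__ = [
    "offline_velocity_r2",
    "offline_kf_velocity_r2",
    "protocol_training_size_sweep",
    "protocol_electrode_drop",
    "protocol_stale_training",
]


def _concat_day(trials):
    counts = np.concatenate([t.spikes.counts for t in trials], axis=1)
    vel = np.concatenate([t.kin.velocity for t in trials], axis=1)
    pos = np.concatenate([t.kin.position for t in trials], axis=1)
    seed_bins = sum(t.n_bins for t in trials[:SEED_TRIALS])
    return counts, vel, pos, seed_bins


def offline_velocity_r2(velocity_params: MRNNParams,
                        norm: NormalizationSpec, trials) -> float:
    """Offline MRNN decode accuracy on a day's trials (beta = 1).

    Trials are concatenated in order and decoded in one pass; the first
    two trials seed the hidden state and are excluded from scoring.
    """
    trials = list(trials)
    counts, vel, _, seed_bins = _concat_day(trials)
    z = mrnn_run(velocity_params, counts)
    decoded = norm.denormalize_velocity(z)
    return decode_accuracy_r2(vel[:, seed_bins:], decoded[:, seed_bins:])


def offline_kf_velocity_r2(params: KFParams, trials) -> float:
    """Offline FIT-KF decode accuracy with true-position feedback."""
    from .datamodel import BinnedSpikeCounts

    trials = list(trials)
    counts, vel, pos, seed_bins = _concat_day(trials)
    decoded = kf_decode(
        params, BinnedSpikeCounts(counts, trials[0].spikes.bin_width),
        cursor_positions=pos)
    return decode_accuracy_r2(vel[:, seed_bins:],
                              decoded.velocity[:, seed_bins:])


def protocol_training_size_sweep(corpus: SessionCorpus,
                                 day_counts: Sequence[int],
                                 config: Optional[HFConfig] = None,
                                 perturb: Optional[PerturbationSpec] = None,
                                 n_units: int = 30,
                                 test_day: Optional[int] = None
                                 ) -> pd.DataFrame:
    """Held-out decode accuracy versus training-set size.

    For each n in ``day_counts`` a velocity MRNN is trained on the n days
    immediately preceding the test day (more data looks further back in
    time, so recency is not conflated with corpus size) and scored on the
    test day's trials, which never enter training.
    """
    days = corpus.day_indices
    test_day = days[-1] if test_day is None else test_day
    pre_days = [d for d in days if d < test_day]
    if not pre_days or max(day_counts) > len(pre_days):
        raise ValueError("not enough days before the test day")
    test_trials = corpus.day_trials(test_day)
    rows = []
    for n in day_counts:
        train = corpus.subset_days(pre_days[-n:])
        params, _, _ = hf_train(train, config, perturb, "velocity",
                                n_units=n_units)
        from .datamodel import fit_normalization
        norm = fit_normalization(train)
        r2 = offline_velocity_r2(params, norm, test_trials)
        rows.append({"n_train_days": n, "test_day": test_day, "r2": r2})
    return pd.DataFrame(rows)


@dataclass
class _ClosedLoopSetup:
    tuning: TuningModel
    user: FeedbackUserModel
    task: TaskConfig
    n_trials: int
    bin_width: float


def _default_setup(tuning: TuningModel, bin_width: float,
                   n_trials: int = 30) -> _ClosedLoopSetup:
    return _ClosedLoopSetup(tuning=tuning, user=FeedbackUserModel(),
                            task=TaskConfig(), n_trials=n_trials,
                            bin_width=bin_width)


def protocol_electrode_drop(corpus: SessionCorpus, tuning: TuningModel,
                            k_list: Sequence[int],
                            config: Optional[HFConfig] = None,
                            perturb: Optional[PerturbationSpec] = None,
                            n_units: int = 30,
                            n_trials: int = 30,
                            seed: int = 0) -> pd.DataFrame:
    """Closed-loop electrode-dropping comparison (no retraining).

    Emulates the original experimental regime: decoders face a recording
    condition continuous with their calibration data — the MRNN trained
    multiday through the final day, FIT Sameday calibrated from a fresh
    block of reaches under that same final-day condition — and the only
    challenge is the drop itself.  For each k the top-k electrodes by
    mutual information with reach direction are zeroed at the decoder
    input and one block is run per decoder.
    """
    from .synthetic import generate_day_trials

    days = corpus.day_indices
    test_day = days[-1]
    train_corpus = corpus
    condition = corpus.condition_truth[test_day]
    # fresh same-condition calibration/ranking block (a new session under
    # the stable final-day condition)
    cal_rng = np.random.default_rng((seed * 9176 + 17) % (2 ** 31))
    n_cal = len(corpus.day_trials(test_day))
    test_trials = generate_day_trials(
        tuning, condition, n_cal, cal_rng, bin_width=corpus.bin_width,
        day_index=test_day + 1)

    pos_p, vel_p, norm = train_decoder_pair(
        train_corpus, config, perturb, n_units=n_units)
    gain = calibrate_output_gain(
        vel_p, norm, train_corpus.day_trials(test_day))
    kf_params = fit_fit_kf(test_trials, dt=corpus.bin_width)
    ranking = rank_electrodes(test_trials)

    rows = []
    for k in k_list:
        dropped = [e for e, _ in ranking[:k]]
        for name in ("mrnn", "fit_sameday"):
            rng = np.random.default_rng(
                (seed * 1009 + k * 31 + (0 if name == "mrnn" else 1))
                % (2 ** 31))
            if name == "mrnn":
                dec = MRNNCursorDecoder(pos_p, vel_p, norm,
                                        output_gain=gain)
            else:
                dec = KFCursorDecoder(kf_params)
            setup = _default_setup(tuning, corpus.bin_width, n_trials)
            block = run_block(dec, setup.user, tuning, condition,
                              setup.task, setup.n_trials, rng,
                              bin_width=setup.bin_width,
                              dropped_electrodes=dropped)
            rows.append({
                "k_dropped": k, "decoder": name,
                "targets_per_min": targets_per_minute(block),
                "success_rate": float(np.mean(
                    [o.success for o in block.outcomes])),
                "failed": block.failed,
                "n_trials": len(block.outcomes),
            })
    return pd.DataFrame(rows)


def protocol_stale_training(corpus: SessionCorpus, tuning: TuningModel,
                            gap_days: int,
                            config: Optional[HFConfig] = None,
                            perturb: Optional[PerturbationSpec] = None,
                            n_units: int = 30,
                            tau: float = 100.0,
                            n_test_days: int = 3,
                            n_trials: int = 30,
                            blocks_per_decoder: int = 2,
                            seed: int = 0) -> pd.DataFrame:
    """Stale-training-data comparison across a withheld gap.

    Training data stop ``gap_days`` + ``n_test_days`` days before the end
    of the corpus.  The MRNN and FIT Long train on the pooled pre-gap
    days, FIT Old on the single last pre-gap day, FIT Sameday on each test
    day's own reaches; all run interleaved closed-loop blocks
    (``blocks_per_decoder`` per decoder per test day, as in an
    "ABCD ABCD" block-set design) on the post-gap test days.  A decoder
    that fails any block on a day is recorded as failed with 0 targets
    per minute for that day.
    """
    days = corpus.day_indices
    if len(days) <= gap_days + n_test_days + 1:
        raise ValueError("corpus shorter than gap + test days")
    test_days = days[-n_test_days:]
    train_days = days[:-(gap_days + n_test_days)]
    train_corpus = corpus.subset_days(train_days)

    pos_p, vel_p, norm = train_decoder_pair(
        train_corpus, config, perturb, n_units=n_units, tau=tau)
    gain = calibrate_output_gain(
        vel_p, norm, train_corpus.day_trials(train_corpus.day_indices[-1]))
    pooled_trials = list(train_corpus.iter_trials())
    kf_long = fit_fit_kf(pooled_trials, dt=corpus.bin_width)
    kf_old = fit_fit_kf(corpus.day_trials(train_days[-1]),
                        dt=corpus.bin_width)

    rows = []
    for i, test_day in enumerate(test_days):
        condition = corpus.condition_truth[test_day]
        kf_sameday = fit_fit_kf(corpus.day_trials(test_day),
                                dt=corpus.bin_width)
        decoders = {
            "mrnn": lambda: MRNNCursorDecoder(pos_p, vel_p, norm,
                                              output_gain=gain),
            "fit_long": lambda: KFCursorDecoder(kf_long),
            "fit_old": lambda: KFCursorDecoder(kf_old),
            "fit_sameday": lambda: KFCursorDecoder(kf_sameday),
        }
        for j, (name, make) in enumerate(decoders.items()):
            setup = _default_setup(tuning, corpus.bin_width, n_trials)
            blocks = []
            for b in range(blocks_per_decoder):
                rng = np.random.default_rng(
                    (seed * 1013 + i * 101 + j * 11 + b) % (2 ** 31))
                blocks.append(run_block(
                    make(), setup.user, tuning, condition, setup.task,
                    setup.n_trials, rng, bin_width=setup.bin_width))
            failed = any(bl.failed for bl in blocks)
            tpm = 0.0 if failed else float(np.mean(
                [targets_per_minute(bl) for bl in blocks]))
            rows.append({
                "test_day": test_day, "decoder": name,
                "targets_per_min": tpm,
                "success_rate": float(np.mean(
                    [o.success for bl in blocks for o in bl.outcomes])),
                "failed": failed,
                "n_blocks": len(blocks),
                "n_trials": int(sum(len(bl.outcomes) for bl in blocks)),
            })
    return pd.DataFrame(rows)
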