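"""Synthetic multi-day motor-cortical corpora with drifting recording conditions.

Real multielectrode recordings drift: electrodes move relative to neurons,
gains and baselines wander, electrodes die, and — crucially for a decoder
trained on a long history — conditions sometimes *recur*, so that the most
similar past recording may be chronologically distant.  This module
emulates that structure with the simplest defensible ingredients:

* minimum-jerk centre-out reaches on a Radial 8 geometry (behaviour held
  statistically stable across days, as well-trained reaching is);
* per-electrode cosine tuning of Poisson spike counts to hand velocity
  (plus an optional weak position term), through a rectified-linear rate;
* a per-day :class:`RecordingConditionSpec` (global gain, per-electrode
  gain/baseline, preferred-direction rotation, lost electrodes) evolved by
  a random walk with occasional resampling of a past condition.

Everything is deterministic given a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .datamodel import (
    BinnedSpikeCounts,
    Kinematics2D,
    SessionCorpus,
    Trial,
)

__all__ = [
    "TuningModel",
    "RecordingConditionSpec",
    "DriftProcess",
    "generate_reach",
    "evolve_condition",
    "emit_counts",
    "generate_corpus",
    "generate_day_trials",
    "radial8_targets",
]

#: Reach durations (ms): outward reaches to the radial targets take 700 ms,
#: returns to centre 600 ms (inward reaches are slightly faster).  Together
#: with the Radial 8 geometry these give trial-averaged velocity traces of
#: 8 x 700 + 8 x 600 = 10,400 ms when concatenated across targets.
OUTWARD_DURATION_MS = 700.0
INWARD_DURATION_MS = 600.0


@dataclass(frozen=True)
class TuningModel:
    """Per-electrode cosine tuning of firing rate to 2D velocity.

    rate_e(t) = baseline_e + depth_e * (pd_e . v(t)) + pos_gain_e * (pd_e . p(t))

    with units Hz, Hz/(cm/s) and Hz/cm.  Negative rates are rectified to
    zero at emission time.
    """

    baseline_rate: np.ndarray        # (E,) Hz
    modulation_depth: np.ndarray     # (E,) Hz/(cm/s)
    preferred_direction: np.ndarray  # (E, 2) unit vectors
    position_gain: np.ndarray        # (E,) Hz/cm

    def __post_init__(self):
        b = np.asarray(self.baseline_rate, dtype=float)
        d = np.asarray(self.modulation_depth, dtype=float)
        pd_ = np.asarray(self.preferred_direction, dtype=float)
        pg = np.asarray(self.position_gain, dtype=float)
        if (b < 0).any():
            raise ValueError("baseline rates must be >= 0")
        norms = np.linalg.norm(pd_, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise ValueError("preferred directions must be unit vectors")
        for name, arr in (("baseline_rate", b), ("modulation_depth", d),
                          ("preferred_direction", pd_), ("position_gain", pg)):
            object.__setattr__(self, name, arr)

    @property
    def n_electrodes(self) -> int:
        return self.baseline_rate.shape[0]

    @classmethod
    def sample(cls, n_electrodes: int, rng: np.random.Generator,
               baseline_range=(5.0, 25.0), depth_median=0.5,
               depth_log_sd=0.9,
               position_gain_range=(0.2, 1.0)) -> "TuningModel":
        """Draw a random population with realistic multiunit scales.

        Baselines of 5-25 Hz and a *heavy-tailed* (log-normal) spread of
        modulation depths reproduce two features of chronic-array
        threshold crossings: velocity modulation comparable to baseline at
        peak reach speeds of ~20-25 cm/s, and informativeness concentrated
        in a few strongly tuned electrodes (which is what makes dropping
        the top-ranked electrodes a severe challenge).
        """
        angles = rng.uniform(0.0, 2.0 * np.pi, size=n_electrodes)
        return cls(
            baseline_rate=rng.uniform(*baseline_range, size=n_electrodes),
            modulation_depth=rng.lognormal(
                np.log(depth_median), depth_log_sd, size=n_electrodes),
            preferred_direction=np.stack(
                [np.cos(angles), np.sin(angles)], axis=1),
            position_gain=rng.uniform(*position_gain_range, size=n_electrodes),
        )


@dataclass(frozen=True)
class RecordingConditionSpec:
    """One day's recording condition: the factors mapping intent to counts."""

    day_gain: float                 # global multiplicative gain, > 0
    electrode_gain: np.ndarray      # (E,) >= 0; 0 = lost electrode
    baseline_offset: np.ndarray     # (E,) Hz, additive baseline shift
    pd_rotation: float              # radians, common PD rotation
    source_day: Optional[int] = None  # set when this day recurred a past one

    def __post_init__(self):
        eg = np.asarray(self.electrode_gain, dtype=float)
        bo = np.asarray(self.baseline_offset, dtype=float)
        if self.day_gain <= 0 or not math.isfinite(self.day_gain):
            raise ValueError("day_gain must be positive and finite")
        if (eg < 0).any():
            raise ValueError("electrode gains must be >= 0")
        if eg.shape != bo.shape:
            raise ValueError("electrode_gain and baseline_offset must align")
        object.__setattr__(self, "electrode_gain", eg)
        object.__setattr__(self, "baseline_offset", bo)

    @classmethod
    def identity(cls, n_electrodes: int) -> "RecordingConditionSpec":
        return cls(day_gain=1.0,
                   electrode_gain=np.ones(n_electrodes),
                   baseline_offset=np.zeros(n_electrodes),
                   pd_rotation=0.0)


@dataclass(frozen=True)
class DriftProcess:
    """Day-to-day drift scales for the recording condition.

    Gains, baselines and the common preferred-direction rotation follow
    mean-reverting (AR(1)) processes: consecutive days are similar, days
    a week or more apart are nearly independent draws from a *bounded*
    family of conditions — new conditions resemble previously encountered
    ones rather than walking off indefinitely.  Electrodes additionally
    suffer occasional *transient* losses (gain to 0, usually recovering
    within days — connector-style failures); together with the gain and
    baseline drift this is the signal-turnover that disables decoders
    calibrated on stale data.  (A corpus may also carry a permanently
    dead electrode set — see ``generate_corpus`` — which, being constant,
    harms no decoder.)
    ``recurrence_prob`` makes a fresh day occasionally resample (a
    jittered copy of) a uniformly drawn past day, so that chronologically
    distant data can be the most similar.
    """

    gain_sd: float = 0.05            # per-day innovation sd of log day_gain
    electrode_gain_sd: float = 0.20  # per-day innovation sd per electrode
    baseline_sd: float = 3.0         # Hz/day innovation per electrode
    rotation_sd: float = 0.30        # rad/day innovation, common PD rotation
    dropout_prob: float = 0.02       # per-electrode P(gain -> 0) per day
    recovery_prob: float = 0.25      # per-day P(a lost electrode returns)
    recurrence_prob: float = 0.30    # P(day resamples a past condition)
    recurrence_jitter: float = 0.25  # fraction of daily sds applied to copy
    mean_reversion: float = 0.85     # per-day pull toward the nominal state

    def __post_init__(self):
        for p in (self.dropout_prob, self.recovery_prob,
                  self.recurrence_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        for s in (self.gain_sd, self.electrode_gain_sd, self.baseline_sd,
                  self.rotation_sd):
            if s < 0:
                raise ValueError("drift sds must be >= 0")

    @classmethod
    def none(cls) -> "DriftProcess":
        """Degenerate drift: the condition never changes."""
        return cls(gain_sd=0.0, electrode_gain_sd=0.0, baseline_sd=0.0,
                   rotation_sd=0.0, dropout_prob=0.0, recovery_prob=0.0,
                   recurrence_prob=0.0)


def radial8_targets(radius: float = 8.0) -> np.ndarray:
    """The 8 equidistant peripheral targets of the Radial 8 geometry (cm)."""
    angles = np.arange(8) * (2.0 * np.pi / 8.0)
    return radius * np.stack([np.cos(angles), np.sin(angles)], axis=1)


def generate_reach(start, target, duration: float,
                   bin_width: float) -> Kinematics2D:
    """Minimum-jerk point-to-point reach sampled at bin centres.

    The minimum-jerk profile s(u) = 10u^3 - 15u^4 + 6u^5 (u = t/duration)
    starts and ends at rest with peak speed at the midpoint; velocity is
    the analytic derivative, not a numerical one.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    start = np.asarray(start, dtype=float).reshape(2)
    target = np.asarray(target, dtype=float).reshape(2)
    n_bins = int(round(duration / bin_width))
    if n_bins < 3:
        raise ValueError("reach must span at least 3 bins")
    t = (np.arange(n_bins) + 0.5) * bin_width  # bin centres, ms
    u = t / duration
    s = 10 * u**3 - 15 * u**4 + 6 * u**5
    ds_du = 30 * u**2 - 60 * u**3 + 30 * u**4
    delta = target - start
    position = start[:, None] + delta[:, None] * s[None, :]
    # d/dt in 1/s: (1/duration_ms)*1000
    velocity = delta[:, None] * ds_du[None, :] * (1000.0 / duration)
    return Kinematics2D(position=position, velocity=velocity,
                        bin_width=bin_width)


def evolve_condition(prev: RecordingConditionSpec, drift: DriftProcess,
                     history: Sequence[RecordingConditionSpec],
                     rng: np.random.Generator) -> RecordingConditionSpec:
    """One day-to-day step of the recording-condition process.

    With probability ``recurrence_prob`` (and a non-empty history) a past
    condition is drawn uniformly and returned with a small jitter and its
    provenance recorded in ``source_day``; otherwise each condition
    component takes one mean-reverting AR(1) step from ``prev`` (a
    component whose innovation sd is zero is left exactly unchanged, so
    degenerate drift is the identity).
    """
    E = prev.electrode_gain.shape[0]
    if len(history) > 0 and rng.random() < drift.recurrence_prob:
        k = int(rng.integers(len(history)))
        base = history[k]
        j = drift.recurrence_jitter
        eg = np.maximum(
            0.0, base.electrode_gain
            + rng.normal(0.0, j * drift.electrode_gain_sd + 1e-12, E)
            * (base.electrode_gain > 0))
        return RecordingConditionSpec(
            day_gain=base.day_gain
            * math.exp(rng.normal(0.0, j * drift.gain_sd)),
            electrode_gain=eg,
            baseline_offset=base.baseline_offset
            + rng.normal(0.0, j * drift.baseline_sd, E),
            pd_rotation=base.pd_rotation
            + rng.normal(0.0, j * drift.rotation_sd),
            source_day=k,
        )
    rho = drift.mean_reversion
    if drift.gain_sd > 0:
        day_gain = math.exp(rho * math.log(prev.day_gain)
                            + rng.normal(0.0, drift.gain_sd))
    else:
        day_gain = prev.day_gain
    if drift.electrode_gain_sd > 0:
        eg = 1.0 + rho * (prev.electrode_gain - 1.0) \
            + rng.normal(0.0, drift.electrode_gain_sd, E)
        eg = np.maximum(eg, 0.0)
    else:
        eg = prev.electrode_gain.copy()
    # electrode loss and recovery
    lost = rng.random(E) < drift.dropout_prob
    eg[lost] = 0.0
    was_dead = prev.electrode_gain == 0
    revived = was_dead & (rng.random(E) < drift.recovery_prob) & ~lost
    eg[revived] = 1.0
    eg[was_dead & ~revived] = 0.0
    if drift.baseline_sd > 0:
        baseline = rho * prev.baseline_offset \
            + rng.normal(0.0, drift.baseline_sd, E)
    else:
        baseline = prev.baseline_offset.copy()
    if drift.rotation_sd > 0:
        rotation = rho * prev.pd_rotation \
            + rng.normal(0.0, drift.rotation_sd)
    else:
        rotation = prev.pd_rotation
    return RecordingConditionSpec(
        day_gain=day_gain,
        electrode_gain=eg,
        baseline_offset=baseline,
        pd_rotation=rotation,
        source_day=None,
    )


def condition_rates(kin: Kinematics2D, tuning: TuningModel,
                    cond: RecordingConditionSpec) -> np.ndarray:
    """Noise-free firing rates (E, T) in Hz under a recording condition.

    rate = max(0, day_gain * eg_e * (baseline_e + offset_e
               + depth_e * (R(theta) pd_e) . v(t) + pos_gain_e * pd_e . p(t)))
    """
    theta = cond.pd_rotation
    rot = np.array([[np.cos(theta), -np.sin(theta)],
                    [np.sin(theta), np.cos(theta)]])
    pd_rot = tuning.preferred_direction @ rot.T      # (E, 2)
    drive = (tuning.baseline_rate[:, None]
             + cond.baseline_offset[:, None]
             + tuning.modulation_depth[:, None] * (pd_rot @ kin.velocity)
             + tuning.position_gain[:, None]
             * (tuning.preferred_direction @ kin.position))
    rates = cond.day_gain * cond.electrode_gain[:, None] * drive
    return np.maximum(rates, 0.0)


def emit_counts(kin: Kinematics2D, tuning: TuningModel,
                cond: RecordingConditionSpec,
                rng: np.random.Generator) -> BinnedSpikeCounts:
    """Draw Poisson spike counts for one trial's kinematics."""
    if kin.bin_width <= 0:
        raise ValueError("bin width must be positive")
    rates = condition_rates(kin, tuning, cond)
    lam = rates * (kin.bin_width / 1000.0)
    counts = rng.poisson(lam)
    return BinnedSpikeCounts(counts=counts, bin_width=kin.bin_width)


def generate_corpus(n_days: int,
                    trials_per_day: int,
                    n_electrodes: int = 32,
                    radius: float = 8.0,
                    drift: Optional[DriftProcess] = None,
                    seed: int = 0,
                    bin_width: float = 20.0,
                    tuning: Optional[TuningModel] = None,
                    duration_jitter: float = 0.08,
                    endpoint_jitter_cm: float = 0.25,
                    hold_ms: float = 200.0,
                    permanent_dead_frac: float = 0.15,
                    ) -> tuple:
    """Generate a multi-day Radial 8 corpus.

    Trials alternate outward (centre -> peripheral target, cycling through
    the 8 targets) and inward (back to centre) reaches.  Behaviour is held
    statistically stable across days (only small duration/endpoint jitter),
    while the recording condition drifts per ``drift``; this isolates
    neural-condition variability the way well-trained reaching does.

    Returns ``(corpus, tuning)``; the corpus carries per-day ground-truth
    conditions in ``condition_truth``.
    """
    if n_days < 1 or trials_per_day < 1:
        raise ValueError("need at least one day and one trial per day")
    drift = drift if drift is not None else DriftProcess()
    rng = np.random.default_rng(seed)
    if tuning is None:
        tuning = TuningModel.sample(n_electrodes, rng)
    elif tuning.n_electrodes != n_electrodes:
        raise ValueError("tuning model size must match n_electrodes")
    # chronic arrays carry a fixed set of permanently dead electrodes;
    # being constant across the corpus they harm no decoder
    n_dead = int(round(permanent_dead_frac * n_electrodes))
    dead_set = rng.choice(n_electrodes, size=n_dead, replace=False)

    def _apply_dead(c: RecordingConditionSpec) -> RecordingConditionSpec:
        if n_dead == 0:
            return c
        eg = c.electrode_gain.copy()
        eg[dead_set] = 0.0
        return replace(c, electrode_gain=eg)

    cond = _apply_dead(RecordingConditionSpec.identity(n_electrodes))
    history: list = []
    days = []
    truth = {}
    for day in range(n_days):
        if day > 0:
            cond = _apply_dead(evolve_condition(cond, drift, history, rng))
        history.append(cond)
        truth[day] = cond
        trials = generate_day_trials(
            tuning, cond, trials_per_day, rng, radius=radius,
            bin_width=bin_width, duration_jitter=duration_jitter,
            endpoint_jitter_cm=endpoint_jitter_cm, hold_ms=hold_ms,
            day_index=day)
        days.append((day, trials))
    corpus = SessionCorpus(days=days, condition_truth=truth)
    return corpus, tuning


def generate_day_trials(tuning: TuningModel,
                        cond: RecordingConditionSpec,
                        n_trials: int,
                        rng: np.random.Generator,
                        radius: float = 8.0,
                        bin_width: float = 20.0,
                        duration_jitter: float = 0.08,
                        endpoint_jitter_cm: float = 0.25,
                        hold_ms: float = 200.0,
                        day_index: int = 0) -> list:
    """One day of alternating out/in Radial 8 reaches under one condition."""
    targets = radial8_targets(radius)
    centre = np.zeros(2)
    trials = []
    for i in range(n_trials):
        outward = (i % 2 == 0)
        base_target = targets[(i // 2) % 8]
        if outward:
            start, target = centre, base_target
            duration = OUTWARD_DURATION_MS
        else:
            start, target = base_target, centre
            duration = INWARD_DURATION_MS
        dur = duration * (1.0 + rng.uniform(-duration_jitter,
                                            duration_jitter))
        dur = round(dur / bin_width) * bin_width  # whole bins
        end = target + rng.uniform(-endpoint_jitter_cm,
                                   endpoint_jitter_cm, size=2)
        kin = generate_reach(start, end, dur, bin_width)
        n_hold = int(round(hold_ms / bin_width))
        if n_hold > 0:
            # target-hold tail: at rest on the endpoint, so every trial
            # covers the full behavioural-similarity epoch
            pos = np.concatenate(
                [kin.position,
                 np.repeat(kin.position[:, -1:], n_hold, axis=1)], axis=1)
            vel = np.concatenate(
                [kin.velocity, np.zeros((2, n_hold))], axis=1)
            kin = Kinematics2D(pos, vel, bin_width)
        spikes = emit_counts(kin, tuning, cond, rng)
        trials.append(Trial(
            spikes=spikes, kin=kin,
            target_position=target, start_position=start,
            day_index=day_index, trial_index=i,
        ))
    return trials
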