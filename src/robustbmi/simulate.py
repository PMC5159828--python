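"""Closed-loop cursor simulation and performance metrics.

The simulator closes the loop that an animal closes in a real BMI
session: a feedback user model looks at the visible cursor and forms an
intended velocity toward the current target; the synthetic tuning model
(under the day's recording condition) turns that intent into spike
counts; the decoder turns counts into a cursor update via the blending
law

    d <- beta (d_prev + gamma_v v_norm dt) + (1 - beta) gamma_p p_norm

with beta = 0.99 in closed loop (velocity-dominated, a slight position
term to absorb drift) and beta = 1 for offline accuracy.  Task state
machines implement the Radial 8 and Random Target tasks with a 4 x 4 cm
acceptance window, 500 ms hold and 5 s timeout, and a block is stopped
and marked failed if the success rate falls below 50% after at least 10
trials; a failed block scores 0 targets per minute.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np

from .datamodel import Kinematics2D, NormalizationSpec
from .kalman import KFParams, KFState, kf_decode_step
from .mrnn import MRNNParams, MRNNState, readout, step as mrnn_step
from .synthetic import (
    RecordingConditionSpec,
    TuningModel,
    condition_rates,
    radial8_targets,
)

__all__ = [
    "BlendSpec",
    "TaskConfig",
    "TrialOutcome",
    "BlockMetrics",
    "FeedbackUserModel",
    "MRNNCursorDecoder",
    "KFCursorDecoder",
    "OracleDecoder",
    "ZeroDecoder",
    "blend_cursor",
    "run_block",
    "targets_per_minute",
    "time_to_target",
    "dial_in_time",
    "normalized_time_to_target",
    "success_rate",
    "decode_accuracy_r2",
]


@dataclass(frozen=True)
class BlendSpec:
    """Position/velocity blending: beta near 1 is velocity-dominated."""

    beta: float = 0.99
    gamma_v: np.ndarray = None    # (2,) cm/s per normalized unit
    gamma_p: np.ndarray = None    # (2,) cm per normalized unit
    dt: float = 20.0              # ms

    def __post_init__(self):
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError("beta must lie in [0, 1]")
        gv = np.ones(2) if self.gamma_v is None \
            else np.asarray(self.gamma_v, dtype=float).reshape(2)
        gp = np.ones(2) if self.gamma_p is None \
            else np.asarray(self.gamma_p, dtype=float).reshape(2)
        object.__setattr__(self, "gamma_v", gv)
        object.__setattr__(self, "gamma_p", gp)

    @classmethod
    def from_normalization(cls, norm: NormalizationSpec, beta: float = 0.99,
                           dt: float = 20.0) -> "BlendSpec":
        return cls(beta=beta, gamma_v=norm.gamma_v, gamma_p=norm.gamma_p,
                   dt=dt)


@dataclass(frozen=True)
class TaskConfig:
    """Task geometry and timing."""

    task: str = "radial8"            # or "random_target"
    radius: float = 8.0              # cm, radial targets
    window: float = 4.0              # cm, square acceptance window side
    hold_ms: float = 500.0
    timeout_ms: float = 5000.0
    workspace: tuple = (40.0, 30.0)  # cm, full width x height
    random_region: float = 20.0      # cm, random-target square side
    recenter_after_failure: bool = True  # rig re-centres the cursor

    def __post_init__(self):
        if self.task not in ("radial8", "random_target"):
            raise ValueError("task must be 'radial8' or 'random_target'")
        if self.hold_ms >= self.timeout_ms:
            raise ValueError("hold must be shorter than timeout")
        if self.window <= 0:
            raise ValueError("acceptance window must be positive")


@dataclass
class TrialOutcome:
    success: bool
    time_to_target_ms: float         # final entry time, excludes hold
    first_entry_ms: Optional[float]
    final_entry_ms: Optional[float]
    target_position: np.ndarray
    start_position: np.ndarray
    duration_ms: float
    peripheral: bool = True


@dataclass
class BlockMetrics:
    outcomes: List[TrialOutcome]
    duration_ms: float
    failed: bool
    cursor_trace: Optional[np.ndarray] = None

    @property
    def targets_per_minute_value(self) -> float:
        return targets_per_minute(self)


@dataclass(frozen=True)
class FeedbackUserModel:
    """Intermittent submovement controller with visuomotor delay.

    Models corrective reaching the way the motor-control literature
    does: the user plans a minimum-jerk submovement from the *visually
    perceived* cursor — the drawn cursor ``reaction_delay_bins`` ago,
    the ~160 ms visuomotor latency — to the target, executes it, and
    replans every ``replan_ms`` (or immediately when the target
    changes).  Submovement duration scales with distance
    (``ms_per_cm``, floored at ``min_duration_ms``), giving the same
    bell-shaped velocity statistics as natural reaching; Gaussian
    intention noise rides on top.  Two properties matter downstream:
    the intent statistics match the reaching data decoders are trained
    on, and the feedback delay means a decoder whose response is badly
    miscalibrated destabilizes the loop — which is what separates
    usable from unusable decoders in closed loop.
    """

    ms_per_cm: float = 87.5        # submovement duration per cm (700 ms / 8 cm)
    min_duration_ms: float = 350.0
    replan_ms: float = 300.0
    noise_sd: float = 1.0          # cm/s
    reaction_delay_bins: int = 8   # 160 ms at 20 ms bins
    hold_dist_cm: float = 0.4      # closer than this: intend stillness

    def __post_init__(self):
        if min(self.ms_per_cm, self.min_duration_ms, self.replan_ms) <= 0:
            raise ValueError("durations must be positive")
        if self.noise_sd < 0 or self.reaction_delay_bins < 0:
            raise ValueError("noise and delay must be >= 0")

    def make_controller(self, bin_width: float) -> "_SubmovementController":
        return _SubmovementController(self, bin_width)


class _SubmovementController:
    """Per-block stateful executor of the submovement user model."""

    def __init__(self, model: FeedbackUserModel, bin_width: float):
        self.m = model
        self.bin_width = bin_width
        self._profile = None      # (2, n) planned velocity samples
        self._idx = 0
        self._since_replan = 0
        self._last_aim = None

    def _plan(self, perceived: np.ndarray, aim: np.ndarray) -> None:
        err = aim - perceived
        dist = float(np.linalg.norm(err))
        if dist < self.m.hold_dist_cm:
            self._profile = np.zeros((2, 1))
        else:
            T_ms = max(self.m.min_duration_ms, self.m.ms_per_cm * dist)
            n = max(3, int(round(T_ms / self.bin_width)))
            u = (np.arange(n) + 0.5) / n
            speed = (30 * u**2 - 60 * u**3 + 30 * u**4) \
                * dist * (1000.0 / T_ms)
            self._profile = (err / dist)[:, None] * speed[None, :]
        self._idx = 0
        self._since_replan = 0

    def intent(self, perceived: np.ndarray, aim: np.ndarray,
               rng: np.random.Generator) -> np.ndarray:
        aim_changed = self._last_aim is None \
            or not np.array_equal(aim, self._last_aim)
        replan_due = self._profile is None \
            or self._idx >= self._profile.shape[1] \
            or self._since_replan * self.bin_width >= self.m.replan_ms
        if aim_changed or replan_due:
            self._plan(perceived, aim)
            self._last_aim = np.asarray(aim, float).copy()
        v = self._profile[:, min(self._idx, self._profile.shape[1] - 1)]
        self._idx += 1
        self._since_replan += 1
        return v + rng.normal(0.0, self.m.noise_sd, size=2)


def blend_cursor(prev: np.ndarray, v_norm: np.ndarray, p_norm: np.ndarray,
                 spec: BlendSpec,
                 workspace: Optional[tuple] = None) -> np.ndarray:
    """One blending update of the drawn cursor position (cm)."""
    dt_s = spec.dt / 1000.0
    d = spec.beta * (np.asarray(prev, float)
                     + spec.gamma_v * np.asarray(v_norm, float) * dt_s) \
        + (1.0 - spec.beta) * spec.gamma_p * np.asarray(p_norm, float)
    if workspace is not None:
        half = np.asarray(workspace, float) / 2.0
        d = np.clip(d, -half, half)
    return d


# ---------------------------------------------------------------------------
# closed-loop decoder adapters
# ---------------------------------------------------------------------------

def calibrate_output_gain(velocity_params: MRNNParams,
                          norm: NormalizationSpec, trials,
                          max_gain: float = 2.0) -> float:
    """Deployment-time cursor-gain calibration on held-back reach data.

    A squared-error-trained decoder attenuates amplitudes (regression to
    the mean), so the cursor moves slower than intended.  This fits the
    slope of decoded-vs-true velocity on the supplied (training-era)
    trials and returns its inverse, clipped to [1, max_gain]; the cursor
    decoder multiplies its velocity output by this scalar — the gain
    knob every closed-loop rig tunes before a session.
    """
    from .mrnn import run as _run

    trials = list(trials)
    counts = np.concatenate([t.spikes.counts for t in trials], axis=1)
    true_v = np.concatenate([t.kin.velocity for t in trials], axis=1)
    decoded = norm.denormalize_velocity(_run(velocity_params, counts))
    slopes = []
    for d in range(2):
        tv = true_v[d]
        if tv.std() == 0:
            continue
        slopes.append(float(tv @ decoded[d] / (tv @ tv)))
    slope = float(np.median(slopes)) if slopes else 1.0
    if slope <= 0:
        return 1.0
    return float(np.clip(1.0 / slope, 1.0, max_gain))

class MRNNCursorDecoder:
    """The MRNN position/velocity pair driving the cursor via blending.

    Hidden states persist across bins and trials; they reset only at
    session (block) start, as in real closed-loop use.  ``output_gain``
    rescales the decoded normalized velocity before integration — the
    standard deployment-time cursor-gain calibration that undoes the
    amplitude attenuation of a squared-error-trained decoder (see
    :func:`calibrate_output_gain`).
    """

    def __init__(self, position_params: MRNNParams,
                 velocity_params: MRNNParams, norm: NormalizationSpec,
                 beta: float = 0.99, workspace: tuple = (40.0, 30.0),
                 output_gain: float = 1.0):
        self.position_params = position_params
        self.velocity_params = velocity_params
        self.blend = BlendSpec.from_normalization(
            norm, beta=beta, dt=velocity_params.dt)
        self.workspace = workspace
        self.output_gain = float(output_gain)
        self.reset()

    def reset(self) -> None:
        N_p = self.position_params.dims[0]
        N_v = self.velocity_params.dims[0]
        self._state_p = MRNNState.zeros(N_p)
        self._state_v = MRNNState.zeros(N_v)
        self.cursor = np.zeros(2)

    def recenter(self) -> None:
        """Re-centre the drawn cursor; the hidden state persists."""
        self.cursor = np.zeros(2)

    def decode_bin(self, counts: np.ndarray, rng=None) -> np.ndarray:
        self._state_p = mrnn_step(self.position_params, self._state_p,
                                  counts)
        self._state_v = mrnn_step(self.velocity_params, self._state_v,
                                  counts)
        p_norm = readout(self.position_params, self._state_p)
        v_norm = self.output_gain * readout(self.velocity_params,
                                            self._state_v)
        self.cursor = blend_cursor(self.cursor, v_norm, p_norm, self.blend,
                                   self.workspace)
        return self.cursor


class KFCursorDecoder:
    """FIT-KF driving the cursor: decoded velocity integrates the cursor,
    and the decoder's known-position feedback is the drawn cursor itself."""

    def __init__(self, params: KFParams, workspace: tuple = (40.0, 30.0)):
        self.params = params
        self.workspace = workspace
        self.reset()

    def reset(self) -> None:
        self.cursor = np.zeros(2)
        self._state = KFState.initial(self.cursor)

    def recenter(self) -> None:
        self.cursor = np.zeros(2)

    def decode_bin(self, counts: np.ndarray, rng=None) -> np.ndarray:
        self._state = kf_decode_step(self.params, self._state, counts,
                                     self.cursor)
        v = self._state.mean[2:4]
        self.cursor = self.cursor + v * (self.params.dt / 1000.0)
        half = np.asarray(self.workspace, float) / 2.0
        self.cursor = np.clip(self.cursor, -half, half)
        return self.cursor


class OracleDecoder:
    """Moves the cursor with the user's own intended velocity.

    Validates the task machinery independent of any trained decoder.
    """

    wants_intention = True

    def __init__(self, dt: float = 20.0, workspace: tuple = (40.0, 30.0)):
        self.dt = dt
        self.workspace = workspace
        self.reset()

    def reset(self) -> None:
        self.cursor = np.zeros(2)

    def decode_bin(self, counts, intended_velocity=None, rng=None):
        self.cursor = self.cursor + np.asarray(intended_velocity, float) \
            * (self.dt / 1000.0)
        half = np.asarray(self.workspace, float) / 2.0
        self.cursor = np.clip(self.cursor, -half, half)
        return self.cursor


class ZeroDecoder:
    """Always outputs zero velocity: the cursor never moves."""

    def __init__(self):
        self.reset()

    def reset(self) -> None:
        self.cursor = np.zeros(2)

    def decode_bin(self, counts, rng=None):
        return self.cursor


# ---------------------------------------------------------------------------
# block simulation
# ---------------------------------------------------------------------------

def _in_window(cursor: np.ndarray, target: np.ndarray,
               window: float) -> bool:
    return bool((np.abs(cursor - target) < window / 2.0).all())


def _next_target(task: TaskConfig, trial_idx: int, prev_target: np.ndarray,
                 rng: np.random.Generator) -> tuple:
    """Target and peripheral flag for the next trial."""
    if task.task == "radial8":
        if trial_idx % 2 == 0:
            return radial8_targets(task.radius)[(trial_idx // 2) % 8], True
        return np.zeros(2), False
    # random target: acceptance areas of consecutive targets must not overlap
    half = task.random_region / 2.0
    while True:
        cand = rng.uniform(-half, half, size=2)
        if (np.abs(cand - prev_target) >= task.window).any():
            return cand, True


def run_block(decoder, user: FeedbackUserModel, tuning: TuningModel,
              condition: RecordingConditionSpec, task: TaskConfig,
              n_trials: int, rng: np.random.Generator,
              bin_width: float = 20.0,
              dropped_electrodes: Sequence[int] = (),
              keep_trace: bool = False) -> BlockMetrics:
    """Simulate one closed-loop block of up to ``n_trials`` trials.

    Per bin: the user forms an intended velocity toward the target from
    the visible cursor, the tuning model emits counts under the block's
    recording condition (optionally with electrodes zeroed), and the
    decoder moves the cursor.  The block halts early, marked failed, if
    the success rate drops below 50% after at least 10 trials.
    """
    decoder.reset()
    dropped = np.asarray(sorted(dropped_electrodes), dtype=int)
    outcomes: List[TrialOutcome] = []
    total_bins = 0
    timeout_bins = int(round(task.timeout_ms / bin_width))
    hold_bins = int(round(task.hold_ms / bin_width))
    delay = user.reaction_delay_bins
    prev_target = np.zeros(2)
    trace = [] if keep_trace else None
    failed = False
    controller = user.make_controller(bin_width)
    # visually perceived cursor lags the drawn cursor by the visuomotor
    # delay; the history persists across trials within the block
    cursor_history = [decoder.cursor.copy()]

    for trial_idx in range(n_trials):
        target, peripheral = _next_target(task, trial_idx, prev_target, rng)
        start_cursor = decoder.cursor.copy()
        first_entry = None
        final_entry = None
        in_hold = 0
        success = False
        t_bin = 0
        for t_bin in range(timeout_bins):
            # before the reaction delay elapses the user still aims at the
            # previous target
            aim = prev_target if t_bin < delay else target
            perceived = cursor_history[max(0, len(cursor_history) - delay)] \
                if delay > 0 else decoder.cursor
            intent = controller.intent(perceived, aim, rng)
            kin = Kinematics2D(
                position=decoder.cursor.reshape(2, 1),
                velocity=intent.reshape(2, 1), bin_width=bin_width)
            rates = condition_rates(kin, tuning, condition)
            counts = rng.poisson(rates[:, 0] * (bin_width / 1000.0))
            if dropped.size:
                counts[dropped] = 0
            if getattr(decoder, "wants_intention", False):
                cursor = decoder.decode_bin(counts,
                                            intended_velocity=intent,
                                            rng=rng)
            else:
                cursor = decoder.decode_bin(counts, rng=rng)
            cursor_history.append(cursor.copy())
            if keep_trace:
                trace.append(cursor.copy())
            if _in_window(cursor, target, task.window):
                now_ms = (t_bin + 1) * bin_width
                if first_entry is None:
                    first_entry = now_ms
                if in_hold == 0:
                    final_entry = now_ms
                in_hold += 1
                if in_hold >= hold_bins:
                    success = True
                    break
            else:
                in_hold = 0
        total_bins += t_bin + 1
        outcomes.append(TrialOutcome(
            success=success,
            time_to_target_ms=final_entry if success else np.nan,
            first_entry_ms=first_entry,
            final_entry_ms=final_entry if success else None,
            target_position=target, start_position=start_cursor,
            duration_ms=(t_bin + 1) * bin_width,
            peripheral=peripheral))
        if success:
            prev_target = target
        elif task.recenter_after_failure and hasattr(decoder, "recenter"):
            # the rig re-centres the cursor after a failed trial, as in
            # real task implementations; decoder internal state persists
            decoder.recenter()
            cursor_history.append(decoder.cursor.copy())
        # block-failure rule: success rate < 50% after at least 10 trials
        if len(outcomes) >= 10:
            rate = np.mean([o.success for o in outcomes])
            if rate < 0.5:
                failed = True
                break
    return BlockMetrics(
        outcomes=outcomes,
        duration_ms=total_bins * bin_width,
        failed=failed,
        cursor_trace=np.array(trace).T if keep_trace else None)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def targets_per_minute(metrics: BlockMetrics) -> float:
    """Peripheral successes per minute of block wall time; failed -> 0."""
    if not metrics.outcomes:
        raise ValueError("no trials in block")
    if metrics.failed:
        return 0.0
    n = sum(1 for o in metrics.outcomes if o.success and o.peripheral)
    minutes = metrics.duration_ms / 60000.0
    return n / minutes if minutes > 0 else 0.0


def success_rate(outcomes: Sequence[TrialOutcome]) -> float:
    outcomes = list(outcomes)
    if not outcomes:
        raise ValueError("no trials")
    return float(np.mean([o.success for o in outcomes]))


def time_to_target(outcomes: Sequence[TrialOutcome]) -> np.ndarray:
    """Times to target (ms, hold excluded) of successful peripheral trials."""
    vals = [o.time_to_target_ms for o in outcomes
            if o.success and o.peripheral]
    if not vals:
        raise ValueError("no successful peripheral trials")
    return np.asarray(vals)


def dial_in_time(outcomes: Sequence[TrialOutcome]) -> float:
    """Mean ms between first and final window entry on successful trials."""
    vals = [o.final_entry_ms - o.first_entry_ms for o in outcomes
            if o.success and o.first_entry_ms is not None]
    if not vals:
        raise ValueError("no successful trials")
    return float(np.mean(vals))


def normalized_time_to_target(outcomes: Sequence[TrialOutcome]) -> float:
    """Mean s/cm over successes that directly follow another success."""
    vals = []
    prev_success_target = None
    prev_success = False
    for o in outcomes:
        if o.success and prev_success and prev_success_target is not None:
            dist = float(np.linalg.norm(
                o.target_position - prev_success_target))
            if dist > 0:
                vals.append((o.time_to_target_ms / 1000.0) / dist)
        if o.success:
            prev_success_target = o.target_position
        prev_success = o.success
    if not vals:
        raise ValueError("no successful trials following successes")
    return float(np.mean(vals))


def decode_accuracy_r2(true_v: np.ndarray, decoded_v: np.ndarray) -> float:
    """Mean over x and y of squared Pearson correlations."""
    true_v = np.asarray(true_v, float)
    decoded_v = np.asarray(decoded_v, float)
    if true_v.shape != decoded_v.shape or true_v.shape[0] != 2:
        raise ValueError("velocity arrays must both be (2, T)")
    if true_v.shape[1] < 3:
        raise ValueError("need at least 3 bins")
    r2s = []
    for d in range(2):
        if np.std(true_v[d]) == 0 or np.std(decoded_v[d]) == 0:
            raise ValueError("zero-variance velocity dimension")
        r = np.corrcoef(true_v[d], decoded_v[d])[0, 1]
        r2s.append(r ** 2)
    return float(np.mean(r2s))
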