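"""Core data containers for multi-day binned spike-count corpora.

The unit of analysis is a point-to-point reach ``Trial`` pairing an
electrodes x timebins matrix of non-negative integer spike counts with 2D
hand/cursor kinematics sampled on the same timebase.  Trials are grouped
into recording days, and days into a :class:`SessionCorpus` — the multiday
training corpus a decoder is fit to.

Conventions: the workspace is a 2D fronto-parallel plane in cm with the
origin at its centre; time is in ms; a bin covers the half-open interval
[t, t + bin_width).  Counts are stored as integers end to end — no rate
conversion happens inside the data model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "BinnedSpikeCounts",
    "Kinematics2D",
    "Trial",
    "SessionCorpus",
    "NormalizationSpec",
    "compute_velocity",
    "fit_normalization",
    "read_corpus",
    "write_corpus",
    "trial_to_csv",
]

DEFAULT_BIN_WIDTH_MS = 20.0


@dataclass(frozen=True)
class BinnedSpikeCounts:
    """Electrodes x timebins matrix of non-negative integer spike counts."""

    counts: np.ndarray          # (E, T) int
    bin_width: float            # ms
    electrode_ids: tuple = None

    def __post_init__(self):
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValueError("counts must be 2D (electrodes x timebins)")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.allclose(counts, np.round(counts)):
                raise ValueError("spike counts must be integers")
            counts = counts.astype(np.int64)
        if counts.size and counts.min() < 0:
            raise ValueError("spike counts must be non-negative")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        object.__setattr__(self, "counts", counts)
        if self.electrode_ids is None:
            object.__setattr__(
                self, "electrode_ids", tuple(range(counts.shape[0]))
            )
        elif len(self.electrode_ids) != counts.shape[0]:
            raise ValueError("electrode_ids length must match electrode count")

    @property
    def n_electrodes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_bins(self) -> int:
        return self.counts.shape[1]


@dataclass(frozen=True)
class Kinematics2D:
    """2D position (cm) and velocity (cm/s) sharing one timebase."""

    position: np.ndarray        # (2, T) cm
    velocity: np.ndarray        # (2, T) cm/s
    bin_width: float            # ms

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        vel = np.asarray(self.velocity, dtype=float)
        if pos.shape != vel.shape or pos.ndim != 2 or pos.shape[0] != 2:
            raise ValueError("position and velocity must both be (2, T)")
        if not (np.isfinite(pos).all() and np.isfinite(vel).all()):
            raise ValueError("kinematics must be finite")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        object.__setattr__(self, "position", pos)
        object.__setattr__(self, "velocity", vel)

    @property
    def n_bins(self) -> int:
        return self.position.shape[1]


@dataclass(frozen=True)
class Trial:
    """One reach: spike counts + kinematics + target metadata."""

    spikes: BinnedSpikeCounts
    kin: Kinematics2D
    target_position: np.ndarray     # (2,) cm
    start_position: np.ndarray      # (2,) cm
    day_index: int = 0
    trial_index: int = 0

    def __post_init__(self):
        if self.spikes.n_bins != self.kin.n_bins:
            raise ValueError(
                f"spikes ({self.spikes.n_bins} bins) and kinematics "
                f"({self.kin.n_bins} bins) must share a timebase"
            )
        object.__setattr__(
            self, "target_position",
            np.asarray(self.target_position, dtype=float).reshape(2),
        )
        object.__setattr__(
            self, "start_position",
            np.asarray(self.start_position, dtype=float).reshape(2),
        )

    @property
    def n_bins(self) -> int:
        return self.spikes.n_bins


@dataclass
class SessionCorpus:
    """Ordered multi-day collection of trials.

    ``condition_truth`` optionally carries the per-day ground-truth
    recording condition when the corpus is synthetic.
    """

    days: list = field(default_factory=list)   # [(day_index, [Trial, ...])]
    condition_truth: Optional[dict] = None     # day_index -> condition spec

    def __post_init__(self):
        indices = [d for d, _ in self.days]
        if indices != sorted(indices) or len(set(indices)) != len(indices):
            raise ValueError("day_index must be strictly increasing")
        es = {t.spikes.n_electrodes for _, trials in self.days for t in trials}
        if len(es) > 1:
            raise ValueError(f"inconsistent electrode counts across trials: {es}")

    @property
    def n_days(self) -> int:
        return len(self.days)

    @property
    def n_electrodes(self) -> int:
        for _, trials in self.days:
            if trials:
                return trials[0].spikes.n_electrodes
        raise ValueError("empty corpus has no electrode count")

    @property
    def bin_width(self) -> float:
        for _, trials in self.days:
            if trials:
                return trials[0].spikes.bin_width
        raise ValueError("empty corpus has no bin width")

    def iter_trials(self) -> Iterator[Trial]:
        for _, trials in self.days:
            yield from trials

    def day_trials(self, day_index: int) -> list:
        for d, trials in self.days:
            if d == day_index:
                return trials
        raise KeyError(f"no day {day_index} in corpus")

    @property
    def day_indices(self) -> list:
        return [d for d, _ in self.days]

    def subset_days(self, day_indices: Sequence[int]) -> "SessionCorpus":
        wanted = set(day_indices)
        days = [(d, trials) for d, trials in self.days if d in wanted]
        truth = None
        if self.condition_truth is not None:
            truth = {d: c for d, c in self.condition_truth.items() if d in wanted}
        return SessionCorpus(days=days, condition_truth=truth)


@dataclass(frozen=True)
class NormalizationSpec:
    """Per-dimension max-abs scales mapping kinematics into [-1, 1].

    ``gamma_v``/``gamma_p`` are the factors converting normalized decoder
    output back to workspace cm/s and cm; by construction they equal the
    fitted scales.
    """

    position_scale: np.ndarray   # (2,) cm
    velocity_scale: np.ndarray   # (2,) cm/s

    def __post_init__(self):
        ps = np.asarray(self.position_scale, dtype=float).reshape(2)
        vs = np.asarray(self.velocity_scale, dtype=float).reshape(2)
        if (ps <= 0).any() or (vs <= 0).any():
            raise ValueError("normalization scales must be positive")
        object.__setattr__(self, "position_scale", ps)
        object.__setattr__(self, "velocity_scale", vs)

    @property
    def gamma_v(self) -> np.ndarray:
        return self.velocity_scale

    @property
    def gamma_p(self) -> np.ndarray:
        return self.position_scale

    def normalize_position(self, position: np.ndarray) -> np.ndarray:
        return np.asarray(position, dtype=float) / self.position_scale[:, None]

    def normalize_velocity(self, velocity: np.ndarray) -> np.ndarray:
        return np.asarray(velocity, dtype=float) / self.velocity_scale[:, None]

    def denormalize_position(self, position_norm: np.ndarray) -> np.ndarray:
        return np.asarray(position_norm, dtype=float) * self.position_scale[:, None]

    def denormalize_velocity(self, velocity_norm: np.ndarray) -> np.ndarray:
        return np.asarray(velocity_norm, dtype=float) * self.velocity_scale[:, None]


def compute_velocity(position: np.ndarray, bin_width: float) -> np.ndarray:
    """Differentiate a (2, T) position trace numerically, cm -> cm/s.

    Interior bins use symmetric central differences (exact for
    polynomials of degree <= 2); the two endpoints use one-sided first
    differences so the velocity trace keeps the full trial length.
    """
    position = np.asarray(position, dtype=float)
    if position.ndim != 2 or position.shape[0] != 2:
        raise ValueError("position must be (2, T)")
    T = position.shape[1]
    if T < 3:
        raise ValueError("need at least 3 bins to differentiate")
    dt_s = bin_width / 1000.0
    vel = np.empty_like(position)
    vel[:, 1:-1] = (position[:, 2:] - position[:, :-2]) / (2.0 * dt_s)
    vel[:, 0] = (position[:, 1] - position[:, 0]) / dt_s
    vel[:, -1] = (position[:, -1] - position[:, -2]) / dt_s
    return vel


def fit_normalization(corpus: SessionCorpus) -> NormalizationSpec:
    """Per-dimension max-absolute scales over all training kinematics."""
    pos_max = np.zeros(2)
    vel_max = np.zeros(2)
    n = 0
    for trial in corpus.iter_trials():
        pos_max = np.maximum(pos_max, np.abs(trial.kin.position).max(axis=1))
        vel_max = np.maximum(vel_max, np.abs(trial.kin.velocity).max(axis=1))
        n += 1
    if n == 0:
        raise ValueError("cannot fit normalization on an empty corpus")
    if (pos_max == 0).any() or (vel_max == 0).any():
        raise ValueError("degenerate (all-zero) kinematic dimension")
    return NormalizationSpec(position_scale=pos_max, velocity_scale=vel_max)


# ---------------------------------------------------------------------------
# Corpus container I/O (HDF5 layout: /days/<idx>/trials/<idx>/{...})
# ---------------------------------------------------------------------------

_COND_FIELDS = ("day_gain", "electrode_gain", "baseline_offset", "pd_rotation")


def write_corpus(corpus: SessionCorpus, path) -> None:
    """Write a corpus to one HDF5 container file (lossless for counts)."""
    if corpus.n_days == 0 or not any(True for _ in corpus.iter_trials()):
        raise ValueError("refusing to write an empty corpus")
    with h5py.File(path, "w") as f:
        f.attrs["format"] = "robustbmi-corpus"
        f.attrs["version"] = 1
        f.attrs["bin_width_ms"] = corpus.bin_width
        f.attrs["n_electrodes"] = corpus.n_electrodes
        days_grp = f.create_group("days")
        for day_index, trials in corpus.days:
            dg = days_grp.create_group(str(day_index))
            tg = dg.create_group("trials")
            for trial in trials:
                g = tg.create_group(str(trial.trial_index))
                g.create_dataset("counts", data=trial.spikes.counts,
                                 dtype=np.int64)
                g.create_dataset("position", data=trial.kin.position)
                g.create_dataset("velocity", data=trial.kin.velocity)
                g.create_dataset("target", data=trial.target_position)
                g.create_dataset("start", data=trial.start_position)
            if corpus.condition_truth and day_index in corpus.condition_truth:
                cond = corpus.condition_truth[day_index]
                cg = dg.create_group("condition_truth")
                for name in _COND_FIELDS:
                    cg.create_dataset(name, data=np.asarray(getattr(cond, name)))
                if getattr(cond, "source_day", None) is not None:
                    cg.attrs["source_day"] = cond.source_day


def read_corpus(path) -> SessionCorpus:
    """Read a corpus container written by :func:`write_corpus`."""
    from .synthetic import RecordingConditionSpec  # local: avoid cycle

    with h5py.File(path, "r") as f:
        if f.attrs.get("format") != "robustbmi-corpus":
            raise ValueError(f"{path}: not a robustbmi corpus container")
        bin_width = float(f.attrs["bin_width_ms"])
        n_electrodes = int(f.attrs["n_electrodes"])
        days = []
        truth = {}
        for day_key in sorted(f["days"], key=int):
            day_index = int(day_key)
            dg = f["days"][day_key]
            trials = []
            for trial_key in sorted(dg["trials"], key=int):
                g = dg["trials"][trial_key]
                counts = g["counts"][()]
                if counts.shape[0] != n_electrodes:
                    raise ValueError(
                        f"{path}: day {day_index} trial {trial_key} has "
                        f"{counts.shape[0]} electrodes, expected {n_electrodes}"
                    )
                trials.append(Trial(
                    spikes=BinnedSpikeCounts(counts, bin_width),
                    kin=Kinematics2D(g["position"][()], g["velocity"][()],
                                     bin_width),
                    target_position=g["target"][()],
                    start_position=g["start"][()],
                    day_index=day_index,
                    trial_index=int(trial_key),
                ))
            days.append((day_index, trials))
            if "condition_truth" in dg:
                cg = dg["condition_truth"]
                truth[day_index] = RecordingConditionSpec(
                    day_gain=float(cg["day_gain"][()]),
                    electrode_gain=cg["electrode_gain"][()],
                    baseline_offset=cg["baseline_offset"][()],
                    pd_rotation=float(cg["pd_rotation"][()]),
                    source_day=(int(cg.attrs["source_day"])
                                if "source_day" in cg.attrs else None),
                )
    return SessionCorpus(days=days, condition_truth=truth or None)


def trial_to_csv(trial: Trial, path) -> None:
    """Plain CSV export of a single trial (one row per bin)."""
    T = trial.n_bins
    data = {
        "bin": np.arange(T),
        "time_ms": np.arange(T) * trial.spikes.bin_width,
        "pos_x_cm": trial.kin.position[0],
        "pos_y_cm": trial.kin.position[1],
        "vel_x_cmps": trial.kin.velocity[0],
        "vel_y_cmps": trial.kin.velocity[1],
    }
    for e, eid in enumerate(trial.spikes.electrode_ids):
        data[f"e{eid}"] = trial.spikes.counts[e]
    pd.DataFrame(data).to_csv(path, index=False)
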