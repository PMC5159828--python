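"""Model/Results surface for the two decoder families.

Follows the fit-from-data convention of statistical modelling packages:
a model object is constructed from a training corpus plus settings, its
``fit()`` returns a results object carrying the estimates (trained
parameters), fit diagnostics and a ``summary()`` table, and prediction,
scoring, closed-loop simulation and plotting hang off the results.

    >>> corpus, tuning = generate_corpus(5, 60, n_electrodes=32, seed=0)
    >>> res = MRNNDecoder(corpus, n_units=30, hf=HFConfig(total_steps=40,
    ...                   max_cg_iters=15)).fit()
    >>> print(res.summary())
    >>> res.score(corpus.day_trials(4))
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    NormalizationSpec,
    SessionCorpus,
    Trial,
    fit_normalization,
)
from .kalman import KFParams, fit_fit_kf, save_kf_params
from .mrnn import MRNNParams, count_params, save_params
from .protocols import offline_kf_velocity_r2, offline_velocity_r2
from .simulate import (
    FeedbackUserModel,
    KFCursorDecoder,
    MRNNCursorDecoder,
    TaskConfig,
    run_block,
)
from .training import HFConfig, PerturbationSpec, hf_train

__all__ = ["MRNNDecoder", "MRNNDecoderResults", "FITKalman",
           "FITKalmanResults"]


def _rule(width=64, char="="):
    return char * width


class MRNNDecoder:
    """Multiplicative-RNN BMI decoder model.

    Parameters
    ----------
    corpus : SessionCorpus
        Multi-day training data (binned counts + kinematics).
    n_units, n_factors : int
        Network size N and factor count F (F defaults to N).
    tau : float
        Network time constant, ms.
    hf : HFConfig
        Hessian-free optimizer settings.
    perturb : PerturbationSpec
        Spike-count augmentation scales; ``PerturbationSpec.none()``
        disables augmentation.
    outputs : {"both", "velocity"}
        Train the position/velocity pair, or the velocity network only
        (sufficient for offline accuracy, which uses beta = 1).
    """

    def __init__(self, corpus: SessionCorpus, n_units: int = 50,
                 n_factors: Optional[int] = None, tau: float = 100.0,
                 hf: Optional[HFConfig] = None,
                 perturb: Optional[PerturbationSpec] = None,
                 outputs: str = "both"):
        if outputs not in ("both", "velocity"):
            raise ValueError("outputs must be 'both' or 'velocity'")
        self.corpus = corpus
        self.n_units = n_units
        self.n_factors = n_factors if n_factors is not None else n_units
        self.tau = tau
        self.hf = hf if hf is not None else HFConfig()
        self.perturb = perturb if perturb is not None else PerturbationSpec()
        self.outputs = outputs

    def fit(self, warm_start: Optional["MRNNDecoderResults"] = None
            ) -> "MRNNDecoderResults":
        """Train with Hessian-free optimization; returns the results.

        ``warm_start`` reuses an earlier fit's weights as the training
        initial conditions (the fast path when retraining after adding
        new data).
        """
        import dataclasses

        norm = fit_normalization(self.corpus)
        init_vel = warm_start.velocity_params if warm_start else None
        cfg_vel = dataclasses.replace(self.hf, seed=self.hf.seed + 1)
        vel_params, vel_snaps, vel_hist = hf_train(
            self.corpus, cfg_vel, self.perturb, "velocity", norm,
            init_vel, n_units=self.n_units, n_factors=self.n_factors,
            tau=self.tau)
        pos_params = pos_snaps = pos_hist = None
        if self.outputs == "both":
            init_pos = warm_start.position_params if warm_start else None
            pos_params, pos_snaps, pos_hist = hf_train(
                self.corpus, self.hf, self.perturb, "position", norm,
                init_pos, n_units=self.n_units, n_factors=self.n_factors,
                tau=self.tau)
        return MRNNDecoderResults(
            model=self, normalization=norm,
            velocity_params=vel_params, position_params=pos_params,
            velocity_snapshots=vel_snaps, position_snapshots=pos_snaps,
            velocity_history=pd.DataFrame(vel_hist),
            position_history=(pd.DataFrame(pos_hist)
                              if pos_hist is not None else None))


@dataclass
class MRNNDecoderResults:
    """Fitted MRNN decoder: trained weights, diagnostics, simulation."""

    model: MRNNDecoder
    normalization: NormalizationSpec
    velocity_params: MRNNParams
    position_params: Optional[MRNNParams]
    velocity_snapshots: list
    position_snapshots: Optional[list]
    velocity_history: pd.DataFrame
    position_history: Optional[pd.DataFrame]

    @property
    def n_params(self) -> int:
        return self.velocity_params.n_params

    @property
    def heldout_loss(self) -> float:
        """Held-out loss of the selected velocity-network snapshot."""
        return min(s[1] for s in self.velocity_snapshots)

    def predict(self, counts, denormalize: bool = True) -> np.ndarray:
        """Decode velocity offline (beta = 1) from an (E, T) count array."""
        from .mrnn import run
        z = run(self.velocity_params, counts)
        return self.normalization.denormalize_velocity(z) if denormalize \
            else z

    def score(self, trials: Sequence[Trial]) -> float:
        """Offline velocity decode r^2 on held-out trials (beta = 1)."""
        return offline_velocity_r2(self.velocity_params,
                                   self.normalization, trials)

    def as_cursor_decoder(self, beta: float = 0.99) -> MRNNCursorDecoder:
        if self.position_params is None:
            raise ValueError(
                "closed-loop control needs the position network; "
                "fit with outputs='both'")
        return MRNNCursorDecoder(self.position_params,
                                 self.velocity_params,
                                 self.normalization, beta=beta)

    def simulate(self, tuning, condition, n_trials: int = 30,
                 user: Optional[FeedbackUserModel] = None,
                 task: Optional[TaskConfig] = None,
                 seed: int = 0, beta: float = 0.99,
                 dropped_electrodes: Sequence[int] = ()):
        """Run one closed-loop block with this decoder; see ``run_block``."""
        rng = np.random.default_rng(seed)
        return run_block(
            self.as_cursor_decoder(beta=beta),
            user if user is not None else FeedbackUserModel(),
            tuning, condition,
            task if task is not None else TaskConfig(),
            n_trials, rng, bin_width=self.velocity_params.dt,
            dropped_electrodes=dropped_electrodes)

    def save(self, path_velocity, path_position=None) -> None:
        save_params(self.velocity_params, path_velocity,
                    self.normalization)
        if path_position is not None and self.position_params is not None:
            save_params(self.position_params, path_position,
                        self.normalization)

    def plot_training(self, ax=None):
        """Training-loss and held-out snapshot curve for the velocity net."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        h = self.velocity_history
        ax.plot(h["step"], h["loss"], label="minibatch loss")
        steps, losses = zip(*[(s, l) for s, l, _ in self.velocity_snapshots])
        ax.plot(steps, losses, "o-", label="held-out loss (snapshots)")
        ax.set_xlabel("HF step")
        ax.set_ylabel("mean squared error")
        ax.set_yscale("log")
        ax.legend()
        return ax

    def summary(self) -> str:
        N, F, E, M = self.velocity_params.dims
        days = self.model.corpus.n_days
        n_trials = sum(1 for _ in self.model.corpus.iter_trials())
        h = self.velocity_history
        lines = [
            _rule(),
            "MRNN decoder fit (Hessian-free)",
            _rule(),
            f"{'Network size N':<32}{N:>12}",
            f"{'Factors F':<32}{F:>12}",
            f"{'Electrodes E':<32}{E:>12}",
            f"{'Outputs M':<32}{M:>12}",
            f"{'Trainable parameters':<32}{count_params(N, F, E, M):>12}",
            f"{'tau (ms)':<32}{self.velocity_params.tau:>12.1f}",
            f"{'dt (ms)':<32}{self.velocity_params.dt:>12.1f}",
            f"{'Training days':<32}{days:>12}",
            f"{'Training trials':<32}{n_trials:>12}",
            f"{'sigma_trial':<32}{self.model.perturb.sigma_trial:>12.3f}",
            f"{'sigma_electrode':<32}"
            f"{self.model.perturb.sigma_electrode:>12.3f}",
            f"{'HF steps run':<32}{len(h):>12}",
            f"{'Final minibatch loss':<32}"
            f"{h['new_loss'].iloc[-1] if len(h) else float('nan'):>12.5f}",
            f"{'Best held-out loss':<32}{self.heldout_loss:>12.5f}",
            f"{'Networks trained':<32}"
            f"{'pos+vel' if self.position_params is not None else 'vel':>12}",
            _rule(),
        ]
        return "\n".join(lines)


class FITKalman:
    """FIT Kalman-filter decoder model.

    ``variant`` selects the training-data policy: ``"sameday"`` (a given
    day's calibration reaches), ``"long"`` (all days pooled) or ``"old"``
    (the single most recent training day).  ``day`` optionally pins the
    day used by "sameday"/"old" (defaults to the last day present).
    """

    def __init__(self, corpus: SessionCorpus, variant: str = "sameday",
                 day: Optional[int] = None, dt: Optional[float] = None):
        if variant not in ("sameday", "long", "old"):
            raise ValueError("variant must be sameday | long | old")
        self.corpus = corpus
        self.variant = variant
        self.day = day
        self.dt = dt if dt is not None else corpus.bin_width

    def _training_trials(self) -> list:
        days = self.corpus.day_indices
        if self.variant == "long":
            return list(self.corpus.iter_trials())
        day = self.day if self.day is not None else days[-1]
        return self.corpus.day_trials(day)

    def fit(self) -> "FITKalmanResults":
        trials = self._training_trials()
        params = fit_fit_kf(trials, dt=self.dt)
        return FITKalmanResults(model=self, params=params,
                                n_training_trials=len(trials))


@dataclass
class FITKalmanResults:
    """Fitted FIT-KF: state-space matrices and decoding entry points."""

    model: FITKalman
    params: KFParams
    n_training_trials: int

    def predict(self, counts, cursor_positions=None):
        """Offline velocity decode with known-position feedback."""
        from .datamodel import BinnedSpikeCounts
        from .kalman import kf_decode
        if not isinstance(counts, BinnedSpikeCounts):
            counts = BinnedSpikeCounts(np.asarray(counts), self.params.dt)
        return kf_decode(self.params, counts,
                         cursor_positions=cursor_positions)

    def score(self, trials: Sequence[Trial]) -> float:
        """Offline velocity decode r^2 with true-position feedback."""
        return offline_kf_velocity_r2(self.params, trials)

    def as_cursor_decoder(self) -> KFCursorDecoder:
        return KFCursorDecoder(self.params)

    def simulate(self, tuning, condition, n_trials: int = 30,
                 user: Optional[FeedbackUserModel] = None,
                 task: Optional[TaskConfig] = None, seed: int = 0,
                 dropped_electrodes: Sequence[int] = ()):
        rng = np.random.default_rng(seed)
        return run_block(
            self.as_cursor_decoder(),
            user if user is not None else FeedbackUserModel(),
            tuning, condition,
            task if task is not None else TaskConfig(),
            n_trials, rng, bin_width=self.params.dt,
            dropped_electrodes=dropped_electrodes)

    def save(self, path) -> None:
        save_kf_params(self.params, path,
                       manifest={"variant": self.model.variant})

    def summary(self) -> str:
        E = self.params.n_electrodes
        vel_A = self.params.A[2:4, 2:5]
        lines = [
            _rule(),
            "FIT Kalman filter fit (maximum likelihood, "
            "intention-rotated kinematics)",
            _rule(),
            f"{'Variant':<32}{self.model.variant:>12}",
            f"{'Electrodes E':<32}{E:>12}",
            f"{'Bin width dt (ms)':<32}{self.params.dt:>12.1f}",
            f"{'Training trials':<32}{self.n_training_trials:>12}",
            f"{'State layout':<32}{'[px py vx vy 1]':>16}",
            "Velocity dynamics rows A[v, (vx vy 1)]:",
            "  " + np.array2string(vel_A, precision=4,
                                   suppress_small=True).replace("\n", "\n  "),
            f"{'tr(W) velocity noise':<32}"
            f"{np.trace(self.params.W[2:4, 2:4]):>12.4f}",
            f"{'mean diag(Q)':<32}"
            f"{float(np.mean(np.diag(self.params.Q))):>12.4f}",
            _rule(),
        ]
        return "\n".join(lines)
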