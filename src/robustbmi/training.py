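"""Hessian-free training of the MRNN on multiday corpora.

Training examples are 5-reach windows: five consecutive trials of a day
concatenated, the first two seeding the hidden state (no error) and the
last three scored.  Windows slide by one trial, so every trial past a
day's first two is learned from.

Each optimizer iteration (i) re-perturbs the spike counts of the sampled
sequences — multiplying each electrode's per-sequence total by trial-level
and electrode-level Gaussian gains of mean 1, then adding/removing spikes
at random bins — and (ii) samples the minibatch so that *every* training
day contributes, which is what lets one network learn many recording
conditions.  The squared-error loss is minimized with Hessian-free
optimization: back-propagation through time for the gradient, and damped
Gauss-Newton systems solved by conjugate gradient using matrix-vector
products (an R-op forward pass followed by an adjoint pass) instead of an
explicit curvature matrix.  Lambda follows the Levenberg-Marquardt
reduction-ratio heuristic.  Snapshots are taken periodically and the one
with the lowest held-out error is returned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from .datamodel import (
    NormalizationSpec,
    SessionCorpus,
    Trial,
    compute_velocity,
    fit_normalization,
)
from .mrnn import InitSpec, MRNNParams, init_mrnn

__all__ = [
    "TrainingSequence",
    "PerturbationSpec",
    "HFConfig",
    "build_training_sequences",
    "perturb_counts",
    "batch_loss",
    "batch_gradient",
    "gauss_newton_vector_product",
    "hf_train",
    "train_decoder_pair",
]

SEED_TRIALS = 2     # trials seeding the hidden state
LEARN_TRIALS = 3    # trials contributing error
WINDOW = SEED_TRIALS + LEARN_TRIALS
#: sd of the random initial hidden states used for training forward
#: passes.  A zero state is a saddle of the multiplicative recurrence
#: (J^u r vanishes at r = 0, so no gradient reaches the weights); random
#: training-time states break it, and drawing them afresh per sequence
#: and optimizer step trains the network to converge from *any* state —
#: closed-loop use visits states far from the reaching manifold, and the
#: network must recover rather than stay lost.  The two-trial seed span
#: absorbs the transient before any error is scored; evaluation and
#: closed-loop use start from the zero state.
TRAIN_STATE_INIT_SD = 0.5


@dataclass(frozen=True)
class TrainingSequence:
    """Five concatenated reaches: a seed span and a learn span."""

    counts: np.ndarray       # (E, T) int
    targets: np.ndarray      # (M, T) normalized kinematics
    seed_end: int            # bins [0, seed_end) seed the state
    day_index: int
    start_trial: int         # index of the first reach in the window

    @property
    def n_bins(self) -> int:
        return self.counts.shape[1]

    @property
    def learn_span(self) -> tuple:
        return (self.seed_end, self.n_bins)


@dataclass(frozen=True)
class PerturbationSpec:
    """Spike-count augmentation scales (Gaussian gains of mean one).

    ``sigma_trial`` scales a global per-sequence gain (array movement,
    arousal); ``sigma_electrode`` a per-electrode gain (dropped electrodes,
    moving baselines).  Both default to the values used for closed-loop
    decoding (0.045 and 0.3).
    """

    sigma_trial: float = 0.045
    sigma_electrode: float = 0.3

    def __post_init__(self):
        if self.sigma_trial < 0 or self.sigma_electrode < 0:
            raise ValueError("perturbation sigmas must be >= 0")

    @classmethod
    def none(cls) -> "PerturbationSpec":
        return cls(sigma_trial=0.0, sigma_electrode=0.0)


@dataclass(frozen=True)
class HFConfig:
    """Hessian-free optimizer settings.

    Defaults are the full-scale settings (minibatch one-fifth of the
    sequences, initial lambda 0.1, 50 CG iterations, 200 steps with a
    snapshot every 10); desk-scale runs shrink ``total_steps`` and
    ``max_cg_iters``.
    """

    minibatch_fraction: float = 0.2
    initial_lambda: float = 0.1
    max_cg_iters: int = 50
    total_steps: int = 200
    snapshot_interval: int = 10
    heldout_fraction: float = 0.1
    seed: int = 0
    lambda_factor: float = 1.5   # LM multiply/divide factor
    cg_tol: float = 1e-8

    def __post_init__(self):
        if not 0 < self.minibatch_fraction <= 1:
            raise ValueError("minibatch_fraction must be in (0, 1]")
        if self.max_cg_iters < 1 or self.total_steps < 1:
            raise ValueError("iteration counts must be >= 1")
        if not 0 <= self.heldout_fraction < 1:
            raise ValueError("heldout_fraction must be in [0, 1)")


def build_training_sequences(day_trials: Sequence[Trial],
                             norm: NormalizationSpec,
                             target_kind: str = "velocity"
                             ) -> List[TrainingSequence]:
    """Sliding 5-trial windows (stride 1) over one day's trials.

    ``target_kind`` selects normalized hand velocity or position targets.
    A day with fewer than 5 trials yields no sequences (with a warning).
    """
    if target_kind not in ("velocity", "position"):
        raise ValueError("target_kind must be 'velocity' or 'position'")
    trials = list(day_trials)
    if len(trials) < WINDOW:
        warnings.warn(
            f"day with {len(trials)} trials (< {WINDOW}) yields no "
            "training sequences", stacklevel=2)
        return []
    sequences = []
    for start in range(len(trials) - WINDOW + 1):
        window = trials[start:start + WINDOW]
        counts = np.concatenate([t.spikes.counts for t in window], axis=1)
        if target_kind == "velocity":
            kin = [norm.normalize_velocity(t.kin.velocity) for t in window]
        else:
            kin = [norm.normalize_position(t.kin.position) for t in window]
        targets = np.concatenate(kin, axis=1)
        seed_end = sum(t.n_bins for t in window[:SEED_TRIALS])
        sequences.append(TrainingSequence(
            counts=counts, targets=targets, seed_end=seed_end,
            day_index=window[0].day_index, start_trial=start))
    return sequences


def perturb_counts(seq_counts: np.ndarray, spec: PerturbationSpec,
                   rng: np.random.Generator) -> np.ndarray:
    """Augment one sequence's counts by scaled spike addition/removal.

    One trial-level gain eta_j and one per-electrode gain eta_c (both
    Gaussian, mean 1) set each electrode's target total
    n_hat = round(eta_j * eta_c * n); the pair is resampled for an
    electrode while n_hat falls outside [0, 2n], which keeps the expected
    perturbed total roughly equal to the true total.  Extra spikes go to
    uniformly random bins (increments allowed); removals strike uniformly
    random existing spike events.  Electrodes with no spikes are untouched.
    """
    counts = np.asarray(seq_counts)
    if counts.size == 0:
        return counts.copy()
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    E, T = counts.shape
    out = counts.copy()
    if spec.sigma_trial == 0.0 and spec.sigma_electrode == 0.0:
        return out
    eta_j = rng.normal(1.0, spec.sigma_trial)
    totals = counts.sum(axis=1)
    for e in range(E):
        n = int(totals[e])
        if n == 0:
            continue
        eta_c = rng.normal(1.0, spec.sigma_electrode)
        n_hat = int(round(eta_j * eta_c * n))
        while n_hat < 0 or n_hat > 2 * n:
            ej = rng.normal(1.0, spec.sigma_trial)
            eta_c = rng.normal(1.0, spec.sigma_electrode)
            n_hat = int(round(ej * eta_c * n))
        if n_hat > n:
            bins = rng.integers(0, T, size=n_hat - n)
            np.add.at(out[e], bins, 1)
        elif n_hat < n:
            events = np.repeat(np.arange(T), out[e])
            drop = rng.choice(events.size, size=n - n_hat, replace=False)
            np.subtract.at(out[e], events[drop], 1)
    return out


# ---------------------------------------------------------------------------
# batched forward / backward / curvature passes
# ---------------------------------------------------------------------------

class _Batch:
    """Padded batch arrays: U (E,T,B), targets (M,T,B), mask (T,B)."""

    __slots__ = ("U", "targets", "mask", "n_learn")

    def __init__(self, sequences: Sequence[TrainingSequence]):
        if len(sequences) == 0:
            raise ValueError("empty batch")
        E = sequences[0].counts.shape[0]
        M = sequences[0].targets.shape[0]
        T = max(s.n_bins for s in sequences)
        B = len(sequences)
        self.U = np.zeros((E, T, B))
        self.targets = np.zeros((M, T, B))
        self.mask = np.zeros((T, B), dtype=bool)
        for b, s in enumerate(sequences):
            n = s.n_bins
            self.U[:, :n, b] = s.counts
            self.targets[:, :n, b] = s.targets
            self.mask[s.seed_end:n, b] = True
        self.n_learn = int(self.mask.sum())


class _ForwardCache:
    __slots__ = ("r", "a", "c", "f", "Z")


def _forward(params: MRNNParams, batch: _Batch,
             x0: Optional[np.ndarray] = None) -> _ForwardCache:
    N, F, E, M = params.dims
    T, B = batch.mask.shape
    al = params.alpha
    cache = _ForwardCache()
    cache.r = np.zeros((T + 1, N, B))      # r[t+1] is the rate after bin t
    cache.a = np.empty((T, F, B))
    cache.c = np.empty((T, F, B))
    cache.f = np.empty((T, F, B))
    cache.Z = np.empty((M, T, B))
    if x0 is None:
        x = np.zeros((N, B))
    else:
        x0 = np.asarray(x0, float)
        if x0.ndim == 1:
            x = np.repeat(x0.reshape(N, 1), B, axis=1)
        else:
            x = x0.copy()
        cache.r[0] = np.tanh(x)
    for t in range(T):
        a = params.J_fu @ batch.U[:, t, :]
        c = params.J_fx @ cache.r[t]
        f = a * c
        x = (1.0 - al) * x + al * (params.J_xf @ f + params.b_x[:, None])
        r = np.tanh(x)
        cache.a[t], cache.c[t], cache.f[t] = a, c, f
        cache.r[t + 1] = r
        cache.Z[:, t, :] = params.W_o @ r + params.b_z[:, None]
    return cache


def _loss_from_cache(cache: _ForwardCache, batch: _Batch) -> float:
    err = (cache.Z - batch.targets) * batch.mask[None, :, :]
    M = batch.targets.shape[0]
    return float((err ** 2).sum() / (M * batch.n_learn))


def _backward(params: MRNNParams, batch: _Batch, cache: _ForwardCache,
              e: np.ndarray) -> np.ndarray:
    """Adjoint pass: given dL/dz = e (M,T,B), return the flat gradient."""
    N, F, E, M = params.dims
    T, B = batch.mask.shape
    al = params.alpha
    gJ_xf = np.zeros((N, F)); gJ_fu = np.zeros((F, E))
    gJ_fx = np.zeros((F, N)); gb_x = np.zeros(N)
    gW_o = np.zeros((M, N)); gb_z = np.zeros(M)
    delta_next = np.zeros((N, B))
    dr_carry = np.zeros((N, B))
    for t in range(T - 1, -1, -1):
        e_t = e[:, t, :]
        r_t = cache.r[t + 1]
        gW_o += e_t @ r_t.T
        gb_z += e_t.sum(axis=1)
        g_r = params.W_o.T @ e_t + dr_carry
        delta = g_r * (1.0 - r_t ** 2) + (1.0 - al) * delta_next
        dh = al * delta
        gJ_xf += dh @ cache.f[t].T
        gb_x += dh.sum(axis=1)
        df = params.J_xf.T @ dh
        da = df * cache.c[t]
        dc = df * cache.a[t]
        gJ_fu += da @ batch.U[:, t, :].T
        gJ_fx += dc @ cache.r[t].T
        dr_carry = params.J_fx.T @ dc
        delta_next = delta
    return np.concatenate([gJ_xf.ravel(), gJ_fu.ravel(), gJ_fx.ravel(),
                           gb_x, gW_o.ravel(), gb_z])


def batch_loss(params: MRNNParams,
               sequences: Sequence[TrainingSequence],
               x0: Optional[np.ndarray] = None) -> float:
    """Mean squared error over learn-span bins only (seed spans excluded)."""
    batch = _Batch(sequences)
    return _loss_from_cache(_forward(params, batch, x0), batch)


def batch_gradient(params: MRNNParams,
                   sequences: Sequence[TrainingSequence],
                   x0: Optional[np.ndarray] = None) -> np.ndarray:
    """Exact BPTT gradient of :func:`batch_loss`, flattened."""
    batch = _Batch(sequences)
    cache = _forward(params, batch, x0)
    M = batch.targets.shape[0]
    e = 2.0 * (cache.Z - batch.targets) * batch.mask[None, :, :]
    e /= (M * batch.n_learn)
    return _backward(params, batch, cache, e)


def _r_forward(params: MRNNParams, batch: _Batch, cache: _ForwardCache,
               V: MRNNParams) -> np.ndarray:
    """R-op: directional derivative Rz (M,T,B) of outputs along V."""
    N, F, E, M = params.dims
    T, B = batch.mask.shape
    al = params.alpha
    Rz = np.empty((M, T, B))
    Rx = np.zeros((N, B))
    Rr = np.zeros((N, B))
    for t in range(T):
        Ra = V.J_fu @ batch.U[:, t, :]
        Rc = V.J_fx @ cache.r[t] + params.J_fx @ Rr
        Rf = Ra * cache.c[t] + cache.a[t] * Rc
        Rh = V.J_xf @ cache.f[t] + params.J_xf @ Rf + V.b_x[:, None]
        Rx = (1.0 - al) * Rx + al * Rh
        r_t = cache.r[t + 1]
        Rr = (1.0 - r_t ** 2) * Rx
        Rz[:, t, :] = V.W_o @ r_t + params.W_o @ Rr + V.b_z[:, None]
    return Rz


def gauss_newton_vector_product(params: MRNNParams,
                                sequences: Sequence[TrainingSequence],
                                v: np.ndarray,
                                lam: float = 0.0,
                                x0: Optional[np.ndarray] = None,
                                _batch: Optional[_Batch] = None,
                                _cache: Optional[_ForwardCache] = None
                                ) -> np.ndarray:
    """(G + lam I) v for the Gauss-Newton matrix G of the MSE loss.

    Computed matrix-free: an R-op forward pass gives the output-space
    directional derivative Jv, which the loss Hessian (a scaled identity
    on learn bins) reweights before the adjoint pass applies J^T.
    """
    batch = _Batch(sequences) if _batch is None else _batch
    cache = _forward(params, batch, x0) if _cache is None else _cache
    V = params.with_vector(np.asarray(v, dtype=float))
    Rz = _r_forward(params, batch, cache, V)
    M = batch.targets.shape[0]
    e = 2.0 * Rz * batch.mask[None, :, :] / (M * batch.n_learn)
    Gv = _backward(params, batch, cache, e)
    if lam != 0.0:
        Gv = Gv + lam * np.asarray(v, dtype=float)
    return Gv


def _cg(matvec, b: np.ndarray, max_iters: int, tol: float) -> np.ndarray:
    """Plain conjugate gradient from a zero start."""
    x = np.zeros_like(b)
    r = b.copy()
    p = r.copy()
    rs = float(r @ r)
    b_norm = np.sqrt(float(b @ b))
    if b_norm == 0.0:
        return x
    for _ in range(max_iters):
        Ap = matvec(p)
        pAp = float(p @ Ap)
        if pAp <= 0:
            break  # numerical loss of positive-definiteness
        alpha = rs / pAp
        x += alpha * p
        r -= alpha * Ap
        rs_new = float(r @ r)
        if np.sqrt(rs_new) <= tol * b_norm:
            break
        p = r + (rs_new / rs) * p
        rs = rs_new
    return x


# ---------------------------------------------------------------------------
# the HF training loop
# ---------------------------------------------------------------------------

def _split_heldout(per_day: dict, fraction: float):
    """Last ``fraction`` of each day's sequences is held out."""
    train, heldout = {}, []
    for day, seqs in per_day.items():
        n_held = int(np.ceil(fraction * len(seqs))) if fraction > 0 else 0
        n_held = min(n_held, len(seqs) - 1) if len(seqs) > 1 else 0
        if n_held > 0:
            train[day] = seqs[:-n_held]
            heldout.extend(seqs[-n_held:])
        else:
            train[day] = list(seqs)
    return train, heldout


def _sample_minibatch(per_day: dict, fraction: float,
                      rng: np.random.Generator):
    """>= 1 sequence from every day; about ``fraction`` of the total."""
    batch = []
    for seqs in per_day.values():
        k = max(1, int(round(fraction * len(seqs))))
        idx = rng.choice(len(seqs), size=min(k, len(seqs)), replace=False)
        batch.extend(seqs[i] for i in idx)
    return batch


def hf_train(corpus: SessionCorpus,
             config: Optional[HFConfig] = None,
             perturb: Optional[PerturbationSpec] = None,
             target_kind: str = "velocity",
             norm: Optional[NormalizationSpec] = None,
             init_params: Optional[MRNNParams] = None,
             n_units: int = 50,
             n_factors: Optional[int] = None,
             tau: float = 100.0) -> tuple:
    """Train one MRNN on a (possibly multiday) corpus with HF.

    Returns ``(best_params, snapshots, history)`` where ``snapshots`` is a
    list of ``(step, heldout_loss, params)`` and ``best_params`` is the
    snapshot with the lowest held-out loss.  ``init_params`` warm-starts
    from an existing decoder (used when retraining with added data).
    """
    config = config if config is not None else HFConfig()
    perturb = perturb if perturb is not None else PerturbationSpec()
    norm = norm if norm is not None else fit_normalization(corpus)
    rng = np.random.default_rng(config.seed)

    per_day = {}
    for day, trials in corpus.days:
        seqs = build_training_sequences(trials, norm, target_kind)
        if seqs:
            per_day[day] = seqs
    if not per_day:
        raise ValueError("corpus yields no training sequences")
    train_days, heldout = _split_heldout(per_day, config.heldout_fraction)
    if not heldout:  # degenerate fallback: validate on training sequences
        heldout = [s for seqs in train_days.values() for s in seqs]

    E = corpus.n_electrodes
    dt = corpus.bin_width
    if init_params is not None:
        params = init_params.copy()
    else:
        F = n_factors if n_factors is not None else n_units
        params = init_mrnn(n_units, F, E, 2,
                           InitSpec(seed=int(rng.integers(2 ** 31))),
                           tau=tau, dt=dt)

    N = params.dims[0]
    lam = config.initial_lambda
    heldout_loss = batch_loss(params, heldout)   # deployment zero state
    snapshots = [(0, heldout_loss, params.copy())]
    history = []
    theta = params.to_vector()

    for step_i in range(1, config.total_steps + 1):
        sampled = _sample_minibatch(train_days, config.minibatch_fraction,
                                    rng)
        # data augmentation anew each iteration
        if perturb.sigma_trial > 0 or perturb.sigma_electrode > 0:
            sampled = [
                TrainingSequence(
                    counts=perturb_counts(s.counts, perturb, rng),
                    targets=s.targets, seed_end=s.seed_end,
                    day_index=s.day_index, start_trial=s.start_trial)
                for s in sampled
            ]
        batch = _Batch(sampled)
        x0 = rng.normal(0.0, TRAIN_STATE_INIT_SD,
                        size=(N, len(sampled)))
        cache = _forward(params, batch, x0)
        loss0 = _loss_from_cache(cache, batch)
        if not np.isfinite(loss0):
            raise FloatingPointError(
                f"training diverged at step {step_i}: loss={loss0}")
        Mdim = batch.targets.shape[0]
        e = (2.0 * (cache.Z - batch.targets) * batch.mask[None, :, :]
             / (Mdim * batch.n_learn))
        grad = _backward(params, batch, cache, e)

        def matvec(p_vec):
            return gauss_newton_vector_product(
                params, sampled, p_vec, lam=lam, x0=x0,
                _batch=batch, _cache=cache)

        delta = _cg(matvec, -grad, config.max_cg_iters, config.cg_tol)
        # LM reduction ratio: actual vs quadratic-model improvement
        q_red = float(grad @ delta + 0.5 * (delta @ matvec(delta)))
        candidate = params.with_vector(theta + delta)
        loss1 = batch_loss(candidate, sampled, x0)
        rho = (loss1 - loss0) / q_red if q_red < 0 else -np.inf
        if rho > 0.75:
            lam /= config.lambda_factor
        elif rho < 0.25:
            lam *= config.lambda_factor
        if loss1 < loss0:
            params = candidate
            theta = params.to_vector()
            accepted = True
        else:
            accepted = False
        history.append({"step": step_i, "loss": loss0, "new_loss": loss1,
                        "lambda": lam, "rho": rho, "accepted": accepted,
                        "minibatch": len(sampled)})
        if step_i % config.snapshot_interval == 0 \
                or step_i == config.total_steps:
            heldout_loss = batch_loss(params, heldout)
            snapshots.append((step_i, heldout_loss, params.copy()))

    best = min(snapshots, key=lambda s: s[1])
    return best[2], snapshots, history


def train_decoder_pair(corpus: SessionCorpus,
                       config: Optional[HFConfig] = None,
                       perturb: Optional[PerturbationSpec] = None,
                       warm_start: Optional[tuple] = None,
                       n_units: int = 50,
                       n_factors: Optional[int] = None,
                       tau: float = 100.0) -> tuple:
    """Train the position/velocity MRNN pair sharing one normalization.

    Returns ``(position_params, velocity_params, norm)``.  ``warm_start``
    optionally supplies ``(position_params, velocity_params)`` from an
    earlier training as initial conditions.
    """
    config = config if config is not None else HFConfig()
    norm = fit_normalization(corpus)
    init_pos = init_vel = None
    if warm_start is not None:
        init_pos, init_vel = warm_start
    import dataclasses
    cfg_pos = config
    cfg_vel = dataclasses.replace(config, seed=config.seed + 1)
    pos_params, _, _ = hf_train(
        corpus, cfg_pos, perturb, "position", norm, init_pos,
        n_units=n_units, n_factors=n_factors, tau=tau)
    vel_params, _, _ = hf_train(
        corpus, cfg_vel, perturb, "velocity", norm, init_vel,
        n_units=n_units, n_factors=n_factors, tau=tau)
    return pos_params, vel_params, norm
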