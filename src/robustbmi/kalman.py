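"""The FIT Kalman-filter baseline decoder.

A linear dynamical system over the kinematic state
z = [p_x, p_y, v_x, v_y, 1] (positions cm, velocities cm/s, constant bias)
observed through binned spike counts y:

    z(t+dt) = A z(t) + w,   w ~ N(0, W)
    y(t)    = C z(t) + q,   q ~ N(0, Q)

fit by maximum likelihood (least squares) on *intention-rotated* training
kinematics: each measured velocity is rotated to point from the cursor
straight at the target (magnitude preserved; zeroed inside the target
acceptance window), encoding the assumption that the user always intends
to move directly to the target.  At decode time the filter assumes the
user knows the cursor position perfectly via visual feedback: the
position estimate's covariance is pinned to zero (position is treated as
known) and the neural activity explainable by that known position is
subtracted from the observation before the velocity update.

Position rows of A implement kinematic integration p <- p + v dt and are
not fit; velocity rows are regressed on [v, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import h5py
import numpy as np

from .datamodel import BinnedSpikeCounts, Kinematics2D, Trial

__all__ = [
    "KFParams",
    "KFState",
    "rotate_intention",
    "fit_lds_ml",
    "fit_fit_kf",
    "kf_decode_step",
    "kf_decode",
    "save_kf_params",
    "load_kf_params",
]

STATE_DIM = 5
_POS = slice(0, 2)
_VEL = slice(2, 4)
DEFAULT_KF_BIN_MS = 25.0  # standalone default; synthetic comparisons
                          # run at the corpus bin width

#: target acceptance window (cm, full width) used for the inside-target
#: velocity-zeroing rule during intention rotation
ACCEPTANCE_WINDOW_CM = 4.0


@dataclass
class KFParams:
    """State-space matrices with state layout [p_x, p_y, v_x, v_y, 1]."""

    A: np.ndarray    # (5, 5)
    C: np.ndarray    # (E, 5)
    W: np.ndarray    # (5, 5) PSD
    Q: np.ndarray    # (E, E) PSD
    dt: float        # ms

    def __post_init__(self):
        if self.A.shape != (STATE_DIM, STATE_DIM):
            raise ValueError("A must be 5x5")
        if self.W.shape != (STATE_DIM, STATE_DIM):
            raise ValueError("W must be 5x5")
        E = self.C.shape[0]
        if self.C.shape != (E, STATE_DIM) or self.Q.shape != (E, E):
            raise ValueError("C/Q shapes inconsistent")
        if not np.allclose(self.W, self.W.T, atol=1e-8):
            raise ValueError("W must be symmetric")
        if not np.allclose(self.Q, self.Q.T, atol=1e-8):
            raise ValueError("Q must be symmetric")

    @property
    def n_electrodes(self) -> int:
        return self.C.shape[0]


@dataclass
class KFState:
    """Filter state: mean and covariance (position/bias rows pinned)."""

    mean: np.ndarray        # (5,)
    covariance: np.ndarray  # (5, 5)

    @classmethod
    def initial(cls, cursor_pos=np.zeros(2)) -> "KFState":
        mean = np.zeros(STATE_DIM)
        mean[_POS] = cursor_pos
        mean[4] = 1.0
        return cls(mean=mean, covariance=np.zeros((STATE_DIM, STATE_DIM)))


def rotate_intention(kin: Kinematics2D, cursor_pos: np.ndarray,
                     target_pos: np.ndarray,
                     window_cm: float = ACCEPTANCE_WINDOW_CM) -> Kinematics2D:
    """Rotate each velocity to point from cursor toward target.

    Speed is preserved bin by bin; inside the target acceptance window
    (|dx| and |dy| both < window/2) the intended velocity is zero.
    Positions are unchanged.
    """
    cursor_pos = np.asarray(cursor_pos, dtype=float)
    target_pos = np.asarray(target_pos, dtype=float)
    if cursor_pos.shape != kin.position.shape \
            or target_pos.shape != kin.position.shape:
        raise ValueError("cursor/target trajectories must be (2, T)")
    to_target = target_pos - cursor_pos
    dist = np.linalg.norm(to_target, axis=0)
    speed = np.linalg.norm(kin.velocity, axis=0)
    inside = (np.abs(to_target) < window_cm / 2.0).all(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = np.where(dist > 0, to_target / np.where(dist > 0, dist, 1.0),
                        0.0)
    velocity = unit * speed[None, :]
    velocity[:, inside] = 0.0
    return Kinematics2D(position=kin.position.copy(), velocity=velocity,
                        bin_width=kin.bin_width)


def _states_from_kin(kin: Kinematics2D) -> np.ndarray:
    T = kin.n_bins
    Z = np.empty((STATE_DIM, T))
    Z[_POS] = kin.position
    Z[_VEL] = kin.velocity
    Z[4] = 1.0
    return Z


def fit_lds_ml(counts_per_trial: Sequence[np.ndarray],
               kin_per_trial: Sequence[Kinematics2D],
               dt: Optional[float] = None,
               diag_load: float = 1e-6) -> KFParams:
    """Maximum-likelihood (least-squares) fit of the constrained LDS.

    Velocity rows of A (and the matching block of W) are regressed on
    [v_x, v_y, 1] over consecutive state pairs; position rows are fixed to
    kinematic integration p <- p + v dt.  C and Q come from regressing
    counts on the full state.  Q gets a small diagonal load so it stays
    invertible when electrodes outnumber bins.
    """
    if len(counts_per_trial) != len(kin_per_trial) or not counts_per_trial:
        raise ValueError("need matching, non-empty counts and kinematics")
    if dt is None:
        dt = kin_per_trial[0].bin_width
    dt_s = dt / 1000.0

    Z_list = [_states_from_kin(k) for k in kin_per_trial]
    # consecutive pairs within trials only
    prev = np.concatenate([Z[:, :-1] for Z in Z_list if Z.shape[1] >= 2],
                          axis=1)
    nxt = np.concatenate([Z[:, 1:] for Z in Z_list if Z.shape[1] >= 2],
                         axis=1)
    if prev.shape[1] < 2:
        raise ValueError("need at least 2 consecutive bins to fit dynamics")

    # velocity rows on regressors [v_x, v_y, 1]
    X = prev[[2, 3, 4], :]                      # (3, T-1)
    Yv = nxt[_VEL]                              # (2, T-1)
    G = X @ X.T
    try:
        coef = np.linalg.solve(G, X @ Yv.T).T   # (2, 3)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "rank-deficient velocity regressors (state dims 2-4)") from exc
    A = np.zeros((STATE_DIM, STATE_DIM))
    A[0, 0] = A[1, 1] = 1.0
    A[0, 2] = A[1, 3] = dt_s
    A[2:4, [2, 3, 4]] = coef
    A[4, 4] = 1.0
    resid_v = Yv - coef @ X
    W = np.zeros((STATE_DIM, STATE_DIM))
    W[2:4, 2:4] = resid_v @ resid_v.T / resid_v.shape[1]

    # observation model: counts on full states
    Yc = np.concatenate([np.asarray(c, dtype=float)
                         for c in counts_per_trial], axis=1)
    Zs = np.concatenate(Z_list, axis=1)
    if Yc.shape[1] != Zs.shape[1]:
        raise ValueError("counts and kinematics bin totals differ")
    Gz = Zs @ Zs.T
    # drop degenerate state dimensions (e.g., rotated training kinematics
    # following straight-line reaches can make dimensions collinear)
    try:
        C = np.linalg.solve(Gz + diag_load * np.eye(STATE_DIM),
                            Zs @ Yc.T).T
    except np.linalg.LinAlgError as exc:
        raise ValueError("rank-deficient state regressors") from exc
    resid = Yc - C @ Zs
    Q = resid @ resid.T / Yc.shape[1]
    Q = (Q + Q.T) / 2.0 + diag_load * np.eye(Q.shape[0])
    return KFParams(A=A, C=C, W=W, Q=Q, dt=dt)


def fit_fit_kf(trials: Iterable[Trial], dt: Optional[float] = None,
               window_cm: float = ACCEPTANCE_WINDOW_CM) -> KFParams:
    """Fit a FIT-KF from reach trials: rotate intentions, then fit the LDS.

    During training the hand controls the cursor, so the cursor trajectory
    is the hand position and the target is the trial's target position.
    """
    trials = list(trials)
    if not trials:
        raise ValueError("no training trials")
    counts, kins = [], []
    for tr in trials:
        target_traj = np.repeat(tr.target_position[:, None], tr.n_bins,
                                axis=1)
        rotated = rotate_intention(tr.kin, tr.kin.position, target_traj,
                                   window_cm=window_cm)
        counts.append(tr.spikes.counts)
        kins.append(rotated)
    return fit_lds_ml(counts, kins, dt=dt)


def _pin_position(mean: np.ndarray, cov: np.ndarray,
                  cursor_pos: np.ndarray) -> None:
    """Treat position (and bias) as known: zero their uncertainty."""
    mean[_POS] = cursor_pos
    mean[4] = 1.0
    cov[0:2, :] = 0.0
    cov[:, 0:2] = 0.0
    cov[4, :] = 0.0
    cov[:, 4] = 0.0


def kf_decode_step(params: KFParams, state: KFState, y: np.ndarray,
                   cursor_pos: np.ndarray) -> KFState:
    """One predict/update cycle with the position-feedback modifications.

    (i) the position estimate is pinned to the known cursor position with
    zero covariance before and after the update; (ii) the observation used
    for the velocity update is the residual after subtracting the neural
    activity explained by the known position (and bias), which the pinned
    prediction mean implements.
    """
    y = np.asarray(y, dtype=float)
    mean = params.A @ state.mean
    cov = params.A @ state.covariance @ params.A.T + params.W
    _pin_position(mean, cov, np.asarray(cursor_pos, dtype=float))
    # innovation: y - C mean subtracts C_pos p_known (and bias) exactly
    S = params.C @ cov @ params.C.T + params.Q
    try:
        K = cov @ params.C.T @ np.linalg.inv(S)
    except np.linalg.LinAlgError:
        S = (S + S.T) / 2.0 + 1e-9 * np.eye(S.shape[0])
        K = cov @ params.C.T @ np.linalg.inv(S)
    innov = y - params.C @ mean
    mean = mean + K @ innov
    # Joseph-form update: PSD-stable even for near-singular Q
    IKC = np.eye(STATE_DIM) - K @ params.C
    cov = IKC @ cov @ IKC.T + K @ params.Q @ K.T
    cov = (cov + cov.T) / 2.0
    _pin_position(mean, cov, np.asarray(cursor_pos, dtype=float))
    eigmin = np.linalg.eigvalsh(cov).min()
    if eigmin < -1e-8:
        raise FloatingPointError(
            f"covariance lost positive semidefiniteness (min eig {eigmin})")
    return KFState(mean=mean, covariance=cov)


def kf_decode(params: KFParams, counts: BinnedSpikeCounts,
              cursor_positions: Optional[np.ndarray] = None) -> Kinematics2D:
    """Decode a full sequence of counts.

    In offline mode ``cursor_positions`` (2, T) supplies the true cursor
    (hand) trajectory as the known position feedback; closed-loop callers
    instead step the filter bin by bin with the simulated cursor.
    Returns decoded kinematics (position integrated from the decoded
    velocity; velocity is the decoder output of record).
    """
    if not np.isclose(counts.bin_width, params.dt):
        raise ValueError(
            f"counts bin width {counts.bin_width} != KF dt {params.dt}")
    T = counts.n_bins
    if cursor_positions is None:
        cursor_positions = np.zeros((2, T))
    cursor_positions = np.asarray(cursor_positions, dtype=float)
    state = KFState.initial(cursor_positions[:, 0] if T else np.zeros(2))
    vel = np.empty((2, T))
    pos = np.empty((2, T))
    dt_s = params.dt / 1000.0
    p = cursor_positions[:, 0].copy() if T else np.zeros(2)
    for t in range(T):
        state = kf_decode_step(params, state, counts.counts[:, t],
                               cursor_positions[:, t])
        vel[:, t] = state.mean[_VEL]
        p = p + vel[:, t] * dt_s
        pos[:, t] = p
    return Kinematics2D(position=pos, velocity=vel,
                        bin_width=counts.bin_width)


def save_kf_params(params: KFParams, path, manifest: Optional[dict] = None):
    with h5py.File(path, "w") as f:
        f.attrs["format"] = "robustbmi-fitkf"
        f.attrs["dt_ms"] = params.dt
        for name in ("A", "C", "W", "Q"):
            f.create_dataset(name, data=getattr(params, name))
        if manifest:
            g = f.create_group("manifest")
            for k, v in manifest.items():
                g.attrs[k] = v


def load_kf_params(path) -> KFParams:
    with h5py.File(path, "r") as f:
        if f.attrs.get("format") != "robustbmi-fitkf":
            raise ValueError(f"{path}: not a FIT-KF parameter bundle")
        return KFParams(A=f["A"][()], C=f["C"][()], W=f["W"][()],
                        Q=f["Q"][()], dt=float(f.attrs["dt_ms"]))
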