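"""The multiplicative RNN (MRNN) decoder network.

A standard rate RNN injects its input as an additive bias.  The MRNN
instead lets the input *reparameterize the recurrent weight matrix* at
every time step: conceptually the network holds an N x N weight matrix per
possible input value, which is made tractable by factorizing that tensor
through F multiplicative factors,

    J^u r  =  J_xf . ( (J_fu u) * (J_fx r) )        (elementwise product)

so the input selects, softly, which neural-to-kinematic mapping is in
force.  Dynamics are leaky (continuous-time, discretized by first-order
Euler with step dt and time constant tau), keeping the decoded output
smooth:

    x <- (1 - dt/tau) x + (dt/tau) (J^u r + b_x),   r = tanh(x)
    z = W_o r + b_z

Inputs u are raw integer spike counts per bin; the trained J_fu absorbs
their scale, so users of real data must feed the same units used in
training.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import h5py
import numpy as np

from .datamodel import BinnedSpikeCounts, NormalizationSpec

__all__ = [
    "MRNNParams",
    "InitSpec",
    "MRNNState",
    "init_mrnn",
    "apply_input_dependent_recurrence",
    "step",
    "readout",
    "run",
    "count_params",
    "save_params",
    "load_params",
]


@dataclass(frozen=True)
class InitSpec:
    """Gaussian initialization scales: Var(J) = g / fan-in, g default 1."""

    g_xf: float = 1.0
    g_fu: float = 1.0
    g_fx: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if min(self.g_xf, self.g_fu, self.g_fx) < 0:
            raise ValueError("init gains must be >= 0")


@dataclass
class MRNNParams:
    """Factorized MRNN weights and the trained readout.

    Trainable set: {J_xf, J_fu, J_fx, b_x, W_o, b_z}; tau and dt are
    architectural constants.
    """

    J_xf: np.ndarray   # (N, F)
    J_fu: np.ndarray   # (F, E)
    J_fx: np.ndarray   # (F, N)
    b_x: np.ndarray    # (N,)
    W_o: np.ndarray    # (M, N)
    b_z: np.ndarray    # (M,)
    tau: float         # ms
    dt: float          # ms

    def __post_init__(self):
        if not (0 < self.dt <= self.tau):
            raise ValueError("require 0 < dt <= tau")
        N, F = self.J_xf.shape
        if self.J_fu.shape[0] != F or self.J_fx.shape != (F, N):
            raise ValueError("factor matrix shapes inconsistent")
        if self.b_x.shape != (N,):
            raise ValueError("b_x shape inconsistent")
        M = self.W_o.shape[0]
        if self.W_o.shape != (M, N) or self.b_z.shape != (M,):
            raise ValueError("readout shapes inconsistent")
        for a in (self.J_xf, self.J_fu, self.J_fx, self.b_x,
                  self.W_o, self.b_z):
            if not np.isfinite(a).all():
                raise ValueError("parameters must be finite")

    @property
    def dims(self) -> tuple:
        """(N, F, E, M)."""
        N, F = self.J_xf.shape
        return (N, F, self.J_fu.shape[1], self.W_o.shape[0])

    @property
    def alpha(self) -> float:
        """Euler leak coefficient dt/tau."""
        return self.dt / self.tau

    @property
    def n_params(self) -> int:
        return count_params(*self.dims)

    # -- flat-vector views used by the optimizer ---------------------------
    _BLOCKS = ("J_xf", "J_fu", "J_fx", "b_x", "W_o", "b_z")

    def to_vector(self) -> np.ndarray:
        return np.concatenate(
            [getattr(self, name).ravel() for name in self._BLOCKS])

    def with_vector(self, vec: np.ndarray) -> "MRNNParams":
        out = {}
        offset = 0
        for name in self._BLOCKS:
            shape = getattr(self, name).shape
            size = int(np.prod(shape))
            out[name] = vec[offset:offset + size].reshape(shape).copy()
            offset += size
        if offset != vec.size:
            raise ValueError("vector length does not match parameter count")
        return replace(self, **out)

    def copy(self) -> "MRNNParams":
        return replace(self, **{n: getattr(self, n).copy()
                                for n in self._BLOCKS})


@dataclass
class MRNNState:
    """Network state: activations x and rates r = tanh(x)."""

    x: np.ndarray
    r: np.ndarray = None

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        if self.r is None:
            self.r = np.tanh(self.x)
        elif not np.allclose(self.r, np.tanh(self.x), atol=1e-12):
            raise ValueError("state invariant r == tanh(x) violated")

    @classmethod
    def zeros(cls, n_units: int) -> "MRNNState":
        return cls(x=np.zeros(n_units))


def count_params(N: int, F: int, E: int, M: int) -> int:
    """Number of trainable parameters in {J_xf, J_fu, J_fx, b_x, W_o, b_z}."""
    if min(N, F, E, M) < 1:
        raise ValueError("all dimensions must be >= 1")
    return N * F + F * E + F * N + N + M * N + M


def init_mrnn(N: int, F: int, E: int, M: int,
              init: Optional[InitSpec] = None,
              tau: float = 100.0, dt: float = 20.0) -> MRNNParams:
    """Fresh MRNN: Gaussian factor matrices, zero readout and biases.

    J entries are drawn N(0, g/fan) with fans F, E and N respectively, so
    the factored recurrence starts at unit dynamic range; W_o, b_x and b_z
    start at zero, making the initial readout identically zero.
    """
    if min(N, F, E, M) < 1:
        raise ValueError("all dimensions must be >= 1")
    init = init if init is not None else InitSpec()
    rng = np.random.default_rng(init.seed)
    return MRNNParams(
        J_xf=rng.normal(0.0, np.sqrt(init.g_xf / F), size=(N, F)),
        J_fu=rng.normal(0.0, np.sqrt(init.g_fu / E), size=(F, E)),
        J_fx=rng.normal(0.0, np.sqrt(init.g_fx / N), size=(F, N)),
        b_x=np.zeros(N),
        W_o=np.zeros((M, N)),
        b_z=np.zeros(M),
        tau=tau, dt=dt,
    )


def apply_input_dependent_recurrence(params: MRNNParams, u: np.ndarray,
                                     r: np.ndarray) -> np.ndarray:
    """J^u r through the factorization, never forming the N x N x |u| tensor.

    Accepts vectors (E,), (N,) or batches (E, B), (N, B).
    """
    u = np.asarray(u, dtype=float)
    r = np.asarray(r, dtype=float)
    N, F, E, _ = params.dims
    if u.shape[0] != E or r.shape[0] != N:
        raise ValueError(
            f"input/rate shapes {u.shape}/{r.shape} do not match dims E={E}, N={N}")
    return params.J_xf @ ((params.J_fu @ u) * (params.J_fx @ r))


def step(params: MRNNParams, state: MRNNState, u: np.ndarray) -> MRNNState:
    """One Euler step of the leaky MRNN dynamics."""
    a = params.alpha
    drive = apply_input_dependent_recurrence(params, u, state.r) + params.b_x
    x = (1.0 - a) * state.x + a * drive
    return MRNNState(x=x)


def readout(params: MRNNParams, state: MRNNState) -> np.ndarray:
    """z = W_o r + b_z."""
    return params.W_o @ state.r + params.b_z


def run(params: MRNNParams, U, x0: Optional[np.ndarray] = None,
        return_state: bool = False):
    """Run the network over a (E, T) count matrix; returns (M, T) outputs.

    ``U`` may be a :class:`BinnedSpikeCounts` (its bin width must equal the
    network dt) or a raw array.
    """
    if isinstance(U, BinnedSpikeCounts):
        if not np.isclose(U.bin_width, params.dt):
            raise ValueError(
                f"corpus bin width {U.bin_width} ms != network dt "
                f"{params.dt} ms (no rebinning rule configured)")
        counts = U.counts
    else:
        counts = np.asarray(U)
    N, F, E, M = params.dims
    if counts.shape[0] != E:
        raise ValueError("electrode count mismatch")
    T = counts.shape[1]
    state = MRNNState(x=np.zeros(N) if x0 is None else np.asarray(x0, float))
    Z = np.empty((M, T))
    for t in range(T):
        state = step(params, state, counts[:, t])
        Z[:, t] = readout(params, state)
    if return_state:
        return Z, state
    return Z


# ---------------------------------------------------------------------------
# parameter-bundle I/O (same hierarchical container family as corpora)
# ---------------------------------------------------------------------------

def save_params(params: MRNNParams, path,
                normalization: Optional[NormalizationSpec] = None,
                manifest: Optional[dict] = None) -> None:
    """Save an MRNN bundle with dims, tau/dt, normalization and manifest."""
    with h5py.File(path, "w") as f:
        f.attrs["format"] = "robustbmi-mrnn"
        f.attrs["tau_ms"] = params.tau
        f.attrs["dt_ms"] = params.dt
        for name in MRNNParams._BLOCKS:
            f.create_dataset(name, data=getattr(params, name))
        if normalization is not None:
            g = f.create_group("normalization")
            g.create_dataset("position_scale", data=normalization.position_scale)
            g.create_dataset("velocity_scale", data=normalization.velocity_scale)
        if manifest:
            g = f.create_group("manifest")
            for k, v in manifest.items():
                g.attrs[k] = v


def load_params(path):
    """Load an MRNN bundle; returns (params, normalization-or-None)."""
    with h5py.File(path, "r") as f:
        if f.attrs.get("format") != "robustbmi-mrnn":
            raise ValueError(f"{path}: not an MRNN parameter bundle")
        kwargs = {name: f[name][()] for name in MRNNParams._BLOCKS}
        params = MRNNParams(tau=float(f.attrs["tau_ms"]),
                            dt=float(f.attrs["dt_ms"]), **kwargs)
        norm = None
        if "normalization" in f:
            norm = NormalizationSpec(
                position_scale=f["normalization/position_scale"][()],
                velocity_scale=f["normalization/velocity_scale"][()],
            )
    return params, norm
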