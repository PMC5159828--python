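"""Electrode importance, subspace similarity and behavioural similarity.

Electrode importance is the mutual information between an electrode's
binned spike count — discretized to the categories {0,1,2,3,4,5+} (five
spikes in a 20 ms bin is an instantaneous rate of 250 Hz) — and the reach
direction, I(X;Y) = H(Y) - H(Y|X).  Electrodes are dropped from highest
to lowest information, without retraining the decoder, to probe
robustness to sudden signal loss.

Day-to-day similarity of neural covariance structure is measured by the
minimum principal angle between the days' top-K PCA subspaces, and
behavioural stability by the Pearson correlation of trial-averaged
velocity traces concatenated across the eight radial targets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np

from .datamodel import BinnedSpikeCounts, SessionCorpus, Trial

__all__ = [
    "DirectionalCountTable",
    "SubspaceBasis",
    "discretize_counts",
    "mutual_information",
    "count_table_for_electrode",
    "rank_electrodes",
    "drop_electrodes",
    "subspace_basis",
    "min_principal_angle",
    "behavioral_similarity",
]

N_COUNT_CATEGORIES = 6   # {0, 1, 2, 3, 4, 5+}
CATEGORY_CAP = 5


@dataclass(frozen=True)
class DirectionalCountTable:
    """Joint counts over (reach direction, spike-count category)."""

    table: np.ndarray     # (D, 6) non-negative
    bin_width: float

    def __post_init__(self):
        t = np.asarray(self.table, dtype=float)
        if t.ndim != 2 or t.shape[1] != N_COUNT_CATEGORIES:
            raise ValueError(
                f"table must be (D, {N_COUNT_CATEGORIES})")
        if t.shape[0] < 2:
            raise ValueError("need at least 2 reach directions")
        if (t < 0).any():
            raise ValueError("table entries must be >= 0")
        object.__setattr__(self, "table", t)


@dataclass(frozen=True)
class SubspaceBasis:
    """Top-K principal-component basis of one day's neural activity."""

    V: np.ndarray          # (E, K) orthonormal columns
    day_index: int
    eigenvalues: Optional[np.ndarray] = None

    def __post_init__(self):
        V = np.asarray(self.V, dtype=float)
        gram = V.T @ V
        if not np.allclose(gram, np.eye(V.shape[1]), atol=1e-10):
            raise ValueError("basis columns must be orthonormal")
        object.__setattr__(self, "V", V)


def discretize_counts(counts: np.ndarray) -> np.ndarray:
    """Map counts 0..4 to themselves and >=5 to the '5+' category (5)."""
    counts = np.asarray(counts)
    if counts.size and counts.min() < 0:
        raise ValueError("counts must be non-negative")
    return np.minimum(counts, CATEGORY_CAP)


def mutual_information(table: DirectionalCountTable) -> float:
    """I(X;Y) = H(Y) - H(Y|X) in bits, with 0 log 0 := 0, clipped at 0."""
    t = table.table
    total = t.sum()
    if total == 0:
        raise ValueError("empty count table")
    p_joint = t / total
    p_y = p_joint.sum(axis=0)
    p_x = p_joint.sum(axis=1)

    def _entropy(p):
        p = p[p > 0]
        return float(-(p * np.log2(p)).sum())

    h_y = _entropy(p_y)
    h_y_given_x = 0.0
    for j in range(t.shape[0]):
        if p_x[j] > 0:
            h_y_given_x += p_x[j] * _entropy(p_joint[j] / p_x[j])
    return max(h_y - h_y_given_x, 0.0)


def _direction_key(trial: Trial, decimals: int = 6):
    d = trial.target_position - trial.start_position
    norm = np.linalg.norm(d)
    if norm == 0:
        return (0.0, 0.0)
    return tuple(np.round(d / norm, decimals))


def count_table_for_electrode(trials: Sequence[Trial],
                              electrode: int) -> DirectionalCountTable:
    """Pool all bins of each trial by reach direction for one electrode."""
    directions: Dict[tuple, np.ndarray] = {}
    bin_width = trials[0].spikes.bin_width
    for tr in trials:
        key = _direction_key(tr)
        row = directions.setdefault(key, np.zeros(N_COUNT_CATEGORIES))
        cats = discretize_counts(tr.spikes.counts[electrode])
        row += np.bincount(cats, minlength=N_COUNT_CATEGORIES)
    if len(directions) < 2:
        raise ValueError("need trials from at least 2 reach directions")
    table = np.stack([directions[k] for k in sorted(directions)], axis=0)
    return DirectionalCountTable(table=table, bin_width=bin_width)


def rank_electrodes(trials_or_corpus) -> list:
    """Electrodes ordered from highest to lowest mutual information.

    Ties break by ascending electrode index (deterministic).  Returns a
    list of (electrode_index, mi_bits), descending.
    """
    if isinstance(trials_or_corpus, SessionCorpus):
        trials = list(trials_or_corpus.iter_trials())
    else:
        trials = list(trials_or_corpus)
    if not trials:
        raise ValueError("no trials supplied")
    E = trials[0].spikes.n_electrodes
    mis = []
    for e in range(E):
        table = count_table_for_electrode(trials, e)
        mis.append(mutual_information(table))
    order = sorted(range(E), key=lambda e: (-mis[e], e))
    return [(e, mis[e]) for e in order]


def drop_electrodes(counts: BinnedSpikeCounts, ranking: Sequence,
                    k: int) -> BinnedSpikeCounts:
    """Zero the rows of the k most informative electrodes (no retraining)."""
    if not 0 <= k <= counts.n_electrodes:
        raise ValueError(f"k={k} outside [0, {counts.n_electrodes}]")
    out = counts.counts.copy()
    for item in list(ranking)[:k]:
        e = item[0] if isinstance(item, (tuple, list)) else int(item)
        out[e, :] = 0
    return BinnedSpikeCounts(counts=out, bin_width=counts.bin_width,
                             electrode_ids=counts.electrode_ids)


def subspace_basis(day_activity: np.ndarray, across_day_means: np.ndarray,
                   K: int = 10, day_index: int = 0) -> SubspaceBasis:
    """Top-K PCA basis of one day's (E, T) activity.

    Rows are centred by each electrode's *across-days* mean rate (so that
    the comparison across days sees shared structure, not per-day means),
    then the covariance (1/T) Y Y^T is eigendecomposed and the K leading
    eigenvectors kept.
    """
    Y = np.asarray(day_activity, dtype=float)
    E, T = Y.shape
    if K >= E:
        raise ValueError("K must be smaller than the electrode count")
    if T <= K:
        raise ValueError("need more time bins than components")
    Yc = Y - np.asarray(across_day_means, dtype=float).reshape(E, 1)
    cov = Yc @ Yc.T / T
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1][:K]
    return SubspaceBasis(V=eigvecs[:, order], day_index=day_index,
                         eigenvalues=eigvals[order])


def min_principal_angle(Vi: SubspaceBasis, Vj: SubspaceBasis) -> float:
    """Minimum principal angle (radians) between two subspaces.

    Angles are arccos of the singular values of Vi^T Vj, clipped to [0,1];
    the smallest angle measures the best-aligned pair of directions.
    """
    A, B = Vi.V, Vj.V
    if A.shape[0] != B.shape[0]:
        raise ValueError("bases must live in the same electrode space")
    s = np.linalg.svd(A.T @ B, compute_uv=False)
    return float(np.arccos(np.clip(s.max(), 0.0, 1.0)))


def _avg_velocity_traces(trials: Sequence[Trial], outward_ms: float,
                         inward_ms: float) -> tuple:
    """Trial-averaged velocity per radial target, concatenated.

    Outward traces cover ``outward_ms`` after target onset, inward traces
    ``inward_ms``; concatenation across the 8 targets gives the x and y
    velocity vectors used for the behavioural-similarity correlation.
    """
    bin_width = trials[0].kin.bin_width
    n_out = int(round(outward_ms / bin_width))
    n_in = int(round(inward_ms / bin_width))
    by_target: Dict[tuple, dict] = {}
    for tr in trials:
        outward = np.linalg.norm(tr.start_position) \
            < np.linalg.norm(tr.target_position)
        key = tuple(np.round(
            tr.target_position if outward else tr.start_position, 3))
        n = n_out if outward else n_in
        if tr.n_bins < n:
            continue
        slot = by_target.setdefault(key, {"out": [], "in": []})
        slot["out" if outward else "in"].append(tr.kin.velocity[:, :n])
    keys = sorted(by_target)
    if len(keys) != 8 or any(
            not by_target[k]["out"] or not by_target[k]["in"] for k in keys):
        missing = [k for k in keys
                   if not by_target[k]["out"] or not by_target[k]["in"]]
        raise ValueError(
            f"need out+in trials for all 8 radial targets "
            f"(have {len(keys)} targets; incomplete: {missing})")
    pieces = []
    for k in keys:
        pieces.append(np.mean(by_target[k]["out"], axis=0))
        pieces.append(np.mean(by_target[k]["in"], axis=0))
    traces = np.concatenate(pieces, axis=1)   # (2, 8*(n_out+n_in))
    return traces, bin_width


def behavioral_similarity(day_i_trials: Sequence[Trial],
                          day_j_trials: Sequence[Trial],
                          outward_ms: float = 700.0,
                          inward_ms: float = 600.0) -> float:
    """Mean Pearson correlation of the two days' x and y velocity vectors.

    Per day, velocities are trial-averaged per radial target over a 700 ms
    outward and 600 ms inward epoch and concatenated across the 8 targets
    (10,400 ms per dimension at the defaults); the x and y correlations
    across days are averaged into one similarity value.
    """
    ti, _ = _avg_velocity_traces(day_i_trials, outward_ms, inward_ms)
    tj, _ = _avg_velocity_traces(day_j_trials, outward_ms, inward_ms)
    if ti.shape != tj.shape:
        raise ValueError("days produced different-length velocity vectors")
    rs = [np.corrcoef(ti[d], tj[d])[0, 1] for d in range(2)]
    return float(np.mean(rs))
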