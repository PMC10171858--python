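"""Pairwise maximum-entropy (Ising) model over binary neural configurations.

The model assigns to each activity configuration ``s`` in {0,1}^N the
probability

    P(s) = exp( sum_i h_i s_i + sum_{i<j} J_ij s_i s_j ) / Z

where the bias ``h_i`` sets the intrinsic activity of neuron i and the
symmetric coupling ``J_ij`` the pairwise interaction. This module holds
the model and raster containers, exact enumeration for small N, and
Gibbs (Glauber) Monte Carlo sampling of synthetic rasters.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._kernels import gibbs_chain

ENUMERATION_LIMIT = 20

__all__ = [
    "ENUMERATION_LIMIT",
    "SpikeRaster",
    "IsingModel",
    "EmpiricalMoments",
    "StateDistribution",
    "all_states",
    "log_weight",
    "exact_distribution",
    "gibbs_conditional",
    "gibbs_sample",
    "moments",
    "p_active_count",
]


def _as_side_array(side, n: int) -> np.ndarray | None:
    if side is None:
        return None
    arr = np.asarray(side, dtype="U1")
    if arr.shape != (n,):
        raise ValueError(f"side labels must have length {n}, got {arr.shape}")
    bad = set(arr.tolist()) - {"L", "R"}
    if bad:
        raise ValueError(f"side labels must be 'L' or 'R', got {sorted(bad)}")
    return arr


@dataclass
class SpikeRaster:
    """Binarized population activity: N neurons x T time bins.

    activity entries are exactly 0 or 1; ``dt`` is the bin width in
    seconds; ``side`` labels each neuron 'L' or 'R'; ``positions`` is an
    optional (N, 3) array of coordinates in micrometers.
    """

    activity: np.ndarray
    dt: float
    side: np.ndarray | None = None
    positions: np.ndarray | None = None

    def __post_init__(self):
        self.activity = np.asarray(self.activity)
        if self.activity.ndim != 2:
            raise ValueError("activity must be an (N, T) matrix")
        vals = np.unique(self.activity)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("activity entries must be 0 or 1")
        self.activity = self.activity.astype(np.uint8)
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        self.side = _as_side_array(self.side, self.n_neurons)
        if self.positions is not None:
            self.positions = np.asarray(self.positions, dtype=float)
            if self.positions.shape != (self.n_neurons, 3):
                raise ValueError("positions must be (N, 3)")

    @property
    def n_neurons(self) -> int:
        return self.activity.shape[0]

    @property
    def n_bins(self) -> int:
        return self.activity.shape[1]

    @property
    def frame_rate(self) -> float:
        return 1.0 / self.dt

    def side_index(self, label: str) -> np.ndarray:
        if self.side is None:
            raise ValueError("raster has no side labels")
        idx = np.flatnonzero(self.side == label)
        if idx.size == 0:
            raise ValueError(f"no neurons labeled {label!r}")
        return idx


@dataclass
class IsingModel:
    """Biases h and symmetric zero-diagonal couplings J of the model."""

    h: np.ndarray
    J: np.ndarray
    side: np.ndarray | None = None

    def __post_init__(self):
        self.h = np.asarray(self.h, dtype=float)
        self.J = np.asarray(self.J, dtype=float)
        n = self.h.shape[0]
        if self.h.ndim != 1:
            raise ValueError("h must be a vector")
        if self.J.shape != (n, n):
            raise ValueError("J must be N x N")
        if not np.allclose(self.J, self.J.T, atol=1e-12):
            raise ValueError("J must be symmetric")
        if not np.allclose(np.diag(self.J), 0.0, atol=1e-12):
            raise ValueError("J must have zero diagonal")
        self.J = 0.5 * (self.J + self.J.T)
        np.fill_diagonal(self.J, 0.0)
        self.side = _as_side_array(self.side, n)

    @property
    def n_neurons(self) -> int:
        return self.h.shape[0]

    def side_index(self, label: str) -> np.ndarray:
        if self.side is None:
            raise ValueError("model has no side labels")
        idx = np.flatnonzero(self.side == label)
        if idx.size == 0:
            raise ValueError(f"no neurons labeled {label!r}")
        return idx


@dataclass
class EmpiricalMoments:
    """First and second moments <s_i>, <s_i s_j> over time bins."""

    mean: np.ndarray
    pair: np.ndarray
    n_bins: int

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float)
        self.pair = np.asarray(self.pair, dtype=float)
        n = self.mean.shape[0]
        if self.pair.shape != (n, n):
            raise ValueError("pair must be N x N")
        if not np.allclose(self.pair, self.pair.T, atol=1e-10):
            raise ValueError("pair moments must be symmetric")
        if not np.allclose(np.diag(self.pair), self.mean, atol=1e-10):
            raise ValueError("pair[i,i] must equal mean[i] (s_i^2 == s_i)")

    @property
    def n_neurons(self) -> int:
        return self.mean.shape[0]


@dataclass
class StateDistribution:
    """Probabilities over all 2^N configurations, indexed by bit pattern.

    State index k encodes the configuration via its binary expansion,
    neuron i active iff bit i of k is set (little-endian).
    """

    probabilities: np.ndarray
    n_neurons: int = field(default=0)

    def __post_init__(self):
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if self.n_neurons == 0:
            self.n_neurons = int(np.log2(self.probabilities.size))
        if self.probabilities.size != 2 ** self.n_neurons:
            raise ValueError("probabilities must have length 2^N")
        if (self.probabilities < 0).any():
            raise ValueError("probabilities must be nonnegative")
        if abs(self.probabilities.sum() - 1.0) > 1e-12:
            raise ValueError("probabilities must sum to 1 within 1e-12")

    def prob(self, s) -> float:
        s = np.asarray(s)
        idx = int((s.astype(np.uint64) << np.arange(s.size, dtype=np.uint64)).sum())
        return float(self.probabilities[idx])


def all_states(n: int) -> np.ndarray:
    """All 2^n binary configurations as a (2^n, n) uint8 matrix."""
    if n > ENUMERATION_LIMIT:
        raise ValueError(
            f"exact enumeration is limited to N <= {ENUMERATION_LIMIT}, got N = {n}"
        )
    idx = np.arange(2 ** n, dtype=np.uint32)
    return ((idx[:, None] >> np.arange(n)) & 1).astype(np.uint8)


def _check_binary(s, n: int) -> np.ndarray:
    s = np.asarray(s)
    if s.shape != (n,):
        raise ValueError(f"configuration must have length {n}, got {s.shape}")
    if not np.isin(s, (0, 1)).all():
        raise ValueError("configuration entries must be 0 or 1")
    return s.astype(float)


def log_weight(model: IsingModel, s) -> float:
    """Unnormalized log-probability sum_i h_i s_i + sum_{i<j} J_ij s_i s_j."""
    s = _check_binary(s, model.n_neurons)
    return float(model.h @ s + 0.5 * s @ model.J @ s)


def exact_distribution(model: IsingModel) -> StateDistribution:
    """Enumerate P(s) = exp(log_weight(s)) / Z over all 2^N states (N <= 20)."""
    S = all_states(model.n_neurons).astype(float)
    logw = S @ model.h + 0.5 * np.einsum("ki,ki->k", S @ model.J, S)
    logw -= logw.max()
    p = np.exp(logw)
    p /= p.sum()
    return StateDistribution(p, model.n_neurons)


def gibbs_conditional(model: IsingModel, s, i: int) -> float:
    """P(s_i = 1 | s_{j != i}) = sigmoid(h_i + sum_j J_ij s_j)."""
    s = _check_binary(s, model.n_neurons)
    if not 0 <= i < model.n_neurons:
        raise IndexError(f"neuron index {i} out of range")
    x = model.h[i] + model.J[i] @ s  # J_ii = 0, so s_i does not contribute
    return float(1.0 / (1.0 + np.exp(-x)))


def _initial_state(model: IsingModel, init, seed: int) -> np.ndarray:
    if isinstance(init, str):
        if init != "random":
            raise ValueError("init must be a binary vector or 'random'")
        rng = np.random.default_rng(seed)
        return rng.integers(0, 2, size=model.n_neurons).astype(float)
    s = np.asarray(init)
    if s.shape != (model.n_neurons,):
        raise ValueError(
            f"init must have length {model.n_neurons}, got {s.shape}"
        )
    if not np.isin(s, (0, 1)).all():
        raise ValueError("init entries must be 0 or 1")
    return s.astype(float)


def gibbs_sample(
    model: IsingModel,
    n_rounds: int,
    seed: int,
    init="random",
    dt: float = 1.0,
    burn_in_rounds: int | None = None,
    delta_h: np.ndarray | None = None,
    schedule: np.ndarray | None = None,
) -> SpikeRaster:
    """Gibbs-sample a synthetic raster, one stored configuration per round.

    A Monte Carlo round is N single-site updates, each on a uniformly
    chosen neuron updated from its conditional sigmoid. The default
    burn-in of 10*N rounds is discarded before recording. ``dt`` is the
    nominal bin width attached to the output (rounds are an abstract
    time; sampling is not a model of real dynamics).

    ``delta_h``/``schedule`` support epoch-dependent extra biases: rows of
    ``delta_h`` (n_kinds, N) are added to h according to the per-round
    index array ``schedule``. Row 0 should be zero (spontaneous).
    """
    if n_rounds < 1:
        raise ValueError("n_rounds must be >= 1")
    n = model.n_neurons
    s0 = _initial_state(model, init, seed)
    if burn_in_rounds is None:
        burn_in_rounds = 10 * n
    if delta_h is None:
        delta_h = np.zeros((1, n))
        schedule = np.zeros(n_rounds, dtype=np.int64)
    else:
        delta_h = np.asarray(delta_h, dtype=float)
        schedule = np.asarray(schedule, dtype=np.int64)
        if schedule.shape != (n_rounds,):
            raise ValueError("schedule must give one kind index per round")
        if schedule.min() < 0 or schedule.max() >= delta_h.shape[0]:
            raise ValueError("schedule indexes outside delta_h rows")
    act = gibbs_chain(
        model.h, model.J, schedule, delta_h, s0,
        seed % (2 ** 31), burn_in_rounds * n,
    )
    return SpikeRaster(act.T, dt=dt, side=model.side)


def moments(raster: SpikeRaster) -> EmpiricalMoments:
    """Mean activities and pairwise moments averaged over time bins."""
    if raster.n_bins < 1:
        raise ValueError("raster has no time bins")
    A = raster.activity.astype(float)
    mean = A.mean(axis=1)
    pair = (A @ A.T) / raster.n_bins
    np.fill_diagonal(pair, mean)
    return EmpiricalMoments(mean, pair, raster.n_bins)


def p_active_count(dist_or_raster) -> np.ndarray:
    """Probability that K = 0..N cells are active in a bin; sums to 1."""
    if isinstance(dist_or_raster, StateDistribution):
        n = dist_or_raster.n_neurons
        counts = all_states(n).sum(axis=1)
        out = np.zeros(n + 1)
        np.add.at(out, counts, dist_or_raster.probabilities)
        return out
    raster = dist_or_raster
    n = raster.n_neurons
    k = raster.activity.sum(axis=0)
    out = np.bincount(k, minlength=n + 1).astype(float)
    return out / out.sum()
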