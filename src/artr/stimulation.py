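"""Stimulus-driven biases: inference, protocol simulation, tilted landscapes.

During unilateral visual stimulation the couplings J are held fixed and
each neuron receives an extra bias delta_h. For each stimulated side the
per-neuron delta_h solves

    rho_i(dh) = (1/B) sum_t sigmoid(h_i + sum_j J_ij s_j(t) + dh)
              = empirical mean of s_i over the B stimulated bins,

a strictly increasing one-dimensional root problem conditioned on the
recorded network configurations. The mean-field picture of stimulation
is a tilt of the free-energy landscape by (dHL, dHR).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .ising import IsingModel, SpikeRaster, gibbs_sample
from .meanfield import Barrier, Landscape, MeanFieldModel, barriers, landscape

__all__ = [
    "StimEpochs",
    "DeltaBiases",
    "make_alternating_protocol",
    "infer_delta_biases",
    "summarize_delta",
    "simulate_protocol",
    "tilted_landscape",
    "path_profile",
    "stimulated_mean_activity",
]

EPOCH_DURATIONS_S = (10.0, 15.0, 20.0, 25.0, 30.0)


@dataclass
class StimEpochs:
    """Non-overlapping, sorted stimulation epochs in bin coordinates.

    Each epoch is (start_bin, end_bin, side) with end exclusive and side
    'left' or 'right' (the illuminated eye).
    """

    epochs: list

    def __post_init__(self):
        prev_end = -1
        for start, end, side in self.epochs:
            if side not in ("left", "right"):
                raise ValueError(f"epoch side must be left/right, got {side!r}")
            if not 0 <= start < end:
                raise ValueError("epochs must satisfy 0 <= start < end")
            if start < prev_end:
                raise ValueError("epochs must be sorted and non-overlapping")
            prev_end = end

    def bins(self, side: str) -> np.ndarray:
        idx = [
            np.arange(s, e) for s, e, sd in self.epochs if sd == side
        ]
        if not idx:
            return np.empty(0, dtype=int)
        return np.concatenate(idx)

    @property
    def n_bins_total(self) -> int:
        return max(e for _, e, _ in self.epochs) if self.epochs else 0


@dataclass
class DeltaBiases:
    """Per-neuron extra biases for left- and right-eye stimulation."""

    delta_left: np.ndarray
    delta_right: np.ndarray

    def __post_init__(self):
        self.delta_left = np.asarray(self.delta_left, dtype=float)
        self.delta_right = np.asarray(self.delta_right, dtype=float)
        if self.delta_left.shape != self.delta_right.shape:
            raise ValueError("delta bias vectors must have equal length")
        if not (
            np.isfinite(self.delta_left).all()
            and np.isfinite(self.delta_right).all()
        ):
            raise ValueError("delta biases must be finite")


def make_alternating_protocol(
    dt: float,
    n_reps_per_side: int = 17,
    durations_s=EPOCH_DURATIONS_S,
    seed: int = 0,
    start_side: str = "left",
) -> StimEpochs:
    """Alternating left/right epochs with durations drawn from the given set."""
    rng = np.random.default_rng(seed)
    sides = ["left", "right"] if start_side == "left" else ["right", "left"]
    epochs = []
    cursor = 0
    for _ in range(n_reps_per_side):
        for side in sides:
            nb = int(round(rng.choice(durations_s) / dt))
            epochs.append((cursor, cursor + nb, side))
            cursor += nb
    return StimEpochs(epochs)


def _rho_factory(model: IsingModel, raster: SpikeRaster, bins: np.ndarray, i: int):
    A = raster.activity[:, bins].astype(float)
    base = model.h[i] + model.J[i] @ A  # (B,) fields excluding dh

    def rho(dh: float) -> float:
        return float(np.mean(1.0 / (1.0 + np.exp(-(base + dh)))))

    return rho


def infer_delta_biases(
    model: IsingModel,
    raster: SpikeRaster,
    epochs: StimEpochs,
    tol: float = 1e-10,
) -> DeltaBiases:
    """Solve rho_i(dh) = stimulated mean of s_i for every neuron and side.

    rho_i is a mean of sigmoids, hence strictly increasing in dh; the
    root is bracketed by exponential expansion and solved by Brent's
    method to |rho - target| < 1e-8. Empirical means of 0 or 1 are
    clamped by the 1/(2B) pseudocount first.
    """
    out = {}
    for side in ("left", "right"):
        bins = epochs.bins(side)
        if bins.size == 0:
            raise ValueError(f"no stimulated bins for side {side!r}")
        B = bins.size
        targets = raster.activity[:, bins].mean(axis=1)
        targets = np.clip(targets, 1.0 / (2 * B), 1.0 - 1.0 / (2 * B))
        dh = np.empty(model.n_neurons)
        for i in range(model.n_neurons):
            rho = _rho_factory(model, raster, bins, i)
            f = lambda x: rho(x) - targets[i]
            lo, hi = -1.0, 1.0
            while f(lo) > 0:
                lo *= 2.0
            while f(hi) < 0:
                hi *= 2.0
            dh[i] = brentq(f, lo, hi, xtol=tol)
        out[side] = dh
    return DeltaBiases(out["left"], out["right"])


def solver_residuals(
    model: IsingModel,
    raster: SpikeRaster,
    epochs: StimEpochs,
    biases: DeltaBiases,
) -> np.ndarray:
    """|rho_i(dh_i) - target_i| for every neuron and both sides."""
    res = []
    for side, dh in (("left", biases.delta_left), ("right", biases.delta_right)):
        bins = epochs.bins(side)
        B = bins.size
        targets = raster.activity[:, bins].mean(axis=1)
        targets = np.clip(targets, 1.0 / (2 * B), 1.0 - 1.0 / (2 * B))
        for i in range(model.n_neurons):
            rho = _rho_factory(model, raster, bins, i)
            res.append(abs(rho(dh[i]) - targets[i]))
    return np.asarray(res)


def summarize_delta(biases: DeltaBiases, side) -> dict:
    """Ipsi/contralateral averages of the extra biases per stimulus side."""
    side = np.asarray(side, dtype="U1")
    li = side == "L"
    ri = side == "R"
    if not li.any() or not ri.any():
        raise ValueError("side labels must contain both L and R neurons")
    return {
        "left_stim_ipsi": float(biases.delta_left[li].mean()),
        "left_stim_contra": float(biases.delta_left[ri].mean()),
        "right_stim_ipsi": float(biases.delta_right[ri].mean()),
        "right_stim_contra": float(biases.delta_right[li].mean()),
    }


def simulate_protocol(
    model: IsingModel,
    biases: DeltaBiases,
    epochs: StimEpochs,
    seed: int,
    n_rounds: int | None = None,
    dt: float = 1.0,
) -> SpikeRaster:
    """Gibbs sampling with epoch-dependent biases; one continuous chain.

    Bins outside any epoch are spontaneous. The chain is never
    re-initialized across epoch boundaries.
    """
    if n_rounds is None:
        n_rounds = epochs.n_bins_total
    schedule = np.zeros(n_rounds, dtype=np.int64)
    for start, end, side in epochs.epochs:
        schedule[start:min(end, n_rounds)] = 1 if side == "left" else 2
    delta_h = np.stack(
        [np.zeros(model.n_neurons), biases.delta_left, biases.delta_right]
    )
    return gibbs_sample(
        model, n_rounds, seed=seed, dt=dt, delta_h=delta_h, schedule=schedule
    )


def stimulated_mean_activity(
    raster: SpikeRaster, epochs: StimEpochs, side: str, neuron_idx: np.ndarray
) -> float:
    """Mean activity of the given neurons over one side's stimulated bins."""
    bins = epochs.bins(side)
    return float(raster.activity[np.ix_(neuron_idx, bins)].mean())


def tilted_landscape(
    mf: MeanFieldModel, dHL: float, dHR: float, grid_size: int = 200
) -> Landscape:
    """Landscape with stimulation biases added to (HL, HR); J, I unchanged."""
    return landscape(mf.tilted(dHL, dHR), grid_size=grid_size)


def path_profile(land: Landscape, transition: tuple[str, str]) -> np.ndarray:
    """Free energy along the bottleneck path, parameterized by mL - mR.

    Returns an (n_points, 2) array of (mL - mR, F); the endpoints carry
    the free energies of the two minima.
    """
    from_label, to_label = transition
    for b in barriers(land):
        if b.from_label == from_label and b.to_label == to_label:
            mL, mR, F = b.path.T
            return np.column_stack([mL - mR, F])
    raise ValueError(f"no transition {from_label} -> {to_label} in landscape")
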