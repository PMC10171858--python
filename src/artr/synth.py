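"""Planted-model generators for every stage of the analysis.

Emulates the statistical structure of the recordings the pipeline is
meant for: two lateral populations with broadly distributed negative
biases, ipsilateral couplings centered on a positive value that decay
with distance, near-zero contralateral couplings, bistable left/right
alternation tunable by a temperature-like knob, alternating-eye
stimulation epochs, and telegraph-driven bout sequences. Every generated
dataset carries its PlantedTruth so recovery tests compare against the
planted ground truth only.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .behavior import BoutSequence
from .ising import IsingModel, SpikeRaster, gibbs_sample
from .stimulation import DeltaBiases, StimEpochs, make_alternating_protocol, simulate_protocol

__all__ = [
    "PlantedSpec",
    "PlantedTruth",
    "planted_ising",
    "generate_raster",
    "generate_stim_dataset",
    "generate_bouts",
    "telegraph_signal",
]

# Marginal parameter statistics of inferred recording-scale models, used
# as generator defaults.
BIAS_MEAN, BIAS_SD = -4.1, 1.1
IPSI_MEAN, IPSI_SD = 0.062, 0.12
CONTRA_MEAN, CONTRA_SD = -0.001, 0.10

# Temperature-knob anchors, in size-invariant units (bias H; ipsilateral
# drive J*(Ns-1); contralateral drive I*Ns). The cold end is bistable
# with persistent high states; the hot end is dominated by the
# low-activity state. Chosen once from the 1-D self-consistency
# m = sigmoid(H + J*(Ns-1)*m); see docs/methods.md.
KNOB_COLD = {"H": -4.0, "Jdrive": 9.5, "Idrive": -0.6}
KNOB_HOT = {"H": -3.6, "Jdrive": 5.0, "Idrive": -0.3}


@dataclass
class PlantedSpec:
    """Generative targets for a planted two-population Ising model.

    With ``temperature_knob=None`` the marginal means/sds below are used
    directly. With a knob value t in [0, 1], the (h, J) means are
    derived instead from cold/hot anchor settings scaled by the
    population sizes, so the collective regime (bistable vs
    low-dominated) is controlled independently of N.
    """

    NL: int = 25
    NR: int = 25
    bias_mean: float = BIAS_MEAN
    bias_sd: float = BIAS_SD
    ipsi_mean: float = IPSI_MEAN
    ipsi_sd: float = IPSI_SD
    contra_mean: float = CONTRA_MEAN
    contra_sd: float = CONTRA_SD
    decay_length: float = 40.0  # um, e-folding of the ipsilateral mean
    temperature_knob: float | None = None
    seed: int = 0

    def __post_init__(self):
        if self.NL < 2 or self.NR < 2:
            raise ValueError("population sizes must be >= 2")
        if min(self.bias_sd, self.ipsi_sd, self.contra_sd) < 0:
            raise ValueError("standard deviations must be nonnegative")
        if self.decay_length <= 0:
            raise ValueError("decay_length must be positive")
        if self.temperature_knob is not None and not 0 <= self.temperature_knob <= 1:
            raise ValueError("temperature_knob must lie in [0, 1]")


@dataclass
class PlantedTruth:
    """Ground truth persisted alongside every generated dataset."""

    model: IsingModel
    positions: np.ndarray
    spec: PlantedSpec
    effective_params: dict
    delta_biases: DeltaBiases | None = None
    extras: dict = field(default_factory=dict)


def _knob_params(spec: PlantedSpec) -> dict:
    t = spec.temperature_knob
    ns = 0.5 * (spec.NL + spec.NR)
    mix = lambda key: (1 - t) * KNOB_COLD[key] + t * KNOB_HOT[key]
    H = mix("H")
    ipsi = mix("Jdrive") / (ns - 1)
    contra = mix("Idrive") / ns
    return {
        "bias_mean": H,
        "bias_sd": 0.3,
        "ipsi_mean": ipsi,
        "ipsi_sd": 0.15 * abs(ipsi),
        "contra_mean": contra,
        "contra_sd": 0.5 * abs(contra),
    }


def _ipsi_block(rng, pos, mean, sd, decay_length):
    """Ipsilateral couplings: distance-decaying mean, marginal (mean, sd).

    The spatial signal is the standardized exp(-d / decay_length) carrying
    half the marginal variance; the rest is independent noise. The
    marginal mean and sd therefore hit the requested targets while the
    conditional mean decreases with distance.
    """
    n = pos.shape[0]
    iu = np.triu_indices(n, k=1)
    d = np.linalg.norm(pos[iu[0]] - pos[iu[1]], axis=1)
    J = np.zeros((n, n))
    if sd == 0:
        vals = np.full(iu[0].size, mean)
    else:
        w = np.exp(-d / decay_length)
        if w.std() > 0:
            signal = (w - w.mean()) / w.std()
        else:
            signal = np.zeros_like(w)
        s_sig = sd * np.sqrt(0.5)
        s_noise = sd * np.sqrt(0.5)
        vals = mean + s_sig * signal + s_noise * rng.standard_normal(iu[0].size)
    J[iu] = vals
    return J + J.T


def planted_ising(spec: PlantedSpec) -> PlantedTruth:
    """Draw a planted two-population model with the requested marginals."""
    rng = np.random.default_rng(spec.seed)
    if spec.temperature_knob is None:
        pars = {
            "bias_mean": spec.bias_mean,
            "bias_sd": spec.bias_sd,
            "ipsi_mean": spec.ipsi_mean,
            "ipsi_sd": spec.ipsi_sd,
            "contra_mean": spec.contra_mean,
            "contra_sd": spec.contra_sd,
        }
    else:
        pars = _knob_params(spec)

    n = spec.NL + spec.NR
    side = np.array(["L"] * spec.NL + ["R"] * spec.NR)
    # two lateral boxes, ~ARTR scale, in micrometers
    pos = np.empty((n, 3))
    pos[: spec.NL, 0] = rng.uniform(-80, -20, spec.NL)
    pos[spec.NL:, 0] = rng.uniform(20, 80, spec.NR)
    pos[:, 1] = rng.uniform(0, 60, n)
    pos[:, 2] = rng.uniform(0, 60, n)

    h = pars["bias_mean"] + pars["bias_sd"] * rng.standard_normal(n)
    J = np.zeros((n, n))
    JL = _ipsi_block(rng, pos[: spec.NL], pars["ipsi_mean"], pars["ipsi_sd"], spec.decay_length)
    JR = _ipsi_block(rng, pos[spec.NL:], pars["ipsi_mean"], pars["ipsi_sd"], spec.decay_length)
    J[: spec.NL, : spec.NL] = JL
    J[spec.NL:, spec.NL:] = JR
    cross = pars["contra_mean"] + pars["contra_sd"] * rng.standard_normal(
        (spec.NL, spec.NR)
    )
    J[: spec.NL, spec.NL:] = cross
    J[spec.NL:, : spec.NL] = cross.T
    np.fill_diagonal(J, 0.0)
    model = IsingModel(h, J, side=side)
    return PlantedTruth(model, pos, spec, pars)


def generate_raster(
    truth: PlantedTruth, n_bins: int, dt: float, seed: int, **kwargs
) -> SpikeRaster:
    """Gibbs-sampled raster from a planted model (one bin per MC round)."""
    raster = gibbs_sample(truth.model, n_bins, seed=seed, dt=dt, **kwargs)
    raster.positions = truth.positions
    return raster


def generate_stim_dataset(
    truth: PlantedTruth,
    delta_ipsi: float,
    delta_contra: float,
    seed: int,
    epochs: StimEpochs | None = None,
    dt: float = 0.1,
    n_reps_per_side: int = 17,
) -> tuple[SpikeRaster, StimEpochs, PlantedTruth]:
    """Simulated alternating-eye stimulation with planted extra biases.

    Ipsilateral neurons (relative to the illuminated eye) receive
    ``delta_ipsi``, contralateral ones ``delta_contra``. Returns the
    raster, epochs, and a truth record carrying the planted deltas.
    """
    model = truth.model
    li = model.side_index("L")
    ri = model.side_index("R")
    dl = np.empty(model.n_neurons)
    dl[li] = delta_ipsi
    dl[ri] = delta_contra
    dr = np.empty(model.n_neurons)
    dr[ri] = delta_ipsi
    dr[li] = delta_contra
    planted = DeltaBiases(dl, dr)
    if epochs is None:
        epochs = make_alternating_protocol(
            dt, n_reps_per_side=n_reps_per_side, seed=seed
        )
    raster = simulate_protocol(model, planted, epochs, seed=seed, dt=dt)
    raster.positions = truth.positions
    truth = replace(truth, delta_biases=planted)
    return raster, epochs, truth


def telegraph_signal(
    kflip: float, duration_s: float, dt: float, seed: int
) -> np.ndarray:
    """+/-1 memoryless two-state signal with switching rate kflip (Hz)."""
    if kflip <= 0 or duration_s <= 0 or dt <= 0:
        raise ValueError("kflip, duration and dt must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s / dt))
    # exact discretization: switch each sample with prob (1-exp(-2k dt))/2
    # keeps the autocorrelation exp(-2 k |t|) of the continuous process
    p_switch = 0.5 * (1.0 - np.exp(-2.0 * kflip * dt))
    flips = rng.random(n) < p_switch
    state = np.where(rng.random() < 0.5, 1.0, -1.0)
    out = state * np.cumprod(np.where(flips, -1.0, 1.0))
    return out


def generate_bouts(
    kflip: float,
    duration_s: float,
    bout_rate_hz: float = 1.0,
    p_forward: float = 0.5,
    forward_sigma_deg: float = 5.0,
    gamma_shape: float = 3.0,
    gamma_scale_deg: float = 12.0,
    seed: int = 0,
) -> tuple[BoutSequence, dict]:
    """Bout sequence driven by a hidden telegraph orientational state.

    The hidden +/-1 state switches at rate ``kflip``; bouts arrive as a
    Poisson process at ``bout_rate_hz``. Each bout is forward with
    probability ``p_forward`` (angle ~ Normal(0, sigma)), otherwise a
    turn in the hidden state's direction with Gamma-distributed
    amplitude. Returns (bouts, truth) with the hidden switch times.
    """
    if kflip <= 0:
        raise ValueError("kflip must be positive")
    rng = np.random.default_rng(seed)
    # hidden state switch times: exponential dwells at rate kflip
    switch_times = []
    t = rng.exponential(1.0 / kflip)
    while t < duration_s:
        switch_times.append(t)
        t += rng.exponential(1.0 / kflip)
    switch_times = np.asarray(switch_times)
    state0 = 1.0 if rng.random() < 0.5 else -1.0

    def state_at(times):
        k = np.searchsorted(switch_times, times)
        return state0 * np.where(k % 2 == 0, 1.0, -1.0)

    n_bouts = rng.poisson(bout_rate_hz * duration_s)
    times = np.sort(rng.uniform(0.0, duration_s, n_bouts))
    times = times[np.concatenate([[True], np.diff(times) > 0])]
    is_forward = rng.random(times.size) < p_forward
    angles = np.empty(times.size)
    angles[is_forward] = forward_sigma_deg * rng.standard_normal(is_forward.sum())
    n_turn = (~is_forward).sum()
    amp = rng.gamma(gamma_shape, gamma_scale_deg, n_turn)
    angles[~is_forward] = state_at(times[~is_forward]) * amp
    truth = {
        "kflip": kflip,
        "switch_times": switch_times,
        "initial_state": state0,
        "n_switches": int(switch_times.size),
        "p_forward": p_forward,
        "bout_rate_hz": bout_rate_hz,
    }
    return BoutSequence(times, angles), truth
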