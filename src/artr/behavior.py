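"""Behavioral turn statistics: bout classification and flip-rate estimation.

Swim bouts reorient the fish by an angle dtheta. The |dtheta|
distribution is modeled as a mixture of a half-Gaussian (forward bouts,
centered on zero) and a Gamma (turn bouts); the density intersection
defines the forward/turn threshold (empirically near 10 deg). Turns are
labeled L/R by sign, and the orientational state — the sign of the last
turn — is a two-state signal whose Lorentzian spectrum yields the
flipping rate kflip; 1/kflip is the typical time spent turning in the
same direction.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import digamma, gammaln

from .activity import SpectrumFit, lorentzian_fit, power_spectrum

__all__ = [
    "BoutSequence",
    "TernarySequence",
    "OrientationalSignal",
    "MixtureFit",
    "classify_bouts",
    "fit_angle_mixture",
    "orientational_signal",
    "kflip_estimate",
]

DEFAULT_SAMPLING_HZ = 25.0  # video rate of the behavioral recordings


@dataclass
class BoutSequence:
    """Bout times (s, strictly increasing) and signed reorientation angles.

    Positive dtheta denotes a leftward reorientation.
    """

    times: np.ndarray
    dtheta: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.dtheta = np.asarray(self.dtheta, dtype=float)
        if self.times.shape != self.dtheta.shape or self.times.ndim != 1:
            raise ValueError("times and dtheta must be equal-length vectors")
        if (np.diff(self.times) <= 0).any():
            raise ValueError("bout times must be strictly increasing")
        if not np.isfinite(self.dtheta).all():
            raise ValueError("angles must be finite")

    @property
    def n_bouts(self) -> int:
        return self.times.size


@dataclass
class TernarySequence:
    symbols: np.ndarray  # 'F', 'L' or 'R' per bout
    threshold_deg: float


@dataclass
class OrientationalSignal:
    """Piecewise-constant +/-1 state of the last turn, sampled at dt.

    +1 encodes a left turn, -1 a right turn; samples before the first
    turn bout are dropped (t0 is the time of the first sample).
    """

    states: np.ndarray
    dt: float
    t0: float

    @property
    def duration(self) -> float:
        return self.states.size * self.dt


@dataclass
class MixtureFit:
    forward_weight: float
    forward_sigma: float
    gamma_shape: float
    gamma_scale: float
    threshold_deg: float
    log_likelihood: float


def _halfnorm_logpdf(x, sigma):
    return (
        0.5 * np.log(2.0 / np.pi) - np.log(sigma) - 0.5 * (x / sigma) ** 2
    )


def _gamma_logpdf(x, shape, scale):
    return (
        (shape - 1.0) * np.log(x) - x / scale
        - gammaln(shape) - shape * np.log(scale)
    )


def _weighted_gamma_mle(x, w):
    """Weighted Gamma MLE via the digamma equation for the shape."""
    W = w.sum()
    mx = (w * x).sum() / W
    mlog = (w * np.log(x)).sum() / W
    c = np.log(mx) - mlog  # >= 0 by Jensen
    c = max(c, 1e-9)

    def eq(a):
        return np.log(a) - digamma(a) - c

    lo, hi = 1e-3, 1e3
    while eq(hi) > 0:
        hi *= 2
    shape = brentq(eq, lo, hi)
    return shape, mx / shape


def fit_angle_mixture(
    abs_angles: np.ndarray,
    n_restarts: int = 10,
    max_iter: int = 500,
    tol: float = 1e-9,
    seed: int = 0,
) -> MixtureFit:
    """EM fit of half-Gaussian (forward) + Gamma (turn) on folded angles.

    The classification threshold is the smallest angle at which the
    weighted Gamma density overtakes the weighted half-Gaussian density.
    """
    x = np.asarray(abs_angles, dtype=float)
    x = np.clip(x, 1e-6, None)  # Gamma support is (0, inf)
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_restarts):
        w = rng.uniform(0.3, 0.7)
        sigma = rng.uniform(0.5, 1.5) * np.percentile(x, 25)
        turn = x[x > np.median(x)]
        shape = rng.uniform(1.5, 5.0)
        scale = turn.mean() / shape
        ll_prev = -np.inf
        for _ in range(max_iter):
            lf = np.log(w) + _halfnorm_logpdf(x, sigma)
            lt = np.log1p(-w) + _gamma_logpdf(x, shape, scale)
            m = np.maximum(lf, lt)
            denom = m + np.log(np.exp(lf - m) + np.exp(lt - m))
            rf = np.exp(lf - denom)
            ll = denom.sum()
            w = max(rf.mean(), 1e-9)
            sigma = np.sqrt((rf * x ** 2).sum() / rf.sum())
            rt = 1.0 - rf
            if rt.sum() < 1e-6:
                break
            shape, scale = _weighted_gamma_mle(x, rt)
            if ll - ll_prev < tol:
                break
            ll_prev = ll
        if best is None or ll > best[0]:
            best = (ll, w, sigma, shape, scale)
    ll, w, sigma, shape, scale = best
    if w < 0.02 or w > 0.98:
        raise RuntimeError(
            "degenerate mixture fit (one component vanished); supply a "
            "manual threshold instead"
        )

    def diff(a):
        return (np.log1p(-w) + _gamma_logpdf(a, shape, scale)) - (
            np.log(w) + _halfnorm_logpdf(a, sigma)
        )

    grid = np.linspace(1e-3, np.percentile(x, 99), 4000)
    d = diff(grid)
    crossings = np.flatnonzero((d[:-1] < 0) & (d[1:] >= 0))
    if crossings.size == 0:
        raise RuntimeError(
            "mixture densities do not cross; supply a manual threshold"
        )
    lo, hi = grid[crossings[0]], grid[crossings[0] + 1]
    threshold = brentq(diff, lo, hi)
    return MixtureFit(w, sigma, shape, scale, float(threshold), float(ll))


def classify_bouts(
    bouts: BoutSequence, threshold_deg: float | None = None, seed: int = 0
) -> TernarySequence:
    """Label bouts F/L/R; the threshold is fitted unless supplied.

    With no threshold, >= 100 bouts are required for the mixture fit.
    Angles above threshold are turns, labeled by sign (+ -> L, - -> R).
    """
    if threshold_deg is None:
        if bouts.n_bouts < 100:
            raise ValueError(
                "need >= 100 bouts to fit the angle mixture; supply "
                "threshold_deg explicitly"
            )
        threshold_deg = fit_angle_mixture(np.abs(bouts.dtheta), seed=seed).threshold_deg
    symbols = np.full(bouts.n_bouts, "F", dtype="U1")
    symbols[bouts.dtheta > threshold_deg] = "L"
    symbols[bouts.dtheta < -threshold_deg] = "R"
    return TernarySequence(symbols, float(threshold_deg))


def orientational_signal(
    tern: TernarySequence,
    bouts: BoutSequence,
    dt: float = 1.0 / DEFAULT_SAMPLING_HZ,
) -> OrientationalSignal:
    """+/-1 state of the last executed turn, sampled every dt seconds.

    Forward bouts are ignored; the signal starts at the first turn bout
    and changes value only at turn bouts.
    """
    turns = tern.symbols != "F"
    if not turns.any():
        raise ValueError("no turn bouts; orientational state undefined")
    t_turn = bouts.times[turns]
    v_turn = np.where(tern.symbols[turns] == "L", 1.0, -1.0)
    t_end = bouts.times[-1]
    grid = np.arange(t_turn[0], t_end + 0.5 * dt, dt)
    idx = np.searchsorted(t_turn, grid, side="right") - 1
    return OrientationalSignal(v_turn[idx], dt, float(t_turn[0]))


def kflip_estimate(signal: OrientationalSignal) -> SpectrumFit:
    """Flipping rate from the Lorentzian fit of the signal periodogram."""
    if signal.duration < 60.0:
        raise ValueError("signal shorter than 60 s; kflip fit unreliable")
    if np.ptp(signal.states) == 0:
        f = np.fft.rfftfreq(signal.states.size, d=signal.dt)
        return SpectrumFit(f, np.zeros_like(f), np.nan, np.nan, np.inf, False)
    f, p = power_spectrum(signal.states, signal.dt, method="periodogram")
    return lorentzian_fit(f, p)
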