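"""Population-level descriptors of left/right circuit activity.

Covers the mean left/right traces mL(t), mR(t), the signed activity
sigma(t) = sign(mL - mR), persistence times above a threshold, power
spectra (Thomson multitaper or periodogram) with Lorentzian fits for
two-state switching rates, 2-D (mL, mR) occupancy maps with pseudocount,
and the base-10 Kullback-Leibler divergence used to compare data and
model maps.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import periodogram
from scipy.signal.windows import dpss

from .ising import SpikeRaster

__all__ = [
    "PopulationTrace",
    "SignSignal",
    "SpectrumFit",
    "ActivityMap2D",
    "PairCorrelations",
    "population_traces",
    "sign_signal",
    "persistence_times",
    "power_spectrum",
    "lorentzian",
    "lorentzian_fit",
    "activity_map",
    "kl_divergence",
    "pearson_pair_correlations",
]


@dataclass
class PopulationTrace:
    """Per-bin mean activity of the left and right populations."""

    mL: np.ndarray
    mR: np.ndarray
    dt: float

    def __post_init__(self):
        self.mL = np.asarray(self.mL, dtype=float)
        self.mR = np.asarray(self.mR, dtype=float)
        if self.mL.shape != self.mR.shape or self.mL.ndim != 1:
            raise ValueError("mL and mR must be equal-length vectors")
        for m in (self.mL, self.mR):
            if ((m < 0) | (m > 1)).any():
                raise ValueError("population activities must lie in [0, 1]")
        if not self.dt > 0:
            raise ValueError("dt must be positive")

    @property
    def n_bins(self) -> int:
        return self.mL.size


@dataclass
class SignSignal:
    sigma: np.ndarray  # entries in {-1, +1}
    dt: float


@dataclass
class SpectrumFit:
    frequencies: np.ndarray
    power: np.ndarray
    kflip: float
    amplitude: float
    residual: float
    success: bool


@dataclass
class ActivityMap2D:
    """Histogram of (mL, mR) on a bins x bins grid over [0, 1]^2.

    Probabilities use the pseudocount rule P_i = (c_i + alpha) / sum_j (c_j + alpha).
    """

    counts: np.ndarray
    alpha: float = 1.0

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("counts must be a square grid")

    @property
    def bins(self) -> int:
        return self.counts.shape[0]

    @property
    def probabilities(self) -> np.ndarray:
        c = self.counts + self.alpha
        return c / c.sum()


@dataclass
class PairCorrelations:
    ipsi: np.ndarray
    contra: np.ndarray
    n_constant_skipped: int

    @property
    def summary(self) -> dict:
        return {
            "ipsi_mean": float(self.ipsi.mean()),
            "ipsi_sd": float(self.ipsi.std()),
            "contra_mean": float(self.contra.mean()),
            "contra_sd": float(self.contra.std()),
        }


def population_traces(raster: SpikeRaster) -> PopulationTrace:
    """mS(t) = (1/N_S) sum_{i in S} s_i(t) for S = L, R."""
    li = raster.side_index("L")
    ri = raster.side_index("R")
    A = raster.activity.astype(float)
    return PopulationTrace(A[li].mean(axis=0), A[ri].mean(axis=0), raster.dt)


def sign_signal(trace: PopulationTrace) -> SignSignal:
    """sigma(t) = sign(mL - mR); ties carry the previous value (+1 at start)."""
    d = trace.mL - trace.mR
    sigma = np.empty(d.size, dtype=float)
    prev = 1.0
    for t in range(d.size):
        if d[t] > 0:
            prev = 1.0
        elif d[t] < 0:
            prev = -1.0
        sigma[t] = prev
    return SignSignal(sigma, trace.dt)


def _runs_above(m: np.ndarray, threshold: float) -> np.ndarray:
    above = np.concatenate([[False], m > threshold, [False]])
    edges = np.diff(above.astype(int))
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    return ends - starts


def persistence_times(
    trace: PopulationTrace, threshold: float = 0.1
) -> np.ndarray:
    """Durations (s) of maximal runs with m > threshold, pooled over L and R.

    For Monte Carlo traces, pass a trace whose ``dt`` is one round divided
    by the experimental frame rate, so durations come out in comparable
    seconds.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    runs = np.concatenate(
        [_runs_above(trace.mL, threshold), _runs_above(trace.mR, threshold)]
    )
    return runs * trace.dt


def power_spectrum(
    signal: np.ndarray,
    dt: float,
    method: str = "multitaper",
    time_halfbandwidth: float = 4.0,
    n_tapers: int = 7,
) -> tuple[np.ndarray, np.ndarray]:
    """One-sided spectral density of a (mean-subtracted) signal.

    "multitaper" averages eigenspectra over DPSS tapers with the given
    time-halfbandwidth product; "periodogram" is the plain boxcar
    estimate. Normalization is Parseval-consistent: sum(power) * df
    approximates the signal variance.
    """
    x = np.asarray(signal, dtype=float)
    if x.size < 64:
        raise ValueError("signal too short for spectral estimation (< 64 samples)")
    x = x - x.mean()
    fs = 1.0 / dt
    if method == "periodogram":
        f, p = periodogram(x, fs=fs, detrend=False)
        return f, p
    if method != "multitaper":
        raise ValueError("method must be 'multitaper' or 'periodogram'")
    n = x.size
    tapers = dpss(n, time_halfbandwidth, Kmax=n_tapers)  # unit-energy rows
    spec = np.fft.rfft(tapers * x, axis=1)
    pk = (np.abs(spec) ** 2) * dt
    # one-sided doubling (DC and, for even n, Nyquist are not doubled)
    pk[:, 1:] *= 2.0
    if n % 2 == 0:
        pk[:, -1] /= 2.0
    f = np.fft.rfftfreq(n, d=dt)
    return f, pk.mean(axis=0)


def lorentzian(f: np.ndarray, amplitude: float, k: float) -> np.ndarray:
    """Two-state (telegraph) process spectrum A * 2k / (4k^2 + (2 pi f)^2)."""
    return amplitude * 2.0 * k / (4.0 * k ** 2 + (2.0 * np.pi * f) ** 2)


def lorentzian_fit(
    frequencies: np.ndarray, power: np.ndarray, skip_low_bins: int = 2
) -> SpectrumFit:
    """Least-squares Lorentzian fit returning the switching rate kflip.

    Fits in linear power over positive frequencies, excluding the lowest
    ``skip_low_bins`` nonzero-frequency bins (spectral leakage).
    """
    f = np.asarray(frequencies, dtype=float)
    p = np.asarray(power, dtype=float)
    keep = f > 0
    f, p = f[keep], p[keep]
    f, p = f[skip_low_bins:], p[skip_low_bins:]
    if f.size < 8 or not (p > 0).any() or p.max() <= 0 or np.ptp(p) == 0:
        return SpectrumFit(f, p, np.nan, np.nan, np.inf, False)
    # initial k from the half-power frequency: S(f)=S_max/2 at 2 pi f = 2k
    pmax = p.max()
    above = f[p >= pmax / 2]
    k0 = np.pi * above.max() if above.size else f[0]
    a0 = pmax * 2.0 * k0
    try:
        popt, _ = curve_fit(
            lorentzian,
            f,
            p,
            p0=[a0, k0],
            bounds=([0.0, 1e-12], [np.inf, np.inf]),
            maxfev=20000,
        )
    except RuntimeError:
        return SpectrumFit(f, p, np.nan, np.nan, np.inf, False)
    amplitude, k = float(popt[0]), float(popt[1])
    residual = float(((lorentzian(f, *popt) - p) ** 2).sum())
    return SpectrumFit(f, p, k, amplitude, residual, True)


def activity_map(
    trace: PopulationTrace, bins: int = 10, alpha: float = 1.0
) -> ActivityMap2D:
    """Occupancy counts of (mL, mR) on a uniform bins x bins grid over [0,1]^2."""
    if bins < 2:
        raise ValueError("bins must be >= 2")
    edges = np.linspace(0.0, 1.0, bins + 1)
    counts, _, _ = np.histogram2d(trace.mL, trace.mR, bins=[edges, edges])
    return ActivityMap2D(counts.astype(int), alpha=alpha)


def kl_divergence(P, Q) -> float:
    """D_KL = sum_i P_i log10(P_i / Q_i), base-10 by convention.

    Accepts ActivityMap2D pairs (same grid and pseudocount required) or
    plain probability arrays.
    """
    if isinstance(P, ActivityMap2D) or isinstance(Q, ActivityMap2D):
        if not (isinstance(P, ActivityMap2D) and isinstance(Q, ActivityMap2D)):
            raise TypeError("P and Q must both be maps or both arrays")
        if P.bins != Q.bins or P.alpha != Q.alpha:
            raise ValueError("maps must share grid size and pseudocount")
        p, q = P.probabilities.ravel(), Q.probabilities.ravel()
    else:
        p = np.asarray(P, dtype=float).ravel()
        q = np.asarray(Q, dtype=float).ravel()
        if p.shape != q.shape:
            raise ValueError("P and Q must have the same shape")
    mask = p > 0
    return float(np.sum(p[mask] * np.log10(p[mask] / q[mask])))


def pearson_pair_correlations(raster: SpikeRaster) -> PairCorrelations:
    """Pairwise Pearson correlations split into ipsi- and contralateral pairs.

    Neurons with constant activity are skipped (and counted) since their
    correlation is undefined.
    """
    li = set(raster.side_index("L").tolist())
    A = raster.activity.astype(float)
    sd = A.std(axis=1)
    keep = np.flatnonzero(sd > 0)
    n_skipped = raster.n_neurons - keep.size
    C = np.corrcoef(A[keep])
    ipsi, contra = [], []
    for a in range(keep.size):
        for b in range(a + 1, keep.size):
            same = (keep[a] in li) == (keep[b] in li)
            (ipsi if same else contra).append(C[a, b])
    return PairCorrelations(
        np.asarray(ipsi), np.asarray(contra), n_skipped
    )
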