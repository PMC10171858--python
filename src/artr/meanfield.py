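"""Two-population mean-field reduction and free-energy landscape analysis.

Replacing the heterogeneous biases and couplings by their population
averages reduces the Ising model to seven parameters (HL, HR, JL, JR,
KL, KR, I) and a Bragg-Williams free energy over the mean activities
(mL, mR):

    F = -KL HL mL - KR HR mR - (JL KL^2 / 2) mL^2 - (JR KR^2 / 2) mR^2
        - I KL KR mL mR + KL s(mL) + KR s(mR),
    s(m) = m ln m + (1 - m) ln(1 - m).

Its stationary points satisfy the self-consistency equations
m = sigmoid(H + J K m + I K' m'), its local minima are the metastable
states, and the barrier along the bottleneck (min-max) grid path sets
the Arrhenius switching time t ~ tau exp(dF). Langevin dynamics with
per-effective-neuron mobility samples exp(-F) exactly.
"""
from __future__ import annotations

import heapq
import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from ._kernels import langevin_chain, langevin_escape
from .activity import ActivityMap2D, PopulationTrace, activity_map, kl_divergence, persistence_times
from .ising import IsingModel, SpikeRaster

EPS = 1e-4  # clamp for the entropy divergence at m = 0, 1

__all__ = [
    "MeanFieldModel",
    "FixedPoint",
    "Minimum",
    "Barrier",
    "Landscape",
    "LangevinTrace",
    "reduce_to_meanfield",
    "free_energy",
    "free_energy_gradient",
    "fixed_points",
    "landscape",
    "barriers",
    "arrhenius_time",
    "langevin_simulate",
    "langevin_escape_times",
    "fit_effective_K",
    "persistence_from_langevin",
]


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class MeanFieldModel:
    HL: float
    HR: float
    JL: float
    JR: float
    KL: float
    KR: float
    I: float

    def __post_init__(self):
        if self.KL <= 0 or self.KR <= 0:
            raise ValueError("effective sizes KL, KR must be positive")

    def tilted(self, dHL: float, dHR: float) -> "MeanFieldModel":
        return MeanFieldModel(
            self.HL + dHL, self.HR + dHR,
            self.JL, self.JR, self.KL, self.KR, self.I,
        )


@dataclass
class FixedPoint:
    mL: float
    mR: float
    kind: str  # "minimum", "saddle" or "maximum"


@dataclass
class Minimum:
    mL: float
    mR: float
    F: float
    label: str  # e.g. "low-low", "high-low"


@dataclass
class Barrier:
    from_label: str
    to_label: str
    dF: float
    saddle_F: float
    path: np.ndarray  # (n_points, 3) of (mL, mR, F)


@dataclass
class Landscape:
    grid: np.ndarray  # shared 1-D grid for both axes, in (0, 1)
    F: np.ndarray  # F[i, j] = F(grid[i], grid[j]) with mL = grid[i]
    minima: list  # of Minimum
    mf: MeanFieldModel | None = None
    _barriers: list | None = field(default=None, repr=False)


@dataclass
class LangevinTrace:
    mL: np.ndarray
    mR: np.ndarray
    dt_integration: float
    tau: float = 1.0
    record_every: int = 1

    @property
    def dt_seconds(self) -> float:
        return self.tau * self.dt_integration * self.record_every


def reduce_to_meanfield(
    model: IsingModel,
    K_override: tuple[float, float] | None = None,
    reference: SpikeRaster | None = None,
    **fit_kwargs,
) -> MeanFieldModel:
    """Average (h, J) over populations; effective sizes from fit or override.

    HL is the mean bias over left neurons, JL the mean coupling over
    distinct ipsilateral left pairs, I the mean contralateral coupling.
    The effective sizes default to the raw population counts unless a
    reference raster is given (then fitted by ``fit_effective_K``) or an
    override is passed.
    """
    li = model.side_index("L")
    ri = model.side_index("R")
    if li.size < 2 or ri.size < 2:
        raise ValueError("each side needs >= 2 neurons for ipsilateral pairs")
    HL = float(model.h[li].mean())
    HR = float(model.h[ri].mean())

    def ipsi_mean(idx):
        sub = model.J[np.ix_(idx, idx)]
        iu = np.triu_indices(idx.size, k=1)
        return float(sub[iu].mean())

    JL = ipsi_mean(li)
    JR = ipsi_mean(ri)
    I = float(model.J[np.ix_(li, ri)].mean())
    if K_override is not None:
        KL, KR = K_override
    elif reference is not None:
        base = MeanFieldModel(HL, HR, JL, JR, float(li.size), float(ri.size), I)
        KL, KR = fit_effective_K(base, reference, **fit_kwargs)[:2]
    else:
        KL, KR = float(li.size), float(ri.size)
    return MeanFieldModel(HL, HR, JL, JR, KL, KR, I)


def _entropy(m):
    return m * np.log(m) + (1.0 - m) * np.log1p(-m)


def free_energy(mf: MeanFieldModel, mL, mR):
    """Bragg-Williams free energy; arguments clamped into [EPS, 1-EPS]."""
    mL = np.clip(np.asarray(mL, dtype=float), EPS, 1.0 - EPS)
    mR = np.clip(np.asarray(mR, dtype=float), EPS, 1.0 - EPS)
    out = (
        -mf.KL * mf.HL * mL
        - mf.KR * mf.HR * mR
        - 0.5 * mf.JL * mf.KL ** 2 * mL ** 2
        - 0.5 * mf.JR * mf.KR ** 2 * mR ** 2
        - mf.I * mf.KL * mf.KR * mL * mR
        + mf.KL * _entropy(mL)
        + mf.KR * _entropy(mR)
    )
    return out if out.ndim else float(out)


def free_energy_gradient(mf: MeanFieldModel, mL, mR):
    """(dF/dmL, dF/dmR); vanishes exactly at the sigmoid fixed points."""
    mL = np.asarray(mL, dtype=float)
    mR = np.asarray(mR, dtype=float)
    gL = mf.KL * (
        -mf.HL - mf.JL * mf.KL * mL - mf.I * mf.KR * mR
        + np.log(mL / (1.0 - mL))
    )
    gR = mf.KR * (
        -mf.HR - mf.JR * mf.KR * mR - mf.I * mf.KL * mL
        + np.log(mR / (1.0 - mR))
    )
    return gL, gR


def _hessian(mf: MeanFieldModel, mL: float, mR: float) -> np.ndarray:
    hLL = mf.KL * (-mf.JL * mf.KL + 1.0 / (mL * (1.0 - mL)))
    hRR = mf.KR * (-mf.JR * mf.KR + 1.0 / (mR * (1.0 - mR)))
    hLR = -mf.I * mf.KL * mf.KR
    return np.array([[hLL, hLR], [hLR, hRR]])


def fixed_points(
    mf: MeanFieldModel,
    n_seeds: int = 20,
    damping: float = 0.5,
    tol: float = 1e-12,
    max_iter: int = 5000,
    dedupe: float = 1e-3,
) -> list[FixedPoint]:
    """Solutions of m = sigmoid(H + J K m + I K' m') from a seed grid.

    Damped fixed-point iteration finds the stable solutions; Newton
    refinement of the gradient from the same seeds also captures saddles.
    Points are deduplicated at ``dedupe`` and classified by the Hessian
    of F (both eigenvalues positive: minimum; mixed signs: saddle).
    """
    seeds = np.linspace(0.02, 0.98, n_seeds)
    found: list[tuple[float, float]] = []

    def push(mL, mR):
        if not (EPS < mL < 1 - EPS and EPS < mR < 1 - EPS):
            mL = min(max(mL, EPS), 1 - EPS)
            mR = min(max(mR, EPS), 1 - EPS)
        for a, b in found:
            if abs(a - mL) < dedupe and abs(b - mR) < dedupe:
                return
        found.append((mL, mR))

    for sL, sR in itertools.product(seeds, seeds):
        mL, mR = sL, sR
        for _ in range(max_iter):
            nL = _sigmoid(mf.HL + mf.JL * mf.KL * mL + mf.I * mf.KR * mR)
            nR = _sigmoid(mf.HR + mf.JR * mf.KR * mR + mf.I * mf.KL * mL)
            nL = (1 - damping) * mL + damping * nL
            nR = (1 - damping) * mR + damping * nR
            if abs(nL - mL) < tol and abs(nR - mR) < tol:
                mL, mR = nL, nR
                break
            mL, mR = nL, nR
        push(mL, mR)

    # Newton iteration on the gradient catches saddle points too
    for sL, sR in itertools.product(seeds[::2], seeds[::2]):
        m = np.array([sL, sR])
        ok = False
        for _ in range(200):
            g = np.array(free_energy_gradient(mf, m[0], m[1]))
            H = _hessian(mf, m[0], m[1])
            try:
                step = np.linalg.solve(H, g)
            except np.linalg.LinAlgError:
                break
            m = np.clip(m - step, EPS, 1 - EPS)
            if np.abs(g).max() < 1e-10:
                ok = True
                break
        if ok:
            push(float(m[0]), float(m[1]))

    out = []
    for mL, mR in found:
        w = np.linalg.eigvalsh(_hessian(mf, mL, mR))
        if (w > 0).all():
            kind = "minimum"
        elif (w < 0).all():
            kind = "maximum"
        else:
            kind = "saddle"
        out.append(FixedPoint(mL, mR, kind))
    return out


def _label_minima(points: list[tuple[float, float, float]]) -> list[Minimum]:
    coords = np.array([[p[0], p[1]] for p in points])
    vals = coords.ravel()
    if vals.max() - vals.min() < 1e-3:
        mid = vals.mean()  # single cluster; labels degenerate
    else:
        mid = 0.5 * (vals.min() + vals.max())
    out = []
    for mL, mR, F in points:
        lab_L = "high" if mL > mid else "low"
        lab_R = "high" if mR > mid else "low"
        out.append(Minimum(mL, mR, F, f"{lab_L}-{lab_R}"))
    return out


def landscape(mf: MeanFieldModel, grid_size: int = 200) -> Landscape:
    """Gridded free energy with descent-refined, labeled local minima."""
    if grid_size < 50:
        raise ValueError("grid_size must be >= 50")
    grid = np.linspace(EPS, 1.0 - EPS, grid_size)
    ML, MR = np.meshgrid(grid, grid, indexing="ij")
    F = free_energy(mf, ML, MR)

    # grid-local minima over the 8-neighborhood
    P = np.pad(F, 1, mode="constant", constant_values=np.inf)
    is_min = np.ones_like(F, dtype=bool)
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            if di == dj == 0:
                continue
            is_min &= F <= P[1 + di:1 + di + F.shape[0], 1 + dj:1 + dj + F.shape[1]]
    cand = np.argwhere(is_min)

    # refine by damped self-consistency iteration: stays within the basin
    # of the candidate (quasi-Newton refiners can jump basins on the
    # strongly anisotropic F near the corners)
    refined: list[tuple[float, float, float]] = []
    for i, j in cand:
        mL, mR = grid[i], grid[j]
        for _ in range(20000):
            nL = _sigmoid(mf.HL + mf.JL * mf.KL * mL + mf.I * mf.KR * mR)
            nR = _sigmoid(mf.HR + mf.JR * mf.KR * mR + mf.I * mf.KL * mL)
            nL = 0.7 * mL + 0.3 * nL
            nR = 0.7 * mR + 0.3 * nR
            if abs(nL - mL) < 1e-13 and abs(nR - mR) < 1e-13:
                mL, mR = nL, nR
                break
            mL, mR = nL, nR
        mL = min(max(mL, EPS), 1 - EPS)
        mR = min(max(mR, EPS), 1 - EPS)
        if (np.linalg.eigvalsh(_hessian(mf, mL, mR)) <= 0).any():
            continue  # drifted to a non-minimum stationary point
        dup = any(
            abs(mL - a) < 1e-3 and abs(mR - b) < 1e-3 for a, b, _ in refined
        )
        if not dup:
            refined.append((float(mL), float(mR), float(free_energy(mf, mL, mR))))
    return Landscape(grid, F, _label_minima(refined), mf=mf)


def _bottleneck_path(F: np.ndarray, start: tuple, goal: tuple):
    """Min-max (bottleneck) path on the 8-connected grid via Dijkstra.

    The cost of a path is the maximum F visited; returns (cost, path
    index list).
    """
    n, m = F.shape
    best = np.full((n, m), np.inf)
    prev = {}
    best[start] = F[start]
    heap = [(F[start], start)]
    while heap:
        c, (i, j) = heapq.heappop(heap)
        if (i, j) == goal:
            break
        if c > best[i, j]:
            continue
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                if di == dj == 0:
                    continue
                a, b = i + di, j + dj
                if 0 <= a < n and 0 <= b < m:
                    nc = max(c, F[a, b])
                    if nc < best[a, b]:
                        best[a, b] = nc
                        prev[(a, b)] = (i, j)
                        heapq.heappush(heap, (nc, (a, b)))
    path = [goal]
    while path[-1] != start:
        path.append(prev[path[-1]])
    path.reverse()
    return float(best[goal]), path


def barriers(land: Landscape) -> list[Barrier]:
    """Barriers dF(a -> b) = max F on the bottleneck path minus F(a).

    Computed for every ordered pair of labeled minima; results are cached
    on the landscape.
    """
    if land._barriers is not None:
        return land._barriers
    if len(land.minima) < 2:
        land._barriers = []
        return land._barriers
    grid = land.grid
    out = []
    for a, b in itertools.permutations(land.minima, 2):
        ia = (int(np.argmin(np.abs(grid - a.mL))), int(np.argmin(np.abs(grid - a.mR))))
        ib = (int(np.argmin(np.abs(grid - b.mL))), int(np.argmin(np.abs(grid - b.mR))))
        saddle, idx_path = _bottleneck_path(land.F, ia, ib)
        path = np.array(
            [[grid[i], grid[j], land.F[i, j]] for i, j in idx_path]
        )
        out.append(
            Barrier(a.label, b.label, max(saddle - a.F, 0.0), saddle, path)
        )
    land._barriers = out
    return out


def arrhenius_time(dF: float, tau: float) -> float:
    """Mean barrier-crossing time t = tau * exp(dF) (activated process)."""
    if dF < 0:
        raise ValueError("barrier height dF must be nonnegative")
    if tau <= 0:
        raise ValueError("tau must be positive")
    return tau * float(np.exp(dF))


def _max_drift_rate(mf: MeanFieldModel) -> float:
    # max |dm/dt| over a coarse probe grid of the open square
    g = np.linspace(0.05, 0.95, 10)
    ML, MR = np.meshgrid(g, g)
    gL, gR = free_energy_gradient(mf, ML, MR)
    return float(max(np.abs(gL / mf.KL).max(), np.abs(gR / mf.KR).max()))


def _check_step(mf: MeanFieldModel, dt: float):
    # per-step drift must stay small or Euler-Maruyama goes unstable
    drift = dt * _max_drift_rate(mf)
    if drift >= 0.1:
        raise ValueError(
            f"dt_integration too large: max per-step drift {drift:.3f} >= 0.1"
        )


def langevin_simulate(
    mf: MeanFieldModel,
    n_steps: int,
    dt_integration: float,
    seed: int,
    init: tuple[float, float] | None = None,
    tau: float = 1.0,
    record_every: int = 1,
) -> LangevinTrace:
    """Euler-Maruyama sampling of exp(-F) in the (mL, mR) plane.

    Per component: m += dt * (H + J K m + I K' m' - logit(m))
    + sqrt(2 dt / K) N(0,1), reflected into [EPS, 1-EPS]. ``tau`` only
    scales the physical time attached to the trace.
    """
    _check_step(mf, dt_integration)
    if init is None:
        init = (0.5, 0.5)
    m0L, m0R = init
    if not (EPS <= m0L <= 1 - EPS and EPS <= m0R <= 1 - EPS):
        raise ValueError("init must lie inside the clamped interval")
    out = langevin_chain(
        mf.HL, mf.HR, mf.JL, mf.JR, mf.I, mf.KL, mf.KR,
        int(n_steps), float(dt_integration), seed % (2 ** 31),
        float(m0L), float(m0R), EPS, int(record_every),
    )
    if not np.isfinite(out).all():
        raise FloatingPointError("Langevin integration produced non-finite values")
    return LangevinTrace(out[:, 0], out[:, 1], dt_integration, tau, record_every)


def langevin_escape_times(
    mf: MeanFieldModel,
    start: tuple[float, float],
    target: tuple[float, float],
    dt_integration: float,
    seed: int,
    n_replicates: int = 32,
    tol: float = 0.08,
    max_steps: int = 10_000_000,
) -> np.ndarray:
    """First-passage times (dimensionless) from one minimum to another."""
    _check_step(mf, dt_integration)
    t = langevin_escape(
        mf.HL, mf.HR, mf.JL, mf.JR, mf.I, mf.KL, mf.KR,
        float(dt_integration), seed % (2 ** 31),
        float(start[0]), float(start[1]), float(target[0]), float(target[1]),
        float(tol), EPS, int(max_steps), int(n_replicates),
    )
    if (t < 0).any():
        raise RuntimeError(
            f"{int((t < 0).sum())}/{n_replicates} escape replicates did not "
            f"arrive within {max_steps} steps"
        )
    return t


def trace_activity_map(trace: LangevinTrace, bins: int = 10, alpha: float = 1.0) -> ActivityMap2D:
    pt = PopulationTrace(np.clip(trace.mL, 0, 1), np.clip(trace.mR, 0, 1), trace.dt_seconds)
    return activity_map(pt, bins=bins, alpha=alpha)


def fit_effective_K(
    mf_base: MeanFieldModel,
    reference: SpikeRaster,
    K_grid: np.ndarray | None = None,
    n_steps: int = 400_000,
    dt_integration: float = 0.01,
    seed: int = 0,
    bins: int = 10,
) -> tuple[float, float, np.ndarray]:
    """Effective sizes minimizing the map KL between mean-field and data.

    Scans a common scale factor applied to (KL, KR) (keeping their ratio
    at the raw population-count ratio of ``mf_base``), simulating the
    Langevin dynamics at each candidate and scoring the base-10 KL
    divergence of the reference (mL, mR) map from the mean-field map.
    Returns (KL, KR, curve) with the scanned (K_mean, KL_div) curve.
    """
    from .activity import population_traces

    if K_grid is None:
        K_grid = np.linspace(2, mf_base.KL + mf_base.KR, 12) / 1.0
    data_map = activity_map(population_traces(reference), bins=bins)
    ratio = mf_base.KR / mf_base.KL
    curve = np.empty((len(K_grid), 2))
    best = (np.inf, None)
    for idx, K in enumerate(K_grid):
        KL, KR = float(K), float(K * ratio)
        cand = MeanFieldModel(
            mf_base.HL, mf_base.HR, mf_base.JL, mf_base.JR, KL, KR, mf_base.I
        )
        # larger K means stronger total drive J*K: shrink the step to
        # keep the per-step drift stable, holding total time fixed
        dt = min(dt_integration, 0.05 / _max_drift_rate(cand))
        steps = int(n_steps * dt_integration / dt)
        tr = langevin_simulate(cand, steps, dt, seed=seed)
        mmap = trace_activity_map(tr, bins=bins)
        d = kl_divergence(data_map, mmap)
        curve[idx] = (K, d)
        if d < best[0] - 1e-12:
            best = (d, (KL, KR))
    if best[1] is None:  # flat objective; take the smallest scanned K
        K = float(K_grid[0])
        best = (curve[0, 1], (K, K * ratio))
    return best[1][0], best[1][1], curve


def persistence_from_langevin(
    trace: LangevinTrace, threshold: float = 0.1
) -> np.ndarray:
    """Persistence durations of the Langevin mL/mR above the threshold."""
    pt = PopulationTrace(
        np.clip(trace.mL, 0, 1), np.clip(trace.mR, 0, 1), trace.dt_seconds
    )
    return persistence_times(pt, threshold=threshold)
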