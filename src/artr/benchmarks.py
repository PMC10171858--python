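"""End-to-end consistency checks exercised by the test suite and scripts.

Each function runs one self-contained pipeline on synthetic data with a
planted ground truth — landscape minima counting, exact-inference
recovery, sampler-vs-enumeration agreement, Arrhenius kinetics,
telegraph spectral recovery, matched-vs-mismatched model comparison,
stimulation-bias recovery, and the temperature-knob trend — and returns
the measured quantities. Problem sizes are chosen so the whole battery
runs in a few minutes on one core; see docs/methods.md.
"""
from __future__ import annotations

import itertools

import numpy as np

from .activity import (
    activity_map,
    kl_divergence,
    lorentzian_fit,
    persistence_times,
    population_traces,
    power_spectrum,
)
from .inference import FitConfig, fit_ising_exact, train_test_split
from .ising import EmpiricalMoments, IsingModel, all_states, exact_distribution, gibbs_sample, moments
from .meanfield import MeanFieldModel, barriers, landscape, langevin_escape_times
from .stimulation import StimEpochs, infer_delta_biases, solver_residuals
from .synth import PlantedSpec, generate_raster, generate_stim_dataset, planted_ising, telegraph_signal

__all__ = [
    "bistable_minima",
    "exact_recovery",
    "sampler_total_variation",
    "arrhenius_regression",
    "telegraph_recovery",
    "kl_model_comparison",
    "stimulation_recovery",
    "knob_trend",
]


def bistable_minima(grid_size: int = 200) -> dict:
    """Count landscape minima for a symmetric bistable parameter set.

    Per-side drive J*K = 12 at H = -5 puts each population in its
    bistable range; weak negative cross-talk I*K = -0.5 leaves all four
    combinations metastable.
    """
    mf = MeanFieldModel(HL=-5.0, HR=-5.0, JL=1.2, JR=1.2, KL=10.0, KR=10.0, I=-0.05)
    land = landscape(mf, grid_size=grid_size)
    return {
        "count": len(land.minima),
        "labels": sorted(m.label for m in land.minima),
        "landscape": land,
    }


def exact_recovery(seed: int = 0, n: int = 8) -> dict:
    """Parameter RMS error of the exact fit on enumerated planted moments."""
    rng = np.random.default_rng(seed)
    h = rng.uniform(-2.0, 0.0, n)
    iu = np.triu_indices(n, k=1)
    J = np.zeros((n, n))
    J[iu] = rng.uniform(-0.5, 0.5, iu[0].size)
    J += J.T
    truth = IsingModel(h, J)
    dist = exact_distribution(truth)
    S = all_states(n).astype(float)
    mean = S.T @ dist.probabilities
    pair = (S * dist.probabilities[:, None]).T @ S
    np.fill_diagonal(pair, mean)
    moms = EmpiricalMoments(mean, pair, n_bins=10 ** 12)
    fit, report = fit_ising_exact(
        moms, FitConfig(moment_tolerance=1e-9, max_iter=5000)
    )
    err2 = np.concatenate([fit.h - h, fit.J[iu] - J[iu]]) ** 2
    return {
        "rmse": float(np.sqrt(err2.mean())),
        "n": n,
        "converged": report.converged,
    }


def sampler_total_variation(
    seed: int = 0, n_rounds: int = 1_000_000
) -> dict:
    """Total-variation distance of a Gibbs chain from exact enumeration (N=10)."""
    truth = planted_ising(PlantedSpec(NL=5, NR=5, seed=seed))
    dist = exact_distribution(truth.model)
    raster = generate_raster(truth, n_rounds, dt=0.1, seed=seed + 1)
    n = truth.model.n_neurons
    weights = (1 << np.arange(n, dtype=np.uint32))[:, None]
    idx = (raster.activity.astype(np.uint32) * weights).sum(axis=0)
    emp = np.bincount(idx, minlength=2 ** n) / idx.size
    tv = 0.5 * float(np.abs(emp - dist.probabilities).sum())
    return {"tv": tv, "n_rounds": n_rounds}


def arrhenius_regression(
    seed: int = 0,
    K_grid=(45.0, 60.0, 75.0, 90.0),
    n_replicates: int = 96,
    dt_integration: float = 0.005,
) -> dict:
    """Slope of log mean Langevin escape time against the barrier height.

    The right population is decoupled (JR = I = 0) so the escape is a
    one-dimensional double-well problem in mL whose barrier is read off
    the landscape. The well shape is fixed (J*K = 5.5 with the low well
    at m = 0.1, away from the boundary and soft enough that the Euler
    step resolves it) and barrier heights are varied through the
    effective size K: the barrier scales linearly with K while the
    Kramers prefactor stays constant (curvatures scale with K, mobility
    with 1/K), so the activated-process law predicts slope exactly 1.
    """
    drive = 5.5
    H = float(np.log(0.1 / 0.9) - drive * 0.1)  # pins the low well at 0.1
    dFs, mean_times = [], []
    for i, K in enumerate(K_grid):
        mf = MeanFieldModel(HL=H, HR=-2.0, JL=drive / K, JR=0.0, KL=K, KR=K, I=0.0)
        land = landscape(mf)
        src = [m for m in land.minima if m.mL < 0.5][0]
        dst = [m for m in land.minima if m.mL > 0.5][0]
        dF = [
            b.dF for b in barriers(land)
            if b.from_label == src.label and b.to_label == dst.label
        ][0]
        t = langevin_escape_times(
            mf, (src.mL, src.mR), (dst.mL, dst.mR),
            dt_integration=dt_integration,
            seed=seed + 1000 * i,
            n_replicates=n_replicates,
        )
        dFs.append(dF)
        mean_times.append(float(t.mean()))
    slope = float(np.polyfit(dFs, np.log(mean_times), 1)[0])
    return {
        "slope": slope,
        "barrier_heights": dFs,
        "mean_escape_times": mean_times,
        "n_barriers": len(dFs),
    }


def telegraph_recovery(
    seed: int = 0,
    rates=(0.05, 0.2, 0.5),
    duration_s: float = 4096.0,
    dt: float = 0.125,
    n_average: int = 8,
) -> dict:
    """Relative error of Lorentzian-fitted kflip on simulated telegraphs."""
    rel_errs = {}
    for j, k in enumerate(rates):
        specs = []
        f = None
        for rep in range(n_average):
            x = telegraph_signal(k, duration_s, dt, seed=seed + 97 * j + rep)
            f, p = power_spectrum(x, dt, method="periodogram")
            specs.append(p)
        fit = lorentzian_fit(f, np.mean(specs, axis=0))
        rel_errs[k] = abs(fit.kflip - k) / k
    return {
        "rel_errors": rel_errs,
        "worst_rel_error": float(max(rel_errs.values())),
        "n_signals": n_average * len(rates),
    }


def _fitted_model_map(raster, seed):
    train, test = train_test_split(raster, 0.75, seed=seed)
    model, _ = fit_ising_exact(
        moments(train),
        FitConfig(moment_tolerance=1e-4, max_iter=300),
        side=train.side,
    )
    synth = gibbs_sample(model, 20000, seed=seed + 1, dt=raster.dt)
    return test, activity_map(population_traces(synth))


def kl_model_comparison(seed: int = 0, n_replicates: int = 10) -> dict:
    """Matched vs mismatched model maps across two planted regimes.

    For each replicate, a cold-ish and a hot-ish regime are generated
    and fitted; a replicate succeeds when each regime's held-out map is
    closer (base-10 KL) to its own fitted model than to the other's.
    """
    wins = 0
    details = []
    for rep in range(n_replicates):
        s = seed + 10 * rep
        truth_a = planted_ising(PlantedSpec(NL=7, NR=7, temperature_knob=0.2, seed=s + 1))
        truth_b = planted_ising(PlantedSpec(NL=7, NR=7, temperature_knob=0.8, seed=s + 2))
        ra = generate_raster(truth_a, 20000, 0.1, seed=s + 3)
        rb = generate_raster(truth_b, 20000, 0.1, seed=s + 4)
        test_a, map_a = _fitted_model_map(ra, s + 5)
        test_b, map_b = _fitted_model_map(rb, s + 6)
        dm_a = activity_map(population_traces(test_a))
        dm_b = activity_map(population_traces(test_b))
        kaa = kl_divergence(dm_a, map_a)
        kab = kl_divergence(dm_a, map_b)
        kbb = kl_divergence(dm_b, map_b)
        kba = kl_divergence(dm_b, map_a)
        ok = kaa < kab and kbb < kba
        wins += ok
        details.append((kaa, kab, kbb, kba))
    return {"wins": wins, "n_replicates": n_replicates, "details": details}


def stimulation_recovery(
    seed: int = 0,
    n_bins_per_side: int = 20000,
    delta_ipsi: float = 1.5,
    delta_contra: float = 0.3,
) -> dict:
    """Recovery of a planted ipsilateral stimulation bias.

    Alternating 250-bin left/right epochs until each side accumulates
    ``n_bins_per_side`` stimulated bins; the bias solver then inverts the
    conditional-mean equation for every neuron.
    """
    truth = planted_ising(PlantedSpec(NL=10, NR=10, seed=seed))
    sides = itertools.cycle(["left", "right"])
    epochs, cursor = [], 0
    while cursor < 2 * n_bins_per_side:
        epochs.append((cursor, cursor + 250, next(sides)))
        cursor += 250
    epochs = StimEpochs(epochs)
    raster, epochs, truth = generate_stim_dataset(
        truth, delta_ipsi, delta_contra, seed=seed + 1, epochs=epochs
    )
    db = infer_delta_biases(truth.model, raster, epochs)
    li = truth.model.side_index("L")
    ri = truth.model.side_index("R")
    ipsi = np.concatenate([db.delta_left[li], db.delta_right[ri]])
    se = float(ipsi.std(ddof=1) / np.sqrt(ipsi.size))
    res = solver_residuals(truth.model, raster, epochs, db)
    return {
        "ipsi_mean": float(ipsi.mean()),
        "ipsi_se": se,
        "planted": delta_ipsi,
        "max_residual": float(res.max()),
        "n_bins_per_side": n_bins_per_side,
    }


def knob_trend(
    seed: int = 0,
    knobs=(0.1, 0.5, 0.9),
    n_bins: int = 30000,
    dt: float = 0.1,
) -> dict:
    """Mean activity and persistence across temperature-knob settings.

    Computed on the generated rasters and on rasters resampled from
    Ising models refitted to each raster's moments; both sequences
    should decrease as the knob moves toward the hot end.
    """
    act_data, pers_data, act_model, pers_model = [], [], [], []
    for j, knob in enumerate(knobs):
        truth = planted_ising(PlantedSpec(NL=7, NR=7, temperature_knob=knob, seed=seed + j))
        raster = generate_raster(truth, n_bins, dt, seed=seed + 100 + j)
        tr = population_traces(raster)
        act_data.append(0.5 * float(tr.mL.mean() + tr.mR.mean()))
        p = persistence_times(tr, 0.1)
        pers_data.append(float(p.mean()) if p.size else 0.0)
        model, _ = fit_ising_exact(
            moments(raster),
            FitConfig(moment_tolerance=1e-4, max_iter=300),
            side=raster.side,
        )
        resampled = gibbs_sample(model, n_bins, seed=seed + 200 + j, dt=dt)
        tm = population_traces(resampled)
        act_model.append(0.5 * float(tm.mL.mean() + tm.mR.mean()))
        pm = persistence_times(tm, 0.1)
        pers_model.append(float(pm.mean()) if pm.size else 0.0)

    dec = lambda x: all(a > b for a, b in zip(x, x[1:]))
    return {
        "knobs": list(knobs),
        "activity_data": act_data,
        "persistence_data": pers_data,
        "activity_model": act_model,
        "persistence_model": pers_model,
        "monotone": dec(act_data) and dec(pers_data) and dec(act_model) and dec(pers_model),
    }
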