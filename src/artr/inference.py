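"""Fitting the Ising model and its independent baseline to data moments.

The maximum-entropy problem — find (h, J) whose model moments match the
empirical <s_i> and <s_i s_j> — is solved by likelihood ascent. For
N <= 15 the gradient (data moments minus model moments) is computed by
exact enumeration and the convex negative log-likelihood is minimized
with L-BFGS; the stopping rule is a bound on the maximum absolute moment
deviation. For larger systems, model moments are estimated each step by
Gibbs sampling (Boltzmann-machine learning), with a convergence target
set relative to the data's own sampling noise: the fit cannot and should
not match moments below the data's binomial standard error.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from .ising import (
    EmpiricalMoments,
    IsingModel,
    SpikeRaster,
    all_states,
    gibbs_sample,
    moments,
)

EXACT_LIMIT = 15

__all__ = [
    "FitConfig",
    "FitReport",
    "GoodnessReport",
    "fit_independent",
    "fit_ising_exact",
    "fit_ising_mc",
    "train_test_split",
    "goodness_of_fit",
    "exact_log_likelihood",
    "pseudo_log_likelihood",
]


@dataclass
class FitConfig:
    learning_rate: float = 0.1
    max_iter: int = 2000
    moment_tolerance: float = 1e-6
    l2_penalty: float = 0.0
    mc_rounds_per_gradient: int = 2000
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.moment_tolerance <= 0:
            raise ValueError("moment_tolerance must be positive")
        if self.l2_penalty < 0:
            raise ValueError("l2_penalty must be nonnegative")
        if self.max_iter < 0 or self.mc_rounds_per_gradient < 1:
            raise ValueError("iteration counts must be positive")


@dataclass
class FitReport:
    converged: bool
    n_iter: int
    max_mean_deviation: float
    max_pair_deviation: float
    train_log_likelihood: float | None = None
    test_log_likelihood: float | None = None
    log_likelihood_path: list = field(default_factory=list)


@dataclass
class GoodnessReport:
    """Model-vs-test scatter of moments plus a per-bin log-likelihood."""

    mean_data: np.ndarray
    mean_model: np.ndarray
    pair_data: np.ndarray
    pair_model: np.ndarray
    log_likelihood_per_bin: float
    likelihood_kind: str  # "exact" or "pseudo"

    @property
    def pair_correlation(self) -> float:
        """Pearson correlation of model vs test off-diagonal pair moments."""
        n = self.pair_data.shape[0]
        iu = np.triu_indices(n, k=1)
        return float(np.corrcoef(self.pair_data[iu], self.pair_model[iu])[0, 1])


def _clamped_mean(mean: np.ndarray, n_bins: int) -> np.ndarray:
    eps = 1.0 / (2.0 * n_bins)
    return np.clip(mean, eps, 1.0 - eps)


def fit_independent(moms: EmpiricalMoments, side=None) -> IsingModel:
    """Couplings-free baseline: h_i = logit(<s_i>), J = 0.

    Empirical means of exactly 0 or 1 are clamped to 1/(2T) first so the
    biases stay finite.
    """
    mean = _clamped_mean(moms.mean, moms.n_bins)
    h = np.log(mean / (1.0 - mean))
    return IsingModel(h, np.zeros((h.size, h.size)), side=side)


def _unpack(theta: np.ndarray, n: int):
    h = theta[:n]
    J = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    J[iu] = theta[n:]
    J += J.T
    return h, J, iu


def _model_moments_exact(S: np.ndarray, h: np.ndarray, J: np.ndarray):
    logw = S @ h + 0.5 * np.einsum("ki,ki->k", S @ J, S)
    logz = logsumexp(logw)
    p = np.exp(logw - logz)
    mean = S.T @ p
    pair = (S * p[:, None]).T @ S
    np.fill_diagonal(pair, mean)
    return mean, pair, logz


def exact_log_likelihood(model: IsingModel, moms: EmpiricalMoments) -> float:
    """Per-bin average log-likelihood by enumeration (N <= 20)."""
    S = all_states(model.n_neurons).astype(float)
    logw = S @ model.h + 0.5 * np.einsum("ki,ki->k", S @ model.J, S)
    logz = logsumexp(logw)
    iu = np.triu_indices(model.n_neurons, k=1)
    return float(
        model.h @ moms.mean + model.J[iu] @ moms.pair[iu] - logz
    )


def pseudo_log_likelihood(model: IsingModel, raster: SpikeRaster) -> float:
    """Per-bin sum of log conditional sigmoids (any N), a likelihood proxy."""
    A = raster.activity.astype(float)
    X = model.h[:, None] + model.J @ A  # fields, (N, T)
    # log P(s_i | rest) = s*X - log(1+exp(X))
    ll = A * X - np.logaddexp(0.0, X)
    return float(ll.sum() / raster.n_bins)


def fit_ising_exact(
    moms: EmpiricalMoments, cfg: FitConfig | None = None, side=None
) -> tuple[IsingModel, FitReport]:
    """Maximum-likelihood (h, J) by enumeration-backed quasi-Newton ascent.

    Stops when the largest absolute deviation between model and data
    moments falls below ``cfg.moment_tolerance`` (for l2_penalty = 0 that
    deviation is exactly the likelihood gradient). The log-likelihood is
    recomputed at every iterate and never decreases.
    """
    cfg = cfg or FitConfig()
    n = moms.n_neurons
    if n > EXACT_LIMIT:
        raise ValueError(
            f"exact fitting enumerates 2^N states and is limited to "
            f"N <= {EXACT_LIMIT}, got N = {n}"
        )
    S = all_states(n).astype(float)
    mean_data = _clamped_mean(moms.mean, moms.n_bins)
    pair_data = moms.pair
    iu = np.triu_indices(n, k=1)
    target = np.concatenate([mean_data, pair_data[iu]])

    h0 = np.log(mean_data / (1.0 - mean_data))
    theta0 = np.concatenate([h0, np.zeros(iu[0].size)])

    path: list[float] = []

    def objective(theta):
        h, J, _ = _unpack(theta, n)
        mean, pair, logz = _model_moments_exact(S, h, J)
        ll = h @ mean_data + J[iu] @ pair_data[iu] - logz
        grad = np.concatenate([mean, pair[iu]]) - target
        pen = 0.0
        if cfg.l2_penalty > 0:
            pen = 0.5 * cfg.l2_penalty * (theta[n:] ** 2).sum()
            grad[n:] += cfg.l2_penalty * theta[n:]
        return -(ll - pen), grad

    def record(theta):
        h, J, _ = _unpack(theta, n)
        mmean, mpair, logz = _model_moments_exact(S, h, J)
        path.append(h @ mean_data + J[iu] @ pair_data[iu] - logz)

    if cfg.max_iter == 0:
        h, J, _ = _unpack(theta0, n)
        model = IsingModel(h, J, side=side)
        mmean, mpair, _ = _model_moments_exact(S, h, J)
        return model, FitReport(
            converged=False,
            n_iter=0,
            max_mean_deviation=float(np.abs(mmean - mean_data).max()),
            max_pair_deviation=float(np.abs((mpair - pair_data)[iu]).max()),
            train_log_likelihood=exact_log_likelihood(model, moms),
        )

    # L-BFGS occasionally stops on its internal progress test before the
    # gradient (= moment deviation) target; restarting resets its memory
    # and resumes progress on this convex problem.
    theta = theta0
    nit = 0
    for _ in range(8):
        res = minimize(
            objective,
            theta,
            jac=True,
            method="L-BFGS-B",
            callback=record,
            options={
                "maxiter": cfg.max_iter - nit,
                "gtol": cfg.moment_tolerance,
                "ftol": 0.0,
                "maxcor": 30,
            },
        )
        theta = res.x
        nit += int(res.nit)
        _, grad = objective(theta)
        if np.abs(grad).max() < cfg.moment_tolerance or nit >= cfg.max_iter:
            break
    res.nit = nit
    h, J, _ = _unpack(res.x, n)
    model = IsingModel(h, J, side=side)
    mmean, mpair, _ = _model_moments_exact(S, h, J)
    max_mean = float(np.abs(mmean - mean_data).max())
    max_pair = float(np.abs((mpair - pair_data)[iu]).max())
    report = FitReport(
        converged=bool(max(max_mean, max_pair) < cfg.moment_tolerance),
        n_iter=int(res.nit),
        max_mean_deviation=max_mean,
        max_pair_deviation=max_pair,
        train_log_likelihood=exact_log_likelihood(model, moms),
        log_likelihood_path=path,
    )
    return model, report


def fit_ising_mc(
    moms: EmpiricalMoments, cfg: FitConfig | None = None, side=None
) -> tuple[IsingModel, FitReport]:
    """Boltzmann-machine learning with Gibbs-sampled model moments.

    Each iteration estimates model moments from a persistent Gibbs chain
    of ``cfg.mc_rounds_per_gradient`` rounds and moves the parameters
    along (data - model) moments, preconditioned by the inverse diagonal
    Fisher information p(1-p) of each moment so sparse neurons (tiny
    moments, tiny gradients) converge at the same rate as active ones.
    Converged when every moment deviation is below 3x the data's
    binomial standard error — fitting below the data's own sampling
    noise is meaningless.
    """
    cfg = cfg or FitConfig()
    n = moms.n_neurons
    mean_data = _clamped_mean(moms.mean, moms.n_bins)
    pair_data = moms.pair.copy()
    iu = np.triu_indices(n, k=1)

    se_mean = np.sqrt(mean_data * (1 - mean_data) / moms.n_bins)
    pd = np.clip(pair_data[iu], 1.0 / (2 * moms.n_bins), 1 - 1.0 / (2 * moms.n_bins))
    se_pair = np.sqrt(pd * (1 - pd) / moms.n_bins)
    fisher_mean = mean_data * (1 - mean_data)
    fisher_pair = pd * (1 - pd)

    h = np.log(mean_data / (1.0 - mean_data))
    J = np.zeros((n, n))
    state = np.zeros(n)

    converged = False
    it = 0
    max_mean = np.inf
    max_pair = np.inf
    for it in range(1, cfg.max_iter + 1):
        model = IsingModel(h, J, side=side)
        raster = gibbs_sample(
            model,
            cfg.mc_rounds_per_gradient,
            seed=cfg.seed + it,
            init=state,
            burn_in_rounds=2 * n if it == 1 else 0,
        )
        state = raster.activity[:, -1].astype(float)
        mm = moments(raster)
        dev_mean = mean_data - mm.mean
        dev_pair = (pair_data - mm.pair)[iu]
        max_mean = float(np.abs(dev_mean).max())
        max_pair = float(np.abs(dev_pair).max())
        if (np.abs(dev_mean) < 3 * se_mean).all() and (
            np.abs(dev_pair) < 3 * se_pair
        ).all():
            converged = True
            break
        h = h + cfg.learning_rate * dev_mean / fisher_mean
        Jup = J[iu] + cfg.learning_rate * dev_pair / fisher_pair
        if cfg.l2_penalty > 0:
            Jup -= cfg.learning_rate * cfg.l2_penalty * J[iu]
        J = np.zeros((n, n))
        J[iu] = Jup
        J += J.T
    model = IsingModel(h, J, side=side)
    return model, FitReport(
        converged=converged,
        n_iter=it if cfg.max_iter > 0 else 0,
        max_mean_deviation=max_mean,
        max_pair_deviation=max_pair,
    )


def train_test_split(
    raster: SpikeRaster, fraction: float = 0.75, seed: int = 0
) -> tuple[SpikeRaster, SpikeRaster]:
    """Random split of time bins (without replacement) into train/test."""
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    T = raster.n_bins
    if T < 4:
        raise ValueError("raster too short to split (T < 4)")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(T)
    n_train = int(round(fraction * T))
    tr, te = np.sort(perm[:n_train]), np.sort(perm[n_train:])
    mk = lambda idx: SpikeRaster(
        raster.activity[:, idx], raster.dt, raster.side, raster.positions
    )
    return mk(tr), mk(te)


def goodness_of_fit(model: IsingModel, test: SpikeRaster) -> GoodnessReport:
    """Moment scatter and per-bin log-likelihood of a model on held-out bins.

    Model moments come from enumeration for N <= 20 and from a Gibbs
    sample otherwise; likewise the likelihood is exact for N <= 20 and a
    pseudo-likelihood (product of conditional sigmoids) above that,
    labeled as such.
    """
    if model.n_neurons != test.n_neurons:
        raise ValueError("model and raster dimensions disagree")
    mt = moments(test)
    n = model.n_neurons
    if n <= 20:
        S = all_states(n).astype(float)
        mmean, mpair, _ = _model_moments_exact(S, model.h, model.J)
        ll = exact_log_likelihood(model, mt)
        kind = "exact"
    else:
        sample = gibbs_sample(model, max(20000, 5 * test.n_bins), seed=0)
        ms = moments(sample)
        mmean, mpair = ms.mean, ms.pair
        ll = pseudo_log_likelihood(model, test)
        kind = "pseudo"
    return GoodnessReport(
        mean_data=mt.mean,
        mean_model=mmean,
        pair_data=mt.pair,
        pair_model=mpair,
        log_likelihood_per_bin=ll,
        likelihood_kind=kind,
    )
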