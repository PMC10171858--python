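"""Numba inner loops for Gibbs sampling and Langevin integration.

These kernels use numba's own Mersenne-Twister state (seeded inside the
kernel), so a given seed reproduces the same chain bit for bit regardless
of the caller's numpy Generator.
"""
import numpy as np
from numba import njit


@njit(cache=True)
def gibbs_chain(h, J, kind, dh, state0, seed, burn_steps):
    """Single-site Glauber chain with per-round bias schedule.

    h : (N,) baseline biases
    J : (N, N) symmetric couplings, zero diagonal
    kind : (n_rounds,) int index into the rows of ``dh`` (0 = spontaneous)
    dh : (n_kinds, N) additional biases per schedule entry
    state0 : (N,) initial binary configuration (float64 0/1)
    burn_steps : single-site updates discarded before recording

    Records one configuration per round (one round = N single-site updates,
    each on a uniformly chosen neuron).
    """
    np.random.seed(seed)
    N = h.shape[0]
    n_rounds = kind.shape[0]
    out = np.empty((n_rounds, N), dtype=np.uint8)
    s = state0.copy()
    # local fields f_i = sum_j J_ij s_j, maintained incrementally
    f = J @ s
    k0 = kind[0] if n_rounds > 0 else 0
    for _ in range(burn_steps):
        i = np.random.randint(N)
        x = h[i] + dh[k0, i] + f[i]
        p = 1.0 / (1.0 + np.exp(-x))
        new = 1.0 if np.random.random() < p else 0.0
        if new != s[i]:
            d = new - s[i]
            s[i] = new
            for j in range(N):
                f[j] += J[j, i] * d
    for r in range(n_rounds):
        k = kind[r]
        for _ in range(N):
            i = np.random.randint(N)
            x = h[i] + dh[k, i] + f[i]
            p = 1.0 / (1.0 + np.exp(-x))
            new = 1.0 if np.random.random() < p else 0.0
            if new != s[i]:
                d = new - s[i]
                s[i] = new
                for j in range(N):
                    f[j] += J[j, i] * d
        for j in range(N):
            out[r, j] = np.uint8(s[j])
    return out


@njit(cache=True, inline="always")
def _reflect(m, eps):
    if m < eps:
        m = 2.0 * eps - m
    elif m > 1.0 - eps:
        m = 2.0 * (1.0 - eps) - m
    # a huge noise kick could overshoot both walls; clamp as last resort
    if m < eps:
        m = eps
    elif m > 1.0 - eps:
        m = 1.0 - eps
    return m


@njit(cache=True)
def langevin_chain(HL, HR, JL, JR, I, KL, KR, n_steps, dt, seed,
                   m0L, m0R, eps, record_every):
    """Euler-Maruyama integration of the two-population mean-field dynamics.

    dm_side = dt * (H + J*K*m_side + I*K_other*m_other - logit(m_side))
              + sqrt(2*dt/K_side) * N(0,1)

    for which exp(-F) is the stationary density. Values are reflected into
    [eps, 1-eps]. Returns (n_steps // record_every, 2) array of (mL, mR).
    """
    np.random.seed(seed)
    n_rec = n_steps // record_every
    out = np.empty((n_rec, 2))
    mL = m0L
    mR = m0R
    sL = np.sqrt(2.0 * dt / KL)
    sR = np.sqrt(2.0 * dt / KR)
    r = 0
    for t in range(n_steps):
        gL = HL + JL * KL * mL + I * KR * mR - np.log(mL / (1.0 - mL))
        gR = HR + JR * KR * mR + I * KL * mL - np.log(mR / (1.0 - mR))
        mL = _reflect(mL + dt * gL + sL * np.random.normal(), eps)
        mR = _reflect(mR + dt * gR + sR * np.random.normal(), eps)
        if (t + 1) % record_every == 0:
            out[r, 0] = mL
            out[r, 1] = mR
            r += 1
    return out


@njit(cache=True)
def langevin_escape(HL, HR, JL, JR, I, KL, KR, dt, seed,
                    m0L, m0R, mtL, mtR, tol, eps, max_steps, n_rep):
    """First-passage times from (m0L, m0R) into a box around (mtL, mtR).

    Returns dimensionless first-passage times (steps * dt); -1.0 marks
    replicates that did not arrive within max_steps.
    """
    np.random.seed(seed)
    times = np.empty(n_rep)
    sL = np.sqrt(2.0 * dt / KL)
    sR = np.sqrt(2.0 * dt / KR)
    for rep in range(n_rep):
        mL = m0L
        mR = m0R
        times[rep] = -1.0
        for t in range(max_steps):
            gL = HL + JL * KL * mL + I * KR * mR - np.log(mL / (1.0 - mL))
            gR = HR + JR * KR * mR + I * KL * mL - np.log(mR / (1.0 - mR))
            mL = _reflect(mL + dt * gL + sL * np.random.normal(), eps)
            mR = _reflect(mR + dt * gR + sR * np.random.normal(), eps)
            if abs(mL - mtL) < tol and abs(mR - mtR) < tol:
                times[rep] = (t + 1) * dt
                break
    return times
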