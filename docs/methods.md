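# Methods

## Model

Binarized activity snapshots s = (s₁ … s_N) ∈ {0,1}^N of a bilateral
circuit are modeled by the pairwise maximum-entropy (Ising) distribution

    P(s) = exp( Σᵢ hᵢ sᵢ + Σ_{i<j} J_ij sᵢ sⱼ ) / Z,

the least-structured distribution reproducing the empirical means ⟨sᵢ⟩
and pairwise moments ⟨sᵢ sⱼ⟩. The temperature is absorbed into the
parameters (energy unit 1). The bias hᵢ sets a neuron's intrinsic
activity; the symmetric, zero-diagonal J_ij couple pairs. The model is
generative but deliberately not dynamical: Gibbs sampling explores
configuration space locally, and a Monte Carlo "round" (N single-site
updates at uniformly random sites) is only a proxy for time.

## Inference

Moment matching is a convex maximum-likelihood problem whose gradient is
(⟨s⟩_data − ⟨s⟩_model, ⟨ss⟩_data − ⟨ss⟩_model).

- **Exact mode (N ≤ 15).** Model moments by enumeration of the 2^N
  states; L-BFGS on the negative log-likelihood with the gradient
  threshold set to `moment_tolerance` — for zero L2 penalty the
  gradient *is* the moment deviation, so this is exactly the "stop when
  moments match to tolerance" rule. L-BFGS occasionally halts on its
  internal progress test first; the fit restarts it (fresh curvature
  memory) until the tolerance or the iteration budget is hit, and the
  returned deviations are always recomputed from the final parameters.
  The recorded likelihood path is non-decreasing.
- **MC mode (any N).** Boltzmann-machine learning: model moments are
  estimated each iteration from a persistent Gibbs chain of
  `mc_rounds_per_gradient` rounds, and parameters move along the moment
  deviation preconditioned by the inverse diagonal Fisher information
  p(1−p) of each data moment. Without preconditioning, sparse neurons
  (means of a few percent, the regime these recordings live in) produce
  gradients proportional to their tiny moments and converge orders of
  magnitude more slowly than active ones. Convergence is declared when
  every deviation is below 3× the data's binomial standard error —
  matching moments beyond the data's own sampling noise is meaningless.
  With MC-estimated moments this flag is conservative (the MC estimate
  adds its own noise), so long fits should inspect the reported
  deviations rather than the flag alone.
- **Independent baseline.** J = 0, hᵢ = logit⟨sᵢ⟩; empirical means of
  exactly 0 or 1 are clamped by the pseudocount 1/(2T) first.
- **Cross-validation.** 75% of time bins (chosen at random, seeded)
  train the model; the held-out 25% scores it by exact log-likelihood
  (N ≤ 20) or a clearly labeled pseudo-likelihood (product of
  single-site conditionals) above that.

## Population statistics

mS(t) = (1/N_S) Σ_{i∈S} sᵢ(t) for S ∈ {L, R}; the signed activity is
sign(mL − mR) with ties carrying the previous value (+1 at the first
bin; the tie rule is a convention, any fixed one works). Persistence
times are maximal runs of m above a threshold of 0.1, pooled over both
sides; the threshold shifts all durations but not comparisons across
conditions. Spectra use Thomson's multitaper estimator (DPSS tapers,
time-halfbandwidth 4, 7 tapers) or the plain periodogram for behavioral
±1 signals, normalized so that power integrates to variance (checked to
5%). Two-state switching rates come from least-squares Lorentzian fits
S(f) ∝ 2k / (4k² + (2πf)²) in linear power, excluding the two lowest
frequency bins (leakage; configurable). Activity maps are 10×10
histograms of (mL, mR) over [0,1]² with pseudocount α = 1, and model
comparison uses the base-10 Kullback–Leibler divergence
Σ P_i log₁₀(P_i / Q_i) with P the data map.

## Mean-field reduction

Averaging biases and couplings within and across the two populations
(H_L, H_R, J_L, J_R, I) and introducing effective sizes K_L, K_R gives
the Bragg–Williams free energy

    F = −K_L H_L mL − K_R H_R mR − ½ J_L K_L² mL² − ½ J_R K_R² mR²
        − I K_L K_R mL mR + K_L s(mL) + K_R s(mR),
    s(m) = m ln m + (1−m) ln(1−m),

whose stationarity conditions are exactly the self-consistency
equations m = σ(H + J K m + I K' m'). The K²/2 self-interaction (rather
than K(K−1)/2) is chosen deliberately so that this equivalence is
exact. P(mL, mR) ∝ exp(−F); local minima are the metastable states,
labeled low/high per coordinate against the midpoint of the two
fixed-point branches.

- **Minima.** Grid-local minima (default 200×200 over [ε, 1−ε],
  ε = 10⁻⁴) refined by damped self-consistency iteration, which cannot
  leave the basin it starts in (quasi-Newton refiners can, near the
  strongly anisotropic corners); Hessian-verified.
- **Barriers.** ΔF(a→b) = (max F along the bottleneck path) − F(a),
  where the bottleneck (min-max) path on the 8-connected grid is found
  by a Dijkstra variant. The bottleneck path is exact for the barrier
  height and approximate for the path geometry; note that between two
  states it may legitimately route through a third, lower saddle, so
  "barriers" between non-adjacent states can tie with the intermediate
  ones.
- **Langevin dynamics.** dm = −(1/K) ∂F/∂m dt + √(2 dt/K) ξ per
  component (Euler–Maruyama, reflecting boundaries at ε), the mobility
  convention for which exp(−F) is the exact stationary law — verified
  against direct quadrature of exp(−F). The printed noise normalization
  of the source equations together with a bare τ does not fix the
  stationary law by itself; τ here is a pure time unit attached to the
  trace. The integrator requires per-step drift < 0.1 (checked on a
  probe grid) and the step auto-shrinks during effective-size scans
  where the total drive J·K grows.
- **Arrhenius kinetics.** Escape times follow t ≈ τ exp(ΔF). The
  package's consistency check varies ΔF through K at fixed well shape
  (low well pinned at m = 0.1, drive J·K = 5.5): barriers scale
  linearly with K while the Kramers prefactor is K-independent
  (curvatures ∝ K, mobility ∝ 1/K), so the log-time-vs-ΔF slope is 1
  with no prefactor drift. Wells too close to the boundary or too stiff
  for the step (λ·dt ≳ 0.5) bias escape times and are avoided by this
  construction.
- **Effective sizes.** K_L, K_R are fitted by scanning a common scale
  (side ratio fixed) and minimizing the base-10 KL divergence between
  the data's (mL, mR) map and the Langevin-sampled mean-field map — a
  stated surrogate for "best match" between the reductions, since
  mean-field theory overestimates interactions and needs K below the
  raw neuron counts.

## Stimulation

During unilateral stimulation the couplings are held fixed and each
neuron gains a bias δh solving

    ρᵢ(δh) = (1/B) Σ_t σ(hᵢ + Σⱼ J_ij sⱼ(t) + δh) = ⟨sᵢ⟩_stim,

the sum running over the B recorded stimulated bins (the solver
conditions on observed network states; no resampling). ρᵢ is a mean of
sigmoids, hence strictly increasing; Brent's method on an exponentially
expanded bracket reaches residuals ≪ 10⁻⁸. Stimulated empirical means
of 0 or 1 are clamped by 1/(2B). Protocol simulation alternates the
extra biases per epoch over one continuous Gibbs chain. In the
mean-field picture stimulation adds ΔH to the stimulated side only,
tilting the landscape: the ipsilateral active state deepens, the
barrier into it shrinks, and at strong drive the inactive minimum
disappears.

## Behavior

Reorientation angles per swim bout are folded and fitted by maximum
likelihood (EM, 10 jittered restarts) as a two-component mixture:
half-Gaussian forwards centered at zero plus Gamma turns. The
classification threshold is the smallest angle where the weighted Gamma
density overtakes the weighted half-Gaussian (≈10° for realistic
parameters); the fitting method is the package's choice, the source
procedure being unspecified beyond the component families. Turns are
labeled L/R by sign (+ = left), and the orientational state — the sign
of the last turn, sampled at the 25 Hz video rate — is fitted by the
telegraph Lorentzian to give k_flip; 1/k_flip is the typical time spent
chaining same-direction turns.

A caveat the tests respect: when the orientational state is observed
only at sparse turn events (turn rate comparable to k_flip), the
reconstructed signal misses hidden flips between turns and the fitted
rate is biased low. Rate-recovery assertions therefore use densely
sampled state signals; the sparse bout pipeline is checked for ordering
and switch-count consistency instead.

## Synthetic data generator

Planted models place NL + NR neurons uniformly in two lateral boxes
(~60 µm scale) and draw parameters with the marginal statistics
reported for recording-scale inferred models: biases
Normal(−4.1, 1.1), ipsilateral couplings with mean 0.062 and SD 0.12,
contralateral couplings with mean −0.001 and SD 0.10. The ipsilateral
mean decays exponentially with distance (default e-folding 40 µm, the
scale of the simulated anatomy): the standardized exp(−d/λ) carries
half the marginal variance and independent noise the other half, so the
marginals stay on target while near pairs couple more strongly —
reconciling the reported marginals with the reported decay exactly is
underdetermined, and this split is the package's choice.

Those marginals describe ~300-neuron recordings; at test-scale N they
give a monostable low state (total drive J·(N−1) ≈ 0.9). The
`temperature_knob` therefore derives the (h, J) means from size-scaled
anchors chosen once from the 1-D self-consistency analysis:
cold (knob 0) H = −4.0, J·(Nₛ−1) = 9.5, I·Nₛ = −0.6 — bistable per
side with persistent high states; hot (knob 1) H = −3.6, J·(Nₛ−1) = 5.0,
I·Nₛ = −0.3 — only the low state survives. Intermediate knobs
interpolate linearly. No physical temperature law is claimed (none is
known for these parameters); the knob is an emulation device
reproducing the observed directionality: hotter → lower mean activity,
shorter persistence. SDs under the knob are kept modest (bias 0.3,
ipsilateral 15% of the mean) so the collective regime is
seed-reproducible.

Behavioral data: a hidden ±1 telegraph state with exponential dwells at
rate k_flip; bouts as a Poisson process (default 1 Hz); each bout
forward with probability 0.5 (angle Normal(0, 5°)) or a turn in the
hidden direction with Gamma(3, 12°) amplitude. Stimulation datasets
apply planted δh per epoch, with alternating epochs whose durations
come from {10, 15, 20, 25, 30} s (17 repetitions per side by default).

What the generator does not emulate: calcium indicator dynamics and
deconvolution errors (rasters are born binary), slow nonstationarity
across a session, anatomical asymmetries beyond unequal side counts,
and any mechanistic temperature dependence. Passing tests therefore
demonstrate the pipeline's internal consistency and recovery power on
data obeying its assumptions, not robustness to those real-data
effects.

## Numerical choices and problem sizes

Defaults chosen once for a few-minute single-core budget: Gibbs burn-in
10·N rounds (the source is silent; recorded in the call signature);
sampler update order uniformly random per the source's description;
enumeration guard N ≤ 20 (distributions) and N ≤ 15 (exact fits);
landscape grid 200, clamp ε = 10⁻⁴; Langevin step 0.005–0.01 with the
drift check above; Lorentzian fits skip 2 leakage bins; consistency
battery sizes: 10⁶ Gibbs rounds vs enumeration at N = 10, 96 Langevin
escape replicates per barrier at 4 barrier heights, 8×4096 s telegraph
signals per rate, 10 replicate regime-comparison fits at N = 14,
2×10⁴ stimulated bins per side at N = 20, 3 knob settings ×
3×10⁴-bin rasters. Random state: numpy Generators seeded everywhere;
the numba kernels seed their own Mersenne state, so chains are
reproducible bit for bit for a given seed.

## Known limitations

- Exact inference is capped at N = 15 by enumeration; beyond that the
  MC fit's accuracy is bounded by Gibbs sampling noise and its
  convergence flag is conservative.
- The mean-field free energy ignores parameter heterogeneity (notably
  the broad contralateral distribution); the effective-K fit
  compensates on average but not in detail.
- Bottleneck paths live on the grid: barrier heights converge with grid
  resolution, path geometry is only approximate, and profile endpoints
  match refined minima to grid resolution.
- Persistence times from Gibbs rounds are converted to seconds by the
  recording frame rate; the mapping of MC rounds to physical time is a
  proxy, not a dynamical claim.
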