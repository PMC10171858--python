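"""Mean-field reduction, landscape, barriers, Langevin and Arrhenius."""
import itertools

import numpy as np
import pytest

from artr import (
    IsingModel,
    MeanFieldModel,
    arrhenius_time,
    barriers,
    fit_effective_K,
    fixed_points,
    free_energy,
    landscape,
    langevin_simulate,
    persistence_from_langevin,
    reduce_to_meanfield,
)
from artr.meanfield import (
    EPS,
    Landscape,
    Minimum,
    _bottleneck_path,
    free_energy_gradient,
    langevin_escape_times,
    trace_activity_map,
)
from artr.synth import PlantedSpec, planted_ising


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


class TestReduction:
    def test_uniform_parameters_average_to_themselves(self):
        n = 6
        side = ["L"] * 3 + ["R"] * 3
        J = np.full((n, n), -0.02)
        J[:3, :3] = 0.1
        J[3:, 3:] = 0.1
        np.fill_diagonal(J, 0)
        model = IsingModel(np.full(n, -4.0), J, side=side)
        mf = reduce_to_meanfield(model, K_override=(3, 3))
        assert (mf.HL, mf.HR) == (-4.0, -4.0)
        assert mf.JL == pytest.approx(0.1) and mf.JR == pytest.approx(0.1)
        assert mf.I == pytest.approx(-0.02)

    def test_symmetric_contralateral_couplings_average_to_zero(self, rng):
        n = 8
        side = ["L"] * 4 + ["R"] * 4
        J = np.zeros((n, n))
        iu = np.triu_indices(n, k=1)
        vals = rng.uniform(-0.3, 0.3, iu[0].size)
        J[iu] = vals
        J += J.T
        cross = J[:4, 4:]
        J[:4, 4:] = cross - cross.mean()
        J[4:, :4] = (cross - cross.mean()).T
        model = IsingModel(np.zeros(n), 0.5 * (J + J.T), side=side)
        mf = reduce_to_meanfield(model, K_override=(4, 4))
        assert abs(mf.I) < 1e-12

    def test_planted_means_recovered(self):
        truth = planted_ising(PlantedSpec(NL=20, NR=20, seed=1))
        mf = reduce_to_meanfield(truth.model, K_override=(20, 20))
        pars = truth.effective_params
        # averages over ~190 pairs: sampling error ~ sd/sqrt(n_pairs)
        assert abs(mf.JL - pars["ipsi_mean"]) < 3 * pars["ipsi_sd"] / np.sqrt(190)
        assert abs(mf.HL - pars["bias_mean"]) < 3 * pars["bias_sd"] / np.sqrt(20)

    def test_single_neuron_side_rejected(self):
        model = IsingModel(np.zeros(3), np.zeros((3, 3)), side=["L", "R", "R"])
        with pytest.raises(ValueError):
            reduce_to_meanfield(model, K_override=(1, 2))


class TestFreeEnergy:
    def test_pure_entropy_value(self):
        mf = MeanFieldModel(0, 0, 0, 0, 10, 10, 0)
        assert free_energy(mf, 0.5, 0.5) == pytest.approx(-20 * np.log(2))

    def test_symmetry_under_side_exchange(self, bistable_mf):
        g = np.linspace(0.05, 0.95, 7)
        for a, b in itertools.product(g, g):
            assert free_energy(bistable_mf, a, b) == pytest.approx(
                free_energy(bistable_mf, b, a)
            )

    def test_gradient_matches_numerics(self, bistable_mf):
        rng = np.random.default_rng(0)
        for _ in range(20):
            mL, mR = rng.uniform(0.05, 0.95, 2)
            gL, gR = free_energy_gradient(bistable_mf, mL, mR)
            d = 1e-7
            nL = (free_energy(bistable_mf, mL + d, mR) - free_energy(bistable_mf, mL - d, mR)) / (2 * d)
            nR = (free_energy(bistable_mf, mL, mR + d) - free_energy(bistable_mf, mL, mR - d)) / (2 * d)
            assert gL == pytest.approx(nL, abs=1e-5)
            assert gR == pytest.approx(nR, abs=1e-5)

    def test_gradient_vanishes_at_fixed_points(self, bistable_mf):
        for fp in fixed_points(bistable_mf):
            gL, gR = free_energy_gradient(bistable_mf, fp.mL, fp.mR)
            assert max(abs(gL), abs(gR)) < 1e-6


class TestFixedPoints:
    def test_uncoupled_unique_sigmoid_point(self):
        mf = MeanFieldModel(-1.0, 0.5, 0, 0, 5, 5, 0)
        fps = [p for p in fixed_points(mf) if p.kind == "minimum"]
        assert len(fps) == 1
        assert fps[0].mL == pytest.approx(_sigmoid(-1.0), abs=1e-9)
        assert fps[0].mR == pytest.approx(_sigmoid(0.5), abs=1e-9)

    def test_bistable_sides_give_four_stable_points(self):
        """With H=-5 and J*K=12 per side and no cross-coupling, each side
        independently solves m = sigmoid(-5 + 12 m); a 1-D brute-force
        scan shows two stable branches, so the plane has 4 minima."""
        mf = MeanFieldModel(-5, -5, 1.2, 1.2, 10, 10, 0)
        grid = np.linspace(1e-4, 1 - 1e-4, 20001)
        f = _sigmoid(-5 + 12 * grid) - grid
        stable_1d = []
        for i in np.flatnonzero(np.diff(np.sign(f)) != 0):
            if f[i] > 0 > f[i + 1]:  # downward crossing = stable
                stable_1d.append(grid[i])
        assert len(stable_1d) == 2
        mins = [p for p in fixed_points(mf) if p.kind == "minimum"]
        assert len(mins) == 4
        for p in mins:
            assert min(abs(p.mL - s) for s in stable_1d) < 1e-3
            assert min(abs(p.mR - s) for s in stable_1d) < 1e-3

    def test_fixed_points_match_landscape_minima(self, bistable_mf):
        land = landscape(bistable_mf)
        stable = [(p.mL, p.mR) for p in fixed_points(bistable_mf) if p.kind == "minimum"]
        assert len(stable) == len(land.minima)
        for m in land.minima:
            assert min(
                abs(m.mL - a) + abs(m.mR - b) for a, b in stable
            ) < 1e-3


class TestLandscape:
    def test_strong_positive_bias_single_high_minimum(self):
        mf = MeanFieldModel(3.0, 3.0, 0, 0, 10, 10, 0)
        land = landscape(mf)
        assert len(land.minima) == 1
        assert land.minima[0].mL > 0.9 and land.minima[0].mR > 0.9

    def test_bistable_four_labeled_minima(self, bistable_mf):
        land = landscape(bistable_mf)
        assert sorted(m.label for m in land.minima) == [
            "high-high", "high-low", "low-high", "low-low",
        ]

    def test_low_low_is_global_minimum_in_hot_regime(self):
        # weak drive: the inactive state has the lowest free energy
        mf = MeanFieldModel(-3.8, -3.8, 0.6, 0.6, 10, 10, -0.03)
        land = landscape(mf)
        ll = [m for m in land.minima if m.label == "low-low"][0]
        assert all(ll.F <= m.F for m in land.minima)

    def test_grid_size_guard(self, bistable_mf):
        with pytest.raises(ValueError):
            landscape(bistable_mf, grid_size=20)


class TestBarriers:
    def test_single_minimum_no_barriers(self):
        mf = MeanFieldModel(2.0, 2.0, 0, 0, 5, 5, 0)
        assert barriers(landscape(mf)) == []

    def test_separable_double_well_saddle_equals_1d_maximum(self):
        """With JR = I = 0 the landscape separates; the 2-D bottleneck
        barrier must equal the 1-D barrier of the mL profile."""
        mf = MeanFieldModel(-5.0, -2.0, 1.0, 0.0, 10, 10, 0.0)
        land = landscape(mf, grid_size=400)
        lows = sorted(land.minima, key=lambda m: m.mL)
        b = [
            x for x in barriers(land)
            if x.from_label == lows[0].label and x.to_label == lows[1].label
        ][0]
        grid = np.linspace(EPS, 1 - EPS, 100001)
        mR_star = _sigmoid(-2.0)
        prof = free_energy(mf, grid, np.full_like(grid, mR_star))
        i0 = np.argmin(np.abs(grid - lows[0].mL))
        i1 = np.argmin(np.abs(grid - lows[1].mL))
        saddle_1d = prof[min(i0, i1):max(i0, i1)].max()
        assert b.saddle_F == pytest.approx(saddle_1d, abs=2e-3)

    def test_bottleneck_path_matches_bruteforce_on_toy_grid(self, rng):
        F = rng.random((5, 5))
        start, goal = (0, 0), (4, 4)
        cost, _ = _bottleneck_path(F, start, goal)

        # exhaustive DFS over simple paths (8-connected)
        best = [np.inf]

        def dfs(pos, seen, cur):
            if cur >= best[0]:
                return
            if pos == goal:
                best[0] = cur
                return
            i, j = pos
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    a, b = i + di, j + dj
                    if (di, dj) != (0, 0) and 0 <= a < 5 and 0 <= b < 5 and (a, b) not in seen:
                        dfs((a, b), seen | {(a, b)}, max(cur, F[a, b]))

        dfs(start, {start}, F[start])
        assert cost == pytest.approx(best[0])

    def test_barrier_decreases_with_ipsilateral_bias_increment(self):
        """Tilting HL lowers the barrier from low-low toward high-low."""
        heights = []
        for dH in np.linspace(0.0, 0.4, 5):
            mf = MeanFieldModel(-5.0 + dH, -5.0, 1.2, 1.2, 10, 10, -0.05)
            land = landscape(mf)
            b = [
                x for x in barriers(land)
                if x.from_label == "low-low" and x.to_label == "high-low"
            ][0]
            heights.append(b.dF)
        assert all(a > b for a, b in zip(heights, heights[1:]))


class TestArrhenius:
    def test_trivial_values(self):
        assert arrhenius_time(0.0, 2.5) == 2.5
        assert arrhenius_time(np.log(10), 1.0) == pytest.approx(10.0)

    def test_negative_barrier_rejected(self):
        with pytest.raises(ValueError):
            arrhenius_time(-0.1, 1.0)

    def test_escape_time_slope_near_unity(self):
        """log mean escape time grows with barrier height with slope 1."""
        from artr.benchmarks import arrhenius_regression

        r = arrhenius_regression(seed=3, n_replicates=24)
        assert abs(r["slope"] - 1.0) < 0.2


class TestLangevin:
    def test_seed_determinism(self, bistable_mf):
        t1 = langevin_simulate(bistable_mf, 2000, 0.01, seed=5)
        t2 = langevin_simulate(bistable_mf, 2000, 0.01, seed=5)
        np.testing.assert_array_equal(t1.mL, t2.mL)

    def test_single_well_stationary_statistics(self):
        """For J = I = 0 the stationary law is exp(-F) for a single
        entropy well: the sampled mean matches direct quadrature of
        exp(-F) tightly, and the independent-unit limit sigmoid(H) and
        variance m(1-m)/K to the O(1/K) accuracy expected at K=100."""
        from scipy.integrate import quad

        H, K = -1.0, 100.0
        mf = MeanFieldModel(H, H, 0, 0, K, K, 0)
        m_star = _sigmoid(H)
        tr = langevin_simulate(
            mf, 1_200_000, 0.003, seed=8, init=(m_star, m_star)
        )
        samples = np.concatenate([tr.mL[5000:], tr.mR[5000:]])

        F = lambda m: free_energy(mf, m, m_star) - free_energy(mf, m_star, m_star)
        Z = quad(lambda m: np.exp(-F(m)), 1e-6, 1 - 1e-6)[0]
        quad_mean = quad(lambda m: m * np.exp(-F(m)), 1e-6, 1 - 1e-6)[0] / Z
        assert samples.mean() == pytest.approx(quad_mean, rel=0.005)
        assert samples.mean() == pytest.approx(m_star, rel=0.02)
        assert samples.var() == pytest.approx(m_star * (1 - m_star) / K, rel=0.05)

    def test_bistable_occupancy_of_both_asymmetric_states(self):
        mf = MeanFieldModel(-4.0, -4.0, 0.95, 0.95, 10, 10, -0.06)
        tr = langevin_simulate(mf, 600_000, 0.01, seed=9)
        left_active = (tr.mL > 0.5) & (tr.mR < 0.5)
        right_active = (tr.mR > 0.5) & (tr.mL < 0.5)
        assert left_active.mean() > 0.02
        assert right_active.mean() > 0.02

    def test_oversized_step_rejected(self, bistable_mf):
        with pytest.raises(ValueError):
            langevin_simulate(bistable_mf, 100, 0.5, seed=0)

    def test_persistence_longer_in_stickier_regime(self):
        """Lowering the barrier out of the active states shortens the
        Langevin persistence above threshold."""
        res = {}
        for tag, H in (("sticky", -3.95), ("loose", -4.15)):
            mf = MeanFieldModel(H, H, 0.95, 0.95, 10, 10, -0.06)
            tr = langevin_simulate(mf, 400_000, 0.01, seed=10)
            res[tag] = persistence_from_langevin(tr, 0.1).mean()
        assert res["sticky"] > res["loose"]


class TestEffectiveK:
    def test_self_consistent_minimum(self):
        """Maps generated at K0 are best matched at K = K0 on the scan."""
        K0 = 10.0
        mf0 = MeanFieldModel(-4.0, -4.0, 0.95, 0.95, K0, K0, -0.06)
        ref_tr = langevin_simulate(mf0, 750_000, 0.004, seed=11)
        from artr.activity import kl_divergence

        ref_map = trace_activity_map(ref_tr)
        scores = {}
        for K in (5.0, 10.0, 20.0):
            mf = MeanFieldModel(-4.0, -4.0, 0.95, 0.95, K, K, -0.06)
            tr = langevin_simulate(mf, 750_000, 0.004, seed=12)
            scores[K] = kl_divergence(ref_map, trace_activity_map(tr))
        assert min(scores, key=scores.get) == K0

    def test_fit_effective_K_prefers_generating_scale(self):
        """End-to-end: Gibbs raster from a planted model is matched at an
        effective K no larger than the true neuron count."""
        from artr.synth import generate_raster

        truth = planted_ising(PlantedSpec(NL=7, NR=7, temperature_knob=0.4, seed=13))
        raster = generate_raster(truth, 30000, dt=0.1, seed=14)
        mf_base = reduce_to_meanfield(truth.model, K_override=(7, 7))
        KL, KR, curve = fit_effective_K(
            mf_base, raster, K_grid=np.array([3.0, 5.0, 7.0, 9.0, 12.0]),
            n_steps=200_000, seed=15,
        )
        assert KL <= 12.0
        assert curve.shape == (5, 2)
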