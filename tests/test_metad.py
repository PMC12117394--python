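"""Well-tempered metadynamics machinery against analytic and brute-force
references."""

import math

import numpy as np
import pytest

from tmdimer import metad as M

KT310 = M.KB * 310.0


class TestHillHeight:
    def test_zero_bias_gives_initial_height(self):
        assert M.wt_hill_height(0.0) == pytest.approx(0.05)

    def test_unit_exponent(self):
        V = (10.0 - 1.0) * KT310
        assert M.wt_hill_height(V) == pytest.approx(0.05 / math.e)

    def test_standard_metadynamics_limit(self):
        assert M.wt_hill_height(5.0, bias_factor=1e9) == pytest.approx(0.05, rel=1e-6)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            M.wt_hill_height(0.0, bias_factor=1.0)
        with pytest.raises(ValueError):
            M.wt_hill_height(0.0, T=0.0)


def _random_log(rng, n=1000):
    return M.HillsLog(
        time=np.sort(rng.uniform(0, 100, n)),
        center=rng.uniform(-2, 2, n),
        sigma=rng.uniform(0.02, 0.3, n),
        height=rng.uniform(0.001, 0.05, n),
        bias_factor=10.0,
        temperature=310.0,
    )


class TestSumHills:
    def test_single_hill_peaks_at_deposited_height(self):
        log = M.HillsLog([0.0], [0.5], [0.1], [0.03], 10.0, 310.0)
        grid = np.linspace(-2, 2, 4001)
        v = M.sum_hills(log, grid)
        assert v.max() == pytest.approx(0.03, abs=1e-6)
        assert grid[np.argmax(v)] == pytest.approx(0.5, abs=1e-3)

    def test_coincident_hills_add(self):
        log = M.HillsLog([0.0, 1.0], [0.5, 0.5], [0.1, 0.1], [0.03, 0.03], 10.0, 310.0)
        v = M.sum_hills(log, np.array([0.5]))
        assert v[0] == pytest.approx(0.06)

    def test_matches_double_loop_oracle(self, rng):
        log = _random_log(rng)
        grid = np.linspace(-3, 3, 301)
        oracle = np.zeros_like(grid)
        for k in range(log.n_hills):  # naive double loop
            for g in range(len(grid)):
                oracle[g] += log.height[k] * math.exp(
                    -((grid[g] - log.center[k]) ** 2) / (2 * log.sigma[k] ** 2)
                )
        np.testing.assert_allclose(M.sum_hills(log, grid), oracle, atol=1e-9)

    def test_time_slicing_and_empty_log(self, rng):
        log = _random_log(rng, n=50)
        grid = np.linspace(-3, 3, 101)
        before_first = M.sum_hills(log, grid, up_to_time=log.time[0] - 1e-9)
        assert np.abs(before_first).max() == 0.0
        np.testing.assert_allclose(
            M.sum_hills(log, grid, up_to_time=log.time[-1]), M.sum_hills(log, grid)
        )


class TestFESFromBias:
    def test_flat_bias_gives_flat_zero_fes(self):
        grid = np.linspace(0, 1, 11)
        fes = M.fes_from_bias(grid, np.full(11, 4.2), 10.0)
        assert np.abs(fes.values).max() == pytest.approx(0.0, abs=1e-12)

    def test_well_tempered_scale_factor(self):
        grid = np.linspace(0, 1, 3)
        fes = M.fes_from_bias(grid, np.array([0.0, 9.0, 0.0]), 10.0)
        # V peak of 9 kJ/mol maps to a 10 kJ/mol FES depth (factor f/(f-1))
        assert fes.values.max() == pytest.approx(10.0)
        assert fes.values[1] == 0.0


@pytest.fixture(scope="module")
def double_well_run():
    system = M.ToySystem.double_well(5.0, 1.0)
    run = M.run_wtmetad(system, n_steps=30_000_000, seed=11, stride=200)
    return system, run


class TestSampler:
    def test_identical_seeds_give_identical_hills(self):
        system = M.ToySystem.double_well(4.0, 0.5)
        r1 = M.run_wtmetad(system, n_steps=300_000, seed=3)
        r2 = M.run_wtmetad(system, n_steps=300_000, seed=3)
        assert r1.hills.center.tobytes() == r2.hills.center.tobytes()
        assert r1.hills.height.tobytes() == r2.hills.height.tobytes()
        assert r1.cv.tobytes() == r2.cv.tobytes()

    def test_zero_temperature_zero_bias_run_stays_at_minimum(self):
        system = M.ToySystem.harmonic(20.0, x0=0.5, temperature=0.0)
        run = M.run_wtmetad(system, n_steps=100_000, seed=0, W0=0.0)
        assert run.hills.n_hills == 0
        assert np.abs(run.cv - 0.5).max() < 1e-6

    def test_hill_heights_positive_bounded_and_envelope_decays(self):
        system = M.ToySystem.harmonic(80.0)
        run = M.run_wtmetad(system, n_steps=10_000_000, seed=4)
        h = run.hills.height
        assert (h > 0).all() and (h <= 0.05 + 1e-12).all()
        # block-averaged envelope decreases monotonically toward a small
        # fraction of W0 as the well fills
        env = h.reshape(20, -1).mean(axis=1)
        assert (np.diff(env) < 0).mean() > 0.8
        assert env[-1] < 0.8 * env[0]

    def test_unstable_run_aborts_with_diagnostic(self):
        # timestep far beyond the stability limit: Euler iteration diverges
        system = M.ToySystem.harmonic(50.0, timestep=1.0)
        with pytest.raises(RuntimeError, match="unstable"):
            M.run_wtmetad(system, n_steps=1_000_000, seed=0, x0=0.1)

    def test_unbounded_potential_rejected(self):
        with pytest.raises(ValueError):
            M.ToySystem(coeffs=(0.0, -50.0, 0.0, 0.0, 0.0))


class TestFESRecovery:
    def test_double_well_fes_matches_boltzmann_quadrature(self, double_well_run):
        """Basin free-energy difference from the recovered FES agrees with
        numerical quadrature of the analytic Boltzmann weight within 1 kT."""
        system, run = double_well_run
        fes = M.fes_from_bias(run.grid, run.bias_final, 10.0, system.temperature)
        right, left = (0.2, 2.0), (-2.0, -0.2)
        dg = M.basin_free_energy_difference(fes, right, left)
        ref = M.boltzmann_reference_dg(system, right, left)
        assert abs(dg - ref) < KT310

    def test_fes_profile_tracks_potential_in_sampled_region(self, double_well_run):
        system, run = double_well_run
        fes = M.fes_from_bias(run.grid, run.bias_final, 10.0, system.temperature)
        mask = (run.grid > -1.5) & (run.grid < 1.5)
        u = system.potential(run.grid[mask])
        dev = fes.values[mask] - (u - u.min())
        assert np.abs(dev - dev.mean()).max() < KT310


class TestReweighting:
    def test_zero_bias_gives_uniform_weights(self, rng):
        empty = M.HillsLog([], [], [], [], 10.0, 310.0)
        times = np.arange(100.0)
        cv = rng.normal(size=100)
        w = M.frame_weights(times, cv, empty)
        np.testing.assert_allclose(w, 1.0 / 100, atol=1e-12)
        centers, hist, _ = M.reweight_boltzmann(cv, cv, empty, times, bins=10)
        raw, edges = np.histogram(cv, bins=10, density=True)
        np.testing.assert_allclose(hist, raw, atol=1e-12)
        del centers, edges

    def test_reweighted_cv_fes_consistent_with_bias_fes(self, double_well_run):
        """Time-dependent reweighting reproduces the bias-derived FES within
        1 kT on the thermally sampled support (within ~4 kT of the minimum)."""
        system, run = double_well_run
        fes_b = M.fes_from_bias(run.grid, run.bias_final, 10.0, system.temperature)
        w = M.frame_weights(run.times, run.cv, run.hills, mode="time-dependent")
        fes_w = M.fes_from_weights(run.cv, w, bins=np.linspace(-1.8, 1.8, 73),
                                   temperature=system.temperature)
        ref = np.interp(fes_w.grid, fes_b.grid, fes_b.values)
        support = ref < 4 * KT310
        dev = fes_w.values[support] - ref[support]
        dev -= dev.mean()
        assert np.abs(dev).max() < KT310

    def test_independent_observable_recovers_boltzmann_marginal(self, rng):
        """Reweighting an observable independent of the CV returns that
        observable's unbiased distribution."""
        log = _random_log(rng, n=200)
        times = np.linspace(0, 100, 5000)
        cv = rng.uniform(-2, 2, size=5000)
        aux = rng.normal(0.0, 1.0, size=5000)
        centers, hist, w = M.reweight_boltzmann(cv, aux, log, times, bins=21)
        expected = np.exp(-0.5 * centers**2) / math.sqrt(2 * math.pi)
        tv = 0.5 * np.sum(np.abs(hist - expected)) * (centers[1] - centers[0])
        assert tv < 0.1
        del w

    def test_length_mismatch_is_hard_error(self, rng):
        log = _random_log(rng, n=10)
        with pytest.raises(ValueError):
            M.reweight_boltzmann(np.zeros(5), np.zeros(6), log, np.arange(5.0))


class TestDeltaG:
    @pytest.fixture()
    def fes(self):
        grid = np.linspace(0, 10, 201)
        vals = np.where(grid < 2, 0.0, 5.0)  # 5 kJ/mol deep bound well
        return M.FreeEnergySurface(grid, vals, 310.0)

    def test_bound_minus_unbound(self, fes):
        assert M.delta_g_bind(fes, (0.0, 2.0), (6.0, 10.0)) == pytest.approx(-5.0)

    def test_flat_fes_gives_zero(self):
        fes = M.FreeEnergySurface(np.linspace(0, 5, 51), np.zeros(51), 310.0)
        assert M.delta_g_bind(fes, (0, 1), (3, 5)) == 0.0

    def test_identical_windows_rejected(self, fes):
        with pytest.raises(ValueError):
            M.delta_g_bind(fes, (0.0, 2.0), (0.0, 2.0))

    def test_window_outside_grid_rejected(self, fes):
        with pytest.raises(ValueError):
            M.delta_g_bind(fes, (0.0, 2.0), (9.0, 12.0))

    def test_suggest_windows_finds_well_and_plateau(self):
        grid = np.linspace(0, 10, 501)
        vals = 8.0 * np.exp(-((grid - 1.5) ** 2) / 0.5) * -1 + 8.0
        vals[grid > 6] = vals[grid > 6.0][0]  # flat unbound tail
        fes = M.FreeEnergySurface(grid, vals - vals.min(), 310.0)
        bound, unbound = M.suggest_windows(fes)
        assert bound[0] <= 1.5 <= bound[1]
        assert unbound[0] > bound[1]
        # suggested windows feed straight into the estimator
        dg = M.delta_g_bind(fes, bound, unbound)
        assert dg < 0


class TestBlockAnalysis:
    def test_iid_error_plateaus_at_analytic_sem(self, rng):
        x = rng.normal(3.0, 2.0, 100_000)
        table = M.block_error_curve(x)
        sem = 2.0 / math.sqrt(len(x))
        assert list(table["n_blocks"][:2]) == [1, 10]
        assert table["n_blocks"].iloc[-1] == 1000
        plateau = table.loc[table["n_blocks"] >= 500, "error"]
        assert np.abs(plateau / sem - 1.0).max() < 0.2

    def test_single_block_error_is_undefined(self, rng):
        mean, err = M.weighted_block_error(rng.normal(size=100), None, 1)
        assert math.isnan(err)

    def test_more_blocks_than_samples_rejected(self, rng):
        with pytest.raises(ValueError):
            M.weighted_block_error(rng.normal(size=10), None, 11)

    def test_uniform_weights_match_plain_block_means(self, rng):
        x = rng.normal(size=1000)
        mean, err = M.weighted_block_error(x, np.full(1000, 0.37), 20)
        bm = x.reshape(20, 50).mean(axis=1)
        assert mean == pytest.approx(x.mean())
        assert err == pytest.approx(bm.std(ddof=1) / math.sqrt(20))


class TestConvergenceReport:
    def test_converged_run_has_stable_delta_g(self, double_well_run):
        system, run = double_well_run
        rep = M.convergence_report(run, (-1.4, -0.6), (0.6, 1.4),
                                   block_counts=np.arange(1, 101, 10))
        dg = rep.delta_g_series["delta_g"].to_numpy()
        final_third = dg[len(dg) * 2 // 3 :]
        assert np.ptp(final_third) < KT310
        assert rep.hill_heights["height"].iloc[-1] < 0.05
        assert len(rep.cv_trace) == len(run.cv)

    def test_more_blocks_than_frames_rejected(self, double_well_run):
        _, run = double_well_run
        with pytest.raises(ValueError):
            M.convergence_report(run, (-1.4, -0.6), (0.6, 1.4),
                                 block_counts=np.array([len(run.cv) + 1]))
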