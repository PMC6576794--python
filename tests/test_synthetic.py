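"""Generators: planted structure, reproducibility, agreement with particle oracles."""

import numpy as np
import pytest

from _oracles import branching_em, em_particles, histogram_density
from landscape_kinetics import fp
from landscape_kinetics import synthetic as syn


class TestTranscriptome:
    def test_zero_amplitudes_give_constant_genes(self):
        truth = syn.m397_like_transcriptome_truth(n_genes=50, noise_sd=0.0, seed=0)
        truth.constraint_amplitudes = np.zeros_like(truth.constraint_amplitudes)
        X = syn.gen_transcriptome(truth)
        assert np.allclose(X.values, X.values[:, :1])

    def test_strictly_positive_output(self):
        truth = syn.m397_like_transcriptome_truth(n_genes=100, noise_sd=0.3, seed=1)
        assert np.all(syn.gen_transcriptome(truth).values > 0)

    def test_non_orthogonal_patterns_rejected(self):
        truth = syn.m397_like_transcriptome_truth(n_genes=50, noise_sd=0.0, seed=0)
        truth.constraint_patterns[1] = truth.constraint_patterns[0]
        with pytest.raises(ValueError, match="orthogonal"):
            syn.gen_transcriptome(truth)

    def test_too_few_genes_rejected(self):
        truth = syn.m397_like_transcriptome_truth(n_genes=50, noise_sd=0.0, seed=0)
        truth.n_genes = 5
        with pytest.raises(ValueError):
            truth.validate()

    def test_identical_seeds_bit_identical(self):
        a = syn.gen_transcriptome(syn.m397_like_transcriptome_truth(200, 0.1, seed=4))
        b = syn.gen_transcriptome(syn.m397_like_transcriptome_truth(200, 0.1, seed=4))
        assert np.array_equal(a.values, b.values)


class TestFlowClouds:
    def test_identical_seeds_bit_identical(self):
        t = syn.m397_like_simulation_truth(n_grid=96, cells_per_timepoint=500, seed=8)
        a = syn.gen_flow_clouds(t, [0.0, 5.0])
        b = syn.gen_flow_clouds(t, [0.0, 5.0])
        for ca, cb in zip(a.clouds, b.clouds):
            assert np.array_equal(ca, cb)

    def test_zero_transverse_noise_lies_on_curve(self):
        t = syn.m397_like_simulation_truth(n_grid=96, cells_per_timepoint=300, seed=2)
        t.transverse_sd = 0.0
        clouds = syn.gen_flow_clouds(t, [3.0])
        expected = t.curve_map(np.asarray(clouds.true_coords[0]))
        assert np.allclose(clouds.clouds[0], expected)

    def test_quadratic_well_matches_particle_oracle_moments(self):
        """Projected samples of the long-time cloud match the stationary
        Gaussian simulated independently by Euler-Maruyama, within 3 SE."""
        grid = np.linspace(0.0, 6.0, 192)
        k, D = 1.0, 0.35
        U = (k / 4.0) * (grid - 3.0) ** 2  # mu = -2U' = -k(x-3)
        t = syn.SimulationTruth(grid=grid, U_true=U, alpha_true=np.zeros(192),
                                D_true=D, curve_map=syn.QuarterArcMap(length=6.0),
                                transverse_sd=0.0, cells_per_timepoint=20_000, seed=5)
        clouds = syn.gen_flow_clouds(t, [25.0])
        x = np.asarray(clouds.true_coords[0])
        rng = np.random.default_rng(99)
        part = em_particles(np.full(100_000, 3.0), lambda y: -k * (y - 3.0), D,
                            t_end=25.0, dt=0.005, rng=rng, bounds=(0.0, 6.0))
        se_mean = np.sqrt(part.var() / x.size + part.var() / part.size)
        assert abs(x.mean() - part.mean()) < 3 * se_mean
        se_var = np.sqrt(2) * part.var() * np.sqrt(1 / x.size + 1 / part.size)
        assert abs(x.var() - part.var()) < 3 * se_var

    def test_sample_histogram_converges_to_density(self):
        """L1 distance between sample histogram and solver density shrinks
        as the number of cells grows."""
        t = syn.m397_like_simulation_truth(n_grid=128, seed=3)
        series = fp.normalize_population(
            fp.solve_fp_source(t.model(), t.initial_density(), [11.0]))
        target = series.densities[0]
        coarse = np.linspace(0.0, 6.0, 48)
        tgt = np.interp(coarse, t.grid, target)
        tgt /= np.trapezoid(tgt, coarse)
        l1 = {}
        for n in (1_000, 100_000):
            t.cells_per_timepoint = n
            x = np.asarray(syn.gen_flow_clouds(t, [11.0]).true_coords[0])
            l1[n] = np.trapezoid(np.abs(histogram_density(x, coarse) - tgt), coarse)
        assert l1[100_000] < l1[1_000]
        assert l1[100_000] < 0.05


class TestSortingRelaxation:
    def test_empty_gate_rejected(self):
        t = syn.drug_naive_simulation_truth(n_grid=96, seed=0)
        with pytest.raises(ValueError, match="gate"):
            syn.gen_sorting_relaxation(t, (5.9, 6.0), [0.0, 1.0])

    def test_full_gate_is_stationary(self):
        t = syn.drug_naive_simulation_truth(n_grid=128, cells_per_timepoint=20_000, seed=1)
        clouds = syn.gen_sorting_relaxation(t, (0.0, 6.0), [0.0, 6.0])
        x0 = np.asarray(clouds.true_coords[0])
        x1 = np.asarray(clouds.true_coords[1])
        se = np.sqrt(x0.var() / x0.size + x1.var() / x1.size)
        assert abs(x0.mean() - x1.mean()) < 3 * se

    def test_gated_mass_decays_toward_steady_fraction(self):
        """Mass in the sorted gate relaxes monotonically toward the unsorted
        fraction; checked against an explicit finite-difference solve at
        10x grid resolution."""
        t = syn.drug_naive_simulation_truth(n_grid=64, seed=2)
        gate = (3.1, 6.0)
        times = [0.0, 1.0, 2.0, 4.0]
        steady = t.steady_state()
        mask = (t.grid >= gate[0]) & (t.grid <= gate[1])
        steady_frac = np.trapezoid(steady[mask], t.grid[mask])

        p0 = np.where(mask, steady, 0.0)
        p0 /= np.trapezoid(p0, t.grid)
        series = fp.solve_fp(t.model(with_growth=False), p0, times[1:])
        fracs = [1.0] + [np.trapezoid(r[mask], t.grid[mask]) for r in series.densities]
        assert all(a > b for a, b in zip(fracs, fracs[1:]))
        assert fracs[-1] > steady_frac

        fine = np.linspace(0.0, 6.0, 640)
        mu_f = np.interp(fine, t.grid, t.mu_true)
        p0_f = np.interp(fine, t.grid, p0)
        p0_f /= np.trapezoid(p0_f, fine)
        ref = _oracle_gate_fracs = []
        from _oracles import explicit_fd_solve

        sol_f = explicit_fd_solve(fine, t.D_true, mu_f, p0_f, times[1:])
        mask_f = (fine >= gate[0]) & (fine <= gate[1])
        for row, frac in zip(sol_f, fracs[1:]):
            frac_f = np.trapezoid(row[mask_f], fine[mask_f])
            assert abs(frac - frac_f) < 0.01

    def test_relaxation_approaches_unsorted_distribution(self):
        t = syn.drug_naive_simulation_truth(n_grid=128, seed=3)
        gate = (3.1, 6.0)
        steady = t.steady_state()
        p0 = np.where((t.grid >= gate[0]) & (t.grid <= gate[1]), steady, 0.0)
        p0 /= np.trapezoid(p0, t.grid)
        series = fp.solve_fp(t.model(with_growth=False), p0, [2.0, 30.0])
        l1 = [np.trapezoid(np.abs(r - steady), t.grid) for r in series.densities]
        assert l1[1] < l1[0]
        assert l1[1] < 0.02


class TestGrowthCounts:
    def test_exact_doubling(self):
        out = syn.gen_growth_counts(1.0, 100.0, [0.0, 1.0, 2.0], noise_cv=0.0)
        assert np.allclose(out["count"], [100.0, 200.0, 400.0])

    def test_zero_rate_constant(self):
        out = syn.gen_growth_counts(0.0, 50.0, [0.0, 3.0, 9.0], noise_cv=0.0)
        assert np.allclose(out["count"], 50.0)

    def test_noisy_refit_recovers_rate(self):
        """Log-linear least squares on noisy counts recovers the rate
        within 10%."""
        times = np.linspace(0.0, 10.0, 6)
        out = syn.gen_growth_counts(0.3, 1e4, times, noise_cv=0.05, seed=12)
        slope = np.polyfit(times, np.log2(out["count"]), 1)[0]
        assert abs(slope / 0.3 - 1) < 0.10

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            syn.gen_growth_counts(0.1, -5.0, [0.0, 1.0])
        with pytest.raises(ValueError):
            syn.gen_growth_counts(0.1, 5.0, [0.0, 1.0], noise_cv=-0.1)


class TestBranchingOracle:
    def test_growth_modified_solver_matches_branching_particles(self):
        """Normalized solver densities agree with a branching Euler-Maruyama
        simulation (independent mechanism) in the two-well growth scenario."""
        grid = np.linspace(0.0, 6.0, 128)
        U = 0.05 * (grid - 3.0) ** 2 \
            - 0.45 * np.exp(-((grid - 2.0) ** 2) / (2 * 0.35**2)) \
            - 0.25 * np.exp(-((grid - 4.3) ** 2) / (2 * 0.40**2))
        mu_grid = -2.0 * np.gradient(U, grid)
        alpha_grid = np.where(grid > 3.2, 0.45, 0.0)
        model = fp.LandscapeModel(grid=grid, D=0.35, mu=mu_grid, alpha=alpha_grid)
        rng = np.random.default_rng(21)
        x0 = rng.normal(2.0, 0.25, 60_000)
        x0 = np.clip(x0, 0.0, 6.0)
        p0 = histogram_density(x0, grid)
        p0 /= np.trapezoid(p0, grid)
        times = [1.5, 4.0]
        sol = fp.normalize_population(fp.solve_fp_source(model, p0, times, dt=0.005))
        parts = branching_em(
            x0, lambda y: np.interp(y, grid, mu_grid),
            lambda y: np.where(y > 3.2, 0.45, 0.0), 0.35, times, dt=0.004,
            rng=rng, bounds=(0.0, 6.0))
        for row, x in zip(sol.densities, parts):
            l1 = np.trapezoid(np.abs(row - histogram_density(x, grid)), grid)
            assert l1 < 0.05
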