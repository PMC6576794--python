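"""Parameter estimation: diffusivity, cutoffs, landscape, growth, comparison."""

import numpy as np
import pytest

from landscape_kinetics import fp, inference
from landscape_kinetics import synthetic as syn
from landscape_kinetics.surprisal import FreeEnergySeries


class TestCutoffs:
    def test_symmetric_trimodal_minima(self):
        """Cutoffs of a three-Gaussian mixture fall at the brute-force
        argmin between adjacent modes."""
        grid = np.linspace(-4.0, 4.0, 401)
        pdf = sum(np.exp(-((grid - m) ** 2) / (2 * 0.5**2)) for m in (-2.0, 0.0, 2.0))
        pdf /= np.trapezoid(pdf, grid)
        c1, c2 = inference.cutoffs_from_minima(pdf, grid)
        # oracle: direct argmin on each inter-mode stretch
        left = grid[np.abs(grid + 1) < 1.0]
        o1 = left[np.argmin(pdf[np.abs(grid + 1) < 1.0])]
        right = grid[np.abs(grid - 1) < 1.0]
        o2 = right[np.argmin(pdf[np.abs(grid - 1) < 1.0])]
        dx = grid[1] - grid[0]
        assert abs(c1 - o1) <= dx and abs(c2 - o2) <= dx
        assert abs(c1 + 1.0) < 0.1 and abs(c2 - 1.0) < 0.1

    def test_unimodal_density_raises(self):
        grid = np.linspace(-3.0, 3.0, 201)
        pdf = np.exp(-grid**2 / 2)
        with pytest.raises(ValueError, match="manual"):
            inference.cutoffs_from_minima(pdf, grid)

    def test_plateau_minimum_resolves_to_midpoint(self):
        grid = np.linspace(0.0, 10.0, 101)
        pdf = np.ones(101)
        pdf[:20] += 1.0  # mode 1
        pdf[45:55] += 1.0  # mode 2
        pdf[80:] += 1.0  # mode 3
        c1, c2 = inference.cutoffs_from_minima(pdf, grid)
        assert c1 == pytest.approx(grid[32], abs=grid[1] - grid[0])
        assert c2 == pytest.approx(grid[67], abs=grid[1] - grid[0])

    def test_extra_minor_mode_ignored(self):
        """With four modes, the cutoffs separate the three largest."""
        grid = np.linspace(-4.0, 6.0, 501)
        pdf = (1.0 * np.exp(-((grid + 2) ** 2) / 0.5)
               + 1.0 * np.exp(-(grid**2) / 0.5)
               + 1.0 * np.exp(-((grid - 2) ** 2) / 0.5)
               + 0.05 * np.exp(-((grid - 4) ** 2) / 0.5))
        c1, c2 = inference.cutoffs_from_minima(pdf, grid)
        assert abs(c1 + 1.0) < 0.2 and abs(c2 - 1.0) < 0.2


class TestDiffusivity:
    def test_exact_density_recovery(self):
        """Relaxation series generated at D = 0.5 is re-fit within 2%."""
        truth = syn.drug_naive_simulation_truth(n_grid=160, seed=0, D=0.5)
        steady = truth.steady_state()
        g = truth.grid
        mask = g >= 3.1
        p0 = np.where(mask, steady, 0.0)
        p0 /= np.trapezoid(p0, g)
        times = np.array([0.0, 1.0, 2.0, 4.0, 7.0])
        sol = fp.solve_fp(truth.model(with_growth=False), p0, times[1:])
        series = fp.DensitySeries(grid=g, densities=np.vstack([p0, sol.densities]),
                                  times=times)
        D = inference.fit_diffusivity(series, steady)
        assert abs(D / 0.5 - 1) < 0.02

    def test_stationary_input_warns_and_returns_grid_minimum(self):
        truth = syn.drug_naive_simulation_truth(n_grid=96, seed=1)
        steady = truth.steady_state()
        series = fp.DensitySeries(grid=truth.grid,
                                  densities=np.vstack([steady, steady, steady]),
                                  times=[0.0, 1.0, 2.0])
        with pytest.warns(RuntimeWarning, match="unimodal"):
            D = inference.fit_diffusivity(series, steady,
                                          D_grid=np.geomspace(0.05, 1.0, 8))
        assert 0.05 <= D <= 1.0

    def test_too_few_timepoints_rejected(self):
        truth = syn.drug_naive_simulation_truth(n_grid=96, seed=1)
        series = fp.DensitySeries(grid=truth.grid,
                                  densities=truth.steady_state()[None, :],
                                  times=[0.0])
        with pytest.raises(ValueError):
            inference.fit_diffusivity(series, truth.steady_state())


class TestGrowthRates:
    def test_exact_doubling_series(self):
        fits = inference.fit_growth_rates(
            ([0.0, 1.0, 2.0], [100.0, 200.0, 400.0]), [(0.0, 2.0)])
        assert fits[0].alpha == pytest.approx(1.0)
        assert fits[0].N0 == pytest.approx(100.0)
        assert fits[0].residual < 1e-12

    def test_two_window_protocol_recovers_rates(self):
        """Counts generated under the planted two-phase growth are re-fit
        within 10% per window."""
        counts = None
        import pandas as pd

        a1, a2 = 0.1, 0.45  # doublings/day
        t1 = np.array([0.0, 7.0, 21.0])
        t2 = np.array([30.0, 43.0, 66.0, 78.0])
        c1 = syn.gen_growth_counts(a1, 1e5, t1, noise_cv=0.05, seed=3)
        n21 = 1e5 * 2 ** (a1 * 21.0)
        c2 = syn.gen_growth_counts(a2, n21, t2 - 21.0, noise_cv=0.05, seed=4)
        c2["time_day"] += 21.0
        counts = pd.concat([c1, c2], ignore_index=True)
        fits = inference.fit_growth_rates(counts, [(0.0, 21.0), (21.0, 78.0)])
        assert abs(fits[0].alpha / a1 - 1) < 0.10
        assert abs(fits[1].alpha / a2 - 1) < 0.10
        assert fits[1].alpha > fits[0].alpha

    def test_invalid_inputs(self):
        with pytest.raises(ValueError, match="positive"):
            inference.fit_growth_rates(([0.0, 1.0], [10.0, 0.0]), [(0.0, 1.0)])
        with pytest.raises(ValueError, match="fewer"):
            inference.fit_growth_rates(([0.0, 5.0], [10.0, 20.0]), [(1.0, 2.0)])


class TestLandscapeFit:
    def test_null_growth_recovery(self):
        """Data generated with no growth refit: alpha within 0.02/day of
        zero and potential correlated > 0.95 with the planted one."""
        grid = np.linspace(0.0, 6.0, 96)
        U = 0.05 * (grid - 3.0) ** 2 \
            - 0.45 * np.exp(-((grid - 2.2) ** 2) / (2 * 0.40**2)) \
            - 0.35 * np.exp(-((grid - 4.2) ** 2) / (2 * 0.45**2))
        U -= U.min()
        mu = -2.0 * np.gradient(U, grid)
        model = fp.LandscapeModel(grid=grid, D=0.35, mu=mu)
        p0 = np.exp(-((grid - 2.0) ** 2) / (2 * 0.3**2))
        p0 /= np.trapezoid(p0, grid)
        times = np.array([0.0, 1.5, 3.0, 5.0, 8.0, 12.0])
        sol = fp.solve_fp(model, p0, times[1:])
        series = fp.DensitySeries(grid=grid,
                                  densities=np.vstack([p0, sol.densities]),
                                  times=times)
        # cutoffs at the inter-well density minimum, as the method prescribes
        fit = inference.fit_landscape(series, 0.35, p0, cutoffs=(3.2, 5.2),
                                      n_starts=1, max_iter=400, seed=0)
        assert abs(fit.alpha1) < 0.02
        assert abs(fit.alpha2) < 0.02
        supp = series.densities.max(axis=0) > 1e-3 * series.densities.max()
        r = np.corrcoef(fit.model.potential()[supp], U[supp])[0, 1]
        assert r > 0.95
        assert np.all(np.diff(fit.loss_trace) <= 0)

    def test_loss_invariant_to_growth_anchor(self):
        """Shifting all region growth rates by a constant leaves the
        normalized dynamics, hence the loss, unchanged."""
        grid = np.linspace(0.0, 6.0, 64)
        p0 = np.exp(-((grid - 2.0) ** 2) / (2 * 0.4**2))
        p0 /= np.trapezoid(p0, grid)
        series = fp.DensitySeries(grid=grid, densities=np.vstack([p0, p0]),
                                  times=[0.0, 2.0])
        fits = [inference.fit_landscape(series, 0.35, p0, cutoffs=(2.0, 4.0),
                                        n_starts=1, max_iter=3, seed=0,
                                        alpha_anchor=anchor)
                for anchor in (0.0, 0.3)]
        assert fits[0].loss == pytest.approx(fits[1].loss, rel=1e-9)

    def test_invalid_inputs(self):
        grid = np.linspace(0.0, 6.0, 64)
        p0 = np.full(64, 1.0 / 6.0)
        series = fp.DensitySeries(grid=grid, densities=np.vstack([p0, p0]),
                                  times=[0.0, 1.0])
        with pytest.raises(ValueError):
            inference.fit_landscape(series, -0.1, p0, cutoffs=(2.0, 4.0))
        with pytest.raises(ValueError):
            inference.fit_landscape(series, 0.35, p0, cutoffs=(4.0, 2.0))


class TestCompareLandscapes:
    def _fes(self, F, times):
        F = np.asarray(F, dtype=float)
        times = np.asarray(times, dtype=float)
        return FreeEnergySeries(F=F, f=np.empty((0, F.size)),
                                G_expect=np.empty((0, F.size)), timepoints=times)

    def test_identical_shapes_full_agreement(self):
        grid = np.linspace(0.0, 6.0, 64)
        U = (grid - 3.0) ** 2
        fes = self._fes([9.0, 0.0, 4.0], [0.0, 11.0, 73.0])
        states = [("a", (0.0, 2.0), [0.0]), ("b", (2.0, 4.0), [11.0]),
                  ("c", (4.0, 6.0), [73.0])]
        rep = inference.compare_landscapes(100.0 * U, grid, fes, states)
        assert rep["agreement"] == 1.0

    def test_opposite_slopes_disagree(self):
        grid = np.linspace(0.0, 6.0, 64)
        U = grid.copy()  # monotonically rising
        fes = self._fes([5.0, 3.0, 1.0], [0.0, 11.0, 73.0])  # falling
        states = [("a", (0.0, 2.0), [0.0]), ("b", (2.0, 4.0), [11.0]),
                  ("c", (4.0, 6.0), [73.0])]
        rep = inference.compare_landscapes(U, grid, fes, states)
        assert rep["agreement"] == 0.0

    def test_scaling_options(self):
        grid = np.linspace(0.0, 6.0, 64)
        fes = self._fes([1.0, 0.0, 2.0], [0.0, 11.0, 73.0])
        states = [("a", (0.0, 2.0), [0.0]), ("b", (2.0, 4.0), [11.0]),
                  ("c", (4.0, 6.0), [73.0])]
        for scaling in ("minmax", "maxabs"):
            rep = inference.compare_landscapes(grid**2, grid, fes, states,
                                               scaling=scaling)
            assert rep["scaling"] == scaling
        with pytest.raises(ValueError):
            inference.compare_landscapes(grid, grid, fes, states, scaling="zzz")
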