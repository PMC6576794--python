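"""Synthetic data with the statistical structure of the melanoma drug-response study.

Generates every input the pipeline consumes, plus the ground truth needed
for parameter-recovery tests:

* kinetic bulk transcriptomes built by inverting the surprisal
  decomposition (a planted steady state plus a few time-varying
  constraints, with additive Gaussian noise on ln-expression, i.e.
  multiplicative lognormal noise on expression);
* per-timepoint two-marker "flow cytometry" clouds sampled from the
  forward solution of the drift-diffusion-growth equation and mapped into
  (log MART-1, log NGFR) space along a curved trajectory;
* sorting-relaxation series (a gated subpopulation of the drug-naive
  steady state relaxing back under pure drift-diffusion), the input for
  diffusivity estimation;
* exponential cell-count series N(t) = N0 * 2^(alpha t) with lognormal
  noise.

Sampling from grid densities uses inverse-CDF draws on the
trapezoid-integrated grid; the independent particle oracle used in the
test-suite simulates the same dynamics by (branching) Euler-Maruyama
instead, so the two routes share no mechanism.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fp import (
    DensitySeries,
    LandscapeModel,
    SolverError,
    normalize_population,
    solve_fp,
    solve_fp_source,
    stationary_density,
)
from .surprisal import ExpressionMatrix

__all__ = [
    "TranscriptomeTruth",
    "SimulationTruth",
    "QuarterArcMap",
    "MarkerCloudSeries",
    "gen_transcriptome",
    "gen_flow_clouds",
    "gen_sorting_relaxation",
    "gen_growth_counts",
    "m397_like_transcriptome_truth",
    "m397_like_simulation_truth",
    "drug_naive_simulation_truth",
]


# ---------------------------------------------------------------------------
# transcriptome


@dataclass
class TranscriptomeTruth:
    """Planted parameters of a synthetic kinetic transcriptome.

    ``constraint_patterns`` (J x n_genes) must be mutually orthogonal unit
    vectors; ``constraint_amplitudes`` (J x n_timepoints) carries all time
    dependence.  ``noise_sd`` is the standard deviation of additive noise
    on ln-expression.
    """

    n_genes: int
    timepoints: np.ndarray
    lambda0: float
    G0: np.ndarray
    constraint_amplitudes: np.ndarray
    constraint_patterns: np.ndarray
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        self.G0 = np.asarray(self.G0, dtype=float)
        self.constraint_amplitudes = np.atleast_2d(np.asarray(self.constraint_amplitudes, dtype=float))
        self.constraint_patterns = np.atleast_2d(np.asarray(self.constraint_patterns, dtype=float))

    @property
    def n_constraints(self) -> int:
        return self.constraint_amplitudes.shape[0]

    def validate(self) -> None:
        J = self.n_constraints
        if self.n_genes < 2 * J:
            raise ValueError("n_genes must be at least twice the number of constraints")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.G0.shape != (self.n_genes,):
            raise ValueError("G0 must have one entry per gene")
        if self.constraint_patterns.shape != (J, self.n_genes):
            raise ValueError("constraint_patterns must be (J, n_genes)")
        if self.constraint_amplitudes.shape[1] != self.timepoints.size:
            raise ValueError("constraint_amplitudes must be (J, n_timepoints)")
        gram = self.constraint_patterns @ self.constraint_patterns.T
        if not np.allclose(gram, np.eye(J), atol=1e-8):
            raise ValueError("constraint_patterns must be mutually orthogonal unit vectors")

    def to_json(self, path) -> None:
        d = {
            "n_genes": self.n_genes,
            "timepoints": self.timepoints.tolist(),
            "lambda0": float(self.lambda0),
            "G0": self.G0.tolist(),
            "constraint_amplitudes": self.constraint_amplitudes.tolist(),
            "constraint_patterns": self.constraint_patterns.tolist(),
            "noise_sd": self.noise_sd,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(d, fh)


def gen_transcriptome(truth: TranscriptomeTruth) -> ExpressionMatrix:
    """Generate expression by inverting the surprisal decomposition.

    ln X_i(t) = -lambda0 G_i0 - sum_j lambda_j(t) G_ij + eps,
    eps ~ N(0, noise_sd^2) i.i.d.  The output is strictly positive; with
    noise_sd = 0 a surprisal refit reproduces the planted amplitude series
    up to sign and ordering.
    """
    truth.validate()
    rng = np.random.default_rng(truth.seed)
    L = -(truth.lambda0 * truth.G0)[:, None] \
        - truth.constraint_patterns.T @ truth.constraint_amplitudes
    if truth.noise_sd > 0:
        L = L + rng.normal(0.0, truth.noise_sd, L.shape)
    gene_ids = [f"g{i:05d}" for i in range(truth.n_genes)]
    return ExpressionMatrix(values=np.exp(L), gene_ids=gene_ids, timepoints=truth.timepoints)


def _orthogonalize_rows(rows: np.ndarray, against: np.ndarray | None = None) -> np.ndarray:
    """Gram-Schmidt the rows (optionally also against extra fixed rows), unit norm."""
    basis = []
    if against is not None:
        for a in np.atleast_2d(against):  # orthonormalize the fixed rows too
            v = a.astype(float).copy()
            for b in basis:
                v -= (v @ b) * b
            nrm = np.linalg.norm(v)
            if nrm > 1e-12:
                basis.append(v / nrm)
    out = []
    for r in rows:
        v = r.astype(float).copy()
        for b in basis:
            v -= (v @ b) * b
        nrm = np.linalg.norm(v)
        if nrm < 1e-12:
            raise ValueError("degenerate pattern during orthogonalization")
        v /= nrm
        basis.append(v)
        out.append(v)
    return np.array(out)


def m397_like_transcriptome_truth(n_genes: int = 10_000, noise_sd: float = 0.1,
                                  seed: int = 0) -> TranscriptomeTruth:
    """Default kinetic-transcriptome scenario (7 timepoints, 3 constraints).

    Timepoints follow the D0-D73 sampling of the drug-treated M397-like
    series.  Constraint 1 rises monotonically (mesenchymal program),
    constraint 2 peaks transiently during the neural-crest-dominated phase,
    constraint 3 spikes at day 3 (acute metabolic response).  Amplitude
    series are centered and orthogonalized so the planted decomposition is
    identifiable; amplitude scales grow with sqrt(n_genes) so per-gene
    fold-changes are size-independent and the baseline stays the dominant
    component.  Constraint patterns are orthonormal and orthogonal to the
    baseline; the neural-crest constraint loads on abundant genes with a
    negative expression-weighted mean while the others are decorrelated
    from the expression weights, which places the free-energy minimum at
    the neural-crest-dominated timepoints, as in the measured system.
    """
    rng = np.random.default_rng(seed)
    timepoints = np.array([0.0, 3.0, 11.0, 17.0, 21.0, 46.0, 73.0])

    b = rng.normal(1.5, 1.5, n_genes)  # ln baseline expression
    lam0 = float(np.linalg.norm(b))
    G0 = -b / lam0  # so that -lambda0 * G0 = b and lambda0 > 0

    shapes = np.array([
        [0.00, 0.05, 0.20, 0.35, 0.50, 0.80, 1.00],  # mesenchymal rise
        [0.00, 0.15, 0.90, 1.00, 0.95, 0.35, 0.05],  # neural-crest bump
        [0.00, 1.00, 0.10, 0.00, 0.00, 0.00, 0.00],  # day-3 spike
    ])
    scales = np.array([90.0, 70.0, 55.0]) * np.sqrt(n_genes / 10_000.0)
    centered = shapes - shapes.mean(axis=1, keepdims=True)
    amps = _orthogonalize_rows(centered) * scales[:, None]

    X_base = np.exp(b)
    x_hat = X_base / np.linalg.norm(X_base)
    raw = rng.normal(0.0, 1.0, (3, n_genes))
    # the neural-crest constraint loads on abundant genes with a negative
    # expression-weighted mean, so its transient bump lowers F(t) at the
    # intermediate timepoints; the other two patterns are decorrelated from
    # the expression weights
    raw[1] += 0.5 * np.sqrt(n_genes) * x_hat
    for j in (0, 2):
        raw[j] -= (raw[j] @ x_hat) * x_hat
    p_nc = _orthogonalize_rows(raw[1:2], against=G0)
    others = _orthogonalize_rows(raw[[0, 2]], against=np.vstack([G0, x_hat, p_nc[0]]))
    patterns = np.vstack([others[0], p_nc[0], others[1]])
    if patterns[1] @ X_base > 0:
        patterns[1] *= -1.0

    return TranscriptomeTruth(n_genes=n_genes, timepoints=timepoints, lambda0=lam0,
                              G0=G0, constraint_amplitudes=amps,
                              constraint_patterns=patterns, noise_sd=noise_sd, seed=seed)


# ---------------------------------------------------------------------------
# flow cytometry


@dataclass
class QuarterArcMap:
    """Monotone map from the 1-D reaction coordinate to 2-D log-marker space.

    The trajectory is a quarter arc in the (log MART-1, log NGFR) plane,
    parameterized by arc length so the ground-truth coordinate of every
    sampled cell is recoverable.  Transverse noise is applied radially.
    """

    length: float
    center: tuple[float, float] = (0.5, 0.3)
    theta0: float = np.pi / 6

    @property
    def radius(self) -> float:
        return self.length / (np.pi / 2)

    def __call__(self, x: np.ndarray, radial_offset: np.ndarray | float = 0.0) -> np.ndarray:
        theta = self.theta0 + np.asarray(x, dtype=float) / self.radius
        r = self.radius + radial_offset
        return np.column_stack([self.center[0] + r * np.cos(theta),
                                self.center[1] + r * np.sin(theta)])

    def to_dict(self) -> dict:
        return {"length": self.length, "center": list(self.center), "theta0": self.theta0}


@dataclass
class MarkerCloudSeries:
    """Per-timepoint 2-D marker-intensity point clouds (log scale)."""

    times: np.ndarray
    clouds: list  # list of (n_i, 2) arrays
    true_coords: list | None = None  # ground-truth 1-D coordinates, if known

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if len(self.clouds) != self.times.size:
            raise ValueError("one cloud per timepoint is required")

    def pooled(self) -> np.ndarray:
        return np.vstack(self.clouds)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t, c in zip(self.times, self.clouds):
            rows.append(pd.DataFrame({"time_day": t, "marker1": c[:, 0], "marker2": c[:, 1]}))
        return pd.concat(rows, ignore_index=True)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "MarkerCloudSeries":
        df = pd.read_csv(path)
        times = np.array(sorted(df["time_day"].unique()))
        clouds = [df[df["time_day"] == t][["marker1", "marker2"]].to_numpy() for t in times]
        return cls(times=times, clouds=clouds)


@dataclass
class SimulationTruth:
    """Planted landscape for the single-cell simulation.

    ``U_true`` follows the Gibbs reporting convention (stationary density
    proportional to exp(-2 U / D)), so the drift is mu = -2 dU/dx.
    ``alpha_true`` is piecewise constant with at most three distinct
    values.  ``p0`` is the day-0 density; if omitted, the stationary
    density of U_true is used.
    """

    grid: np.ndarray
    U_true: np.ndarray
    alpha_true: np.ndarray
    D_true: float
    curve_map: QuarterArcMap
    transverse_sd: float = 0.15
    cells_per_timepoint: int = 10_000
    seed: int = 0
    p0: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.U_true = np.asarray(self.U_true, dtype=float)
        self.alpha_true = np.asarray(self.alpha_true, dtype=float)
        dx = np.diff(self.grid)
        if np.any(dx <= 0) or np.ptp(dx) > 1e-8 * dx[0]:
            raise ValueError("grid must be uniform and strictly increasing")
        if np.unique(self.alpha_true).size > 3:
            raise ValueError("alpha_true must take at most three distinct values")
        if self.D_true <= 0:
            raise ValueError("D_true must be positive")
        if self.cells_per_timepoint <= 0:
            raise ValueError("cells_per_timepoint must be positive")

    @property
    def mu_true(self) -> np.ndarray:
        return -2.0 * np.gradient(self.U_true, self.grid)

    def model(self, with_growth: bool = True) -> LandscapeModel:
        return LandscapeModel(grid=self.grid, D=self.D_true, mu=self.mu_true,
                              alpha=self.alpha_true if with_growth else None)

    def steady_state(self) -> np.ndarray:
        return stationary_density(self.U_true, self.D_true, self.grid)

    def initial_density(self) -> np.ndarray:
        if self.p0 is not None:
            p = np.asarray(self.p0, dtype=float)
            return p / np.trapezoid(p, self.grid)
        return self.steady_state()

    def to_json(self, path) -> None:
        d = {
            "grid": {"start": float(self.grid[0]), "stop": float(self.grid[-1]), "n": int(self.grid.size)},
            "U_true": self.U_true.tolist(),
            "alpha_true": self.alpha_true.tolist(),
            "D_true": self.D_true,
            "curve_map": self.curve_map.to_dict(),
            "transverse_sd": self.transverse_sd,
            "cells_per_timepoint": self.cells_per_timepoint,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(d, fh)


def sample_from_density(grid: np.ndarray, p: np.ndarray, n: int,
                        rng: np.random.Generator) -> np.ndarray:
    """Inverse-CDF draws from a grid density (trapezoid-integrated CDF)."""
    mids = 0.5 * (p[:-1] + p[1:]) * np.diff(grid)
    cdf = np.concatenate([[0.0], np.cumsum(mids)])
    if cdf[-1] <= 0:
        raise ValueError("density has zero mass")
    cdf /= cdf[-1]
    return np.interp(rng.random(n), cdf, grid)


def _clouds_from_densities(truth: SimulationTruth, series: DensitySeries,
                           rng: np.random.Generator) -> MarkerCloudSeries:
    clouds, coords = [], []
    for row in series.densities:
        if row.min() < 0:
            raise SolverError("negative density from solver during cloud generation")
        x = sample_from_density(series.grid, row, truth.cells_per_timepoint, rng)
        eta = rng.normal(0.0, truth.transverse_sd, x.size) if truth.transverse_sd > 0 else 0.0
        clouds.append(truth.curve_map(x, eta))
        coords.append(x)
    return MarkerCloudSeries(times=series.times, clouds=clouds, true_coords=coords)


def gen_flow_clouds(truth: SimulationTruth, times) -> MarkerCloudSeries:
    """Sample per-timepoint marker clouds from the forward growth-modified solution.

    Cells at each requested time are inverse-CDF draws from the normalized
    p(x, t) of the drift-diffusion-growth equation started at the planted
    initial density, then mapped to 2-D marker space with radial
    transverse noise.  Reproducible given the truth seed.
    """
    times = np.asarray(times, dtype=float)
    rng = np.random.default_rng(truth.seed)
    series = solve_fp_source(truth.model(), truth.initial_density(), times)
    return _clouds_from_densities(truth, normalize_population(series), rng)


def gen_sorting_relaxation(truth: SimulationTruth, gate: tuple[float, float],
                           times) -> MarkerCloudSeries:
    """Gate a subpopulation of the steady state and track its relaxation.

    The t=0 cloud is drawn from the steady-state density truncated and
    renormalized to the ``gate`` interval; later clouds follow the plain
    (growth-free, drug-naive) drift-diffusion dynamics.
    """
    times = np.asarray(times, dtype=float)
    rng = np.random.default_rng(truth.seed + 1)
    steady = truth.steady_state()
    lo, hi = gate
    mask = (truth.grid >= lo) & (truth.grid <= hi)
    gated = np.where(mask, steady, 0.0)
    mass = np.trapezoid(gated, truth.grid)
    if mass <= 1e-6:  # below one expected cell at 10^4 events
        raise ValueError("gate does not overlap the support of the steady state")
    p0 = gated / mass
    series = solve_fp(truth.model(with_growth=False), p0, times)
    return _clouds_from_densities(truth, series, rng)


def gen_growth_counts(rate_per_day: float, n0: float, times, noise_cv: float = 0.0,
                      seed: int = 0) -> pd.DataFrame:
    """Cell counts N(t) = N0 * 2^(rate t) with mean-one lognormal noise."""
    if n0 <= 0:
        raise ValueError("n0 must be positive")
    if noise_cv < 0:
        raise ValueError("noise_cv must be nonnegative")
    times = np.asarray(times, dtype=float)
    counts = n0 * np.exp2(rate_per_day * times)
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        sigma = np.sqrt(np.log1p(noise_cv**2))
        counts = counts * np.exp(rng.normal(-sigma**2 / 2.0, sigma, times.size))
    return pd.DataFrame({"time_day": times, "count": counts})


# ---------------------------------------------------------------------------
# named scenarios


def _gauss(x, m, s):
    return np.exp(-((x - m) ** 2) / (2.0 * s**2))


#: default timepoints (days) of the drug-treated kinetic series
M397_TIMEPOINTS = np.array([0.0, 3.0, 11.0, 17.0, 21.0, 46.0, 73.0])
#: region cutoffs of the default tri-state landscape (melanocytic | neural crest | mesenchymal)
M397_CUTOFFS = (2.0, 4.0)
#: planted net growth rates (1/day): melanocytic anchored at 0
M397_ALPHAS = (0.0, 0.08, 0.4)


def m397_like_simulation_truth(n_grid: int = 256, cells_per_timepoint: int = 10_000,
                               seed: int = 0, D: float = 0.35,
                               alphas: tuple = M397_ALPHAS) -> SimulationTruth:
    """Drug-treated tri-state scenario on x in [0, 6] q.

    Three wells at x ~ 1 (melanocytic), 3 (neural crest, deepest: the
    attractor) and 5 (mesenchymal); net growth (0, 0.08, 0.4)/day over the
    regions split at x = 2 and 4, so the mesenchymal state is the
    fastest-growing despite its higher potential.  Day 0 starts as a
    narrow melanocytic population.
    """
    grid = np.linspace(0.0, 6.0, n_grid)
    U = (0.05 * (grid - 3.0) ** 2
         - 0.45 * _gauss(grid, 1.0, 0.35)
         - 0.75 * _gauss(grid, 3.0, 0.40)
         - 0.50 * _gauss(grid, 5.0, 0.40))
    U -= U.min()
    c1, c2 = M397_CUTOFFS
    alpha = np.where(grid < c1, alphas[0], np.where(grid < c2, alphas[1], alphas[2]))
    p0 = _gauss(grid, 1.0, 0.3)
    p0 /= np.trapezoid(p0, grid)
    return SimulationTruth(grid=grid, U_true=U, alpha_true=alpha, D_true=D,
                           curve_map=QuarterArcMap(length=6.0), transverse_sd=0.15,
                           cells_per_timepoint=cells_per_timepoint, seed=seed, p0=p0)


def drug_naive_simulation_truth(n_grid: int = 256, cells_per_timepoint: int = 10_000,
                                seed: int = 0, D: float = 0.35) -> SimulationTruth:
    """Drug-naive bimodal scenario used for sorting-relaxation experiments.

    The steady state is a two-mode density (NGFR-low major mode, NGFR-high
    minor mode); there is no net growth.  Gating out the upper mode and
    relaxing back is the diffusivity-estimation experiment.
    """
    grid = np.linspace(0.0, 6.0, n_grid)
    p_inf = 0.62 * _gauss(grid, 2.3, 0.30) / (0.30 * np.sqrt(2 * np.pi)) \
        + 0.38 * _gauss(grid, 3.9, 0.35) / (0.35 * np.sqrt(2 * np.pi))
    p_inf /= np.trapezoid(p_inf, grid)
    U = -(D / 2.0) * np.log(np.maximum(p_inf, 1e-12 * p_inf.max()))
    U -= U.min()
    return SimulationTruth(grid=grid, U_true=U, alpha_true=np.zeros(n_grid), D_true=D,
                           curve_map=QuarterArcMap(length=6.0), transverse_sd=0.15,
                           cells_per_timepoint=cells_per_timepoint, seed=seed)
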