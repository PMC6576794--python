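"""Fitting the kinetic-model parameters from density series.

Three estimators and one comparison:

* :func:`fit_diffusivity` recovers the diffusivity D from a
  sorting-relaxation experiment: for each candidate D the drift is
  Gibbs-inverted from the drug-naive steady state (making that density
  stationary), the gated initial density is forward-solved, and the
  unweighted sum of squares against the measured series is minimized over
  a coarse grid followed by bounded scalar refinement.

* :func:`fit_landscape` fits the drug-treated landscape: drift as a cubic
  spline through 20 uniformly spaced knots and piecewise net growth
  (0, alpha1, alpha2) over the three state regions, by multi-start
  gradient descent (finite-difference gradients, backtracking line
  search) on the L2 loss between predicted and measured normalized
  densities.  The melanocytic growth rate is anchored at 0: the dynamics
  of the normalized density are invariant to a constant shift of alpha.

* :func:`fit_growth_rates` fits N(t) = N0 * 2^(alpha t) per time window
  by log2-linear least squares (alpha in doublings/day).

* :func:`compare_landscapes` compares the kinetic-model potential with the
  surprisal free-energy landscape by slope signs between consecutive cell
  states, after rescaling each landscape (the absolute scales of the two
  potentials are not comparable).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.optimize import minimize_scalar
from scipy.signal import find_peaks

from .fp import (
    DensitySeries,
    LandscapeModel,
    drift_from_density,
    normalize_population,
    solve_fp,
    solve_fp_source,
)
from .surprisal import FreeEnergySeries

__all__ = [
    "FitResult",
    "GrowthFit",
    "fit_diffusivity",
    "cutoffs_from_minima",
    "fit_landscape",
    "fit_growth_rates",
    "compare_landscapes",
]


@dataclass
class FitResult:
    """Fitted landscape with optimization diagnostics."""

    model: LandscapeModel
    loss: float
    loss_trace: np.ndarray
    alpha1: float
    alpha2: float
    n_spline: int
    seed: int
    converged: bool

    def to_dict(self) -> dict:
        return {
            "model": self.model.to_dict(),
            "loss": float(self.loss),
            "loss_trace": np.asarray(self.loss_trace).tolist(),
            "alpha1": float(self.alpha1),
            "alpha2": float(self.alpha2),
            "n_spline": int(self.n_spline),
            "seed": int(self.seed),
            "converged": bool(self.converged),
        }


@dataclass
class GrowthFit:
    """Exponential growth fit over one time window, alpha in doublings/day."""

    alpha: float
    N0: float
    window: tuple[float, float]
    residual: float


def _l2_loss(pred: np.ndarray, meas: np.ndarray, grid: np.ndarray) -> float:
    return float(np.trapezoid((pred - meas) ** 2, grid).sum())


def fit_diffusivity(relaxation: DensitySeries, steady: np.ndarray,
                    D_grid: np.ndarray | None = None, dt: float | None = None,
                    return_details: bool = False):
    """Best-fit diffusivity from a sorting-relaxation density series.

    ``relaxation`` must contain the gated t=0 density followed by at least
    one later measurement; ``steady`` is the unsorted drug-naive steady
    state on the same grid.  For each candidate D, the Gibbs-inverted
    drift mu = D dln(steady)/dx is forward-solved from the t=0 density and
    scored by the unweighted sum of squares against the later measured
    densities.  A coarse candidate grid (30 log-spaced values over
    [0.01, 3] q^2/day by default) is refined by bounded scalar
    minimization around its minimum; if the coarse loss profile is not
    unimodal the global grid minimum is returned with a warning.
    """
    if relaxation.times.size < 2:
        raise ValueError("relaxation series needs at least two timepoints")
    steady = np.asarray(steady, dtype=float)
    if np.any(steady <= 0):
        steady = np.maximum(steady, 1e-12 * steady.max())
    grid = relaxation.grid
    dlnp = np.gradient(np.log(steady), grid)
    p0 = relaxation.densities[0]
    p0 = p0 / np.trapezoid(p0, grid)
    targets = relaxation.densities[1:]
    t_rel = relaxation.times[1:] - relaxation.times[0]

    def loss(D: float) -> float:
        model = LandscapeModel(grid=grid, D=D, mu=D * dlnp)
        sol = solve_fp(model, p0, t_rel, dt=dt)
        return _l2_loss(sol.densities, targets, grid)

    if D_grid is None:
        D_grid = np.geomspace(0.01, 3.0, 30)
    D_grid = np.asarray(D_grid, dtype=float)
    losses = np.array([loss(D) for D in D_grid])
    k = int(np.argmin(losses))

    interior_minima = np.sum((losses[1:-1] <= losses[:-2]) & (losses[1:-1] <= losses[2:]))
    flat = np.ptp(losses) <= 1e-12 * max(np.abs(losses).max(), 1e-300)
    refined = False
    if flat or interior_minima > 1 or k in (0, D_grid.size - 1):
        warnings.warn(
            "diffusivity loss profile is not unimodal over the candidate grid "
            "(flat, multi-minimum, or edge minimum); returning the global grid "
            "minimum", RuntimeWarning)
        D_best = float(D_grid[k])
    else:
        lo = D_grid[max(k - 1, 0)]
        hi = D_grid[min(k + 1, D_grid.size - 1)]
        res = minimize_scalar(loss, bounds=(lo, hi), method="bounded",
                              options={"xatol": 1e-4})
        D_best = float(res.x)
        refined = True
    if return_details:
        return D_best, {"grid": D_grid, "losses": losses, "refined": refined}
    return D_best


def cutoffs_from_minima(pdf: np.ndarray, grid: np.ndarray) -> tuple[float, float]:
    """The two interior local minima separating the three largest modes.

    Plateau minima resolve to the plateau midpoint; modes are ranked by
    the probability mass between adjacent minima (or a domain boundary).
    Raises if the density has fewer than two interior minima, in which
    case cutoffs must be supplied manually.
    """
    pdf = np.asarray(pdf, dtype=float)
    minima, _ = find_peaks(-pdf, plateau_size=1)
    if minima.size < 2:
        raise ValueError(
            "density has fewer than two interior local minima; "
            "supply the state cutoffs manually"
        )
    edges = np.concatenate([[0], minima, [pdf.size - 1]])
    masses = np.array([
        np.trapezoid(pdf[edges[i]: edges[i + 1] + 1], grid[edges[i]: edges[i + 1] + 1])
        for i in range(edges.size - 1)
    ])
    top3 = np.sort(np.argsort(masses)[::-1][:3])  # region indices, left to right
    cuts = []
    for ra, rb in zip(top3[:-1], top3[1:]):
        # minima strictly between the two selected regions; pick the lowest
        cand = minima[(minima >= edges[ra + 1]) & (minima <= edges[rb])]
        cuts.append(grid[cand[np.argmin(pdf[cand])]])
    return (float(cuts[0]), float(cuts[1]))


def _alpha_on_grid(grid: np.ndarray, cutoffs, a1: float, a2: float) -> np.ndarray:
    c1, c2 = cutoffs
    return np.where(grid < c1, 0.0, np.where(grid < c2, a1, a2))


def _gradient_descent(objective, theta0, scales, max_iter, tol, patience, fd_eps=1e-3):
    """Plain gradient descent with forward-difference gradients and
    backtracking (Armijo) line search; diagonal scaling preconditions the
    step.  Returns (theta, loss, trace, converged)."""
    theta = theta0.copy()
    f = objective(theta)
    trace = [f]
    step = 1.0
    stall = 0
    converged = False
    n = theta.size
    for _ in range(max_iter):
        g = np.empty(n)
        for i in range(n):
            h = fd_eps * scales[i]
            th = theta.copy()
            th[i] += h
            g[i] = (objective(th) - f) / h
        d = -g * scales**2
        slope = float(g @ d)
        if slope >= 0:
            break
        accepted = False
        s = min(step * 2.0, 1.0)
        for _ in range(25):
            f_new = objective(theta + s * d)
            if f_new <= f + 1e-4 * s * slope:
                accepted = True
                break
            s *= 0.5
        if not accepted:
            converged = True
            break
        improvement = (f - f_new) / max(abs(f), 1e-300)
        theta = theta + s * d
        f = f_new
        step = s
        trace.append(f)
        stall = stall + 1 if improvement < tol else 0
        if stall >= patience:
            converged = True
            break
    return theta, f, np.array(trace), converged


def fit_landscape(series: DensitySeries, D: float, p0: np.ndarray, cutoffs,
                  n_knots: int = 20, n_starts: int = 5, max_iter: int = 2000,
                  tol: float = 1e-6, patience: int = 10, seed: int = 0,
                  dt: float | None = None, init_slope: float = -0.5,
                  fit_growth: bool = True, alpha_anchor: float = 0.0) -> FitResult:
    """Fit drift spline and piecewise net growth to a normalized density series.

    ``series`` holds the measured p(x, t_i) (the t=0 entry, if present, is
    used only as a consistency anchor; the forward solves start from
    ``p0``).  The drift is a natural cubic spline through ``n_knots``
    uniformly spaced knots; alpha is (0, alpha1, alpha2) over the three
    regions delimited by ``cutoffs``.  The L2 loss
    L = sum_i int (p_pred - p_exp)^2 dx is minimized by multi-start
    gradient descent from the initialization alpha1 = alpha2 = 0 and a
    weak linear restoring drift; additional starts are seeded random
    perturbations of it and the best loss is kept.

    ``fit_growth=False`` freezes alpha at zero everywhere (the plain
    Fokker-Planck fit, drift only).  ``alpha_anchor`` shifts all three
    region values by a constant; the normalized dynamics are invariant to
    this shift, which anchoring the melanocytic rate at 0 merely fixes.
    """
    if D <= 0:
        raise ValueError("D must be positive")
    if not series.normalized:
        series = normalize_population(series)
    grid = series.grid
    c1, c2 = cutoffs
    if not (grid[0] <= c1 < c2 <= grid[-1]):
        raise ValueError("cutoffs must be ordered and lie within the grid")
    p0 = np.asarray(p0, dtype=float)
    p0 = p0 / np.trapezoid(p0, grid)

    pos = series.times > series.times[0] if series.times[0] == 0 else slice(None)
    t_fit = series.times[pos] if series.times[0] == 0 else series.times
    meas = series.densities[pos] if series.times[0] == 0 else series.densities
    knots_x = np.linspace(grid[0], grid[-1], n_knots)

    n_free = n_knots + (2 if fit_growth else 0)

    def expand(theta: np.ndarray):
        mu = CubicSpline(knots_x, theta[:n_knots], bc_type="natural")(grid)
        a1 = theta[n_knots] if fit_growth else 0.0
        a2 = theta[n_knots + 1] if fit_growth else 0.0
        alpha = alpha_anchor + _alpha_on_grid(grid, (c1, c2), a1, a2)
        return mu, alpha, a1, a2

    def objective(theta: np.ndarray) -> float:
        mu, alpha, _, _ = expand(theta)
        model = LandscapeModel(grid=grid, D=D, mu=mu, alpha=alpha, cutoffs=(c1, c2))
        try:
            sol = normalize_population(solve_fp_source(model, p0, t_fit, dt=dt))
        except Exception:
            return 1e6
        return _l2_loss(sol.densities, meas, grid)

    scales = np.concatenate([np.full(n_knots, 1.0), np.full(n_free - n_knots, 0.25)])
    base = np.concatenate([init_slope * (knots_x - knots_x.mean()),
                           np.zeros(n_free - n_knots)])
    rng = np.random.default_rng(seed)

    best = None
    for s in range(n_starts):
        theta0 = base.copy()
        if s > 0:
            theta0 += rng.normal(0.0, 0.3, base.size) * scales
        theta, loss, trace, conv = _gradient_descent(
            objective, theta0, scales, max_iter, tol, patience)
        if best is None or loss < best[1]:
            best = (theta, loss, trace, conv)

    theta, loss, trace, conv = best
    mu, alpha, a1, a2 = expand(theta)
    model = LandscapeModel(grid=grid, D=D, mu=mu, alpha=alpha, cutoffs=(float(c1), float(c2)))
    return FitResult(model=model, loss=loss, loss_trace=trace,
                     alpha1=float(a1), alpha2=float(a2),
                     n_spline=n_knots, seed=seed, converged=conv)


def fit_growth_rates(counts, windows) -> list[GrowthFit]:
    """Log2-linear least-squares growth fits per time window.

    ``counts`` is a DataFrame with columns (time_day, count) or a
    (times, counts) pair; ``windows`` is a list of (t_start, t_end)
    intervals, each of which must contain at least two counts.
    """
    if hasattr(counts, "columns"):
        times = counts["time_day"].to_numpy(dtype=float)
        vals = counts["count"].to_numpy(dtype=float)
    else:
        times, vals = (np.asarray(a, dtype=float) for a in counts)
    if np.any(vals <= 0):
        raise ValueError("cell counts must be positive")
    fits = []
    for t0, t1 in windows:
        sel = (times >= t0) & (times <= t1)
        if sel.sum() < 2:
            raise ValueError(f"window ({t0}, {t1}) contains fewer than two counts")
        tt = times[sel] - t0
        y = np.log2(vals[sel])
        slope, intercept = np.polyfit(tt, y, 1)
        resid = float(np.sqrt(np.mean((np.polyval([slope, intercept], tt) - y) ** 2)))
        fits.append(GrowthFit(alpha=float(slope), N0=float(2.0 ** intercept),
                              window=(float(t0), float(t1)), residual=resid))
    return fits


def _rescale(v: np.ndarray, scaling: str) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if scaling == "minmax":
        rng = np.ptp(v)
        return (v - v.min()) / rng if rng > 0 else np.zeros_like(v)
    if scaling == "maxabs":
        m = np.abs(v).max()
        return v / m if m > 0 else v
    raise ValueError("scaling must be 'minmax' or 'maxabs'")


def compare_landscapes(U_fp: np.ndarray, grid: np.ndarray, fes: FreeEnergySeries,
                       states, scaling: str = "minmax") -> dict:
    """Slope-sign comparison of the two potential landscapes across cell states.

    ``states`` is an ordered list of (name, (x_lo, x_hi), [timepoints])
    entries mapping each cell state to its reaction-coordinate region and
    the timepoints at which it dominates.  The kinetic-model value of a
    state is the minimum of ``U_fp`` within its region (the well depth);
    the surprisal value is the mean F(t) over its timepoints.  Both
    landscapes are rescaled (default min-max) and the signs of the slopes
    between consecutive states are compared; absolute levels are never
    compared.
    """
    U_fp = np.asarray(U_fp, dtype=float)
    names, u_vals, f_vals = [], [], []
    for name, (lo, hi), tps in states:
        names.append(name)
        mask = (grid >= lo) & (grid <= hi)
        if not np.any(mask):
            raise ValueError(f"region of state '{name}' does not intersect the grid")
        u_vals.append(U_fp[mask].min())
        sel = np.isin(fes.timepoints, np.asarray(tps, dtype=float))
        if not np.any(sel):
            raise ValueError(f"no free-energy timepoints found for state '{name}'")
        f_vals.append(float(fes.F[sel].mean()))
    u_n = _rescale(np.array(u_vals), scaling)
    f_n = _rescale(np.array(f_vals), scaling)
    su = np.sign(np.diff(u_n))
    sf = np.sign(np.diff(f_n))
    agree = float(np.mean(su == sf)) if su.size else 1.0
    return {
        "states": names,
        "potential_fp": u_n.tolist(),
        "potential_surprisal": f_n.tolist(),
        "slope_signs_fp": su.tolist(),
        "slope_signs_surprisal": sf.tolist(),
        "agreement": agree,
        "scaling": scaling,
    }
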