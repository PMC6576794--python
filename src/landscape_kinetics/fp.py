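"""Forward solvers for 1-D drift-diffusion dynamics on the cell-state reaction coordinate.

Two equations are solved on a uniform grid with reflecting (zero-flux)
boundaries:

* the plain Fokker-Planck equation for a probability density ``p(x, t)``::

      dp/dt = -d/dx [mu(x) p] + D d2p/dx2

* the self-sourcing variant for an unnormalized population ``P(x, t)``,
  where ``alpha(x)`` is a cell-state-dependent net growth rate
  (proliferation minus drug killing)::

      dP/dt = -d/dx [mu(x) P] + D d2P/dx2 + alpha(x) P

Discretization is a conservative finite-volume stencil (central interface
fluxes) with Crank-Nicolson time stepping; the growth term is applied by
symmetric (Strang) splitting as an exact pointwise exponential, so a
spatially uniform growth rate factors out of the normalized solution
exactly.  The tridiagonal solves are JIT-compiled.

The stationary density and the drift are linked by the zero-flux condition
``mu = D dln(p_inf)/dx``.  The reported potential follows the Gibbs
convention ``U = -(D/2) ln p_inf``, which means ``mu = -2 dU/dx``; the
alternative convention ``U = -int mu dx`` is available wherever a potential
is computed.  Only shapes and slopes of the landscape are ever compared, so
the choice affects the y-scale alone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.integrate import cumulative_trapezoid

__all__ = [
    "SolverError",
    "DensitySeries",
    "LandscapeModel",
    "solve_fp",
    "solve_fp_source",
    "normalize_population",
    "gibbs_potential",
    "drift_from_density",
    "potential_from_drift",
    "stationary_density",
]

#: relative magnitude below which a negative density value is treated as
#: time-stepping roundoff (zeroed) rather than a solver failure (raised).
_NEG_TOL = 1e-9


class SolverError(RuntimeError):
    """Raised when a forward solve produces an invalid (negative) density."""


@dataclass
class DensitySeries:
    """Densities on a fixed 1-D grid, one row per timepoint.

    ``normalized=True`` marks probability densities p(x, t); otherwise the
    rows are unnormalized populations P(x, t) and ``N`` holds the total
    mass N(t) = integral of P dx.
    """

    grid: np.ndarray
    densities: np.ndarray  # (n_times, n_grid)
    times: np.ndarray
    normalized: bool = True
    N: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.densities = np.atleast_2d(np.asarray(self.densities, dtype=float))
        self.times = np.asarray(self.times, dtype=float)
        if self.densities.shape != (self.times.size, self.grid.size):
            raise ValueError("densities must be (n_times, n_grid)")
        if np.any(self.densities < 0):
            raise ValueError("densities must be nonnegative")

    def integrals(self) -> np.ndarray:
        """Trapezoid integral of each row over the grid."""
        return np.trapezoid(self.densities, self.grid, axis=1)

    def to_frame(self):
        import pandas as pd

        rows = []
        for t, row in zip(self.times, self.densities):
            rows.append(pd.DataFrame({"x": self.grid, "t": t, "value": row}))
        return pd.concat(rows, ignore_index=True)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, normalized: bool = True) -> "DensitySeries":
        import pandas as pd

        df = pd.read_csv(path)
        times = np.array(sorted(df["t"].unique()))
        grid = np.array(sorted(df["x"].unique()))
        dens = np.empty((times.size, grid.size))
        for i, t in enumerate(times):
            sub = df[df["t"] == t].sort_values("x")
            dens[i] = sub["value"].to_numpy()
        return cls(grid=grid, densities=dens, times=times, normalized=normalized)


@dataclass
class LandscapeModel:
    """A fitted or planted 1-D landscape: drift, diffusivity and net growth.

    Parameters
    ----------
    grid : uniform coordinate array, units q (the flow-cytometry length unit).
    D : diffusivity, q^2/day.
    mu : drift evaluated on the grid, q/day.  The drift is the primary
        quantity; potentials are derived from it on demand.
    alpha : net growth rate on the grid, 1/day (``None`` means no growth).
    cutoffs : the two coordinates separating the melanocytic, neural-crest
        and mesenchymal regions (optional).
    """

    grid: np.ndarray
    D: float
    mu: np.ndarray
    alpha: np.ndarray | None = None
    cutoffs: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.mu = np.asarray(self.mu, dtype=float)
        if self.D <= 0:
            raise ValueError("diffusivity D must be positive")
        dx = np.diff(self.grid)
        if self.grid.size < 4 or np.any(dx <= 0) or np.ptp(dx) > 1e-8 * dx[0]:
            raise ValueError("grid must be uniform and strictly increasing")
        if self.mu.shape != self.grid.shape:
            raise ValueError("mu must be defined on the grid")
        if self.alpha is not None:
            self.alpha = np.asarray(self.alpha, dtype=float)
            if self.alpha.shape != self.grid.shape:
                raise ValueError("alpha must be defined on the grid")

    @property
    def dx(self) -> float:
        return float(self.grid[1] - self.grid[0])

    def potential(self, convention: str = "gibbs") -> np.ndarray:
        """Scalar potential derived from the drift, shifted to min 0.

        ``convention="gibbs"`` reports U = -(1/2) int mu dx, consistent with
        U = -(D/2) ln p_inf at stationarity; ``convention="integral"``
        reports U = -int mu dx.
        """
        U = -cumulative_trapezoid(self.mu, self.grid, initial=0.0)
        if convention == "gibbs":
            U = U / 2.0
        elif convention != "integral":
            raise ValueError("convention must be 'gibbs' or 'integral'")
        return U - U.min()

    def to_dict(self) -> dict:
        d = {
            "grid": {"start": float(self.grid[0]), "stop": float(self.grid[-1]), "n": int(self.grid.size)},
            "D": float(self.D),
            "mu": self.mu.tolist(),
            "alpha": None if self.alpha is None else self.alpha.tolist(),
            "cutoffs": None if self.cutoffs is None else [float(c) for c in self.cutoffs],
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "LandscapeModel":
        g = d["grid"]
        grid = np.linspace(g["start"], g["stop"], g["n"])
        alpha = None if d.get("alpha") is None else np.asarray(d["alpha"], dtype=float)
        cutoffs = None if d.get("cutoffs") is None else tuple(d["cutoffs"])
        return cls(grid=grid, D=d["D"], mu=np.asarray(d["mu"], dtype=float), alpha=alpha, cutoffs=cutoffs)


# ---------------------------------------------------------------------------
# discretization


def _operator_bands(grid: np.ndarray, D: float, mu: np.ndarray):
    """Tridiagonal bands of the conservative drift-diffusion operator A.

    Row i of A gives dp_i/dt from interface fluxes
    F_{i+1/2} = mu_{i+1/2} (p_i + p_{i+1})/2 - D (p_{i+1} - p_i)/dx
    with F = 0 at both domain ends (reflecting boundaries).  The scheme is
    vertex-centered: interior cells have width dx and the two boundary
    cells width dx/2, so the conserved discrete mass is exactly the
    trapezoid integral of p over the grid.
    """
    n = grid.size
    dx = grid[1] - grid[0]
    mu_f = 0.5 * (mu[:-1] + mu[1:])  # interface drift, length n-1
    adv = mu_f / 2.0
    dif = D / dx

    lower = np.zeros(n)  # coefficient of p[i-1] in row i
    diag = np.zeros(n)
    upper = np.zeros(n)  # coefficient of p[i+1] in row i

    # contribution of -F_{i+1/2} (rows 0..n-2)
    diag[:-1] += -adv - dif
    upper[:-1] += -adv + dif
    # contribution of +F_{i-1/2} (rows 1..n-1)
    lower[1:] += adv + dif
    diag[1:] += adv - dif

    w = np.full(n, dx)
    w[0] = w[-1] = dx / 2.0
    return lower / w, diag / w, upper / w


@njit(cache=True)
def _cn_run(low, dg, up, bl, bd, bu, growth, p, n_steps):  # pragma: no cover
    """Crank-Nicolson steps with Strang-split pointwise growth.

    (low, dg, up): bands of the LHS matrix I - dt/2 A
    (bl, bd, bu): bands of the RHS matrix I + dt/2 A
    growth: exp(alpha dt / 2) per grid point (ones when no source term)
    """
    n = p.size
    w = np.empty(n)
    dfac = np.empty(n)
    # Thomas factorization of the (constant) LHS
    dfac[0] = dg[0]
    for i in range(1, n):
        w[i] = low[i] / dfac[i - 1]
        dfac[i] = dg[i] - w[i] * up[i - 1]
    rhs = np.empty(n)
    for _ in range(n_steps):
        for i in range(n):
            p[i] *= growth[i]
        rhs[0] = bd[0] * p[0] + bu[0] * p[1]
        for i in range(1, n - 1):
            rhs[i] = bl[i] * p[i - 1] + bd[i] * p[i] + bu[i] * p[i + 1]
        rhs[n - 1] = bl[n - 1] * p[n - 2] + bd[n - 1] * p[n - 1]
        # forward sweep
        p[0] = rhs[0]
        for i in range(1, n):
            p[i] = rhs[i] - w[i] * p[i - 1]
        # back substitution
        p[n - 1] = p[n - 1] / dfac[n - 1]
        for i in range(n - 2, -1, -1):
            p[i] = (p[i] - up[i] * p[i + 1]) / dfac[i]
        for i in range(n):
            p[i] *= growth[i]
    return p


def _default_dt(model: LandscapeModel) -> float:
    vmax = float(np.max(np.abs(model.mu)))
    dt = 0.02
    if vmax > 0:
        dt = min(dt, 0.4 * model.dx / vmax)
    return max(dt, 1e-5)


def _evolve(model: LandscapeModel, p0: np.ndarray, times: np.ndarray,
            dt: float | None, with_source: bool) -> np.ndarray:
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise ValueError("at least one output time is required")
    if np.any(np.diff(times) <= 0) or times[0] < 0:
        raise ValueError("times must be strictly increasing and start at >= 0")
    if dt is None:
        dt = _default_dt(model)

    low, dg, up = _operator_bands(model.grid, model.D, model.mu)
    n = model.grid.size
    out = np.empty((times.size, n))
    p = np.asarray(p0, dtype=float).copy()

    t_prev = 0.0
    for k, t in enumerate(times):
        span = t - t_prev
        if span > 0:
            n_steps = max(1, int(np.ceil(span / dt)))
            h = span / n_steps
            lhs = (-h / 2 * low, 1.0 - h / 2 * dg, -h / 2 * up)
            rhs = (h / 2 * low, 1.0 + h / 2 * dg, h / 2 * up)
            if with_source and model.alpha is not None:
                growth = np.exp(model.alpha * h / 2.0)
            else:
                growth = np.ones(n)
            p = _cn_run(lhs[0], np.ascontiguousarray(lhs[1]), lhs[2],
                        rhs[0], np.ascontiguousarray(rhs[1]), rhs[2],
                        growth, p, n_steps)
        pmax = float(p.max())
        if pmax <= 0 or not np.isfinite(pmax):
            raise SolverError("forward solve lost all mass or diverged")
        if p.min() < -_NEG_TOL * pmax:
            raise SolverError(
                f"forward solve produced negative density ({p.min():.3e} at t={t:g}); "
                "reduce the time step or check the drift"
            )
        out[k] = np.maximum(p, 0.0)
        t_prev = t
    return out


def solve_fp(model: LandscapeModel, p0: np.ndarray, times, dt: float | None = None) -> DensitySeries:
    """Evolve a probability density under drift-diffusion (no growth).

    ``p0`` must be nonnegative and integrate to 1 on the grid (tolerance
    1e-3; it is renormalized exactly before stepping).  Total probability
    is conserved by construction; the returned series is not renormalized,
    so conservation can be verified on the output.
    """
    p0 = np.asarray(p0, dtype=float)
    if np.any(p0 < 0):
        raise ValueError("initial density must be nonnegative")
    mass = np.trapezoid(p0, model.grid)
    if abs(mass - 1.0) > 1e-3:
        raise ValueError(f"initial density must integrate to 1 (got {mass:.4f})")
    dens = _evolve(model, p0 / mass, np.asarray(times, dtype=float), dt, with_source=False)
    return DensitySeries(grid=model.grid, densities=dens, times=times, normalized=True)


def solve_fp_source(model: LandscapeModel, P0: np.ndarray, times, dt: float | None = None) -> DensitySeries:
    """Evolve an unnormalized population under drift-diffusion-growth.

    Returns the unnormalized ``P(x, t)`` together with the total mass
    ``N(t)``; the mass balance d ln N/dt = int alpha p dx holds to the
    splitting accuracy of the stepper.
    """
    if model.alpha is None:
        raise ValueError("model.alpha is required for the self-sourcing equation")
    P0 = np.asarray(P0, dtype=float)
    if np.any(P0 < 0):
        raise ValueError("initial population must be nonnegative")
    if np.trapezoid(P0, model.grid) <= 0:
        raise ValueError("initial population must have positive mass")
    dens = _evolve(model, P0, np.asarray(times, dtype=float), dt, with_source=True)
    N = np.trapezoid(dens, model.grid, axis=1)
    return DensitySeries(grid=model.grid, densities=dens, times=times, normalized=False, N=N)


def normalize_population(series: DensitySeries) -> DensitySeries:
    """Factor out the norm: p(x, t) = P(x, t) / N(t)."""
    if series.normalized:
        return series
    N = series.integrals()
    if np.any(N <= 0):
        raise ValueError("cannot normalize a series with zero total mass")
    return DensitySeries(grid=series.grid, densities=series.densities / N[:, None],
                         times=series.times, normalized=True)


# ---------------------------------------------------------------------------
# density <-> drift <-> potential conversions


def _floored_log(p: np.ndarray, floor_frac: float = 1e-12) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if np.all(p <= 0):
        raise ValueError("density is identically zero")
    return np.log(np.maximum(p, floor_frac * p.max()))


def gibbs_potential(p_inf: np.ndarray, D: float, floor_frac: float = 1e-12) -> np.ndarray:
    """Potential from a stationary density: U = -(D/2) ln p_inf, min-shifted to 0.

    Density values below ``floor_frac`` times the maximum are floored before
    the logarithm, since KDE tails reach numerical zero.
    """
    U = -(D / 2.0) * _floored_log(p_inf, floor_frac)
    return U - U.min()


def drift_from_density(p_inf: np.ndarray, D: float, grid: np.ndarray,
                       floor_frac: float = 1e-12) -> np.ndarray:
    """The unique drift for which ``p_inf`` is stationary under zero flux.

    Zero flux means mu p = D dp/dx pointwise, i.e. mu = D dln(p_inf)/dx.
    """
    return D * np.gradient(_floored_log(p_inf, floor_frac), grid)


def potential_from_drift(mu: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """U(x) = -int_0^x mu(y) dy along the grid (no min shift)."""
    return -cumulative_trapezoid(np.asarray(mu, dtype=float), grid, initial=0.0)


def stationary_density(U: np.ndarray, D: float, grid: np.ndarray) -> np.ndarray:
    """Normalized stationary density exp(-2 U / D) of the zero-flux dynamics."""
    p = np.exp(-2.0 * np.asarray(U, dtype=float) / D)
    return p / np.trapezoid(p, grid)
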