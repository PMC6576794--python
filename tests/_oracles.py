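"""Independent oracles for the test suite.

These deliberately share no mechanism with the package: particle clouds
are simulated by (branching) Euler-Maruyama instead of inverse-CDF draws
from a grid density, and the reference PDE solve is an explicit upwind
finite-difference scheme instead of the Crank-Nicolson finite-volume
stepper.
"""

from __future__ import annotations

import numpy as np


def _reflect(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    x = np.where(x < lo, 2 * lo - x, x)
    x = np.where(x > hi, 2 * hi - x, x)
    return np.clip(x, lo, hi)


def em_particles(x0: np.ndarray, mu_fn, D: float, t_end: float, dt: float,
                 rng: np.random.Generator, bounds: tuple[float, float]) -> np.ndarray:
    """Euler-Maruyama with reflecting boundaries; noise variance 2 D dt."""
    x = np.asarray(x0, dtype=float).copy()
    n_steps = int(round(t_end / dt))
    s = np.sqrt(2.0 * D * dt)
    for _ in range(n_steps):
        x = x + mu_fn(x) * dt + s * rng.standard_normal(x.size)
        x = _reflect(x, *bounds)
    return x


def branching_em(x0: np.ndarray, mu_fn, alpha_fn, D: float, times, dt: float,
                 rng: np.random.Generator, bounds: tuple[float, float]) -> list:
    """Branching Euler-Maruyama: birth with prob alpha*dt (death if negative).

    Returns the particle positions at each requested checkpoint time.
    """
    x = np.asarray(x0, dtype=float).copy()
    s = np.sqrt(2.0 * D * dt)
    out = []
    t = 0.0
    for t_next in np.asarray(times, dtype=float):
        n_steps = int(round((t_next - t) / dt))
        for _ in range(n_steps):
            x = x + mu_fn(x) * dt + s * rng.standard_normal(x.size)
            x = _reflect(x, *bounds)
            a = alpha_fn(x)
            u = rng.random(x.size)
            born = x[(a > 0) & (u < a * dt)]
            alive = ~((a < 0) & (u < -a * dt))
            x = np.concatenate([x[alive], born])
        out.append(x.copy())
        t = t_next
    return out


def histogram_density(x: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Normalized density of particle positions on grid-centered bins."""
    dx = grid[1] - grid[0]
    edges = np.concatenate([grid - dx / 2, [grid[-1] + dx / 2]])
    counts, _ = np.histogram(x, bins=edges)
    return counts / (x.size * dx)


def explicit_fd_solve(grid: np.ndarray, D: float, mu: np.ndarray, p0: np.ndarray,
                      times) -> np.ndarray:
    """Explicit upwind/FTCS reference solve with zero-flux boundaries."""
    dx = grid[1] - grid[0]
    vmax = max(np.abs(mu).max(), 1e-12)
    dt = 0.3 * min(dx**2 / (2.0 * D), dx / vmax)
    p = np.asarray(p0, dtype=float).copy()
    out = np.empty((len(times), grid.size))
    mu_f = 0.5 * (mu[:-1] + mu[1:])  # interface drift
    t = 0.0
    for k, t_next in enumerate(np.asarray(times, dtype=float)):
        n_steps = max(1, int(np.ceil((t_next - t) / dt))) if t_next > t else 0
        h = (t_next - t) / n_steps if n_steps else 0.0
        for _ in range(n_steps):
            # upwind advective flux at interfaces, diffusive flux central
            upw = np.where(mu_f > 0, p[:-1], p[1:])
            flux = mu_f * upw - D * np.diff(p) / dx
            dp = np.zeros_like(p)
            dp[:-1] -= flux / dx
            dp[1:] += flux / dx
            p = p + h * dp
        out[k] = p
        t = t_next
    return out
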