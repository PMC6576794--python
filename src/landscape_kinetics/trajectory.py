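"""Reduction of 2-D marker clouds to the 1-D reaction coordinate.

The reaction coordinate x is the arc-length position along a principal
curve fitted to the pooled (log MART-1, log NGFR) events of all
timepoints.  Events are projected to their nearest point on the curve and
the projected arc lengths are the 1-D data; per-timepoint probability
densities are then obtained by Gaussian kernel density estimation on a
fixed uniform grid.

The curve fitter is a local-averaging projection-expectation iteration:
starting from the first principal-component line, it alternates projecting
events onto the current polyline and replacing each curve vertex with the
box-kernel average of the events whose projections fall nearby (span a
fixed fraction of the coordinate range), until the mean squared projection
distance stabilizes.  Arc length 0 is anchored at the end of the curve
nearest the earliest timepoint's centroid (the melanocytic end).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fp import DensitySeries
from .synthetic import MarkerCloudSeries

__all__ = [
    "PrincipalCurve",
    "fit_principal_curve",
    "project",
    "estimate_density",
    "default_grid",
]


@dataclass
class PrincipalCurve:
    vertices: np.ndarray  # (m, 2) ordered points
    arclength: np.ndarray  # (m,) cumulative distance, starts at 0
    span: float
    n_iter: int

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.arclength = np.asarray(self.arclength, dtype=float)
        if not np.all(np.isfinite(self.vertices)):
            raise ValueError("curve vertices must be finite")
        if self.arclength[0] != 0 or np.any(np.diff(self.arclength) <= 0):
            raise ValueError("arclength must strictly increase from 0")

    @property
    def length(self) -> float:
        return float(self.arclength[-1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"arclength": self.arclength,
                             "marker1": self.vertices[:, 0],
                             "marker2": self.vertices[:, 1]})


def _project_to_polyline(pts: np.ndarray, vertices: np.ndarray,
                         arclength: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Nearest-point projection of each point onto the polyline.

    Returns (arc-length coordinates, squared distances).  Ties between
    segments resolve to the lower arc length (first-occurrence argmin).
    """
    a = vertices[:-1]  # (m-1, 2)
    d = vertices[1:] - a
    seg_len2 = np.einsum("ij,ij->i", d, d)
    seg_len2 = np.maximum(seg_len2, 1e-300)
    # (n, m-1) parameter of the foot of the perpendicular, clamped to segment
    t = np.clip(((pts[:, None, :] - a[None]) * d[None]).sum(-1) / seg_len2, 0.0, 1.0)
    foot = a[None] + t[..., None] * d[None]
    dist2 = ((pts[:, None, :] - foot) ** 2).sum(-1)
    best = np.argmin(dist2, axis=1)
    idx = np.arange(pts.shape[0])
    lam = arclength[best] + t[idx, best] * np.sqrt(seg_len2[best])
    return lam, dist2[idx, best]


def _smooth_curve(pts: np.ndarray, lam: np.ndarray, span: float,
                  n_vertices: int) -> np.ndarray:
    """Box-kernel local averages of the points over the projection index."""
    lo, hi = lam.min(), lam.max()
    grid = np.linspace(lo, hi, n_vertices)
    half = max(span * (hi - lo) / 2.0, 1e-12)
    order = np.argsort(lam, kind="stable")
    lam_s = lam[order]
    pts_s = pts[order]
    csum = np.vstack([np.zeros(2), np.cumsum(pts_s, axis=0)])
    left = np.searchsorted(lam_s, grid - half, side="left")
    right = np.searchsorted(lam_s, grid + half, side="right")
    # guarantee at least one point per window by widening to the nearest
    empty = right <= left
    if np.any(empty):
        nearest = np.clip(np.searchsorted(lam_s, grid[empty]), 0, lam_s.size - 1)
        left[empty] = nearest
        right[empty] = nearest + 1
    counts = (right - left)[:, None]
    return (csum[right] - csum[left]) / counts


def fit_principal_curve(clouds, span: float = 0.15, max_iter: int = 10,
                        tol: float = 1e-6, n_vertices: int = 100) -> PrincipalCurve:
    """Fit a principal curve to the pooled events of all timepoints.

    ``clouds`` is a :class:`MarkerCloudSeries` or an (n, 2) array.  The
    orientation is fixed so that arc length 0 lies at the curve end closest
    to the centroid of the earliest timepoint's events (for a bare array,
    the end closest to the first event).
    """
    if isinstance(clouds, MarkerCloudSeries):
        pts = clouds.pooled()
        anchor = clouds.clouds[0].mean(axis=0)
    else:
        pts = np.asarray(clouds, dtype=float)
        anchor = pts[0]
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("events must be 2-D points")
    if pts.shape[0] < 100:
        raise ValueError("at least 100 pooled events are required")
    if np.ptp(pts, axis=0).max() < 1e-12:
        raise ValueError("degenerate input: all events are identical")

    center = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - center, full_matrices=False)
    lam = (pts - center) @ vt[0]

    prev_msd = np.inf
    n_iter = 0
    vertices = None
    arclength = None
    for n_iter in range(1, max_iter + 1):
        vertices = _smooth_curve(pts, lam, span, n_vertices)
        steps = np.linalg.norm(np.diff(vertices, axis=0), axis=1)
        keep = np.concatenate([[True], steps > 1e-12])  # drop coincident vertices
        vertices = vertices[keep]
        arclength = np.concatenate([[0.0], np.cumsum(
            np.linalg.norm(np.diff(vertices, axis=0), axis=1))])
        lam, dist2 = _project_to_polyline(pts, vertices, arclength)
        msd = dist2.mean()
        if abs(prev_msd - msd) < tol:
            break
        prev_msd = msd

    # orient: anchor (earliest-timepoint centroid) maps near arc length 0
    lam_anchor, _ = _project_to_polyline(anchor[None, :], vertices, arclength)
    if lam_anchor[0] > arclength[-1] / 2.0:
        vertices = vertices[::-1]
        arclength = arclength[-1] - arclength[::-1]
    return PrincipalCurve(vertices=vertices, arclength=arclength, span=span, n_iter=n_iter)


def project(clouds, curve: PrincipalCurve):
    """Arc-length coordinates of events along the fitted curve (units q).

    For a :class:`MarkerCloudSeries`, returns one 1-D array per timepoint;
    for a bare (n, 2) array, a single array.
    """
    if isinstance(clouds, MarkerCloudSeries):
        return [
            _project_to_polyline(c, curve.vertices, curve.arclength)[0]
            for c in clouds.clouds
        ]
    pts = np.atleast_2d(np.asarray(clouds, dtype=float))
    return _project_to_polyline(pts, curve.vertices, curve.arclength)[0]


def default_grid(coords, n: int = 256, pad: float = 0.05) -> np.ndarray:
    """Uniform coordinate grid spanning the pooled data range, padded 5%."""
    pooled = np.concatenate([np.ravel(c) for c in coords]) if isinstance(coords, (list, tuple)) \
        else np.ravel(coords)
    lo, hi = pooled.min(), pooled.max()
    halo = pad * (hi - lo)
    return np.linspace(lo - halo, hi + halo, n)


def _silverman(x: np.ndarray) -> float:
    sd = x.std(ddof=1)
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    return 0.9 * spread * x.size ** (-0.2)


def estimate_density(coords, times, grid: np.ndarray | None = None,
                     bandwidth: float | None = None) -> DensitySeries:
    """Gaussian-KDE densities of projected coordinates on a fixed grid.

    ``bandwidth`` is in coordinate units (q); the default is Silverman's
    rule per timepoint.  Each density is renormalized to integrate to 1 on
    the grid.  Degenerate samples (all at one point) fall back to a single
    kernel bump of width ``bandwidth`` (or 1% of the grid span).
    """
    coords = [np.asarray(c, dtype=float) for c in coords]
    if bandwidth is not None and bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    if any(c.size < 2 for c in coords):
        raise ValueError("at least 2 samples per timepoint are required")
    if grid is None:
        grid = default_grid(coords)
    span = grid[-1] - grid[0]
    dens = np.empty((len(coords), grid.size))
    for i, x in enumerate(coords):
        h = bandwidth if bandwidth is not None else _silverman(x)
        if not h > 0:
            h = bandwidth if bandwidth else 0.01 * span
        z = (grid[None, :] - x[:, None]) / h
        rho = np.exp(-0.5 * z**2).sum(axis=0) / (x.size * h * np.sqrt(2 * np.pi))
        dens[i] = rho / np.trapezoid(rho, grid)
    return DensitySeries(grid=grid, densities=dens, times=np.asarray(times, dtype=float),
                         normalized=True)
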