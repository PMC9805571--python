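"""Geometric medians and the distances used by consensus voting.

The geometric median of a point set {x_1..x_n} in R^d is

    u^ = argmin_x  sum_i || x - x_i ||_2,

the multivariate generalisation of the median: robust to outliers, not
necessarily a data point, defined in any dimension.  It is computed with
the Weiszfeld fixed-point iteration, using the Vardi-Zhang modified update
when an iterate lands on a data point (where the plain iteration is
undefined).

``oracle_geometric_median`` minimises the same objective with a
general-purpose numeric optimiser from several starts; it exists purely as
an independent cross-check for tests and is never used in the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

_SINGULARITY_EPS = 1e-12


@dataclass(frozen=True)
class GeoMedianResult:
    median: np.ndarray
    objective: float
    iterations: int
    converged: bool


def _as_points(points) -> np.ndarray:
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.size == 0:
        raise ValueError("geometric median of an empty point set is undefined")
    if not np.all(np.isfinite(pts)):
        raise ValueError("points must be finite")
    return pts


def distance_sum(x: np.ndarray, points: np.ndarray) -> float:
    """Objective sum_i ||x - x_i||_2 at a candidate point x."""
    return float(np.linalg.norm(points - x, axis=1).sum())


def geometric_median(points, tol: float = 1e-7, max_iter: int = 500) -> GeoMedianResult:
    """Weiszfeld iteration for the geometric median.

    Parameters
    ----------
    points : array-like of shape (n, d)
    tol : convergence tolerance on the step norm.
    max_iter : iteration cap.

    Returns
    -------
    GeoMedianResult
        With the median, the objective value there, the iteration count
        and a convergence flag.

    Notes
    -----
    n = 1 returns the point; n = 2 returns the midpoint (every point on
    the segment is optimal; the midpoint is the canonical choice).  The
    iteration starts at the coordinate-wise mean, so the objective at the
    result never exceeds the objective at the mean.
    """
    pts = _as_points(points)
    n, d = pts.shape
    if n == 1:
        return GeoMedianResult(pts[0].copy(), 0.0, 0, True)
    if n == 2:
        mid = pts.mean(axis=0)
        return GeoMedianResult(mid, distance_sum(mid, pts), 0, True)

    y = pts.mean(axis=0)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        diff = pts - y
        dist = np.linalg.norm(diff, axis=1)
        at_point = dist < _SINGULARITY_EPS
        if at_point.any():
            # Vardi-Zhang update: y coincides with eta data points.
            nz = ~at_point
            if not nz.any():
                converged = True
                break
            w = 1.0 / dist[nz]
            t_step = (pts[nz] * w[:, None]).sum(axis=0) / w.sum()
            r_vec = (diff[nz] * w[:, None]).sum(axis=0)
            r = float(np.linalg.norm(r_vec))
            eta = float(at_point.sum())
            if r <= eta:  # y is the optimum (subgradient condition)
                converged = True
                break
            gamma = eta / r
            y_new = (1.0 - gamma) * t_step + gamma * y
        else:
            w = 1.0 / dist
            y_new = (pts * w[:, None]).sum(axis=0) / w.sum()
        step = float(np.linalg.norm(y_new - y))
        y = y_new
        if step <= tol:
            converged = True
            break
    return GeoMedianResult(y, distance_sum(y, pts), it, converged)


def manhattan_distance(a, b) -> float:
    """L1 distance sum_j |a_j - b_j| between two equal-length vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"dimension mismatch: {a.shape} vs {b.shape}")
    return float(np.abs(a - b).sum())


def oracle_geometric_median(points) -> np.ndarray:
    """Independent numeric minimiser of the geometric-median objective.

    Runs gradient-based minimisation from several starts (mean,
    coordinate-wise median, a jittered data point) and returns the best.
    Test-scale only (n <= ~1000); the pipeline always uses
    :func:`geometric_median`.
    """
    pts = _as_points(points)
    n, d = pts.shape
    if n == 1:
        return pts[0].copy()

    def objective(x):
        return np.linalg.norm(pts - x, axis=1).sum()

    def gradient(x):
        diff = x - pts
        dist = np.linalg.norm(diff, axis=1)
        dist = np.maximum(dist, 1e-12)
        return (diff / dist[:, None]).sum(axis=0)

    starts = [pts.mean(axis=0), np.median(pts, axis=0), pts[0] + 1e-3]
    best_x, best_f = None, np.inf
    for x0 in starts:
        res = minimize(objective, x0, jac=gradient, method="L-BFGS-B",
                       options={"maxiter": 2000, "ftol": 1e-15, "gtol": 1e-12})
        if res.fun < best_f:
            best_x, best_f = res.x, res.fun
    return best_x
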