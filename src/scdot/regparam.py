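"""L-curve selection of the regularization weight.

The L-curve plots the data misfit ``||dphi - J dc||_2^2`` against the
regularizer value (``||dc||_1`` for the L1 solvers, ``||dc||_2^2`` for
Tikhonov) over a descending ladder of lambda values.  The preferred lambda
sits at the elbow — the point of maximum curvature of the log-log curve.
Because a full scan per outer iteration would be prohibitively expensive
and adds little, the scan is run on the first linearization only and the
chosen lambda is reused for the remaining outer iterations.

Curvature is measured at a macroscopic scale: ladder points are first
thinned so that no two retained points are closer than a minimum arc
length in log-log space (solver tolerance makes densely clustered points
wobble), and the signed curvature at each retained point is the Menger
(circumscribed-circle) curvature of the triple formed with the nearest
retained neighbours at least ``scale`` log-units away on each side.  The
sign convention makes an L-shaped elbow positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import NoCornerError, ParameterError
from .solvers import SolverSettings, UpdateProblem, solve_update

__all__ = [
    "LCurve",
    "default_ladder",
    "lcurve_scan",
    "lcurve_corner",
    "polyline_curvature",
]


def polyline_curvature(
    x: np.ndarray, y: np.ndarray, scale: float = 0.0, thin: float = 0.0
) -> np.ndarray:
    """Signed Menger curvature along a polyline.

    For each interior point the curvature of the circle through the point
    and its nearest neighbours at arc length >= ``scale`` on either side
    (adjacent points when ``scale`` is 0).  ``thin`` drops points closer
    than the given arc length to the previously retained one before any
    curvature is measured; dropped points and endpoints get nan.  The sign
    is positive for an elbow turning from decreasing x toward increasing y.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    out = np.full(n, np.nan)
    keep = [0]
    for i in range(1, n):
        if np.hypot(x[i] - x[keep[-1]], y[i] - y[keep[-1]]) >= thin:
            keep.append(i)
    xk, yk = x[keep], y[keep]
    m = len(keep)
    if m < 3:
        return out
    seg = np.hypot(np.diff(xk), np.diff(yk))
    s = np.concatenate([[0.0], np.cumsum(seg)])
    for ii in range(1, m - 1):
        lo = np.flatnonzero(s[ii] - s[: ii] >= scale)
        hi = np.flatnonzero(s[ii + 1 :] - s[ii] >= scale) + ii + 1
        j = lo[-1] if lo.size else ii - 1
        k = hi[0] if hi.size else ii + 1
        ax, ay = xk[ii] - xk[j], yk[ii] - yk[j]
        bx, by = xk[k] - xk[ii], yk[k] - yk[ii]
        cross = ax * by - ay * bx
        la = np.hypot(ax, ay)
        lb = np.hypot(bx, by)
        lc = np.hypot(xk[k] - xk[j], yk[k] - yk[j])
        if la * lb * lc == 0:
            continue
        out[keep[ii]] = -2.0 * cross / (la * lb * lc)
    return out


@dataclass
class LCurve:
    """Residual/regularizer pairs along a descending lambda ladder."""

    lambdas: np.ndarray  # strictly decreasing
    residuals: np.ndarray  # ||dphi - J dc||^2, nan where the solver failed
    regularizers: np.ndarray  # ||dc||_1 or ||dc||_2^2
    method: str = ""
    solutions: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.lambdas = np.asarray(self.lambdas, dtype=float)
        self.residuals = np.asarray(self.residuals, dtype=float)
        self.regularizers = np.asarray(self.regularizers, dtype=float)
        if np.any(np.diff(self.lambdas) >= 0):
            raise ParameterError("lambda ladder must be strictly decreasing")

    @property
    def valid(self) -> np.ndarray:
        # zero-regularizer points (all-zero solutions) carry no log-log
        # geometry and are excluded alongside solver failures
        return (
            np.isfinite(self.residuals)
            & np.isfinite(self.regularizers)
            & (self.regularizers > 0)
            & (self.residuals > 0)
        )

    def curvature(self, scale: float | None = None) -> np.ndarray:
        """Signed macro-scale curvature at each ladder point (nan where not
        measurable).  ``scale`` defaults to a tenth of the curve's log-log
        arc length."""
        out = np.full(len(self.lambdas), np.nan)
        m = self.valid
        if m.sum() < 3:
            return out
        x = np.log10(self.residuals[m])
        y = np.log10(self.regularizers[m])
        if scale is None:
            arc = np.hypot(np.diff(x), np.diff(y)).sum()
            scale = max(0.05, 0.1 * arc)
        out[np.flatnonzero(m)] = polyline_curvature(x, y, scale=scale, thin=scale / 4)
        return out


def default_ladder(
    problem: UpdateProblem, n_points: int = 25, factor: float = 10**0.25
) -> np.ndarray:
    """Descending ladder from lambda_max = ||J^T dphi||_inf, the smallest
    weight with an all-zero L1 solution under the implemented convention,
    down by a fixed factor per point."""
    lam_max = float(np.abs(problem.matrix.T @ problem.dphi).max())
    if lam_max == 0:
        raise ParameterError("zero data vector: no ladder can be built")
    return lam_max * factor ** -np.arange(n_points)


def lcurve_scan(
    problem: UpdateProblem,
    settings: SolverSettings,
    ladder: np.ndarray | None = None,
    keep_solutions: bool = False,
) -> LCurve:
    """One solver run per ladder point, warm-started from the previous one.

    Solver failures are recorded as missing (nan) points and the scan
    continues.  The problem should be the first outer linearization.
    """
    lambdas = default_ladder(problem) if ladder is None else np.asarray(ladder, float)
    if len(lambdas) < 5:
        raise ParameterError("ladder needs at least 5 points")
    J = problem.matrix
    res = np.full(len(lambdas), np.nan)
    reg = np.full(len(lambdas), np.nan)
    sols = []
    warm = None
    for i, lam in enumerate(lambdas):
        sub = UpdateProblem(J, problem.dphi, lam)
        try:
            result = solve_update(sub, settings, x0=warm)
        except Exception:
            sols.append(None)
            continue
        x = result.delta_c
        warm = x
        r = problem.dphi - J @ x
        res[i] = float(r @ r)
        reg[i] = float(x @ x) if settings.method == "tikhonov" else float(np.abs(x).sum())
        sols.append(x if keep_solutions else None)
    return LCurve(lambdas, res, reg, settings.method, sols)


def lcurve_corner(
    curve: LCurve, window: tuple | None = None, scale: float | None = None
) -> float:
    """Lambda at the maximum-curvature elbow of the L-curve.

    ``window=(lam_lo, lam_hi)`` restricts the search, supporting the manual
    refinement workflow.  Ties break toward larger lambda.  Raises
    :class:`NoCornerError` when no measurable point has positive curvature.
    """
    if curve.valid.sum() < 5:
        raise NoCornerError("fewer than 5 valid L-curve points")
    k = curve.curvature(scale=scale)
    mask = np.isfinite(k)
    if window is not None:
        lo, hi = sorted(window)
        mask &= (curve.lambdas >= lo) & (curve.lambdas <= hi)
    if not mask.any() or np.nanmax(np.where(mask, k, -np.inf)) <= 1e-12:
        raise NoCornerError("L-curve has no elbow (no positive-curvature point)")
    k_masked = np.where(mask, k, -np.inf)
    idx = int(np.argmax(k_masked))  # first occurrence = largest lambda on ties
    return float(curve.lambdas[idx])
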