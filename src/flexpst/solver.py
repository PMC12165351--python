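"""Solve the stationarity equation for the flexible significance threshold.

The critical value x* minimizing the weighted error cost epsilon solves

    t_nu(x) / [t_nu(x - delta) + t_nu(x + delta)] = k,   x > 0.

The residual is smooth and even; as x -> 0+ the density ratio is at
least 1/2 and as x -> inf it returns to 1/2 (Student-t tails are
polynomial), so for k < 1/2 the equation generically has two positive
roots: the smaller is the local minimum of epsilon, the larger a local
maximum.  The solver brackets every sign change on a coarse grid,
refines each with Brent's method, and keeps the root with the smallest
epsilon.  When no sign change exists (delta = 0, or k beyond the range
of the ratio) epsilon is monotone and has only a boundary minimum; the
solution is then flagged non-converged with a diagnostic rather than
inventing a threshold.

:func:`solve_pst_batch` is the same equation solved by vectorized
bisection across many (nu, delta) pairs at once; the Monte Carlo
simulator uses it to recompute per-replica thresholds cheaply.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .errors import ErrorRates, InferenceWeights, TestGeometry, alpha_of_x, epsilon_of_x, stationarity_residual

__all__ = ["ThresholdSolution", "solve_flexible_pst", "solve_pst_batch"]

#: |residual| at the root below which the solve is declared converged.
RESIDUAL_TOL = 1e-8
#: absolute tolerance on x for the bracketed root refinement.
X_TOL = 1e-10


@dataclass(frozen=True)
class ThresholdSolution:
    """Flexible-threshold solve outcome.

    x_crit : critical t value x* (positive root of the stationarity
        equation; NaN when no stationary point exists).
    pst : the flexible p significance threshold alpha(x*) = 2*F_nu(-x*).
    rates : alpha, beta, epsilon evaluated at x*.
    converged : whether a stationary point was found with residual
        below tolerance.
    method : 'root' (bracketed root find), 'fallback_minimize'
        (bounded minimization of epsilon after root finding failed), or
        'no_stationary_point'.
    diagnostic : human-readable note for non-converged solves.
    """

    x_crit: float
    pst: float
    rates: ErrorRates
    converged: bool
    method: str
    diagnostic: str = ""


def _scan_grid(delta: float) -> np.ndarray:
    hi = delta + 12.0
    return np.concatenate([np.geomspace(1e-3, 0.5, 48),
                           np.linspace(0.5, hi, 300)[1:]])


def solve_flexible_pst(geometry: TestGeometry, weights: InferenceWeights) -> ThresholdSolution:
    """Find the critical value minimizing the weighted error cost.

    Root bracketing on [1e-3, delta + 12] followed by Brent refinement;
    among multiple stationary points the epsilon-smallest is returned.
    If bracketing finds no sign change, a bounded scalar minimization of
    epsilon is attempted; a minimum on the boundary means no usable
    stationary point exists and the result is flagged non-converged.
    The threshold itself is never rounded here.
    """
    nu, delta = geometry.nu, geometry.delta

    def residual(x: float) -> float:
        return stationarity_residual(x, geometry)

    def failure(method: str, note: str) -> ThresholdSolution:
        return ThresholdSolution(
            x_crit=float("nan"), pst=float("nan"),
            rates=ErrorRates(float("nan"), float("nan"), float("nan")),
            converged=False, method=method, diagnostic=note)

    if delta == 0.0:
        # ratio is identically 1/2: epsilon is monotone unless k = 1/2.
        return failure("no_stationary_point",
                       "delta = 0: the density ratio is constant at 1/2, "
                       "no stationary point exists")

    xs = _scan_grid(delta)
    res = stationarity_residual(xs, geometry)
    sign = np.sign(res)
    crossings = np.nonzero(sign[:-1] * sign[1:] < 0)[0]

    roots: list[float] = []
    for i in crossings:
        try:
            roots.append(optimize.brentq(residual, xs[i], xs[i + 1], xtol=X_TOL))
        except ValueError:
            continue
    roots.extend(xs[np.nonzero(res == 0.0)[0]].tolist())

    if roots:
        best = min(roots, key=lambda r: epsilon_of_x(r, geometry, weights).epsilon)
        rates = epsilon_of_x(best, geometry, weights)
        ok = abs(residual(best)) <= RESIDUAL_TOL
        return ThresholdSolution(
            x_crit=float(best), pst=float(alpha_of_x(best, nu)), rates=rates,
            converged=ok, method="root",
            diagnostic="" if ok else "root refinement did not reach residual tolerance")

    # No sign change: epsilon has no interior stationary point on the
    # scanned range, or the dip slipped through the grid.  Try a bounded
    # minimization of epsilon directly.
    opt = optimize.minimize_scalar(
        lambda x: epsilon_of_x(x, geometry, weights).epsilon,
        bounds=(1e-6, delta + 12.0), method="bounded",
        options={"xatol": 1e-10})
    x = float(opt.x)
    interior = 1e-4 < x < delta + 12.0 - 1e-4
    if opt.success and interior and abs(residual(x)) <= RESIDUAL_TOL:
        rates = epsilon_of_x(x, geometry, weights)
        return ThresholdSolution(
            x_crit=x, pst=float(alpha_of_x(x, nu)), rates=rates,
            converged=True, method="fallback_minimize")
    return failure("no_stationary_point" if not interior else "fallback_minimize",
                   "weighted error sum is monotone on x > 0 (boundary minimum); "
                   "no stationary point for this (nu, delta, k)")


def solve_pst_batch(nu, delta, k, n_grid: int = 160, n_bisect: int = 72):
    """Vectorized flexible-threshold solve for arrays of (nu, delta).

    Locates the first sign change of the stationarity residual on a
    per-element grid over (0, delta + 12] and refines it by bisection
    (the first positive-to-negative crossing is the epsilon-minimizing
    stationary point).  Returns ``(x_crit, pst, converged)`` arrays;
    elements with no crossing get NaN and ``converged=False``.

    Agrees with :func:`solve_flexible_pst` to well below 1e-9 on x.
    """
    nu = np.atleast_1d(np.asarray(nu, dtype=float))
    delta = np.atleast_1d(np.asarray(delta, dtype=float))
    nu, delta = np.broadcast_arrays(nu, delta)
    shape = nu.shape
    nu_c = nu[:, None]
    delta_c = delta[:, None]

    def residual(x):
        lf = stats.t.logpdf
        l0 = lf(x, df=nu_c if x.ndim > 1 else nu)
        d = delta_c if x.ndim > 1 else delta
        n = nu_c if x.ndim > 1 else nu
        return 1.0 / (np.exp(lf(x - d, df=n) - l0) + np.exp(lf(x + d, df=n) - l0)) - k

    hi = delta + 12.0
    frac = np.linspace(1e-4, 1.0, n_grid)
    xs = frac[None, :] * hi[:, None]          # (N, n_grid), starts near 0
    res = residual(xs)
    sign_flip = np.sign(res[:, :-1]) * np.sign(res[:, 1:]) < 0
    has_root = sign_flip.any(axis=1)
    first = np.where(has_root, sign_flip.argmax(axis=1), 0)

    rows = np.arange(shape[0])
    lo = xs[rows, first].copy()
    up = xs[rows, first + 1].copy()
    flo = res[rows, first].copy()

    for _ in range(n_bisect):
        mid = 0.5 * (lo + up)
        fmid = residual(mid)
        take_low = np.sign(fmid) == np.sign(flo)
        lo = np.where(take_low, mid, lo)
        flo = np.where(take_low, fmid, flo)
        up = np.where(take_low, up, mid)

    x = 0.5 * (lo + up)
    converged = has_root & (np.abs(residual(x)) <= RESIDUAL_TOL)
    x = np.where(converged, x, np.nan)
    pst = 2.0 * stats.t.cdf(-x, df=nu)
    return x.reshape(shape), pst.reshape(shape), converged.reshape(shape)
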