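"""Powell's conjugate-direction minimiser.

Derivative-free local minimisation: cycle over a set of search
directions (initially the coordinate axes), line-minimise along each,
and after every cycle optionally replace the direction of largest
single decrease with the cycle's net displacement, following Powell's
acceptance test.  This keeps the direction set close to conjugate for
near-quadratic objectives without ever evaluating a gradient.

The line search brackets the minimum by geometric expansion from the
current point and then refines it with bounded Brent minimisation
(golden section with parabolic interpolation steps).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = ["PowellResult", "powell_minimize"]


@dataclass
class PowellResult:
    """Outcome of a Powell minimisation."""

    x: np.ndarray
    fun: float
    converged: bool
    n_cycles: int
    nfev: int


def _line_minimize(g: Callable[[float], float], f0: float,
                   tol: float) -> tuple[float, float, int]:
    """Minimise g(alpha) starting from alpha=0 where g(0)=f0.

    Returns (alpha, g(alpha), n_evaluations).  The direction vector is
    assumed to carry the natural step scale, so alpha=1 is one step.
    """
    nfev = 0

    def ev(a: float) -> float:
        nonlocal nfev
        nfev += 1
        return g(a)

    step = 1.0
    f_plus = ev(step)
    if f_plus < f0:
        sgn = 1.0
    else:
        f_minus = ev(-step)
        if f_minus < f0:
            sgn, f_plus = -1.0, f_minus
        else:
            # Minimum near alpha=0; refine inside [-1, 1].
            res = minimize_scalar(ev, bounds=(-step, step), method="bounded",
                                  options={"xatol": tol, "maxiter": 60})
            if res.fun < f0:
                return float(res.x), float(res.fun), nfev
            return 0.0, f0, nfev
    # Expand downhill until the function turns back up.
    a, fa = 0.0, f0
    b, fb = sgn * step, f_plus
    c, fc = b, fb
    for _ in range(40):
        c_new = b * 2.0
        fc_new = ev(c_new)
        if fc_new >= fb:
            c, fc = c_new, fc_new
            break
        a, fa = b, fb
        b, fb = c_new, fc_new
        c, fc = b, fb
    lo, hi = sorted((a, c))
    res = minimize_scalar(ev, bounds=(lo, hi), method="bounded",
                          options={"xatol": tol * max(1.0, abs(hi - lo)),
                                   "maxiter": 80})
    if res.fun <= fb:
        return float(res.x), float(res.fun), nfev
    return float(b), float(fb), nfev


def powell_minimize(objective: Callable[[np.ndarray], float],
                    x0: Sequence[float],
                    *,
                    xtol: float = 1e-8,
                    ftol: float = 1e-11,
                    max_cycles: int = 200,
                    initial_step: Sequence[float] | None = None,
                    line_tol: float = 1e-7) -> PowellResult:
    """Minimise ``objective`` from ``x0`` by Powell's direction-set method.

    Parameters
    ----------
    objective
        Callable returning a finite scalar; raises ``ValueError`` if it
        is non-finite at ``x0``.
    xtol, ftol
        Stop when the cycle moves every coordinate by less than
        ``xtol`` (absolute) or shrinks the objective by less than
        ``ftol`` relative to its magnitude.
    max_cycles
        Hard cap on direction-set cycles; exceeding it returns
        ``converged=False``.
    initial_step
        Per-coordinate scale of the initial (axis-aligned) directions;
        defaults to ``max(0.1 * |x0_i|, 1e-3)``.
    """
    x = np.asarray(x0, dtype=float).copy()
    n = x.size
    nfev = 0

    def f(pt: np.ndarray) -> float:
        nonlocal nfev
        nfev += 1
        return float(objective(pt))

    fx = f(x)
    if not np.isfinite(fx):
        raise ValueError("objective is not finite at x0")

    if initial_step is None:
        steps = np.maximum(0.1 * np.abs(x), 1e-3)
    else:
        steps = np.asarray(initial_step, dtype=float)
        if steps.shape != x.shape or np.any(steps <= 0):
            raise ValueError("initial_step must be positive, one per axis")
    dirs = np.diag(steps).astype(float)

    converged = False
    cycle = 0
    tiny = 1e-25
    for cycle in range(1, max_cycles + 1):
        x_start, f_start = x.copy(), fx
        delta, i_big = 0.0, 0
        for i in range(n):
            d = dirs[i]

            def g(alpha, _d=d):
                return f(x + alpha * _d)

            alpha, f_new, ne = _line_minimize(g, fx, line_tol)
            del ne  # counted through f
            if fx - f_new > delta:
                delta, i_big = fx - f_new, i
            x = x + alpha * d
            fx = f_new
        if 2.0 * (f_start - fx) <= ftol * (abs(f_start) + abs(fx)) + tiny:
            converged = True
            break
        if np.all(np.abs(x - x_start) < xtol):
            converged = True
            break
        # Powell's update: try the cycle's net displacement as a new
        # direction if the extrapolated point keeps descending.
        x_ext = 2.0 * x - x_start
        f_ext = f(x_ext)
        if f_ext < f_start:
            t = (2.0 * (f_start - 2.0 * fx + f_ext)
                 * (f_start - fx - delta) ** 2
                 - delta * (f_start - f_ext) ** 2)
            if t < 0.0:
                d_new = x - x_start

                def g(alpha, _d=d_new):
                    return f(x + alpha * _d)

                alpha, f_new, _ = _line_minimize(g, fx, line_tol)
                if f_new < fx:
                    x = x + alpha * d_new
                    fx = f_new
                dirs[i_big] = dirs[n - 1]
                dirs[n - 1] = d_new
    return PowellResult(x=x, fun=fx, converged=converged,
                        n_cycles=cycle, nfev=nfev)
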