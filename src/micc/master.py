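"""Full distribution of the failed count: the master equation for P(f, t).

The failed count is a birth(-death) chain on f = 0..N with birth rate
``w(f) = r (f + eps N)(N - f)`` and (with repair) death rate ``alpha f``.
The master equation

    dP(f,t)/dt = w(f-1) P(f-1,t) - w(f) P(f,t)   [+ repair terms]

is a linear ODE system.  In the Gompertz regime the occupied states stay tiny
relative to N, so the solver works on a truncated support 0..f_max with an
explicit absorbing "leak" accumulator monitoring the truncated mass, and
enlarges f_max automatically if the leak exceeds a tolerance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.integrate import solve_ivp

from .params import ModelParams

__all__ = ["DistGrid", "solve_master", "discrete_time_step", "dist_moments"]

#: Maximum leak mass tolerated at any output time before enlarging f_max.
LEAK_TOL = 1e-6
#: Hard cap on the truncated support size during auto-enlargement.
F_MAX_CAP = 40_000


@dataclass
class DistGrid:
    """P(f, t) on a truncated support.

    ``P`` has shape (len(t_grid), len(f_support)); ``leak[i]`` is the
    probability mass that has crossed the truncation boundary by ``t_grid[i]``.
    At every time ``P.sum() + leak == 1`` to within 1e-12.
    """

    t_grid: np.ndarray
    f_support: np.ndarray
    P: np.ndarray
    leak: np.ndarray

    @property
    def f_max(self) -> int:
        return int(self.f_support[-1])

    def cdf(self) -> np.ndarray:
        """Cumulative distribution over f at each time (leak mass excluded)."""
        return np.cumsum(self.P, axis=1)


def default_f_max(params: ModelParams, t_end: float) -> int:
    """Truncation heuristic: ~20x the exponential mean at the horizon, min 50."""
    f_max = max(50, math.ceil(20.0 * max(params.f0, 1.0) * math.exp(params.b * t_end)))
    return int(min(f_max, params.N, F_MAX_CAP))


def _generator(params: ModelParams, f_max: int) -> sparse.csc_matrix:
    """Sparse generator on states 0..f_max plus one absorbing leak state."""
    n = f_max + 1
    f = np.arange(n, dtype=float)
    birth = params.r * (f + params.epsilon * params.N) * (params.N - f)
    birth = np.maximum(birth, 0.0)
    death = params.alpha * f
    diag = -(birth + death)
    A = sparse.lil_matrix((n + 1, n + 1))
    A.setdiag(np.append(diag, 0.0))
    rows = np.arange(1, n)
    A[rows, rows - 1] = birth[rows - 1]
    if params.alpha > 0:
        A[rows - 1, rows] = death[1:]
        # mass leaving f_max downward stays inside the support
    A[n, n - 1] = birth[-1]  # flux across the truncation boundary
    return A.tocsc()


def solve_master(
    params: ModelParams,
    t_grid,
    f_max: int | None = None,
    leak_tol: float = LEAK_TOL,
    rtol: float = 1e-9,
    atol: float = 1e-14,
) -> DistGrid:
    """Integrate the master equation on a truncated support.

    Starts from a point mass at f0 (rounded to an integer state).  If the
    accumulated leak exceeds ``leak_tol`` at any output time, the support is
    doubled and the solve re-run, up to a hard cap; exceeding the cap raises
    with the support size that would have been required.
    """
    t_arr = np.atleast_1d(np.asarray(t_grid, dtype=float))
    if np.any(t_arr < 0) or np.any(np.diff(t_arr) <= 0):
        raise ValueError("t_grid must be non-negative and strictly increasing")
    f0 = int(round(params.f0))
    if f_max is None:
        f_max = default_f_max(params, float(t_arr[-1]))
    if f_max < f0:
        raise ValueError(f"f_max = {f_max} must be >= f0 = {f0}")
    f_max = int(min(f_max, params.N))

    while True:
        A = _generator(params, f_max)

        def rhs(_t, y):
            return A @ y

        def jac(_t, _y):
            return A

        y0 = np.zeros(f_max + 2)
        y0[f0] = 1.0
        t_eval = t_arr if t_arr[0] > 0 else t_arr.copy()
        sol = solve_ivp(
            rhs,
            (0.0, float(t_arr[-1]) if t_arr[-1] > 0 else 1e-12),
            y0,
            t_eval=t_eval,
            method="BDF",
            jac=jac,
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:  # pragma: no cover
            raise RuntimeError(f"master-equation integration failed: {sol.message}")
        Y = sol.y.T  # (nt, states+leak)
        P = np.clip(Y[:, :-1], 0.0, None)
        leak = np.clip(Y[:, -1], 0.0, None)
        if np.max(leak) <= leak_tol or f_max >= min(params.N, F_MAX_CAP):
            break
        f_max = int(min(f_max * 2, params.N, F_MAX_CAP))

    if np.max(leak) > leak_tol:
        raise RuntimeError(
            f"truncation leak {np.max(leak):.3g} > {leak_tol:.1g} even at "
            f"f_max = {f_max}; a larger support (cap {F_MAX_CAP}) would be required"
        )
    # Project back onto the conserved-mass manifold: integrator drift is
    # O(rtol), the type contract requires 1e-12.
    total = P.sum(axis=1) + leak
    P /= total[:, None]
    leak /= total
    return DistGrid(t_grid=t_arr, f_support=np.arange(f_max + 1), P=P, leak=leak)


def discrete_time_step(params: ModelParams, P_t: np.ndarray, dt: float) -> np.ndarray:
    """One explicit (forward-Euler) update of the master equation.

    ``P(f, t+dt) = P(f,t) + dt [w(f-1) P(f-1,t) - w(f) P(f,t)]`` (plus repair
    terms when alpha > 0).  Requires the per-state jump probability
    ``w(f) dt <= 0.1``; first-order accurate, converging to
    :func:`solve_master` as dt -> 0.  Mass crossing the top of the support is
    lost (truncation), so pass a generous support.
    """
    P_t = np.asarray(P_t, dtype=float)
    if P_t.ndim != 1:
        raise ValueError("P_t must be a 1-d distribution over f = 0..f_max")
    if dt < 0:
        raise ValueError("dt must be >= 0")
    f = np.arange(len(P_t), dtype=float)
    birth = params.r * (f + params.epsilon * params.N) * np.maximum(params.N - f, 0.0)
    death = params.alpha * f
    worst = np.argmax((birth + death) * dt)
    if (birth[worst] + death[worst]) * dt > 0.1:
        raise ValueError(
            f"dt = {dt} too large: state f = {int(f[worst])} has transition "
            f"probability {(birth[worst] + death[worst]) * dt:.3g} > 0.1"
        )
    P_new = P_t.copy()
    P_new -= dt * (birth + death) * P_t
    P_new[1:] += dt * birth[:-1] * P_t[:-1]
    if params.alpha > 0:
        P_new[:-1] += dt * death[1:] * P_t[1:]
    if np.any(P_new < -1e-12):  # pragma: no cover - guarded by the dt check
        raise ValueError("negative probability produced; reduce dt")
    return np.clip(P_new, 0.0, None)


def dist_moments(dist: DistGrid) -> pd.DataFrame:
    """Per-time mean, variance, median and skewness of P(f, t).

    Exact discrete moments over the support; the median is the smallest f
    with CDF >= 0.5 (ties resolved downward); skewness of a zero-variance
    distribution is reported as 0.
    """
    f = dist.f_support.astype(float)
    mass = dist.P.sum(axis=1)
    mean = (dist.P @ f) / mass
    var = (dist.P @ f**2) / mass - mean**2
    var = np.maximum(var, 0.0)
    m3 = (dist.P @ f**3) / mass - 3 * mean * var - mean**3
    with np.errstate(divide="ignore", invalid="ignore"):
        skew = np.where(var > 0, m3 / np.power(var, 1.5), 0.0)
    cdf = dist.cdf() / mass[:, None]
    median = dist.f_support[np.argmax(cdf >= 0.5, axis=1)]
    return pd.DataFrame(
        {
            "t": dist.t_grid,
            "mean": mean,
            "var": var,
            "median": median.astype(float),
            "skew": skew,
            "leak": dist.leak,
        }
    )
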