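"""Linear-noise approximation (LNA) of the failed-count fluctuations.

Van Kampen's system-size expansion of the master equation gives, to leading
order, a Gaussian distribution around the mean-field trajectory: the mean
follows the logistic curve and the variance ``N * Xi(t)`` obeys the standard
one-species LNA equation

    dV/dt = 2 r (N - 2<f>) V + r <f> (N - <f>),

driven by the logistic mean.  In the early-age regime (t << tau) with zero
initial variance this integrates to the closed form

    V(t) = f0 exp(2 rN t) (1 - exp(-rN t)),

which grows almost — but slower than — exponentially at rate 2 rN.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .core import logistic_failed_count
from .params import ModelParams, RegimeWarning

__all__ = ["LNAResult", "lna_mean", "lna_variance_closed", "lna_variance_ode"]


@dataclass
class LNAResult:
    """LNA mean and variance of f(t) on a grid."""

    t_grid: np.ndarray
    mean: np.ndarray
    variance: np.ndarray
    xi0: float


def lna_mean(params: ModelParams, t) -> np.ndarray | float:
    """LNA (= mean-field) mean of f(t): the logistic curve."""
    return logistic_failed_count(params, t)


def lna_variance_closed(params: ModelParams, t) -> np.ndarray | float:
    """Closed-form early-age variance ``f0 e^{2rNt}(1 - e^{-rNt})`` (Xi(0)=0).

    Valid for t << tau; a warning is issued beyond tau/4.  For rNt << 1 the
    variance is ~ f0 rN t (Poisson-like onset); at later (still early) ages it
    grows almost exponentially, but always slower than e^{2rNt}.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("ages must be non-negative")
    if 0 < params.f0 < params.N and np.any(t_arr > params.tau / 4):
        warnings.warn(
            f"t beyond tau/4 = {params.tau / 4:.4g} y: closed-form variance is an "
            "early-age (t << tau) approximation",
            RegimeWarning,
            stacklevel=2,
        )
    out = params.f0 * np.exp(2 * params.b * t_arr) * (-np.expm1(-params.b * t_arr))
    return out if t_arr.ndim else float(out)


def lna_variance_ode(params: ModelParams, t_grid, xi0: float = 0.0) -> LNAResult:
    """General LNA variance by adaptive integration of the variance ODE.

    ``xi0`` is the initial scaled variance, Var(f(0)) = N * xi0.  With
    ``xi0 = 0`` and t << tau this matches :func:`lna_variance_closed`; unlike
    the closed form it remains the LNA ground truth through and beyond the
    logistic inflection.
    """
    if xi0 < 0:
        raise ValueError("xi0 must be >= 0")
    t_arr = np.atleast_1d(np.asarray(t_grid, dtype=float))
    if np.any(t_arr < 0) or (len(t_arr) > 1 and np.any(np.diff(t_arr) <= 0)):
        raise ValueError("t_grid must be non-negative and strictly increasing")
    t_end = float(t_arr[-1])

    def rhs(s, V):
        m = logistic_failed_count(params, float(s))
        return [
            2.0 * params.r * (params.N - 2.0 * m) * V[0]
            + params.r * m * (params.N - m)
        ]

    sol = solve_ivp(
        rhs,
        (0.0, max(t_end, 1e-12)),
        [params.N * xi0],
        t_eval=np.unique(np.concatenate([[0.0], t_arr])),
        method="LSODA",
        rtol=1e-9,
        atol=1e-12,
    )
    if not sol.success:  # pragma: no cover
        raise RuntimeError(f"LNA variance integration failed: {sol.message}")
    lookup = dict(zip(sol.t, sol.y[0]))
    variance = np.maximum(np.array([lookup[v] for v in t_arr]), 0.0)
    mean = np.asarray(logistic_failed_count(params, t_arr))
    return LNAResult(t_grid=t_arr, mean=mean, variance=variance, xi0=xi0)
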