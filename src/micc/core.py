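"""Mean-field solutions of the MICC failure-accumulation model.

The deterministic (mean-field) model is the logistic ODE

    dF/dt = r F (N - F),

whose solution grows exponentially, ``F(t) ~ f0 exp(rNt)``, while the failed
fraction is small, producing a Gompertz death hazard ``mu(t) = k F(t)/N ~
R0 exp(bt)`` with ``b = rN``.  The exponential regime ends at the inflection
age ``tau`` where F(tau) = N/2, which is where late-life mortality
deceleration sets in.

Also here: the two model alterations (spontaneous failure ``epsilon``,
repair ``alpha``) and the constant-failure-rate null model, whose hazard is
demonstrably *not* Gompertzian (its log-slope decreases with age).
"""

from __future__ import annotations

import math
import warnings

import numpy as np
from scipy.integrate import solve_ivp

from .params import HazardScale, ModelParams, RegimeWarning

__all__ = [
    "logistic_failed_count",
    "inflection_time",
    "mortality_rate",
    "gompertz_rate",
    "gompertz_survival",
    "cumulative_hazard",
    "survival_and_density",
    "spontaneous_failed_count",
    "apply_repair",
    "constant_rate_failed_count",
]

#: Relative tolerance for the adaptive ODE integrations in this module.
ODE_RTOL = 1e-9
ODE_ATOL = 1e-12


def _check_base(params: ModelParams) -> None:
    if params.epsilon != 0 or params.alpha != 0:
        raise ValueError(
            "base-model solution requires epsilon = 0 and alpha = 0; "
            "use spontaneous_failed_count / apply_repair for the alterations"
        )


def _check_ages(t) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("ages must be non-negative")
    return t


def logistic_failed_count(params: ModelParams, t) -> np.ndarray | float:
    """Mean failed-subsystem count F(t) of the base model (logistic growth).

    ``F(t) = N f0 / (f0 + (N - f0) exp(-rNt))``; accepts scalar or array ages
    in years.
    """
    _check_base(params)
    t_arr = _check_ages(t)
    if params.f0 == 0:
        warnings.warn("f0 = 0: frozen state, F(t) = 0 for all t", RegimeWarning, stacklevel=2)
        out = np.zeros_like(t_arr)
        return out if t_arr.ndim else 0.0
    decay = np.exp(-params.b * t_arr)
    out = params.N * params.f0 / (params.f0 + (params.N - params.f0) * decay)
    return out if t_arr.ndim else float(out)


def inflection_time(params: ModelParams) -> float:
    """Inflection age tau (years) at which F(tau) = N/2.

    Warns when f0 >= N/2 (tau <= 0: the parameter set starts outside the
    small-failed-fraction regime).
    """
    tau = params.tau
    if params.f0 >= params.N / 2:
        warnings.warn(
            f"f0 = {params.f0} >= N/2: tau = {tau:.4g} <= 0, outside the "
            "small-failed-fraction regime",
            RegimeWarning,
            stacklevel=2,
        )
    return tau


def mortality_rate(params: ModelParams, scale: HazardScale, t) -> np.ndarray | float:
    """Population hazard mu(t) = k F(t)/N (1/year) of the base model.

    Increases monotonically from ``R0 = k f0/N`` towards the plateau ``k``;
    for ages well below tau it tracks the Gompertz curve ``R0 exp(bt)``.
    """
    F = logistic_failed_count(params, t)
    return scale.k * F / params.N


def gompertz_rate(r0: float, b: float, t) -> np.ndarray | float:
    """Gompertz hazard ``mu(t) = R0 exp(b t)`` (1/year)."""
    if r0 <= 0:
        raise ValueError("r0 must be positive")
    t_arr = _check_ages(t)
    out = r0 * np.exp(b * t_arr)
    return out if t_arr.ndim else float(out)


def gompertz_survival(r0: float, b: float, t) -> np.ndarray | float:
    """Survival under a pure Gompertz hazard: ``exp(-(R0/b)(exp(bt) - 1))``."""
    t_arr = _check_ages(t)
    out = np.exp(-(r0 / b) * np.expm1(b * t_arr))
    return out if t_arr.ndim else float(out)


def cumulative_hazard(params: ModelParams, scale: HazardScale, t) -> np.ndarray | float:
    """Integrated hazard of the base model, ``int_0^t mu(s) ds``.

    The logistic hazard integrates in closed form:
    ``(k/b) ln((f0 exp(bt) + N - f0)/N)``, evaluated through ``logaddexp``
    so large ``bt`` does not overflow.
    """
    _check_base(params)
    t_arr = _check_ages(t)
    if params.f0 == 0 or scale.k == 0:
        out = np.zeros_like(t_arr)
        return out if t_arr.ndim else 0.0
    log_f0 = math.log(params.f0)
    log_rest = math.log(params.N - params.f0) if params.f0 < params.N else -np.inf
    # anchor at the t=0 value so that the integral is exactly 0 at t=0
    log_num = np.logaddexp(log_f0 + params.b * t_arr, log_rest)
    out = (scale.k / params.b) * (log_num - np.logaddexp(log_f0, log_rest))
    return out if t_arr.ndim else float(out)


def survival_and_density(
    params: ModelParams, scale: HazardScale, t_grid
) -> tuple[np.ndarray, np.ndarray]:
    """Survival S(t) and life-span density p(t) = mu(t) S(t) on a grid.

    ``t_grid`` must be strictly increasing and start at 0, so that
    S(0) = 1 and p(0) = R0.
    """
    t_grid = _check_ages(t_grid)
    if t_grid.ndim != 1 or len(t_grid) < 1:
        raise ValueError("t_grid must be a 1-d array")
    if t_grid[0] != 0:
        raise ValueError("t_grid must start at 0")
    if len(t_grid) > 1 and np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing")
    S = np.exp(-np.asarray(cumulative_hazard(params, scale, t_grid)))
    if scale.k == 0:
        p = np.zeros_like(S)
    else:
        p = np.asarray(mortality_rate(params, scale, t_grid)) * S
    return S, p


def spontaneous_failed_count(params: ModelParams, t) -> np.ndarray | float:
    """Mean failed count with spontaneous failure: dF/dt = r (F + eps N)(N - F).

    Solved by adaptive stiff-capable integration (rtol 1e-9).  Reduces to
    :func:`logistic_failed_count` when ``epsilon = 0``.  When
    ``epsilon*N >> f0`` the early growth is linear (rate ``r eps N^2``), not
    exponential — the hazard is then non-Gompertzian, like the constant-rate
    null model.
    """
    if params.alpha != 0:
        raise ValueError("spontaneous_failed_count requires alpha = 0")
    if params.epsilon == 0:
        return logistic_failed_count(params, t)
    t_arr = _check_ages(t)
    t_flat = np.atleast_1d(t_arr)
    t_end = float(t_flat.max()) if len(t_flat) else 0.0
    eps_n = params.epsilon * params.N

    def rhs(_s, F):
        return params.r * (F + eps_n) * (params.N - F)

    sol = solve_ivp(
        rhs,
        (0.0, max(t_end, 1e-12)),
        [params.f0],
        t_eval=np.unique(np.concatenate([[0.0], t_flat])),
        method="LSODA",
        rtol=ODE_RTOL,
        atol=ODE_ATOL,
    )
    if not sol.success:  # pragma: no cover
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    lookup = dict(zip(sol.t, sol.y[0]))
    out = np.array([lookup[v] for v in t_flat])
    return out if t_arr.ndim else float(out[0])


def apply_repair(params: ModelParams) -> ModelParams | None:
    """Absorb the repair rate into an effective base-model capacity.

    With spontaneous repair at rate ``alpha`` the mean-field ODE is
    ``dF/dt = r F (N - alpha/r - F)``: the same logistic dynamics with the
    capacity replaced by ``N' = N - alpha/r``.  Returns the effective
    base-model parameter set, or ``None`` (with a warning) when
    ``N' <= max(f0, 1)`` — the sub-critical case where repair outpaces the
    interaction and failures decay instead of growing.
    """
    if params.alpha == 0:
        return params.with_(alpha=0.0)
    n_eff = params.N - params.alpha / params.r
    if n_eff <= max(params.f0, 1.0):
        warnings.warn(
            f"sub-critical: effective capacity N - alpha/r = {n_eff:.4g} <= "
            f"max(f0, 1); failures decay, no logistic growth",
            RegimeWarning,
            stacklevel=2,
        )
        return None
    return ModelParams(N=n_eff, r=params.r, f0=params.f0, epsilon=params.epsilon, alpha=0.0)


def constant_rate_failed_count(N: float, f0: float, C: float, t) -> np.ndarray | float:
    """Null model: subsystems fail independently at constant rate C (1/year).

    ``dF/dt = C (N - F)`` gives ``F(t) = N - (N - f0) exp(-Ct)``.  The implied
    hazard ``k F/N`` is concave in log: its log-slope ``C (N - F)/F`` is
    strictly decreasing with age — the opposite signature of Gompertz growth.
    """
    if C <= 0:
        raise ValueError("C must be positive")
    if not 0 <= f0 <= N:
        raise ValueError("need 0 <= f0 <= N")
    t_arr = _check_ages(t)
    out = N - (N - f0) * np.exp(-C * t_arr)
    return out if t_arr.ndim else float(out)
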