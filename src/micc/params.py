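"""Parameter bundles for the multiple-and-interdependent-component-cause (MICC) model.

The organism is modelled as ``N`` interchangeable subsystems.  Failed
subsystems raise the failure rate of the intact ones: each intact subsystem
fails at rate ``r * (f + epsilon * N)`` where ``f`` is the current failed
count, ``r`` the pairwise interaction rate (per year per subsystem) and
``epsilon`` an optional small spontaneous-failure admixture.  ``alpha`` is an
optional per-subsystem repair rate returning failed subsystems to the intact
state.  The death hazard of an individual is proportional to its failed
fraction ``f/N``; the proportionality constant lives in :class:`HazardScale`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace


class RegimeWarning(UserWarning):
    """A parameter set is mathematically valid but outside the model's intended regime."""


@dataclass(frozen=True)
class ModelParams:
    """MICC parameter bundle.

    Parameters
    ----------
    N:
        Number of subsystems in one organism (dimensionless; large in the
        Gompertz regime).  Stored as a float so that repair-effective
        capacities ``N - alpha/r`` remain representable.
    r:
        Pairwise interaction rate, 1/(year * subsystem).  The early-age
        exponential growth rate of the failed count is ``b = r * N``.
    f0:
        Failed-subsystem count at age zero.  The Gompertz approximation
        requires ``f0/N`` to be very small.
    epsilon:
        Spontaneous-failure fraction: intact subsystems additionally fail at
        rate ``r * epsilon * N`` independent of the failed count. Default 0.
    alpha:
        Spontaneous repair rate per failed subsystem, 1/year. Default 0.
    """

    N: float
    r: float
    f0: float
    epsilon: float = 0.0
    alpha: float = 0.0

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError(f"N must be >= 1, got {self.N}")
        if not 0.0 <= self.f0 <= self.N:
            raise ValueError(f"f0 must lie in [0, N], got f0={self.f0}, N={self.N}")
        if self.r <= 0:
            raise ValueError(f"r must be positive, got {self.r}")
        if self.epsilon < 0:
            raise ValueError(f"epsilon must be >= 0, got {self.epsilon}")
        if self.alpha < 0:
            raise ValueError(f"alpha must be >= 0, got {self.alpha}")
        if self.f0 == 0 and self.epsilon == 0:
            warnings.warn(
                "f0 = 0 with epsilon = 0: the all-intact state is absorbing and "
                "no failure ever occurs",
                RegimeWarning,
                stacklevel=2,
            )

    @property
    def b(self) -> float:
        """Early-age exponential growth rate r*N (1/year); the Gompertz slope."""
        return self.r * self.N

    @property
    def f0_frac(self) -> float:
        """Initial failed fraction f0/N."""
        return self.f0 / self.N

    @property
    def tau(self) -> float:
        """Inflection age of the logistic mean, ``ln(N/f0 - 1) / (r N)`` (years).

        The mean failed count satisfies F(tau) = N/2; Gompertzian growth holds
        for ages well below tau.
        """
        if not 0 < self.f0 < self.N:
            raise ValueError("tau requires 0 < f0 < N")
        return math.log(self.N / self.f0 - 1.0) / self.b

    @classmethod
    def from_rates(
        cls,
        N: float,
        b: float,
        f0_frac: float | None = None,
        f0: float | None = None,
        epsilon: float = 0.0,
        alpha: float = 0.0,
    ) -> "ModelParams":
        """Build from the aggregate growth rate ``b = r N`` instead of ``r``.

        Exactly one of ``f0_frac`` (initial failed fraction, as quoted in
        calibrations) or ``f0`` (count) must be given.
        """
        if (f0_frac is None) == (f0 is None):
            raise ValueError("give exactly one of f0_frac or f0")
        if f0 is None:
            f0 = f0_frac * N
        return cls(N=N, r=b / N, f0=f0, epsilon=epsilon, alpha=alpha)

    def with_(self, **changes) -> "ModelParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **changes)


@dataclass(frozen=True)
class HazardScale:
    """Proportionality constant of the death hazard.

    The model states only that the hazard is proportional to the failed
    fraction; the convention here is ``mu(t) = k * F(t) / N`` with ``k`` in
    1/year.  Fixing ``k = R0 * N / f0`` makes ``mu(0)`` equal the Gompertz
    hazard-at-birth ``R0``, so a printed ``(R0, b)`` pair fully specifies the
    hazard.
    """

    k: float

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError(f"k must be >= 0, got {self.k}")

    @classmethod
    def from_r0(cls, r0: float, params: ModelParams) -> "HazardScale":
        """Scale such that the hazard at age zero equals ``r0`` (1/year)."""
        if r0 < 0:
            raise ValueError("r0 must be >= 0")
        if params.f0 <= 0:
            raise ValueError("r0-based scale needs f0 > 0")
        return cls(k=r0 * params.N / params.f0)

    def r0(self, params: ModelParams) -> float:
        """Hazard at age zero, ``k * f0 / N`` (1/year)."""
        return self.k * params.f0 / params.N
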