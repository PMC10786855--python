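"""Canonical parameter sets.

The default calibration reproduces the published fit of the model to pooled
Danish mortality data (all deaths 1990-2019): Gompertz slope
``b = 9.24e-3``/yr, hazard at birth ``R0 = 4.2e-5``/yr, system size
``N = 1e6``.  Two variants are provided:

``danish-meanfield``
    ``rN = b`` exactly — the mean-field (deterministic) calibration.
``danish-stochastic``
    ``rN = b / 0.977`` — the rate used when simulating individual stochastic
    trajectories, compensating for the small lag of the stochastic median
    behind the mean-field curve.
"""

from __future__ import annotations

from .params import HazardScale, ModelParams

#: Gompertz slope fitted to Danish mortality data (1/year).
DANISH_B = 9.24e-3
#: Fitted hazard at birth (1/year).
DANISH_R0 = 4.2e-5
#: System size used in the published calibration.
DANISH_N = 1e6
#: Default initial failed fraction of the calibration.
DANISH_F0_FRAC = 1e-5
#: Lag-correction factor: stochastic simulations use rN = b / LAG_FACTOR.
LAG_FACTOR = 0.977


def danish_meanfield(f0_frac: float = DANISH_F0_FRAC) -> tuple[ModelParams, HazardScale]:
    """Mean-field calibration (rN = b)."""
    params = ModelParams.from_rates(N=DANISH_N, b=DANISH_B, f0_frac=f0_frac)
    return params, HazardScale.from_r0(DANISH_R0, params)


def danish_stochastic(f0_frac: float = DANISH_F0_FRAC) -> tuple[ModelParams, HazardScale]:
    """Stochastic-simulation calibration (rN = b / 0.977, lag-corrected)."""
    params = ModelParams.from_rates(N=DANISH_N, b=DANISH_B / LAG_FACTOR, f0_frac=f0_frac)
    return params, HazardScale.from_r0(DANISH_R0, params)


PRESETS = {
    "danish-meanfield": danish_meanfield,
    "danish-stochastic": danish_stochastic,
}
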