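"""Exact stochastic simulation of individual failure trajectories and deaths.

Each individual is a continuous-time Markov chain on the failed count ``f``:
failures occur at total rate ``r (f + eps N)(N - f)`` (each intact subsystem
fails at rate proportional to the failed count, plus an optional spontaneous
term), repairs at rate ``alpha f``.  Trajectories are simulated exactly with
the Gillespie algorithm — exponential waiting times, no time discretisation —
with an optional fixed-step binomial-thinning scheme for cross-checks.

Death is one-way coupled: an individual's hazard is ``mu_i(t) = k f_i(t)/N``,
piecewise constant between failure/repair events, and the death time is drawn
exactly by accumulating the integrated hazard against a unit-exponential
threshold.  Two individuals with identical trajectories share an identical
hazard history but generally die at different times.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import logistic_failed_count
from .params import HazardScale, ModelParams, RegimeWarning

__all__ = [
    "Trajectory",
    "Cohort",
    "simulate_trajectory",
    "simulate_death",
    "simulate_cohort",
    "failed_count_matrix",
    "cohort_stats",
    "biological_age",
]

EVENT_FAILURE = 1
EVENT_REPAIR = -1

#: Block size for vectorised waiting-time draws in the pure-birth fast path.
_BLOCK = 512


@dataclass
class Trajectory:
    """One individual's failure history on [0, t_max].

    ``f_path[i]`` is the failed count immediately *after* ``event_times[i]``
    (right-continuous convention); before the first event the count is ``f0``.
    """

    params: ModelParams
    t_max: float
    event_times: np.ndarray
    event_kinds: np.ndarray
    f_path: np.ndarray
    death_time: float | None = None
    seed: object = None

    @property
    def f0(self) -> int:
        return int(round(self.params.f0))

    def f_at(self, t) -> np.ndarray | int:
        """Failed count at age(s) t (right-continuous step interpolation)."""
        t_arr = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.event_times, t_arr, side="right")
        values = np.concatenate([[self.f0], self.f_path])
        out = values[idx]
        return out if t_arr.ndim else int(out)

    def segments(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Piecewise-constant decomposition: (start ages, end ages, f on segment)."""
        starts = np.concatenate([[0.0], self.event_times])
        ends = np.concatenate([self.event_times, [self.t_max]])
        values = np.concatenate([[self.f0], self.f_path])
        return starts, ends, values


def _simulate_pure_birth(params: ModelParams, rng: np.random.Generator, t_max: float):
    """Vectorised exact simulation when the state ladder is deterministic.

    With epsilon = alpha = 0 the chain can only step f -> f+1, so the event
    times are a cumulative sum of independent exponentials with rates
    r f (N - f); draw them in blocks until t_max or absorption at f = N.
    """
    f0 = int(round(params.f0))
    N = int(round(params.N))
    times: list[np.ndarray] = []
    f = f0
    t = 0.0
    while 0 < f < N:
        m = min(_BLOCK, N - f)
        levels = np.arange(f, f + m, dtype=float)
        rates = params.r * levels * (params.N - levels)
        waits = rng.standard_exponential(m) / rates
        cum = t + np.cumsum(waits)
        inside = cum <= t_max
        if not inside.all():
            times.append(cum[inside])
            f += int(inside.sum())
            break
        times.append(cum)
        f += m
        t = float(cum[-1])
    event_times = np.concatenate(times) if times else np.empty(0)
    n_ev = len(event_times)
    return (
        event_times,
        np.full(n_ev, EVENT_FAILURE, dtype=np.int8),
        f0 + np.arange(1, n_ev + 1, dtype=np.int64),
    )


def _simulate_general(params: ModelParams, rng: np.random.Generator, t_max: float):
    """Event-by-event Gillespie loop handling spontaneous failure and repair."""
    f = int(round(params.f0))
    N = params.N
    eps_n = params.epsilon * params.N
    t = 0.0
    ev_t, ev_k, ev_f = [], [], []
    while True:
        lam_fail = params.r * (f + eps_n) * (N - f) if f < N else 0.0
        lam_rep = params.alpha * f
        total = lam_fail + lam_rep
        if total <= 0:
            break
        t += rng.standard_exponential() / total
        if t > t_max:
            break
        if rng.random() * total < lam_fail:
            f += 1
            ev_k.append(EVENT_FAILURE)
        else:
            f -= 1
            ev_k.append(EVENT_REPAIR)
        ev_t.append(t)
        ev_f.append(f)
    return (
        np.asarray(ev_t, dtype=float),
        np.asarray(ev_k, dtype=np.int8),
        np.asarray(ev_f, dtype=np.int64),
    )


def simulate_trajectory(
    params: ModelParams,
    seed=None,
    t_max: float = 150.0,
    rng: np.random.Generator | None = None,
    scheme: str = "event",
    dt: float | None = None,
) -> Trajectory:
    """Simulate one individual's failure trajectory up to ``t_max`` years.

    ``scheme="event"`` (default) is the exact Gillespie simulation;
    ``scheme="fixed"`` uses binomial thinning on a fixed step ``dt`` and is
    provided for cross-validation of the continuous-time scheme.
    """
    if t_max <= 0:
        raise ValueError("t_max must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)
    f0 = int(round(params.f0))
    if f0 == 0 and params.epsilon == 0:
        warnings.warn(
            "zero total rate at start (f0 = 0, epsilon = 0): trajectory is frozen",
            RegimeWarning,
            stacklevel=2,
        )
    if scheme == "event":
        if params.epsilon == 0 and params.alpha == 0:
            ev_t, ev_k, ev_f = _simulate_pure_birth(params, rng, t_max)
        else:
            ev_t, ev_k, ev_f = _simulate_general(params, rng, t_max)
    elif scheme == "fixed":
        if dt is None or dt <= 0:
            raise ValueError("fixed scheme requires a positive dt")
        ev_t, ev_k, ev_f = _simulate_fixed(params, rng, t_max, dt)
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    return Trajectory(
        params=params,
        t_max=t_max,
        event_times=ev_t,
        event_kinds=ev_k,
        f_path=ev_f,
        seed=seed,
    )


def _simulate_fixed(params: ModelParams, rng: np.random.Generator, t_max: float, dt: float):
    """Fixed-step binomial-thinning scheme.

    Within each step every intact subsystem fails with probability
    ``r (f + eps N) dt`` and every failed one is repaired with probability
    ``alpha dt``.  Unit events are spread at sorted uniform times within the
    step so the trajectory keeps strictly increasing event times.
    """
    N = int(round(params.N))
    f = int(round(params.f0))
    eps_n = params.epsilon * params.N
    p_rep = min(params.alpha * dt, 1.0)
    ev_t, ev_k, ev_f = [], [], []
    n_steps = int(np.ceil(t_max / dt))
    for step in range(n_steps):
        t0 = step * dt
        width = min(dt, t_max - t0)
        p_fail = min(params.r * (f + eps_n) * dt, 1.0)
        n_fail = rng.binomial(N - f, p_fail) if f < N else 0
        n_rep = rng.binomial(f, p_rep) if p_rep > 0 else 0
        n_ev = n_fail + n_rep
        if n_ev == 0:
            continue
        offsets = np.sort(rng.random(n_ev)) * width
        kinds = np.concatenate(
            [np.full(n_fail, EVENT_FAILURE, np.int8), np.full(n_rep, EVENT_REPAIR, np.int8)]
        )
        rng.shuffle(kinds)
        for off, kind in zip(offsets, kinds):
            f = min(N, f + 1) if kind == EVENT_FAILURE else max(0, f - 1)
            ev_t.append(t0 + off)
            ev_k.append(kind)
            ev_f.append(f)
    return (
        np.asarray(ev_t, dtype=float),
        np.asarray(ev_k, dtype=np.int8),
        np.asarray(ev_f, dtype=np.int64),
    )


def simulate_death(
    traj: Trajectory, scale: HazardScale, rng: np.random.Generator
) -> float | None:
    """Draw a death time from the trajectory's own hazard ``k f_i(t)/N``.

    The hazard is piecewise constant between events, so the draw is exact:
    the cumulative hazard is accumulated segment by segment against a
    unit-exponential threshold.  Returns ``None`` if no death occurs before
    the trajectory ends.  Deaths never feed back into the failure dynamics.
    """
    if scale.k == 0:
        return None
    starts, ends, values = traj.segments()
    rates = scale.k * values / traj.params.N
    seg_hazard = rates * (ends - starts)
    cum = np.concatenate([[0.0], np.cumsum(seg_hazard)])
    threshold = rng.standard_exponential()
    if threshold >= cum[-1]:
        return None
    i = int(np.searchsorted(cum, threshold, side="right")) - 1
    return float(starts[i] + (threshold - cum[i]) / rates[i])


@dataclass
class Cohort:
    """A reproducible collection of independently simulated individuals."""

    params: ModelParams
    scale: HazardScale | None
    trajectories: list[Trajectory] = field(repr=False)
    master_seed: object = None
    t_max: float = 150.0
    censor_mode: str = "ignore_deaths"

    @property
    def n(self) -> int:
        return len(self.trajectories)

    @property
    def death_times(self) -> np.ndarray:
        """Death ages with NaN for individuals alive at t_max."""
        return np.array(
            [np.nan if tr.death_time is None else tr.death_time for tr in self.trajectories]
        )


def simulate_cohort(
    params: ModelParams,
    scale: HazardScale | None,
    n: int,
    master_seed,
    t_max: float = 150.0,
    censor_mode: str = "ignore_deaths",
    scheme: str = "event",
    dt: float | None = None,
    sample_deaths: bool = True,
) -> Cohort:
    """Simulate ``n`` independent individuals with per-individual derived seeds.

    Seeds are spawned from ``master_seed`` via ``numpy.random.SeedSequence``,
    so cohorts are reproducible and order-independent.  Each individual's
    stream first drives its trajectory, then (if ``sample_deaths`` and a
    scale is given) its death draw.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if censor_mode not in ("ignore_deaths", "censor_at_death"):
        raise ValueError(f"unknown censor_mode {censor_mode!r}")
    ss = np.random.SeedSequence(master_seed)
    trajectories = []
    for child in ss.spawn(n):
        rng = np.random.default_rng(child)
        traj = simulate_trajectory(params, seed=child, t_max=t_max, rng=rng,
                                   scheme=scheme, dt=dt)
        if sample_deaths and scale is not None:
            traj.death_time = simulate_death(traj, scale, rng)
        trajectories.append(traj)
    return Cohort(
        params=params,
        scale=scale,
        trajectories=trajectories,
        master_seed=master_seed,
        t_max=t_max,
        censor_mode=censor_mode,
    )


def failed_count_matrix(cohort: Cohort, t_grid) -> np.ndarray:
    """Matrix of failed counts, shape (n individuals, n ages)."""
    t_arr = np.atleast_1d(np.asarray(t_grid, dtype=float))
    if np.any(t_arr < 0) or np.any(t_arr > cohort.t_max):
        raise ValueError("t_grid must lie within [0, t_max]")
    return np.vstack([tr.f_at(t_arr) for tr in cohort.trajectories])


def cohort_stats(
    cohort: Cohort,
    t_grid,
    censor_mode: str | None = None,
    quantiles: tuple[float, ...] = (0.25, 0.75),
) -> pd.DataFrame:
    """Cross-sectional statistics of f_i(t) at the given ages.

    ``ignore_deaths`` (default, the right-censoring-free convention) uses all
    trajectories at every age; ``censor_at_death`` drops individuals past
    their death age.  Variance is the unbiased (ddof=1) estimator.
    """
    if cohort.n == 0:
        raise ValueError("empty cohort")
    mode = censor_mode or cohort.censor_mode
    t_arr = np.atleast_1d(np.asarray(t_grid, dtype=float))
    M = failed_count_matrix(cohort, t_arr).astype(float)
    if mode == "censor_at_death":
        deaths = cohort.death_times[:, None]
        M[np.asarray(t_arr)[None, :] > deaths] = np.nan
    elif mode != "ignore_deaths":
        raise ValueError(f"unknown censor_mode {mode!r}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN ages
        data = {
            "t": t_arr,
            "n": np.sum(~np.isnan(M), axis=0),
            "mean": np.nanmean(M, axis=0),
            "median": np.nanmedian(M, axis=0),
            "var": np.nanvar(M, axis=0, ddof=1),
            "std": np.nanstd(M, axis=0, ddof=1),
        }
        for q in quantiles:
            data[f"q{int(round(q * 100)):02d}"] = np.nanquantile(M, q, axis=0)
    return pd.DataFrame(data)


def biological_age(params: ModelParams, f) -> np.ndarray | float:
    """Project a failed count onto the mean trajectory: the age t* with F(t*) = f.

    Inverse of the logistic mean,
    ``BA(f) = ln( f (N - f0) / (f0 (N - f)) ) / (rN)``; BA(f0) = 0 and
    BA(N/2) = tau.  Individuals whose failed count runs ahead of the
    population mean are biologically older than their chronological age.
    """
    f_arr = np.asarray(f, dtype=float)
    lo = params.f0 * (1 - 1e-12)  # tolerate roundoff at the lower edge
    if np.any(f_arr < lo) or np.any(f_arr >= params.N):
        raise ValueError("biological age is defined for f0 <= f < N")
    out = np.log(f_arr * (params.N - params.f0) / (params.f0 * (params.N - f_arr))) / params.b
    return out if f_arr.ndim else float(out)
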