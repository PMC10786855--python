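"""CSV/JSON readers and writers and the synthetic lifespan-fixture generator.

All files are plain-text, UTF-8, comma-delimited with headers:

* lifespan CSV: one column ``age_at_death`` (fractional years)
* life-table CSV: ``age_lo,age_hi,deaths,exposure``
* trajectory CSV (long): ``traj_id,t,f,event`` with an ``init`` row at t=0
* deaths CSV: ``traj_id,death_age``
* distribution CSV (long): ``t,f,P``
* mean-field curve CSV: ``t,F,mu,S,p``
* Gompertz fit JSON: ``{R0, b, rmse_log, window, n_bins_used}``

Every writer can drop a ``<name>.meta.json`` sidecar echoing the resolved
parameters and seeds so a run is reproducible from its outputs alone.

The fixture generator emulates a national lifespan register (one age at
death per person) by sampling from the model's own hazard, either by exact
inverse-CDF sampling of the analytic lifespan distribution (mode
``analytic``) or from fully stochastic cohorts with death events (mode
``stochastic``).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .calibration import GompertzFit, LifeTable
from .params import HazardScale, ModelParams
from .stochastic import EVENT_REPAIR, Cohort, simulate_cohort

__all__ = [
    "read_lifespans",
    "write_lifespans",
    "read_life_table",
    "write_life_table",
    "write_trajectories",
    "read_trajectories",
    "write_deaths",
    "write_distribution",
    "write_curves",
    "write_fit_json",
    "read_fit_json",
    "write_meta",
    "sample_lifespans_analytic",
    "generate_fixture_cohort",
]

_FLOAT_FMT = "%.12g"


def _read_csv(path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}; header must contain {required}")
    for col in required:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            row = int(np.argmax(bad.to_numpy())) + 2  # 1-based + header line
            raise ValueError(f"{path}: non-numeric value in column {col!r} at line {row}")
        if df[col].isna().any():
            row = int(np.argmax(df[col].isna().to_numpy())) + 2
            raise ValueError(f"{path}: empty cell in column {col!r} at line {row}")
    return df


def read_lifespans(path) -> np.ndarray:
    """Read a single-column ``age_at_death`` CSV into an array of ages (years)."""
    df = _read_csv(path, ["age_at_death"])
    ages = df["age_at_death"].to_numpy(dtype=float)
    if np.any(ages < 0):
        row = int(np.argmax(ages < 0)) + 2
        raise ValueError(f"{path}: negative age at death at line {row}")
    return ages


def write_lifespans(path, ages) -> None:
    pd.DataFrame({"age_at_death": np.asarray(ages, dtype=float)}).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def read_life_table(path) -> LifeTable:
    df = _read_csv(path, ["age_lo", "age_hi", "deaths", "exposure"])
    return LifeTable(
        age_lo=df["age_lo"].to_numpy(float),
        age_hi=df["age_hi"].to_numpy(float),
        deaths=df["deaths"].to_numpy(float),
        exposure=df["exposure"].to_numpy(float),
    )


def write_life_table(path, table: LifeTable) -> None:
    table.to_frame().drop(columns="hazard").to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_trajectories(path, cohort: Cohort) -> None:
    """Long-format event log; each trajectory starts with an ``init`` row."""
    rows = []
    for tid, tr in enumerate(cohort.trajectories):
        rows.append((tid, 0.0, tr.f0, "init"))
        for t, f, kind in zip(tr.event_times, tr.f_path, tr.event_kinds):
            rows.append((tid, t, f, "repair" if kind == EVENT_REPAIR else "failure"))
    pd.DataFrame(rows, columns=["traj_id", "t", "f", "event"]).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def read_trajectories(path) -> pd.DataFrame:
    df = _read_csv(path, ["traj_id", "t", "f"])
    if "event" not in df.columns:
        raise ValueError(f"{path}: missing column(s) ['event']")
    return df


def write_deaths(path, cohort: Cohort) -> None:
    dead = [
        (tid, tr.death_time)
        for tid, tr in enumerate(cohort.trajectories)
        if tr.death_time is not None
    ]
    pd.DataFrame(dead, columns=["traj_id", "death_age"]).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def write_distribution(path, dist) -> None:
    nt, ns = dist.P.shape
    df = pd.DataFrame(
        {
            "t": np.repeat(dist.t_grid, ns),
            "f": np.tile(dist.f_support, nt),
            "P": dist.P.ravel(),
        }
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_curves(path, t, F, mu, S, p) -> None:
    pd.DataFrame({"t": t, "F": F, "mu": mu, "S": S, "p": p}).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def write_fit_json(path, fit: GompertzFit) -> None:
    payload = {
        "R0": fit.r0,
        "b": fit.b,
        "rmse_log": fit.rmse_log,
        "window": list(fit.fit_window),
        "n_bins_used": fit.n_bins_used,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")


def read_fit_json(path) -> GompertzFit:
    d = json.loads(Path(path).read_text(encoding="utf-8"))
    return GompertzFit(
        r0=d["R0"],
        b=d["b"],
        fit_window=tuple(d["window"]),
        rmse_log=d["rmse_log"],
        n_bins_used=d["n_bins_used"],
    )


def write_meta(path, **fields) -> None:
    """Reproducibility sidecar: resolved parameters, seeds and package version."""
    payload = {"micc_version": __version__, **fields}
    Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n", encoding="utf-8")


def sample_lifespans_analytic(
    params: ModelParams, scale: HazardScale, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Exact inverse-CDF draws from the analytic lifespan distribution.

    The cumulative hazard (k/b) ln((f0 e^{bt} + N - f0)/N) is inverted in
    closed form against unit-exponential thresholds E:

        t = ln( (N exp(bE/k) - (N - f0)) / f0 ) / b
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if scale.k <= 0:
        raise ValueError("analytic sampling requires k > 0")
    E = rng.standard_exponential(n)
    b, N, f0 = params.b, params.N, params.f0
    return np.log((N * np.exp(b * E / scale.k) - (N - f0)) / f0) / b


def generate_fixture_cohort(
    params: ModelParams,
    scale: HazardScale,
    n: int,
    seed: int,
    out_dir,
    mode: str = "analytic",
    t_max: float = 150.0,
) -> dict[str, Path]:
    """Write a synthetic lifespan fixture emulating register data.

    Mode ``analytic``: n exact draws from the analytic lifespan density
    (no trajectories).  Mode ``stochastic``: a full event-driven cohort with
    death events; individuals alive at ``t_max`` are censored (excluded from
    the lifespan file, counted in the sidecar).  Deterministic: the same seed
    yields byte-identical files.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "lifespans": out_dir / "lifespans.csv",
        "meta": out_dir / "lifespans.meta.json",
    }
    meta = {
        "mode": mode,
        "n": n,
        "seed": seed,
        "params": vars(params).copy(),
        "k": scale.k,
    }
    if mode == "analytic":
        rng = np.random.default_rng(seed)
        ages = sample_lifespans_analytic(params, scale, n, rng)
        write_lifespans(paths["lifespans"], ages)
    elif mode == "stochastic":
        cohort = simulate_cohort(params, scale, n=n, master_seed=seed, t_max=t_max)
        ages = cohort.death_times
        censored = int(np.isnan(ages).sum())
        write_lifespans(paths["lifespans"], ages[~np.isnan(ages)])
        paths["trajectories"] = out_dir / "trajectories.csv"
        paths["deaths"] = out_dir / "deaths.csv"
        write_trajectories(paths["trajectories"], cohort)
        write_deaths(paths["deaths"], cohort)
        meta.update(t_max=t_max, censored=censored)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    write_meta(paths["meta"], **meta)
    return paths
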