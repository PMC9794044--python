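"""The three simulation studies as reproducible parameter sweeps, plus
equilibrium summary statistics.

* **validation** — well-mixed populations, cost swept over
  {14, 12, 10, 8, 6.67, 6.5} at benefit 6; evolved hawk frequencies
  should match the analytic ``b/c`` whenever ``b/c <= 0.9``.
* **group-size** — structured populations, no dispersal, cost in
  {6, 8, 12} and maximum group size in {12, 16, 20, 30, 40, 50, 60,
  70, 80}; small groups suppress hawks far below ``b/c``.
* **dispersal** — structured populations at b=6, c=8 with natal
  dispersal swept 0.0..1.0; rising dispersal dissolves the group
  effect and hawk frequencies approach ``b/c = 0.75``.

Default scales are desk-sized (N_0=600, N_max=2500, 5e4 steps, see
``DESK_*`` constants); ``full=True`` restores the original scale
(N_0=2400, N_max=10000, 1e7 steps, 10 replicates).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .engine import SimulationConfig, TimeSeries, run
from .game import GameParams, ess_hawk_frequency

__all__ = [
    "SweepSpec",
    "SummaryStats",
    "equilibrium_hawk_frequency",
    "run_sweep",
    "summarize_sweep",
    "run_validation_sweep",
    "run_group_size_sweep",
    "run_dispersal_sweep",
    "VALIDATION_COSTS",
    "GROUP_SIZE_COSTS",
    "GROUP_SIZE_GSMAX",
    "DISPERSAL_RATES",
]

VALIDATION_COSTS = (14.0, 12.0, 10.0, 8.0, 6.67, 6.5)
GROUP_SIZE_COSTS = (6.0, 8.0, 12.0)
GROUP_SIZE_GSMAX = (12, 16, 20, 30, 40, 50, 60, 70, 80)
DISPERSAL_RATES = tuple(round(0.1 * i, 1) for i in range(11))

DESK_N0 = 600
DESK_NMAX = 2500
DESK_STEPS = 50_000
DESK_REPLICATES = 5

FULL_N0 = 2400
FULL_NMAX = 10_000
FULL_STEPS = 10_000_000
FULL_REPLICATES = 10

DEFAULT_BURN_IN = 0.5


@dataclass
class SweepSpec:
    """One parameter sweep: a base config, the swept field(s), the
    values, and the replicate count."""

    base: SimulationConfig
    param: str | tuple[str, ...]
    values: list = field(default_factory=list)
    n_replicates: int = 10
    burn_in_fraction: float = DEFAULT_BURN_IN

    def __post_init__(self) -> None:
        if isinstance(self.param, str):
            self.param = (self.param,)
        else:
            self.param = tuple(self.param)
        cfg_fields = self.base.to_dict()
        for name in self.param:
            if name not in cfg_fields:
                raise ValueError(f"unknown config field {name!r}")
        if not self.values:
            raise ValueError("swept values must be non-empty")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    def cells(self) -> list[dict]:
        out = []
        for v in self.values:
            vals = (v,) if len(self.param) == 1 else tuple(v)
            out.append(dict(zip(self.param, vals)))
        return out


@dataclass(frozen=True)
class SummaryStats:
    """Aggregate over replicates of one sweep cell."""

    value: tuple
    mean_p_hat: float
    sd_p_hat: float
    extinction_fraction: float
    predicted_bc: float
    n_replicates: int


def equilibrium_hawk_frequency(
    series: TimeSeries, burn_in_fraction: float = DEFAULT_BURN_IN
) -> float | None:
    """Mean recorded hawk frequency after the burn-in window.

    The first ``floor(burn_in_fraction * len(series))`` records are
    discarded. A run that went extinct has no equilibrium: returns
    ``None`` (extinct replicates are reported via the extinction
    fraction instead).
    """
    if len(series) == 0:
        raise ValueError("empty time series")
    if not 0.0 <= burn_in_fraction < 1.0:
        raise ValueError(
            f"burn_in_fraction must lie in [0, 1), got {burn_in_fraction}"
        )
    if series.extinct:
        return None
    freqs = [r.hawk_frequency for r in series.records]
    k = math.floor(burn_in_fraction * len(freqs))
    window = freqs[k:]
    return float(np.mean(window))


def _replicate_seeds(root_seed: int, n: int) -> list[int]:
    """Independent, reproducible per-run seeds derived from one root."""
    children = np.random.SeedSequence(root_seed).spawn(n)
    return [int(c.generate_state(1, np.uint64)[0]) for c in children]


def run_sweep(spec: SweepSpec, *, progress: bool = False) -> pd.DataFrame:
    """Run every (cell, replicate) and return the per-replicate table.

    Columns: ``swept_param, value, replicate, seed, p_hat, extinct,
    predicted_bc`` plus one column per swept field. ``p_hat`` is NaN
    for extinct replicates.
    """
    cells = spec.cells()
    seeds = _replicate_seeds(
        spec.base.seed, len(cells) * spec.n_replicates
    )
    jobs = [
        (cell, rep)
        for cell in cells
        for rep in range(spec.n_replicates)
    ]
    if progress:
        from tqdm import tqdm

        jobs = tqdm(jobs, unit="run")
    rows = []
    for i, (cell, rep) in enumerate(jobs):
        cfg = spec.base.replace(**cell, seed=seeds[i])
        series = run(cfg)
        p_hat = equilibrium_hawk_frequency(series, spec.burn_in_fraction)
        row = {
            "swept_param": ",".join(spec.param),
            "value": ",".join(str(cell[p]) for p in spec.param),
            "replicate": rep,
            "seed": seeds[i],
            "p_hat": float("nan") if p_hat is None else p_hat,
            "extinct": series.extinct,
            "predicted_bc": ess_hawk_frequency(
                GameParams(benefit=cfg.b, cost=cfg.c)
            ),
        }
        row.update(cell)
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_sweep(df: pd.DataFrame) -> pd.DataFrame:
    """Aggregate a per-replicate table: mean/SD of ``p_hat`` over
    surviving replicates plus the extinction fraction per cell."""
    def _agg(g: pd.DataFrame) -> pd.Series:
        alive = g.loc[~g["extinct"], "p_hat"]
        return pd.Series(
            {
                "mean_p_hat": alive.mean() if len(alive) else float("nan"),
                "sd_p_hat": alive.std(ddof=1)
                if len(alive) > 1
                else float("nan"),
                "extinction_fraction": g["extinct"].mean(),
                "predicted_bc": g["predicted_bc"].iloc[0],
                "n_replicates": len(g),
            }
        )

    swept_cols = [c for c in df.columns if c in df["swept_param"].iloc[0].split(",")]
    out = (
        df.groupby(swept_cols, sort=False)
        .apply(_agg, include_groups=False)
        .reset_index()
    )
    out["n_replicates"] = out["n_replicates"].astype(int)
    return out


def _scaled_base(full: bool, **overrides) -> SimulationConfig:
    if full:
        base = SimulationConfig(
            N_0=FULL_N0, N_max=FULL_NMAX, n_steps=FULL_STEPS
        )
    else:
        base = SimulationConfig(
            N_0=DESK_N0, N_max=DESK_NMAX, n_steps=DESK_STEPS
        )
    return base.replace(**overrides)


def run_validation_sweep(
    *,
    n_replicates: int | None = None,
    seed: int = 0,
    full: bool = False,
    costs: tuple[float, ...] = VALIDATION_COSTS,
    burn_in_fraction: float = DEFAULT_BURN_IN,
    progress: bool = False,
    **overrides,
) -> pd.DataFrame:
    """Well-mixed cost sweep (study 1): b=6, c over ``costs``."""
    if n_replicates is None:
        n_replicates = FULL_REPLICATES if full else DESK_REPLICATES
    base = _scaled_base(full, structured=False, b=6.0, seed=seed, **overrides)
    spec = SweepSpec(
        base=base,
        param="c",
        values=list(costs),
        n_replicates=n_replicates,
        burn_in_fraction=burn_in_fraction,
    )
    return run_sweep(spec, progress=progress)


def run_group_size_sweep(
    *,
    n_replicates: int | None = None,
    seed: int = 0,
    full: bool = False,
    costs: tuple[float, ...] = GROUP_SIZE_COSTS,
    gs_max_values: tuple[int, ...] = GROUP_SIZE_GSMAX,
    burn_in_fraction: float = DEFAULT_BURN_IN,
    progress: bool = False,
    **overrides,
) -> pd.DataFrame:
    """Structured (c, GS_max) grid sweep at d=0 (study 2)."""
    if n_replicates is None:
        n_replicates = FULL_REPLICATES if full else DESK_REPLICATES
    base = _scaled_base(
        full, structured=True, b=6.0, d=0.0, seed=seed, **overrides
    )
    spec = SweepSpec(
        base=base,
        param=("c", "GS_max"),
        values=[(c, g) for c in costs for g in gs_max_values],
        n_replicates=n_replicates,
        burn_in_fraction=burn_in_fraction,
    )
    return run_sweep(spec, progress=progress)


def run_dispersal_sweep(
    *,
    n_replicates: int | None = None,
    seed: int = 0,
    full: bool = False,
    dispersal_rates: tuple[float, ...] = DISPERSAL_RATES,
    gs_max_values: tuple[int, ...] = GROUP_SIZE_GSMAX,
    burn_in_fraction: float = DEFAULT_BURN_IN,
    progress: bool = False,
    **overrides,
) -> pd.DataFrame:
    """Structured (GS_max, d) grid sweep at b=6, c=8 (study 3)."""
    if n_replicates is None:
        n_replicates = FULL_REPLICATES if full else DESK_REPLICATES
    base = _scaled_base(
        full, structured=True, b=6.0, c=8.0, seed=seed, **overrides
    )
    spec = SweepSpec(
        base=base,
        param=("GS_max", "d"),
        values=[(g, d) for g in gs_max_values for d in dispersal_rates],
        n_replicates=n_replicates,
        burn_in_fraction=burn_in_fraction,
    )
    return run_sweep(spec, progress=progress)
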