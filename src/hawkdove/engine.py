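"""Per-time-step scheduler: games, reproduction, mortality, group
maintenance, recording.

Each step runs four phases in a fixed, documented order:

1. **Games** — within every group the members are randomly permuted and
   paired sequentially; each pair plays one contest and both payoffs
   accrue to the agents' resources. With an odd group size one agent
   sits out; singletons play nothing. In well-mixed mode
   (``structured=False``) the pairing runs over the whole population.
   Every agent plays at most one game per step by construction.
2. **Reproduction** — all agents at or above the threshold ``T``
   attempt reproduction in randomized order (so the capacity cap does
   not systematically favour anyone); each pays ``T`` and the offspring
   enters only while the population is below ``N_max``.
3. **Aging/mortality** — pre-existing agents age by one step and die
   once ``age >= lifespan``. Newborns of the current step neither play
   nor age.
4. **Group maintenance** (structured mode only) — fission/fusion until
   all group sizes are within bounds.

This ordering is a modelling choice, pinned here and covered by tests;
mortality is lifespan-only (resources never kill, they may go
negative).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields, replace
from functools import cached_property
from typing import Iterator

import numpy as np

from . import _kernels
from .game import GameParams
from .population import (
    DemographyParams,
    Population,
    draw_lifespans,
    maintain_groups,
)

__all__ = [
    "SimulationConfig",
    "InitialConditions",
    "TimeSeriesRecord",
    "TimeSeries",
    "ExtinctPopulationError",
    "initialize_population",
    "step",
    "run",
]

logger = logging.getLogger("hawkdove")

TIME_SERIES_COLUMNS = (
    "step",
    "n_agents",
    "n_hawks",
    "hawk_frequency",
    "n_groups",
    "mean_group_size",
    "extinct",
)

_FLOAT_FIELDS = ("b", "c", "T", "L", "L_SD", "m_r", "d", "hawk_fraction_0")
_INT_FIELDS = (
    "GS_min",
    "GS_max",
    "N_max",
    "N_0",
    "n_steps",
    "seed",
    "record_every",
)
_BOOL_FIELDS = ("structured", "fuse_at_or_below", "dispersal_excludes_natal")


class ExtinctPopulationError(RuntimeError):
    """Raised when stepping a population with no agents left."""


@dataclass(frozen=True)
class SimulationConfig:
    """Flat run configuration (game + demography + engine controls).

    Field names mirror the model's parameter table (``b``, ``c``,
    ``T``, ``L``, ``L_SD``, ``m_r``, ``d``, ``GS_min``, ``GS_max``,
    ``N_max``, ``N_0``) so a config file doubles as documentation;
    defaults are the fixed values used across all experiments.
    ``structured=False`` runs the well-mixed validation mode: a single
    unbounded group with no fission/fusion and no dispersal.
    """

    b: float = 6.0
    c: float = 8.0
    T: float = 30.0
    L: float = 150.0
    L_SD: float = 15.0
    m_r: float = 0.01
    d: float = 0.0
    GS_min: int = 3
    GS_max: int = 12
    N_max: int = 10_000
    N_0: int = 2400
    hawk_fraction_0: float = 0.5
    structured: bool = True
    n_steps: int = 10_000
    seed: int = 0
    record_every: int = 100
    fuse_at_or_below: bool = True
    dispersal_excludes_natal: bool = True

    def __post_init__(self) -> None:
        for name in _FLOAT_FIELDS:
            object.__setattr__(self, name, float(getattr(self, name)))
        for name in _INT_FIELDS:
            val = getattr(self, name)
            if val != int(val):
                raise ValueError(f"{name} must be an integer, got {val!r}")
            object.__setattr__(self, name, int(val))
        for name in _BOOL_FIELDS:
            object.__setattr__(self, name, bool(getattr(self, name)))
        # delegate range checks so errors carry the field names
        self.game
        self.demography
        if self.n_steps < 1:
            raise ValueError(f"n_steps must be >= 1, got {self.n_steps}")
        if self.record_every < 1:
            raise ValueError(
                f"record_every must be >= 1, got {self.record_every}"
            )
        if not 0.0 <= self.hawk_fraction_0 <= 1.0:
            raise ValueError(
                f"hawk_fraction_0 must lie in [0, 1], "
                f"got {self.hawk_fraction_0}"
            )
        if self.N_0 < 1:
            raise ValueError(f"N_0 must be >= 1, got {self.N_0}")
        if self.N_max < self.N_0:
            raise ValueError(
                f"N_max ({self.N_max}) must be >= N_0 ({self.N_0})"
            )

    @cached_property
    def game(self) -> GameParams:
        return GameParams(benefit=self.b, cost=self.c)

    @cached_property
    def demography(self) -> DemographyParams:
        return DemographyParams(
            T=self.T,
            L=self.L,
            L_SD=self.L_SD,
            m_r=self.m_r,
            d=self.d,
            GS_max=self.GS_max,
            GS_min=self.GS_min,
            fuse_at_or_below=self.fuse_at_or_below,
            dispersal_excludes_natal=self.dispersal_excludes_natal,
        )

    @property
    def initial(self) -> "InitialConditions":
        if self.structured:
            size0 = max(1, self.GS_max // 2)
            n_groups = max(1, self.N_0 // size0)
        else:
            n_groups = 1
        return InitialConditions(
            N_0=self.N_0,
            hawk_fraction_0=self.hawk_fraction_0,
            GS_0=n_groups,
            R_0=0.0,
        )

    def replace(self, **changes) -> "SimulationConfig":
        return replace(self, **changes)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass(frozen=True)
class InitialConditions:
    """Derived view of the starting state of a run."""

    N_0: int
    hawk_fraction_0: float
    GS_0: int  # number of groups at step 0
    R_0: float


@dataclass(frozen=True)
class TimeSeriesRecord:
    step: int
    n_agents: int
    n_hawks: int
    hawk_frequency: float
    n_groups: int
    mean_group_size: float
    extinct: bool


class TimeSeries:
    """Recorded trajectory of one run."""

    def __init__(
        self,
        records: list[TimeSeriesRecord],
        config: SimulationConfig | None = None,
    ) -> None:
        self.records = list(records)
        self.config = config
        self._df = None

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[TimeSeriesRecord]:
        return iter(self.records)

    @property
    def extinct(self) -> bool:
        return bool(self.records) and self.records[-1].extinct

    @property
    def dataframe(self):
        import pandas as pd

        if self._df is None:
            self._df = pd.DataFrame(
                [
                    {c: getattr(r, c) for c in TIME_SERIES_COLUMNS}
                    for r in self.records
                ],
                columns=list(TIME_SERIES_COLUMNS),
            )
        return self._df

    def to_csv(self, path) -> None:
        self.dataframe.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TimeSeries":
        import pandas as pd

        df = pd.read_csv(path)
        missing = set(TIME_SERIES_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"time-series CSV missing columns: {missing}")
        records = [
            TimeSeriesRecord(
                step=int(row.step),
                n_agents=int(row.n_agents),
                n_hawks=int(row.n_hawks),
                hawk_frequency=float(row.hawk_frequency),
                n_groups=int(row.n_groups),
                mean_group_size=float(row.mean_group_size),
                extinct=bool(row.extinct),
            )
            for row in df.itertuples()
        ]
        return cls(records)


# -- initialisation ----------------------------------------------------


def initialize_population(
    config: SimulationConfig, rng: np.random.Generator
) -> Population:
    """Starting population.

    Structured mode: ``N_0 // (GS_max // 2)`` groups of size
    ``GS_max // 2`` (the last group absorbs any remainder), each half
    hawks. Well-mixed mode: one group of ``N_0`` agents at the initial
    hawk fraction. Everyone starts with zero resources, a uniform
    random integer age in ``[0, L]`` and a fresh lifespan draw.
    """
    n0 = config.N_0
    n_hawks = round(config.hawk_fraction_0 * n0)
    if config.structured:
        size0 = config.GS_max // 2
        if size0 < 1:
            raise ValueError("GS_max too small to form initial groups")
        n_groups = n0 // size0
        if n_groups < 1:
            n_groups = 1
        sizes = np.full(n_groups, size0, dtype=np.int64)
        sizes[-1] += n0 - int(sizes.sum())
    else:
        n_groups = 1
        sizes = np.array([n0], dtype=np.int64)

    # per-group hawk counts: even split, leftovers round-robin
    hawks_per_group = sizes // 2 if config.hawk_fraction_0 == 0.5 else (
        np.floor(config.hawk_fraction_0 * sizes).astype(np.int64)
    )
    left = n_hawks - int(hawks_per_group.sum())
    g = 0
    while left > 0:
        if hawks_per_group[g] < sizes[g]:
            hawks_per_group[g] += 1
            left -= 1
        g = (g + 1) % n_groups
    while left < 0:
        if hawks_per_group[g] > 0:
            hawks_per_group[g] -= 1
            left += 1
        g = (g + 1) % n_groups

    strategy = np.zeros(n0, dtype=np.uint8)
    group_id = np.repeat(np.arange(n_groups, dtype=np.int64), sizes)
    offset = 0
    for k in range(n_groups):
        strategy[offset: offset + int(hawks_per_group[k])] = 1
        offset += int(sizes[k])

    age = rng.integers(0, int(config.L) + 1, size=n0).astype(np.int64)
    lifespan = draw_lifespans(n0, config.L, config.L_SD, rng)
    return Population(
        strategy=strategy,
        resources=np.zeros(n0, dtype=np.float64),
        age=age,
        lifespan=lifespan,
        group_id=group_id,
        capacity=config.N_max,
    )


# -- game phase --------------------------------------------------------


def _pair_agents(
    pop: Population, structured: bool, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Random within-group pairing.

    Returns ``(idx, partner, playable)``: row indices in random order,
    their partners' row indices, and a mask of agents that actually
    play (everyone except the odd agent out of each odd-sized group).
    Each agent occurs exactly once in ``idx``, so applying payoffs over
    ``idx[playable]`` gives every agent at most one game per step.
    """
    n = pop.n
    if n == 0:
        e = np.empty(0, dtype=np.int64)
        return e, e, np.empty(0, dtype=bool)
    if structured:
        # grouped-by-group, random-within-group order in one quicksort:
        # high bits = group id, low 32 bits = random tiebreaker (group
        # ids stay far below 2**31 at any reachable scale)
        key = (pop.group_id << 32) | rng.integers(
            0, 1 << 32, n, dtype=np.int64
        )
        idx = np.argsort(key)
        gs = pop.group_id[idx]
        starts = np.flatnonzero(np.r_[True, gs[1:] != gs[:-1]])
        sizes = np.diff(np.append(starts, n))
        start_rep = np.repeat(starts, sizes)
        size_rep = np.repeat(sizes, sizes)
        pos = np.arange(n) - start_rep
        playable = pos < (size_rep & ~1)
        mate = np.where(playable, pos ^ 1, pos)
        partner = idx[start_rep + mate]
    else:
        idx = rng.permutation(n)
        pos = np.arange(n)
        playable = pos < (n & ~1)
        mate = np.where(playable, pos ^ 1, pos)
        partner = idx[mate]
    return idx, partner, playable


def _apply_payoffs_numpy(
    pop: Population,
    idx: np.ndarray,
    partner: np.ndarray,
    playable: np.ndarray,
    b: float,
    c: float,
) -> None:
    s = pop.strategy[idx] == 1
    o = pop.strategy[partner] == 1
    pay = np.where(
        s,
        np.where(o, 0.5 * (b - c), b),
        np.where(o, 0.0, 0.5 * b),
    )
    pop.resources[idx[playable]] += pay[playable]


def _play_games(
    pop: Population,
    game: GameParams,
    structured: bool,
    rng: np.random.Generator,
) -> None:
    n = pop.n
    if n < 2:
        return
    b, c = game.benefit, game.cost
    if _kernels.ENABLED:
        # same grouped+randomized order as _pair_agents, but the
        # pairing and payoff accrual run in one compiled pass
        if structured:
            key = (pop.group_id << 32) | rng.integers(
                0, 1 << 32, n, dtype=np.int64
            )
            idx = np.argsort(key)
            gs = pop.group_id[idx]
        else:
            idx = rng.permutation(n)
            gs = np.zeros(n, dtype=np.int64)
        _kernels.pair_and_pay(idx, gs, pop.strategy, pop.resources, b, c)
        return
    idx, partner, playable = _pair_agents(pop, structured, rng)
    if idx.size == 0:
        return
    _apply_payoffs_numpy(pop, idx, partner, playable, b, c)


# -- reproduction phase ------------------------------------------------


def _reproduce(
    pop: Population,
    dem: DemographyParams,
    structured: bool,
    rng: np.random.Generator,
) -> tuple[int, int, np.ndarray]:
    """Bulk reproduction; returns (#placed, #rejected, newborn group ids).

    Exactly equivalent to running the per-agent operator over all
    eligible agents in a random order: each pays ``T``, and the first
    ``N_max - n`` in that order place an offspring.
    """
    no_births = np.empty(0, dtype=np.int64)
    eligible = np.flatnonzero(pop.resources >= dem.T)
    if eligible.size == 0:
        return 0, 0, no_births
    eligible = eligible[rng.permutation(eligible.size)]
    pop.resources[eligible] -= dem.T
    slots = max(0, pop.capacity - pop.n)
    placed = eligible[:slots]
    k = placed.size
    rejected = eligible.size - k
    if k == 0:
        return 0, rejected, no_births
    strat = pop.strategy[placed].copy()
    flip = rng.random(k) < dem.m_r
    strat[flip] ^= 1
    life = draw_lifespans(k, dem.L, dem.L_SD, rng)
    gid = pop.group_id[placed].copy()
    if structured and dem.d > 0.0:
        active = np.unique(pop.group_id)
        n_groups = active.size
        if n_groups > 1:
            disp = np.flatnonzero(rng.random(k) < dem.d)
            if disp.size:
                if dem.dispersal_excludes_natal:
                    natal_pos = np.searchsorted(active, gid[disp])
                    r = rng.integers(0, n_groups - 1, size=disp.size)
                    r += r >= natal_pos
                    gid[disp] = active[r]
                else:
                    gid[disp] = active[
                        rng.integers(0, n_groups, size=disp.size)
                    ]
    pop.add_agents(strat, life, gid)
    return k, rejected, gid


# -- step / run --------------------------------------------------------


def _record(pop: Population, structured: bool) -> TimeSeriesRecord:
    n = pop.n
    if n == 0:
        return TimeSeriesRecord(
            step=pop.step_count,
            n_agents=0,
            n_hawks=0,
            hawk_frequency=float("nan"),
            n_groups=0,
            mean_group_size=0.0,
            extinct=True,
        )
    n_hawks = pop.n_hawks
    n_groups = pop.n_groups if structured else 1
    return TimeSeriesRecord(
        step=pop.step_count,
        n_agents=n,
        n_hawks=n_hawks,
        hawk_frequency=n_hawks / n,
        n_groups=n_groups,
        mean_group_size=n / n_groups,
        extinct=False,
    )


def step(
    population: Population,
    config: SimulationConfig,
    rng: np.random.Generator,
    *,
    collect: bool = True,
) -> TimeSeriesRecord | None:
    """Advance the population by one time step.

    Raises :class:`ExtinctPopulationError` if called on an extinct
    population. Returns the per-step record, or None when ``collect``
    is False (the engine's fast path between recording points).
    """
    if population.n == 0:
        raise ExtinctPopulationError("cannot step an extinct population")
    dem = config.demography
    _play_games(population, config.game, config.structured, rng)
    n_before = population.n
    _, _, birth_gids = _reproduce(population, dem, config.structured, rng)
    # aging applies to pre-existing agents only; newborns sit at the
    # end of the arrays and stay at age 0 until the next step
    population.age[:n_before] += 1
    dead = population.age >= population.lifespan
    if dead.any():
        death_gids = population.group_id[dead]
        population.remove(dead, groups_unchanged=True)
    else:
        death_gids = birth_gids[:0]
    if config.structured and population.n > 0:
        # only groups that gained or lost members can newly violate
        # the size bounds
        population._registry_apply_deltas(birth_gids, death_gids)
        maintain_groups(
            population,
            dem,
            rng,
            candidates=np.concatenate([birth_gids, death_gids]),
        )
    population.step_count += 1
    if collect or population.n == 0:
        return _record(population, config.structured)
    return None


def run(config: SimulationConfig, *, progress: bool = False) -> TimeSeries:
    """Run a full trajectory from the config's seed.

    Records the initial state, every ``record_every``-th step, the
    final step, and the extinction step if the population dies out
    (the run stops there). Identical config (including seed) gives a
    bit-identical series.
    """
    rng = np.random.default_rng(config.seed)
    pop = initialize_population(config, rng)
    records = [_record(pop, config.structured)]
    steps_iter = range(1, config.n_steps + 1)
    if progress:
        from tqdm import tqdm

        steps_iter = tqdm(steps_iter, unit="step")
    for t in steps_iter:
        collect = (t % config.record_every == 0) or (t == config.n_steps)
        rec = step(pop, config, rng, collect=collect)
        if pop.n == 0:
            logger.info("population extinct at step %d", t)
            records.append(rec if rec is not None else _record(pop, True))
            break
        if rec is not None:
            records.append(rec)
    return TimeSeries(records, config=config)
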