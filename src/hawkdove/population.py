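"""Agents, groups, and the demographic operators.

The population is stored column-wise in NumPy arrays (one row per
living agent) so that the per-step engine can run vectorised over tens
of thousands of agents; :class:`Agent` and :class:`Group` are thin
proxies over those arrays for the per-agent operators and for tests.

Demographic rules implemented here:

* lifespans are Gaussian draws rounded to the nearest integer
  (clamped at 1 so the contract is total);
* an agent reproduces once its accumulated resources reach the
  threshold ``T``; it pays ``T`` whether or not the offspring enters
  the population (a Moran-like cap: births fail once the population
  is at capacity);
* offspring inherit the parental pure strategy, flipped with
  probability ``m_r``, and join the natal group or — with probability
  ``d`` — a uniformly chosen *other* group (natal dispersal);
* groups that reach ``GS_max`` members fission into two random halves;
  groups that fall below ``GS_min`` fuse into a uniformly chosen other
  group.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np

__all__ = [
    "DemographyParams",
    "Agent",
    "Group",
    "Population",
    "ReproductionOutcome",
    "draw_lifespan",
    "draw_lifespans",
    "attempt_reproduction",
    "place_offspring",
    "fission_group",
    "fuse_group",
    "maintain_groups",
]

HAWK = 1
DOVE = 0


@dataclass(frozen=True)
class DemographyParams:
    """Reproduction, lifespan, dispersal and group-size parameters.

    Defaults are the fixed values used across all experiments:
    reproduction threshold ``T=30``, mean lifespan ``L=150`` with SD
    ``L_SD=15``, mutation rate ``m_r=0.01``, dispersal ``d=0``,
    group-size bounds ``GS_min=3`` / ``GS_max=12``.
    """

    T: float = 30.0
    L: float = 150.0
    L_SD: float = 15.0
    m_r: float = 0.01
    d: float = 0.0
    GS_max: int = 12
    GS_min: int = 3
    # A group of GS_min members (or fewer) fuses into another group;
    # set False for the stricter "fuse only below GS_min" trigger.
    # The default reproduces the published group-size suppression
    # levels (~10-12% hawks at GS_max=12, c=2b).
    fuse_at_or_below: bool = True
    # Dispersing offspring pick uniformly among groups *other* than the
    # natal one; set False to let them draw from all groups instead.
    dispersal_excludes_natal: bool = True

    def __post_init__(self) -> None:
        for name in ("T", "L", "L_SD", "m_r", "d"):
            object.__setattr__(self, name, float(getattr(self, name)))
        for name in ("GS_max", "GS_min"):
            val = getattr(self, name)
            if val != int(val):
                raise ValueError(f"{name} must be an integer, got {val}")
            object.__setattr__(self, name, int(val))
        if not self.T > 0:
            raise ValueError(f"T must be > 0, got {self.T}")
        if not self.L > 0:
            raise ValueError(f"L must be > 0, got {self.L}")
        if self.L_SD < 0:
            raise ValueError(f"L_SD must be >= 0, got {self.L_SD}")
        if not 0.0 <= self.m_r <= 1.0:
            raise ValueError(f"m_r must lie in [0, 1], got {self.m_r}")
        if not 0.0 <= self.d <= 1.0:
            raise ValueError(f"d must lie in [0, 1], got {self.d}")
        if self.GS_min < 1:
            raise ValueError(f"GS_min must be >= 1, got {self.GS_min}")
        if self.GS_max <= self.GS_min:
            raise ValueError(
                f"GS_max must exceed GS_min, got GS_max={self.GS_max} "
                f"<= GS_min={self.GS_min}"
            )


class ReproductionOutcome(Enum):
    NOT_ELIGIBLE = "not_eligible"
    OFFSPRING_PLACED = "offspring_placed"
    OFFSPRING_REJECTED = "offspring_rejected"


class Population:
    """All living agents, stored column-wise, plus global bookkeeping.

    Invariants: every agent belongs to exactly one group (its
    ``group_id``), agent ids are unique, and the agent count never
    exceeds ``capacity`` (births are refused at the cap).
    """

    _FIELDS = (
        ("strategy", np.uint8),
        ("resources", np.float64),
        ("age", np.int64),
        ("lifespan", np.int64),
        ("group_id", np.int64),
        ("ids", np.int64),
    )

    def __init__(
        self,
        *,
        strategy: np.ndarray,
        resources: np.ndarray,
        age: np.ndarray,
        lifespan: np.ndarray,
        group_id: np.ndarray,
        capacity: int,
        ids: np.ndarray | None = None,
        step_count: int = 0,
    ) -> None:
        strategy = np.asarray(strategy, dtype=np.uint8)
        n = strategy.size
        if n > capacity:
            raise ValueError(
                f"initial population {n} exceeds capacity {capacity}"
            )
        if ids is None:
            ids = np.arange(n, dtype=np.int64)
        given = {
            "strategy": strategy,
            "resources": resources,
            "age": age,
            "lifespan": lifespan,
            "group_id": group_id,
            "ids": ids,
        }
        # double-buffered fixed-capacity storage: births write into the
        # tail, deaths compact into the spare buffer (no reallocations
        # in the per-step hot path)
        self.capacity = int(capacity)
        self._n = n
        self._buf: dict[str, np.ndarray] = {}
        self._spare: dict[str, np.ndarray] = {}
        for name, dtype in self._FIELDS:
            arr = np.asarray(given[name], dtype=dtype)
            if arr.size != n:
                raise ValueError(f"array length mismatch for {name}")
            self._buf[name] = np.empty(self.capacity, dtype=dtype)
            self._buf[name][:n] = arr
            self._spare[name] = np.empty(self.capacity, dtype=dtype)
        self.step_count = int(step_count)
        self._next_agent_id = int(self.ids.max()) + 1 if n else 0
        self._next_group_id = int(self.group_id.max()) + 1 if n else 0
        # lazily built active-group registry (list + position map +
        # size map) for O(1) group creation/removal, uniform partner
        # sampling, and scan-free size checks
        self._glist: list[int] | None = None
        self._gpos: dict[int, int] | None = None
        self._gsize: dict[int, int] | None = None
        self._registry_dirty = False

    # -- column views --------------------------------------------------

    @property
    def strategy(self) -> np.ndarray:
        return self._buf["strategy"][: self._n]

    @property
    def resources(self) -> np.ndarray:
        return self._buf["resources"][: self._n]

    @property
    def age(self) -> np.ndarray:
        return self._buf["age"][: self._n]

    @property
    def lifespan(self) -> np.ndarray:
        return self._buf["lifespan"][: self._n]

    @property
    def group_id(self) -> np.ndarray:
        return self._buf["group_id"][: self._n]

    @property
    def ids(self) -> np.ndarray:
        return self._buf["ids"][: self._n]

    # -- observables ---------------------------------------------------

    @property
    def n(self) -> int:
        return self._n

    @property
    def n_hawks(self) -> int:
        return int(np.count_nonzero(self.strategy == HAWK))

    @property
    def hawk_frequency(self) -> float:
        if self.n == 0:
            return float("nan")
        return self.n_hawks / self.n

    def group_sizes(self) -> tuple[np.ndarray, np.ndarray]:
        """Active group ids (sorted) and their member counts."""
        return np.unique(self.group_id, return_counts=True)

    @property
    def n_groups(self) -> int:
        return np.unique(self.group_id).size

    # -- proxies -------------------------------------------------------

    def agent(self, index: int) -> "Agent":
        return Agent(self, index)

    def group(self, gid: int) -> "Group":
        return Group(self, int(gid))

    # -- group registry ------------------------------------------------

    def _invalidate_groups(self) -> None:
        self._registry_dirty = True

    def _ensure_group_registry(self) -> None:
        if self._glist is None or self._registry_dirty:
            gids, counts = np.unique(self.group_id, return_counts=True)
            self._glist = [int(g) for g in gids]
            self._gpos = {int(g): i for i, g in enumerate(gids)}
            self._gsize = {
                int(g): int(c) for g, c in zip(gids, counts)
            }
            self._registry_dirty = False

    def _registry_add(self, gid: int, size: int) -> None:
        self._gpos[gid] = len(self._glist)
        self._glist.append(gid)
        self._gsize[gid] = size

    def _registry_remove(self, gid: int) -> None:
        lst, pos = self._glist, self._gpos
        i = pos.pop(gid)
        last = lst.pop()
        if last != gid:
            lst[i] = last
            pos[last] = i
        del self._gsize[gid]

    def _registry_apply_deltas(
        self, birth_gids: np.ndarray, death_gids: np.ndarray
    ) -> None:
        """Adjust tracked group sizes after a batch of births/deaths
        (no-op while the registry is unbuilt or stale)."""
        if self._glist is None or self._registry_dirty:
            return
        gsize = self._gsize
        for g in birth_gids.tolist():
            gsize[g] += 1
        for g in death_gids.tolist():
            gsize[g] -= 1

    def _sample_other_group(
        self, gid: int, rng: np.random.Generator
    ) -> int | None:
        """Uniform draw over active groups other than ``gid`` (O(1))."""
        lst, pos = self._glist, self._gpos
        k = len(lst)
        if k < 2:
            return None
        i = pos[gid]
        j = int(rng.integers(k - 1))
        if j == i:
            j = k - 1
        return lst[j]

    # -- mutation ------------------------------------------------------

    def new_group_id(self) -> int:
        gid = self._next_group_id
        self._next_group_id += 1
        return gid

    def add_agents(
        self,
        strategy: np.ndarray,
        lifespan: np.ndarray,
        group_id: np.ndarray,
    ) -> np.ndarray:
        """Append newborns (resources 0, age 0); returns their row indices."""
        k = len(strategy)
        n = self._n
        if n + k > self.capacity:
            raise ValueError("adding agents would exceed capacity")
        buf = self._buf
        buf["strategy"][n: n + k] = np.asarray(strategy, dtype=np.uint8)
        buf["resources"][n: n + k] = 0.0
        buf["age"][n: n + k] = 0
        buf["lifespan"][n: n + k] = np.asarray(lifespan, dtype=np.int64)
        gid = np.asarray(group_id, dtype=np.int64)
        buf["group_id"][n: n + k] = gid
        buf["ids"][n: n + k] = np.arange(
            self._next_agent_id, self._next_agent_id + k, dtype=np.int64
        )
        self._next_agent_id += k
        self._n = n + k
        if k:
            self._next_group_id = max(
                self._next_group_id, int(gid.max()) + 1
            )
        if self._glist is not None and not self._registry_dirty:
            # newborns joining unknown group ids stale the registry
            gpos = self._gpos
            for g in gid.tolist():
                if g not in gpos:
                    self._registry_dirty = True
                    break
        return np.arange(n, n + k)

    def remove(self, mask: np.ndarray, *, groups_unchanged: bool = False) -> None:
        """Drop all agents where ``mask`` is True.

        Compacts the survivors into the spare buffer and swaps; any
        previously obtained column views are stale afterwards.
        ``groups_unchanged=True`` promises the caller will reconcile
        any groups emptied by the removal (the engine does this via
        group maintenance); otherwise the group registry is rebuilt on
        next use.
        """
        if not groups_unchanged:
            self._invalidate_groups()
        keep = ~np.asarray(mask, dtype=bool)
        m = int(np.count_nonzero(keep))
        n = self._n
        for name, _ in self._FIELDS:
            np.compress(keep, self._buf[name][:n], out=self._spare[name][:m])
        self._buf, self._spare = self._spare, self._buf
        self._n = m

    def validate(self) -> None:
        """Raise if a structural invariant is broken (test hook)."""
        n = self.n
        for name in ("resources", "age", "lifespan", "group_id", "ids"):
            if getattr(self, name).size != n:
                raise AssertionError(f"length mismatch for {name}")
        if n > self.capacity:
            raise AssertionError("population exceeds capacity")
        if np.unique(self.ids).size != n:
            raise AssertionError("duplicate agent ids")
        if n and (self.age < 0).any():
            raise AssertionError("negative age")
        if n and (self.lifespan < 1).any():
            raise AssertionError("lifespan below 1")
        if self._glist is not None and not self._registry_dirty:
            gids, counts = np.unique(self.group_id, return_counts=True)
            expected = {int(g): int(c) for g, c in zip(gids, counts)}
            if self._gsize != expected:
                raise AssertionError("group registry out of sync")
            if sorted(self._glist) != sorted(expected):
                raise AssertionError("group registry list out of sync")


class Agent:
    """Proxy for one row of the population arrays.

    Valid until the population is compacted (a removal); cheap enough
    to recreate on demand.
    """

    __slots__ = ("population", "index")

    def __init__(self, population: Population, index: int) -> None:
        self.population = population
        self.index = int(index)

    @property
    def id(self) -> int:
        return int(self.population.ids[self.index])

    @property
    def strategy(self) -> int:
        return int(self.population.strategy[self.index])

    @strategy.setter
    def strategy(self, value: int) -> None:
        self.population.strategy[self.index] = value

    @property
    def resources(self) -> float:
        return float(self.population.resources[self.index])

    @resources.setter
    def resources(self, value: float) -> None:
        self.population.resources[self.index] = value

    @property
    def age(self) -> int:
        return int(self.population.age[self.index])

    @property
    def lifespan(self) -> int:
        return int(self.population.lifespan[self.index])

    @property
    def group_id(self) -> int:
        return int(self.population.group_id[self.index])


class Group:
    """Proxy for the set of agents sharing one ``group_id``."""

    __slots__ = ("population", "id")

    def __init__(self, population: Population, gid: int) -> None:
        self.population = population
        self.id = int(gid)

    @property
    def member_indices(self) -> np.ndarray:
        return np.flatnonzero(self.population.group_id == self.id)

    @property
    def member_ids(self) -> np.ndarray:
        return self.population.ids[self.member_indices]

    @property
    def size(self) -> int:
        return int(np.count_nonzero(self.population.group_id == self.id))


# -- lifespans ---------------------------------------------------------


def draw_lifespans(
    n: int, L: float, L_SD: float, rng: np.random.Generator
) -> np.ndarray:
    """``n`` lifespans: round(Normal(L, L_SD)), clamped to >= 1."""
    draws = np.rint(rng.normal(L, L_SD, size=n))
    return np.maximum(draws, 1.0).astype(np.int64)


def draw_lifespan(L: float, L_SD: float, rng: np.random.Generator) -> int:
    return int(draw_lifespans(1, L, L_SD, rng)[0])


# -- reproduction and placement ---------------------------------------


def place_offspring(
    offspring: Agent,
    natal_group: Group,
    population: Population,
    d: float,
    rng: np.random.Generator,
    *,
    exclude_natal: bool = True,
) -> Group:
    """Assign the newborn to its group under the dispersal rule.

    With probability ``1 - d`` the newborn stays in the natal group;
    otherwise it moves to a uniformly chosen other group (or any group
    when ``exclude_natal`` is False). A lone-group population is the
    degenerate case: the newborn stays put.
    """
    target = natal_group.id
    if rng.random() < d:
        active = np.unique(population.group_id)
        if exclude_natal:
            active = active[active != natal_group.id]
        if active.size > 0:
            target = int(active[rng.integers(active.size)])
    population.group_id[offspring.index] = target
    return Group(population, target)


def attempt_reproduction(
    agent: Agent,
    population: Population,
    params: DemographyParams,
    rng: np.random.Generator,
) -> ReproductionOutcome:
    """One reproduction attempt by ``agent``.

    Below the threshold ``T`` nothing happens. Otherwise the agent
    always pays ``T``; the offspring then enters the population only
    if there is room below capacity (otherwise it dies unborn).
    """
    i = agent.index
    if population.resources[i] < params.T:
        return ReproductionOutcome.NOT_ELIGIBLE
    population.resources[i] -= params.T
    if population.n >= population.capacity:
        return ReproductionOutcome.OFFSPRING_REJECTED
    strat = int(population.strategy[i])
    if rng.random() < params.m_r:
        strat ^= 1
    life = draw_lifespan(params.L, params.L_SD, rng)
    natal_gid = int(population.group_id[i])
    population.add_agents(
        np.array([strat], dtype=np.uint8),
        np.array([life], dtype=np.int64),
        np.array([natal_gid], dtype=np.int64),
    )
    child = Agent(population, population.n - 1)
    place_offspring(
        child,
        Group(population, natal_gid),
        population,
        params.d,
        rng,
        exclude_natal=params.dispersal_excludes_natal,
    )
    return ReproductionOutcome.OFFSPRING_PLACED


# -- fission / fusion --------------------------------------------------


def fission_group(
    group: Group, population: Population, rng: np.random.Generator
) -> tuple[Group, Group]:
    """Randomly split a group into two new groups of sizes
    floor(n/2) and ceil(n/2); the original group id disappears."""
    members = group.member_indices
    n = members.size
    if n < 2:
        raise ValueError(f"cannot fission group of size {n}")
    members = members[rng.permutation(n)]
    half = n // 2
    g1 = population.new_group_id()
    g2 = population.new_group_id()
    population.group_id[members[:half]] = g1
    population.group_id[members[half:]] = g2
    population._invalidate_groups()
    return Group(population, g1), Group(population, g2)


def fuse_group(
    group: Group, population: Population, rng: np.random.Generator
) -> Group:
    """Merge all members of ``group`` into a uniformly chosen other
    group; no-op when no partner group exists."""
    active = np.unique(population.group_id)
    others = active[active != group.id]
    if others.size == 0:
        return group
    target = int(others[rng.integers(others.size)])
    population.group_id[group.member_indices] = target
    population._invalidate_groups()
    return Group(population, target)


def _fuse_threshold_hit(size: int, params: DemographyParams) -> bool:
    if params.fuse_at_or_below:
        return size <= params.GS_min
    return size < params.GS_min


def maintain_groups(
    population: Population,
    params: DemographyParams,
    rng: np.random.Generator,
    *,
    candidates: np.ndarray | None = None,
    max_events: int = 100_000,
) -> tuple[int, int]:
    """Apply fission/fusion until every group satisfies the size bounds.

    Splits every group at or above ``GS_max``, then fuses undersized
    groups one by one; a fusion that pushes its target to ``GS_max`` is
    followed immediately by a fission of the merged group. Returns
    ``(n_fissions, n_fusions)``.

    ``candidates`` is the engine's fast path: an array of group ids
    whose sizes may have changed since the last call (groups that
    gained a newborn or lost a dead member; the engine keeps the
    registry's size map current via ``_registry_apply_deltas``). Only
    those groups are checked — all others were within bounds before
    and still are. Candidate groups whose last member died are retired
    here. With ``candidates=None`` every group is checked.
    """
    pop = population
    if pop.n == 0:
        pop._invalidate_groups()
        return (0, 0)
    pop._ensure_group_registry()
    gsize = pop._gsize

    if candidates is None:
        check = list(pop._glist)
    else:
        # duplicates are harmless: the event loop re-checks sizes and
        # skips already-removed groups
        check = np.asarray(candidates).tolist()

    fiss_stack: list[int] = []
    fuse_stack: list[int] = []
    for gid in check:
        sz = gsize.get(gid)
        if sz is None:
            continue
        if sz == 0:
            pop._registry_remove(gid)  # group died out entirely
        elif sz >= params.GS_max:
            fiss_stack.append(gid)
        elif _fuse_threshold_hit(sz, params):
            fuse_stack.append(gid)
    if not fiss_stack and not fuse_stack:
        return (0, 0)

    # member lists materialised lazily, only for groups we touch
    members: dict[int, np.ndarray] = {}
    removed: set[int] = set()
    gid_arr = pop.group_id

    def get_members(gid: int) -> np.ndarray:
        m = members.get(gid)
        if m is None:
            # live scan is correct: untouched groups keep their
            # membership until we mutate them (and then cache)
            m = np.flatnonzero(gid_arr == gid)
            members[gid] = m
        return m

    n_fissions = n_fusions = 0
    events = 0
    while fiss_stack or fuse_stack:
        events += 1
        if events > max_events:
            raise RuntimeError(
                "group maintenance did not converge "
                f"(GS_min={params.GS_min}, GS_max={params.GS_max})"
            )
        if fiss_stack:
            gid = fiss_stack.pop()
            if gid in removed:
                continue
            sz = gsize[gid]
            if sz < params.GS_max:
                continue
            m = get_members(gid)
            m = m[rng.permutation(m.size)]
            half = sz // 2
            g1 = pop.new_group_id()
            g2 = pop.new_group_id()
            pop.group_id[m[:half]] = g1
            pop.group_id[m[half:]] = g2
            removed.add(gid)
            members.pop(gid, None)
            pop._registry_remove(gid)
            for g_new, m_new in ((g1, m[:half]), (g2, m[half:])):
                members[g_new] = m_new
                pop._registry_add(g_new, m_new.size)
                if m_new.size >= params.GS_max:
                    fiss_stack.append(g_new)
                elif _fuse_threshold_hit(m_new.size, params):
                    fuse_stack.append(g_new)
            n_fissions += 1
            continue

        gid = fuse_stack.pop()
        if gid in removed:
            continue
        sz = gsize[gid]
        if not _fuse_threshold_hit(sz, params):
            continue
        target = pop._sample_other_group(gid, rng)
        if target is None:
            continue  # no partner group exists
        m = get_members(gid)
        target_members = get_members(target)
        pop.group_id[m] = target
        members[target] = np.concatenate([target_members, m])
        gsize[target] += sz
        removed.add(gid)
        members.pop(gid, None)
        pop._registry_remove(gid)
        n_fusions += 1
        if gsize[target] >= params.GS_max:
            fiss_stack.append(target)

    return (n_fissions, n_fusions)


def build_population(
    group_strategies: Sequence[Sequence[int]],
    *,
    capacity: int,
    resources: float | Sequence[float] = 0.0,
    lifespan: int = 150,
    age: int = 0,
) -> Population:
    """Construct a population from per-group strategy lists (test and
    example helper). ``group_strategies[k]`` lists the strategy codes
    (0=dove, 1=hawk) of group ``k``'s members."""
    strat = np.concatenate(
        [np.asarray(g, dtype=np.uint8) for g in group_strategies]
    ) if group_strategies else np.empty(0, dtype=np.uint8)
    gid = np.concatenate(
        [
            np.full(len(g), k, dtype=np.int64)
            for k, g in enumerate(group_strategies)
        ]
    ) if group_strategies else np.empty(0, dtype=np.int64)
    n = strat.size
    res = np.broadcast_to(
        np.asarray(resources, dtype=np.float64), (n,)
    ).copy()
    return Population(
        strategy=strat,
        resources=res,
        age=np.full(n, age, dtype=np.int64),
        lifespan=np.full(n, lifespan, dtype=np.int64),
        group_id=gid,
        capacity=capacity,
    )
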