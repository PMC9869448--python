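"""The spatial and demographic engine.

Grid land, collective territorial contest, community fission (the social
protocell inheritance channel) and dispersal, agent energetics,
reproduction with optional genetic crossover of cognitive capacity,
mortality, world seeding and the master per-update scheduler.

State layout: each community packs its members in contiguous numpy arrays
(age, energy, reproduction buffer, lifetime rank score, cognitive capacity,
and a boolean allele matrix indexed by locus slot).  The owner grid is the
single source of truth for territory; communities mirror their cells as a
set of flat indices with lazily rebuilt coordinate caches.
"""

from __future__ import annotations

import copy
import math
from collections import deque
from dataclasses import dataclass, field

import numpy as np

from . import culture, ecology
from .config import BOOST_TARGET, SimConfig
from .culture import LocusRegistry

__all__ = [
    "Community", "World", "SplitEvent", "seed_world", "community_strength",
    "perimeter_power", "contest_cells", "fission", "disperse",
    "agent_update", "step",
]

UNOCCUPIED = -1


@dataclass
class SplitEvent:
    update: int
    parent: int
    parent_class: int
    daughters: tuple[int, int]
    due: int
    daughter_classes: tuple[int | None, int | None] | None = None
    settled: bool = False


class Community:
    """A social community: packed member arrays plus a territory."""

    __slots__ = ("id", "parent_id", "birth_time", "_n", "_cap", "_age",
                 "_energy", "_buffer", "_rank", "_capacity", "_alleles",
                 "_wbest_a", "_wbest_b", "_cells", "_cell_cache",
                 "last_claimed")

    def __init__(self, cid: int, width: int, parent_id: int | None = None,
                 birth_time: int = 0, cap: int = 16) -> None:
        self.id = cid
        self.parent_id = parent_id
        self.birth_time = birth_time
        self._n = 0
        self._cap = cap
        self._age = np.zeros(cap)
        self._energy = np.zeros(cap)
        self._buffer = np.zeros(cap)
        self._rank = np.zeros(cap)
        self._capacity = np.zeros(cap)
        self._alleles = np.zeros((cap, width), dtype=bool)
        self._wbest_a = np.zeros(cap, dtype=np.int16)
        self._wbest_b = np.zeros(cap, dtype=np.int16)
        self._cells: set[int] = set()
        self._cell_cache: np.ndarray | None = None
        self.last_claimed: np.ndarray | None = None

    # -- members --------------------------------------------------------
    @property
    def n(self) -> int:
        return self._n

    @property
    def age(self) -> np.ndarray:
        return self._age[:self._n]

    @property
    def energy(self) -> np.ndarray:
        return self._energy[:self._n]

    @property
    def buffer(self) -> np.ndarray:
        return self._buffer[:self._n]

    @property
    def rank_score(self) -> np.ndarray:
        return self._rank[:self._n]

    @property
    def capacity(self) -> np.ndarray:
        return self._capacity[:self._n]

    @property
    def alleles_view(self) -> np.ndarray:
        return self._alleles[:self._n]

    def ensure_width(self, width: int) -> None:
        if self._alleles.shape[1] < width:
            extra = np.zeros((self._alleles.shape[0],
                              width - self._alleles.shape[1]), dtype=bool)
            self._alleles = np.concatenate([self._alleles, extra], axis=1)

    def _grow(self, need: int) -> None:
        if need <= self._cap:
            return
        new_cap = max(need, self._cap * 2)
        for name in ("_age", "_energy", "_buffer", "_rank", "_capacity"):
            arr = getattr(self, name)
            grown = np.zeros(new_cap)
            grown[:self._n] = arr[:self._n]
            setattr(self, name, grown)
        for name in ("_wbest_a", "_wbest_b"):
            arr = getattr(self, name)
            grown = np.zeros(new_cap, dtype=np.int16)
            grown[:self._n] = arr[:self._n]
            setattr(self, name, grown)
        grown_al = np.zeros((new_cap, self._alleles.shape[1]), dtype=bool)
        grown_al[:self._n] = self._alleles[:self._n]
        self._alleles = grown_al
        self._cap = new_cap

    def add_agent(self, age: float, energy: float, buffer: float = 0.0,
                  rank: float = 0.0, capacity: float = 0.0,
                  alleles: np.ndarray | None = None,
                  wbest: tuple[int, int] = (0, 0)) -> int:
        self._grow(self._n + 1)
        i = self._n
        self._n += 1
        self._age[i] = age
        self._energy[i] = energy
        self._buffer[i] = buffer
        self._rank[i] = rank
        self._capacity[i] = capacity
        self._alleles[i] = False
        if alleles is not None:
            self._alleles[i, :len(alleles)] = alleles
        self._wbest_a[i], self._wbest_b[i] = wbest
        return i

    def remove_rows(self, idx: np.ndarray) -> None:
        """Remove member rows (packed swap-removal; order not preserved)."""
        if len(idx) == 0:
            return
        keep = np.ones(self._n, dtype=bool)
        keep[idx] = False
        m = int(keep.sum())
        for name in ("_age", "_energy", "_buffer", "_rank", "_capacity",
                     "_wbest_a", "_wbest_b"):
            arr = getattr(self, name)
            arr[:m] = arr[:self._n][keep]
        self._alleles[:m] = self._alleles[:self._n][keep]
        self._n = m

    # -- performance window --------------------------------------------
    def record_best(self, realized: np.ndarray) -> None:
        np.maximum(self._wbest_a[:self._n], realized.astype(np.int16),
                   out=self._wbest_a[:self._n])

    def swap_window(self) -> None:
        self._wbest_b[:self._n] = self._wbest_a[:self._n]
        self._wbest_a[:self._n] = 0

    def window_best(self) -> np.ndarray:
        return np.maximum(self._wbest_a[:self._n], self._wbest_b[:self._n])

    # -- territory ------------------------------------------------------
    @property
    def territory(self) -> set[int]:
        return self._cells

    @property
    def territory_size(self) -> int:
        return len(self._cells)

    def set_cells(self, cells: set[int]) -> None:
        self._cells = cells
        self._cell_cache = None

    def cells_changed(self) -> None:
        self._cell_cache = None

    def cell_array(self, ncols: int) -> np.ndarray:
        """Territory cells as an (k, 2) row/column array."""
        if self._cell_cache is None:
            flat = np.fromiter(self._cells, dtype=np.int64,
                               count=len(self._cells))
            flat.sort()
            self._cell_cache = np.column_stack(divmod(flat, ncols))
        return self._cell_cache

    def centroid(self, ncols: int) -> tuple[float, float]:
        rc = self.cell_array(ncols)
        return float(rc[:, 0].mean()), float(rc[:, 1].mean())


def community_strength(community: Community, cfg: SimConfig) -> int:
    """Population count over the adulthood age threshold."""
    return int(np.count_nonzero(community.age >= cfg.adult_age))


def perimeter_power(community: Community, cell: tuple[int, int],
                    cfg: SimConfig, ncols: int | None = None) -> float:
    """Community strength abated radially from the territory centroid."""
    ncols = ncols if ncols is not None else 10**9
    cr, cc = community.centroid(ncols)
    d = math.hypot(cell[0] - cr, cell[1] - cc)
    s = community_strength(community, cfg)
    return s / (1.0 + cfg.power_abatement * d)


class World:
    """Complete simulation state plus per-interval measurement counters."""

    def __init__(self, cfg: SimConfig, rng: np.random.Generator) -> None:
        self.cfg = cfg
        self.rng = rng
        self.registry = LocusRegistry()
        self.owner = np.full(cfg.grid_size, UNOCCUPIED, dtype=np.int32)
        self.communities: dict[int, Community] = {}
        self.t = 0
        self.next_community_id = 0
        self.pending_splits: list[SplitEvent] = []
        self.split_events: list[SplitEvent] = []
        self.dispersals = 0
        self.births = 0
        self.deaths = 0
        # per-interval accumulators (reset by the metrics sampler)
        self.acc_opportunities = 0
        self.acc_successes = 0
        self.acc_energy: dict[str, float] = {}
        self.metrics_rows: list[dict] = []
        self.learning_log: list | None = None    # enable to collect events
        self.compact_interval = 200
        self.scratch: dict[str, np.ndarray] = {}

    def __deepcopy__(self, memo):
        cls = self.__class__
        new = cls.__new__(cls)
        memo[id(self)] = new
        for k, v in self.__dict__.items():
            if k == "scratch":
                new.scratch = {}
            else:
                setattr(new, k, copy.deepcopy(v, memo))
        return new

    # -- bookkeeping ----------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.owner.shape  # type: ignore[return-value]

    @property
    def population(self) -> int:
        return sum(c.n for c in self.communities.values())

    @property
    def occupied_cells(self) -> int:
        return sum(c.territory_size for c in self.communities.values())

    def sorted_communities(self) -> list[Community]:
        return [self.communities[cid] for cid in sorted(self.communities)]

    def new_community(self, parent_id: int | None = None) -> Community:
        cid = self.next_community_id
        self.next_community_id += 1
        com = Community(cid, self.registry.width, parent_id, self.t)
        self.communities[cid] = com
        return com

    def random_parent_capacity(self) -> float:
        """Capacity of a mate drawn uniformly from the global population."""
        total = self.population
        if total == 0:
            return self.cfg.cognition_baseline
        r = int(self.rng.integers(total))
        for com in self.sorted_communities():
            if r < com.n:
                return float(com.capacity[r])
            r -= com.n
        raise AssertionError("unreachable")

    def copy(self) -> "World":
        return copy.deepcopy(self)

    def state_hash(self) -> int:
        """Order-stable hash of the full world state (for determinism tests)."""
        import hashlib
        h = hashlib.sha256()
        h.update(self.owner.tobytes())
        h.update(str(self.t).encode())
        for com in self.sorted_communities():
            h.update(np.ascontiguousarray(com.age).tobytes())
            h.update(np.ascontiguousarray(com.energy).tobytes())
            h.update(np.ascontiguousarray(com.buffer).tobytes())
            h.update(np.ascontiguousarray(com.alleles_view).tobytes())
            h.update(np.fromiter(sorted(com.territory), dtype=np.int64).tobytes())
        return int.from_bytes(h.digest()[:8], "big")


# ---------------------------------------------------------------------------
# Seeding


def seed_world(cfg: SimConfig, rng: np.random.Generator | None = None) -> World:
    """Single centrally placed community with no cultural knowledge.

    The founding population is a dozen young adults (at least
    ``min_population + 1``) with empty allele sets and a founding disc
    territory large enough to feed them while they expand.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    world = World(cfg, rng)
    for target in cfg.apex_targets():
        world.registry.add_apex(target, t=0)
    n_found = max(cfg.min_population + 1, 12)
    n_cells = max(cfg.min_territory, 4 * n_found)
    nrows, ncols = cfg.grid_size
    if n_cells > nrows * ncols:
        raise ValueError(
            f"grid {cfg.grid_size} too small for a founding disc of "
            f"{n_cells} cells")
    rr, cc = np.indices(cfg.grid_size)
    d2 = (rr - (nrows - 1) / 2.0) ** 2 + (cc - (ncols - 1) / 2.0) ** 2
    order = np.argsort(d2.ravel(), kind="stable")[:n_cells]
    com = world.new_community()
    com.ensure_width(world.registry.width)
    com.set_cells(set(int(i) for i in order))
    world.owner.ravel()[order] = com.id
    for _ in range(n_found):
        com.add_agent(age=float(rng.uniform(cfg.adult_age, cfg.adult_age + 10)),
                      energy=cfg.cost_of_living, buffer=0.0, rank=0.0,
                      capacity=cfg.cognition_baseline)
    return world


# ---------------------------------------------------------------------------
# Territorial contest

_SHIFTS = ((-1, 0), (1, 0), (0, -1), (0, 1))


def _scratch(world: World, name: str, dtype) -> np.ndarray:
    """Reusable full-grid buffer (allocation-free contest inner loop)."""
    buf = world.scratch.get(name)
    if buf is None or buf.shape != world.shape or buf.dtype != dtype:
        buf = np.empty(world.shape, dtype=dtype)
        world.scratch[name] = buf
    return buf


def _power_grid(world: World) -> np.ndarray:
    cfg = world.cfg
    P = _scratch(world, "P", np.float64)
    P.fill(cfg.unoccupied_cell_power)
    ncols = world.shape[1]
    for com in world.sorted_communities():
        if com.territory_size == 0:
            continue
        rc = com.cell_array(ncols)
        cr, cc = com.centroid(ncols)
        d = np.hypot(rc[:, 0] - cr, rc[:, 1] - cc)
        s = community_strength(com, cfg)
        P[rc[:, 0], rc[:, 1]] = s / (1.0 + cfg.power_abatement * d)
    return P


def transfer_probability(p_challenger: np.ndarray, p_defender: np.ndarray,
                         cfg: SimConfig) -> np.ndarray:
    """Per-update probability that a contested cell changes owner."""
    denom = p_challenger + p_defender
    ratio = np.where(denom > 0,
                     (p_challenger - p_defender) / np.maximum(denom, 1e-12),
                     0.0)
    return cfg.contest_rate / (1.0 + np.exp(-cfg.contest_steepness * ratio))


def contest_cells(world: World) -> list[tuple[int, int, int]]:
    """Stochastic ownership changes on all perimeter cells.

    Every cell with at least one differently-owned 4-neighbour is contested
    by its strongest adjacent challenger (unoccupied sides use the
    unoccupied cell power).  Transfers are synchronous.  Returns
    ``(flat_cell, old_owner, new_owner)`` changes.
    """
    cfg = world.cfg
    O = world.owner
    P = _power_grid(world)
    H, W = O.shape
    best_p = _scratch(world, "best_p", np.float64)
    best_p.fill(-np.inf)
    best_o = _scratch(world, "best_o", np.int32)
    best_o.fill(UNOCCUPIED)
    # edge-padded views: border "neighbours" equal the cell's own owner and
    # are excluded by the differing-owner test without a sentinel pass
    OP = np.pad(O, 1, mode="edge")
    PP = np.pad(P, 1, mode="edge")
    for dr, dc in _SHIFTS:
        nb_o = OP[1 + dr:1 + dr + H, 1 + dc:1 + dc + W]
        nb_p = PP[1 + dr:1 + dr + H, 1 + dc:1 + dc + W]
        cand = (nb_o != O) & (nb_p > best_p)
        best_p[cand] = nb_p[cand]
        best_o[cand] = nb_o[cand]
    contested = np.flatnonzero(best_p.ravel() > -np.inf)
    if len(contested) == 0:
        return []
    pc = best_p.ravel()[contested]
    pd = P.ravel()[contested]
    prob = transfer_probability(pc, pd, cfg)
    flips = contested[world.rng.random(len(contested)) < prob]
    changes: list[tuple[int, int, int]] = []
    flat_owner = O.ravel()
    flat_new = best_o.ravel()
    for cell in flips:
        old, new = int(flat_owner[cell]), int(flat_new[cell])
        changes.append((int(cell), old, new))
    for cell, old, new in changes:
        flat_owner[cell] = new
        if old != UNOCCUPIED and old in world.communities:
            com = world.communities[old]
            com.territory.discard(cell)
            com.cells_changed()
        if new != UNOCCUPIED and new in world.communities:
            com = world.communities[new]
            com.territory.add(cell)
            com.cells_changed()
    return changes


# ---------------------------------------------------------------------------
# Fission / dispersal


def _bisect_territory(cells: set[int], ncols: int,
                      rng: np.random.Generator) -> tuple[set[int], set[int]]:
    """Split a territory into two connected halves.

    The split direction is the line through the centroid perpendicular to
    the territory's principal axis; the two extreme cells along the axis
    seed an alternating multi-source flood fill, which guarantees both
    halves are edge-connected and near-equal in size.
    """
    flat = np.fromiter(cells, dtype=np.int64, count=len(cells))
    flat.sort()
    rc = np.column_stack(divmod(flat, ncols)).astype(np.float64)
    centered = rc - rc.mean(axis=0)
    cov = centered.T @ centered
    evals, evecs = np.linalg.eigh(cov)
    if abs(evals[1] - evals[0]) < 1e-9 * max(1.0, evals[1]):
        theta = rng.uniform(0, np.pi)
        axis = np.array([np.cos(theta), np.sin(theta)])
    else:
        axis = evecs[:, 1]
    proj = centered @ axis
    seed_a = int(flat[np.argmax(proj)])
    seed_b = int(flat[np.argmin(proj)])
    assign: dict[int, int] = {seed_a: 0, seed_b: 1}
    queues = (deque([seed_a]), deque([seed_b]))
    counts = [1, 1]
    while queues[0] or queues[1]:
        side = 0 if (queues[0] and (counts[0] <= counts[1] or not queues[1])) else 1
        q = queues[side]
        cell = q.popleft()
        r, c = divmod(cell, ncols)
        for dr, dc in _SHIFTS:
            nr, nc = r + dr, c + dc
            nb = nr * ncols + nc
            if 0 <= nc < ncols and nb in cells and nb not in assign:
                assign[nb] = side
                counts[side] += 1
                q.append(nb)
    # cells unreachable from either seed (territory already fragmented by
    # contest) go to the side with fewer cells
    for cell in cells:
        if cell not in assign:
            side = 0 if counts[0] <= counts[1] else 1
            assign[cell] = side
            counts[side] += 1
    side_a = {c for c, s in assign.items() if s == 0}
    return side_a, cells - side_a


def fission(world: World, com: Community) -> SplitEvent | None:
    """Split a community into two daughters (the inheritance event).

    Half the territory and half the population go to each daughter; agents
    retain alleles, energy, age, rank and capacity.  Daughters start fresh
    performance windows; their complexity classes are recorded after the
    settling window.  Returns None when the territory is degenerate
    (< 2 cells) and the fission is deferred.
    """
    cfg = world.cfg
    if com.territory_size < 2 or com.n < 2:
        return None
    from . import metrics
    parent_class = metrics.complexity_class(com, world).cls
    ncols = world.shape[1]
    side_a, side_b = _bisect_territory(com.territory, ncols, world.rng)
    perm = world.rng.permutation(com.n)
    n_a = (com.n + 1) // 2
    halves = (perm[:n_a], perm[n_a:])
    daughters = []
    for side_cells, members in zip((side_a, side_b), halves):
        d = world.new_community(parent_id=com.id)
        d.ensure_width(com.alleles_view.shape[1])
        for i in members:
            d.add_agent(age=float(com.age[i]), energy=float(com.energy[i]),
                        buffer=float(com.buffer[i]), rank=float(com.rank_score[i]),
                        capacity=float(com.capacity[i]),
                        alleles=com.alleles_view[i])
        d.set_cells(side_cells)
        flat = np.fromiter(side_cells, dtype=np.int64, count=len(side_cells))
        world.owner.ravel()[flat] = d.id
        daughters.append(d)
    del world.communities[com.id]
    event = SplitEvent(update=world.t, parent=com.id,
                       parent_class=parent_class,
                       daughters=(daughters[0].id, daughters[1].id),
                       due=world.t + cfg.settling_window)
    world.pending_splits.append(event)
    return event


def fission_due(world: World, com: Community) -> bool:
    cfg = world.cfg
    if cfg.fission_mode == "population_threshold":
        return community_strength(com, cfg) > cfg.fission_threshold
    if cfg.fission_mode == "constant_rate":
        return bool(world.rng.random() < cfg.fission_rate) and com.n >= 2
    raise ValueError(cfg.fission_mode)


def disperse(world: World, com: Community) -> None:
    """Remove a non-viable community; territory reverts to unoccupied and
    remaining agents are destroyed."""
    flat = np.fromiter(com.territory, dtype=np.int64, count=com.territory_size)
    world.owner.ravel()[flat] = UNOCCUPIED
    del world.communities[com.id]
    world.dispersals += 1


# ---------------------------------------------------------------------------
# Agent dynamics


def agent_update(world: World, com: Community) -> None:
    """Energetics, reproduction and mortality for one community's members.

    Harvest income was credited and expression costs debited earlier in the
    update.  Fixed costs are paid; energy above the one-year reserve cap
    overflows into the reproduction buffer; adults whose buffer exceeds the
    threshold produce one newborn (empty alleles, one-year energy
    endowment); death hazards combine a baseline, a senescent power of age
    and a starvation term.
    """
    cfg = world.cfg
    rng = world.rng
    n = com.n
    if n == 0:
        return
    cost = cfg.cost_of_living
    if cfg.genetics_enabled:
        com.energy[:] -= (cost + cfg.cognition_cost_per_unit * com.capacity) * cfg.dt
    else:
        com.energy[:] -= cost * cfg.dt
    cap = cfg.cost_of_living
    excess = com.energy - cap
    over = excess > 0
    com.buffer[over] += excess[over]
    com.energy[over] = cap

    newborn_caps: list[float] = []
    reproducers = np.flatnonzero((com.buffer > cfg.reproduction_threshold)
                                 & (com.age >= cfg.adult_age))
    for i in reproducers:
        com.buffer[i] -= cfg.reproduction_threshold
        if cfg.genetics_enabled:
            mate_cap = world.random_parent_capacity()
            child = 0.5 * (com.capacity[i] + mate_cap) \
                + rng.normal(0.0, cfg.cognition_mutation_sd)
            newborn_caps.append(max(0.0, child))
        else:
            newborn_caps.append(cfg.cognition_baseline)

    rel_age = com.age / cfg.senescence_age
    expo = cfg.mortality_age_exponent
    if expo == int(expo) and 0 < expo <= 8:
        sen = rel_age
        for _ in range(int(expo) - 1):
            sen = sen * rel_age
    else:
        sen = rel_age ** expo
    hazard = (cfg.mortality_baseline + cfg.mortality_age_coeff * sen
              + cfg.starvation_hazard * (com.energy < 0)) * cfg.dt
    dead = np.flatnonzero(rng.random(n) < hazard)
    if len(dead):
        world.deaths += len(dead)
        com.remove_rows(dead)
    com.age[:] += cfg.dt
    for capval in newborn_caps:
        com.add_agent(age=0.0, energy=cfg.cost_of_living, buffer=0.0,
                      rank=0.0, capacity=capval)
    world.births += len(newborn_caps)


# ---------------------------------------------------------------------------
# Master scheduler


def step(world: World) -> World:
    """One synchronous model update.

    Per community: express -> resolve -> harvest -> learn -> invent; then
    globally: territorial contest -> fission checks -> dispersal checks ->
    agent dynamics; finally split-event settling, registry compaction and
    metrics sampling.  Deterministic under a fixed seed.
    """
    cfg = world.cfg
    world.t += 1
    registry = world.registry
    boost_slot = registry.apex_by_target.get(BOOST_TARGET)

    half = max(1, cfg.class_window // 2)
    swap = world.t % half == 0

    for com in world.sorted_communities():
        if com.n == 0:
            continue
        com.ensure_width(registry.width)
        tally = culture.express_traditions(com, cfg)
        perfs = culture.resolve_institutions(tally, registry, com, world.rng)
        best: dict[str, np.ndarray] = {}
        for apex_slot, (agents, realized, _full) in perfs.items():
            if apex_slot == boost_slot:
                continue
            target = registry.loci[apex_slot].target
            arr = np.zeros(com.n)
            arr[agents] = realized
            best[target] = arr
        igut = best.get("igut")
        if igut is not None:
            com.record_best(igut)
        ledger = ecology.harvest(com, best, cfg)
        for name, val in ledger.per_resource.items():
            world.acc_energy[name] = world.acc_energy.get(name, 0.0) + val
        ops, succ, events = culture.social_learning_step(
            tally, com, perfs, cfg, registry, world.rng)
        world.acc_opportunities += ops
        world.acc_successes += succ
        if world.learning_log is not None:
            for agent, slot in events:
                world.learning_log.append(
                    {"update": world.t, "community": com.id, "agent": agent,
                     "locus": registry.loci[slot].id, "kind": "learning"})
        inv = culture.invent(com, registry, cfg, world.rng, world.t)
        if world.learning_log is not None:
            for agent, slot in inv:
                world.learning_log.append(
                    {"update": world.t, "community": com.id, "agent": agent,
                     "locus": registry.loci[slot].id, "kind": "invention"})
        if swap:
            com.swap_window()

    contest_cells(world)

    for cid in sorted(world.communities):
        com = world.communities.get(cid)
        if com is not None and fission_due(world, com):
            fission(world, com)

    for cid in sorted(world.communities):
        com = world.communities[cid]
        if com.n < cfg.min_population or com.territory_size < cfg.min_territory:
            disperse(world, com)

    for cid in sorted(world.communities):
        com = world.communities[cid]
        agent_update(world, com)
        if com.n == 0:
            disperse(world, com)

    _settle_splits(world)

    if world.t % world.compact_interval == 0:
        _compact_registry(world)

    if world.t % cfg.metrics_interval == 0:
        from . import metrics
        world.metrics_rows.append(metrics.sample_row(world))
        world.acc_opportunities = 0
        world.acc_successes = 0
        world.acc_energy = {}
    return world


def _settle_splits(world: World) -> None:
    from . import metrics
    still_pending = []
    for ev in world.pending_splits:
        if ev.due > world.t:
            still_pending.append(ev)
            continue
        classes = []
        for did in ev.daughters:
            com = world.communities.get(did)
            classes.append(None if com is None
                           else metrics.complexity_class(com, world).cls)
        ev.daughter_classes = (classes[0], classes[1])
        ev.settled = True
        world.split_events.append(ev)
    world.pending_splits = still_pending


def _compact_registry(world: World) -> None:
    """Retire component loci with no carriers anywhere."""
    registry = world.registry
    width = registry.width
    carriers = np.zeros(width, dtype=np.int64)
    for com in world.communities.values():
        al = com.alleles_view
        carriers[:al.shape[1]] += al.sum(axis=0)
    # free extinct leaves only, repeating so extinct chains unwind without
    # ever orphaning a live descendant
    while True:
        child_count = np.zeros(width, dtype=np.int64)
        for slot in range(width):
            if registry.loci[slot] is not None and registry.parent[slot] >= 0:
                child_count[registry.parent[slot]] += 1
        freed = 0
        for slot in range(width):
            locus = registry.loci[slot]
            if (locus is not None and locus.kind == "component"
                    and carriers[slot] == 0 and child_count[slot] == 0):
                registry.free(slot)
                freed += 1
        if freed == 0:
            break
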