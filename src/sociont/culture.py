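"""Tradition loci, institution trees, expression, resolution, social
learning and invention.

A *locus* is a tradition type; an *allele* is an agent's possessed instance
of it.  Apex loci target an external function (a resource, or the social
learning booster); component loci improve another locus, and the parent
links form a rooted institution tree whose complexity is its locus count.
Topology carries no fitness weight beyond the count, but it does constrain
resolution: a component expression can only be claimed under a claimed
parent.

Resolution is the paper-facing bottleneck of the whole model: each update
the community's expressed apex alleles are "populated" with available
component expressions, and the realized complexity of each performance
determines harvesting efficiency.  For tree-structured institutions the
sequential random-order greedy claim process has a closed form (see
:func:`resolve_institutions`), which the test suite checks against
brute-force enumeration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import BOOST_TARGET, SimConfig

__all__ = [
    "Locus", "LocusRegistry", "PerformanceRecord", "ExpressionTally",
    "express_traditions", "resolve_institutions", "complexity",
    "social_learning_step", "boost_factor", "invent",
]


@dataclass(frozen=True)
class Locus:
    id: int                    # stable log-facing identifier
    kind: str                  # "apex" | "component"
    target: str | None         # apex only
    parent: int | None         # component only (slot of parent)
    birth_time: int


class LocusRegistry:
    """Global registry of loci with recyclable matrix columns ("slots").

    Allele matrices are indexed by slot.  When a component locus goes
    globally extinct its slot is freed for reuse (an extinct tradition has
    no carriers left to relearn from, and communities do not exchange
    culture, so it can never return).  Log-facing locus ids stay unique.
    """

    def __init__(self) -> None:
        self.loci: list[Locus | None] = []      # per slot
        self.parent = np.empty(0, dtype=np.int32)   # -1 for apex/free
        self.apex_root = np.empty(0, dtype=np.int32)
        self.alive = np.empty(0, dtype=bool)
        self._free: list[int] = []
        self._next_id = 0
        self._tree_cache: dict[int, np.ndarray] = {}
        self.apex_slots: list[int] = []
        self.apex_by_target: dict[str, int] = {}

    # -- construction ---------------------------------------------------
    def _alloc(self) -> int:
        if self._free:
            return self._free.pop()
        slot = len(self.loci)
        self.loci.append(None)
        for name in ("parent", "apex_root"):
            arr = getattr(self, name)
            setattr(self, name, np.append(arr, -1).astype(np.int32))
        self.alive = np.append(self.alive, False)
        return slot

    def add_apex(self, target: str, t: int = 0) -> int:
        slot = self._alloc()
        self.loci[slot] = Locus(self._next_id, "apex", target, None, t)
        self._next_id += 1
        self.parent[slot] = -1
        self.apex_root[slot] = slot
        self.alive[slot] = True
        self.apex_slots.append(slot)
        self.apex_by_target[target] = slot
        self._tree_cache.pop(slot, None)
        self._tree_cache.pop(("arr", slot), None)
        return slot

    def add_component(self, parent_slot: int, t: int = 0) -> int:
        if not self.alive[parent_slot]:
            raise ValueError(f"parent slot {parent_slot} is not a live locus")
        slot = self._alloc()
        self.loci[slot] = Locus(self._next_id, "component", None,
                                parent_slot, t)
        self._next_id += 1
        self.parent[slot] = parent_slot
        root = int(self.apex_root[parent_slot])
        self.apex_root[slot] = root
        self.alive[slot] = True
        self._tree_cache.pop(root, None)
        self._tree_cache.pop(("arr", root), None)
        return slot

    def free(self, slot: int) -> None:
        """Retire an extinct component locus and recycle its slot."""
        locus = self.loci[slot]
        if locus is None or locus.kind != "component":
            raise ValueError(f"slot {slot} is not a retirable component")
        root = int(self.apex_root[slot])
        self.alive[slot] = False
        self.parent[slot] = -1
        self.apex_root[slot] = -1
        self.loci[slot] = None
        self._free.append(slot)
        self._tree_cache.pop(root, None)
        self._tree_cache.pop(("arr", root), None)

    # -- queries --------------------------------------------------------
    @property
    def width(self) -> int:
        """Number of slots (columns any allele matrix must have)."""
        return len(self.loci)

    def tree_components(self, apex_slot: int) -> np.ndarray:
        """Component slots of an apex's tree in topological (parent-first)
        order."""
        cached = self._tree_cache.get(apex_slot)
        if cached is not None:
            return cached
        members = [s for s in range(self.width)
                   if self.alive[s] and self.apex_root[s] == apex_slot
                   and s != apex_slot]
        order: list[int] = []
        remaining = set(members)
        placed = {apex_slot}
        while remaining:
            progress = [s for s in remaining if self.parent[s] in placed]
            if not progress:   # pragma: no cover - registry corruption
                raise RuntimeError("institution tree contains a cycle")
            for s in sorted(progress):
                order.append(s)
                placed.add(s)
                remaining.discard(s)
        arr = np.asarray(order, dtype=np.int32)
        self._tree_cache[apex_slot] = arr
        return arr

    def tree_arrays(self, apex_slot: int):
        """``(components, parent_positions, levels)`` with parents before
        children; a parent position of -1 means the apex itself.  ``levels``
        groups positions by tree depth (index arrays per level below the
        first) so minpath can be computed level-vectorized."""
        key = ("arr", apex_slot)
        cached = self._tree_cache.get(key)  # type: ignore[arg-type]
        if cached is None:
            comps_arr = self.tree_components(apex_slot)
            comps = [int(s) for s in comps_arr]
            pos = {s: i for i, s in enumerate(comps)}
            ppos = [pos.get(int(self.parent[s]), -1) for s in comps]
            depth = [0 if p < 0 else -1 for p in ppos]
            for i, p in enumerate(ppos):
                if p >= 0:
                    depth[i] = depth[p] + 1
            levels = []
            d = 1
            while True:
                idx = [i for i, dd in enumerate(depth) if dd == d]
                if not idx:
                    break
                levels.append((np.asarray(idx, dtype=np.intp),
                               np.asarray([ppos[i] for i in idx],
                                          dtype=np.intp)))
                d += 1
            cached = (np.asarray(comps, dtype=np.intp), ppos, levels)
            self._tree_cache[key] = cached  # type: ignore[index]
        return cached

    def tree_complexity(self, apex_slot: int) -> int:
        return 1 + len(self.tree_components(apex_slot))

    def leaf_count_check(self) -> None:
        for s in self.apex_slots:
            self.tree_components(s)


def complexity(registry: LocusRegistry, apex_slot: int) -> int:
    """Number of loci in the institution tree (apex plus components)."""
    return registry.tree_complexity(apex_slot)


@dataclass
class PerformanceRecord:
    agent: int
    apex: int
    realized_complexity: int
    full_performance: bool


class ExpressionTally:
    """Per-update expression counter with attribution.

    ``counts[slot]`` is the number of expressions of that locus this update.
    Every allele is expressed exactly once, so attribution of expressions to
    agents is the community's allele matrix itself.
    """

    def __init__(self, counts: np.ndarray, alleles: np.ndarray) -> None:
        self.counts = counts
        self.alleles = alleles

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def expressers(self, slot: int) -> np.ndarray:
        return np.flatnonzero(self.alleles[:, slot])


def express_traditions(community, cfg: SimConfig) -> ExpressionTally:
    """Express every allele of every member once and debit the cost.

    Agents may go energy-negative; mortality handles that later in the
    update.
    """
    alleles = community.alleles_view
    counts = alleles.sum(axis=0, dtype=np.int32)
    community.energy[:] -= cfg.allele_expression_cost * alleles.sum(axis=1)
    return ExpressionTally(counts, alleles)


def _minpath(tally, comps, levels) -> np.ndarray:
    """min over each component's ancestor path (apex excluded) of the
    available expression counts, computed one tree level at a time."""
    mp = tally[comps].astype(np.int64)
    for idx, pidx in levels:
        mp[idx] = np.minimum(mp[idx], mp[pidx])
    return mp


def resolve_institutions(tally: ExpressionTally, registry: LocusRegistry,
                         community, rng: np.random.Generator,
                         ) -> dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Populate apex performances with component expressions.

    Contract: apex expressions are processed in uniformly random order; each
    claims, top-down from the apex, one available expression of every
    reachable tree locus, decrementing the counter; a component is claimable
    only under a claimed parent; claimed expressions are unavailable to
    later performances.

    For a tree this sequential greedy is order-invariant: the performance
    processed at rank ``j`` claims component ``l`` iff ``j < minpath(l)``,
    where ``minpath`` is the minimum expression count along ``l``'s ancestor
    path.  Hence realized complexity per rank has a closed form; only the
    assignment of agents to ranks is random.

    Returns, per apex slot: ``(agents, realized, full)`` where ``agents``
    are the performing agents in processing order.  Also stores per-agent
    best realized complexity per apex target on ``community`` and updates
    the community's claimed-expression accounting.
    """
    out: dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    claimed = np.zeros_like(tally.counts)
    for apex_slot in registry.apex_slots:
        n_a = int(tally.counts[apex_slot])
        if n_a == 0:
            continue
        agents = tally.expressers(apex_slot)
        agents = agents[rng.permutation(n_a)]
        comps, _ppos, levels = registry.tree_arrays(apex_slot)
        if len(comps) == 0:
            realized = np.ones(n_a, dtype=np.int64)
            full = np.ones(n_a, dtype=bool)
        else:
            mp = _minpath(tally.counts, comps, levels)
            ranks = np.arange(n_a)
            # number of components with minpath > j, via sorted counts
            mp_sorted = np.sort(mp)
            claimed_per_rank = len(mp) - np.searchsorted(mp_sorted, ranks,
                                                         side="right")
            realized = 1 + claimed_per_rank
            present = tally.counts[comps] > 0
            if present.any():
                min_present = int(mp[present].min())
            else:
                min_present = np.iinfo(np.int64).max
            full = ranks < min_present
            claimed[comps] += np.minimum(mp, n_a)
        claimed[apex_slot] += n_a
        out[apex_slot] = (agents, realized, full)
    community.last_claimed = claimed
    return out


def boost_factor(model_booster_realized: int | None,
                 observer_capacity: float, cfg: SimConfig) -> float:
    """Learning multiplier conferred by a model agent who performed the
    SLR-boosting apex this update.

    ``B = 1 + boost_coefficient * (min(c, cap) - 1)`` where ``c`` is the
    model's realized booster complexity and ``cap`` the observer's cognitive
    capacity (unbounded unless genetics couple cognition to the booster).
    A lone booster apex (c = 1) confers nothing: the boosting is the
    function of the institutional structure, and a bare apex that boosted
    its own transmission would be a self-catalytic cultural parasite.
    """
    if not cfg.boost_enabled or model_booster_realized is None:
        return 1.0
    c = float(model_booster_realized)
    if cfg.genetics_enabled and not cfg.cognition_decoupled:
        c = min(c, float(observer_capacity))
    return 1.0 + cfg.boost_coefficient * max(0.0, c - 1.0)


def social_learning_step(tally: ExpressionTally, community,
                         performances, cfg: SimConfig,
                         registry: LocusRegistry,
                         rng: np.random.Generator,
                         ) -> tuple[int, int, list[tuple[int, int]]]:
    """One update of observational learning.

    Each agent draws one observation opportunity: an expression sampled from
    the community tally.  If the observed locus is one the agent lacks, the
    draw is a learning opportunity and succeeds with probability
    ``slr/1000`` times the rank/conformity biases and the boost factor of
    the (uniformly sampled) expressing model agent (boosted when that model
    performed the SLR-boosting institution this update).  The conformity
    bias penalizes variants expressed below the community's mean expression
    density (factor ``min(1, (density/mean density)^conformity_exponent)``)
    — rare variants are disproportionately hard to pick up.  At most one
    allele per locus per agent, ever.

    Returns ``(opportunities, successes, events)``.
    """
    n = community.n
    total = tally.total
    if n == 0 or total == 0 or cfg.slr == 0.0:
        return 0, 0, []
    counts = tally.counts
    expressed = np.flatnonzero(counts)
    cum = np.cumsum(counts[expressed])
    # every agent observes once; a fractional attention surplus grants some
    # agents an extra observation this update
    whole, frac = divmod(cfg.observation_rate, 1.0)
    observers = np.repeat(np.arange(n), int(whole))
    extra = np.flatnonzero(rng.random(n) < frac)
    observers = np.concatenate([observers, extra]) if len(extra) \
        else observers
    if len(observers) == 0:
        return 0, 0, []
    draws = rng.integers(0, total, size=len(observers))
    sampled_l = expressed[np.searchsorted(cum, draws, side="right")]
    lacking = ~community.alleles_view[observers, sampled_l]
    obs = observers[lacking]          # agent per learning opportunity
    loc = sampled_l[lacking]          # observed locus per opportunity
    opportunities = len(obs)
    if opportunities == 0:
        return 0, 0, []

    p0 = cfg.learn_prob
    mean_count = counts[expressed].mean()
    need_model = (cfg.rank_bias > 0.0
                  or (cfg.boost_enabled
                      and registry.apex_by_target.get(BOOST_TARGET) is not None))
    boost_perf = None
    if cfg.boost_enabled:
        bslot = registry.apex_by_target.get(BOOST_TARGET)
        if bslot is not None and bslot in performances:
            agents, realized, _ = performances[bslot]
            boost_perf = np.zeros(n, dtype=np.int64)
            boost_perf[agents] = realized
    rank_pct = None
    if cfg.rank_bias > 0.0 and n > 1:
        order = np.argsort(np.argsort(community.rank_score[:n]))
        rank_pct = order / (n - 1)

    uniforms = rng.random(opportunities)
    if not need_model:
        if cfg.conformity_exponent == 0.0:
            won = uniforms < min(p0, 1.0)
        else:
            rel = counts[loc] / mean_count
            probs = p0 * np.minimum(rel ** cfg.conformity_exponent, 1.0)
            won = uniforms < np.minimum(probs, 1.0)
        community.alleles_view[obs[won], loc[won]] = True
        events = [(int(a), int(l)) for a, l in zip(obs[won], loc[won])]
        return opportunities, len(events), events

    events = []
    for a, l, u in zip(obs, loc, uniforms):
        slot = int(l)
        p = p0
        if cfg.conformity_exponent > 0.0:
            p *= min((counts[slot] / mean_count) ** cfg.conformity_exponent,
                     1.0)
        carriers = tally.expressers(slot)
        m = int(carriers[rng.integers(len(carriers))])
        if rank_pct is not None:
            p *= 1.0 + cfg.rank_bias * rank_pct[m]
        if boost_perf is not None and boost_perf[m] > 0:
            p *= boost_factor(int(boost_perf[m]),
                              float(community.capacity[a]), cfg)
        if u < min(p, 1.0):
            community.alleles_view[a, slot] = True
            events.append((int(a), slot))
    return opportunities, len(events), events


def invent(community, registry: LocusRegistry, cfg: SimConfig,
           rng: np.random.Generator, t: int,
           ) -> list[tuple[int, int]]:
    """Stochastic invention of new tradition loci.

    Each agent independently, with probability ``invention_rate`` per
    update, either (a) creates one new component locus under one of the
    institutions whose apex allele it holds (institution chosen uniformly,
    then the parent locus uniformly within its tree), or (b) if it holds no apex allele, acquires one of the
    globally available apex loci (first acquisition of an apex counts as an
    invention draw against the apex).

    An invention (a new component, or first acquisition of an apex) is a
    demonstrated, social act: besides the inventor, a random
    ``invention_seed_fraction`` share of the community adopts the practice
    immediately (a lone novel allele cannot otherwise survive the
    conformity penalty long enough to be observed).

    Returns ``(agent, new_or_acquired_slot)`` events, one per inventor.
    """
    if cfg.invention_rate == 0.0 or community.n == 0:
        return []
    inventors = np.flatnonzero(rng.random(community.n) < cfg.invention_rate)
    events: list[tuple[int, int]] = []
    for i in inventors:
        alleles = community.alleles_view
        held_apexes = [s for s in registry.apex_slots if alleles[i, s]]
        if not held_apexes:
            slot = int(registry.apex_slots[rng.integers(
                len(registry.apex_slots))])
            n_seed = int(round(cfg.invention_seed_fraction * community.n))
            if n_seed > 1:
                co = rng.choice(community.n, size=n_seed, replace=False)
                community.alleles_view[co, slot] = True
        else:
            # innovation attention is split evenly over held institutions:
            # pick one, then a uniform locus inside its tree as the parent
            apex = held_apexes[rng.integers(len(held_apexes))]
            tree = [apex] + [int(s) for s in registry.tree_components(apex)]
            parent = tree[rng.integers(len(tree))]
            slot = registry.add_component(parent, t)
            community.ensure_width(registry.width)
            n_seed = int(round(cfg.invention_seed_fraction * community.n))
            if n_seed > 1:
                co = rng.choice(community.n, size=n_seed, replace=False)
                community.alleles_view[co, slot] = True
        community.alleles_view[i, slot] = True
        events.append((int(i), slot))
    return events
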