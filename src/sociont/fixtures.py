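"""Deterministic synthetic world states and the fission (split) harness.

These are first-class generators of study conditions, not ad hoc test
helpers: they construct communities with prescribed institution trees and
allele densities, and the split harness measures sociont-inheritance
fidelity at a fixed complexity class by running a lineage of communities
through repeated grow–fission cycles at the model's own steady-state allele
densities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import config as _config
from . import metrics, world as _world
from .config import SimConfig, override, preset
from .world import World, disperse, seed_world, step

__all__ = ["make_fixture", "harness_config", "SplitHarnessResult",
           "run_split_harness"]


def harness_config(**overrides) -> SimConfig:
    """BASE configuration restricted to a small closed arena with a fixed
    institution repertoire (no invention)."""
    base = dict(grid_size=(12, 12), invention_rate=0.0)
    base.update(overrides)
    return override(preset("BASE"), **base)


def _random_recursive_tree(registry, apex_slot: int, k: int,
                           rng: np.random.Generator, t: int = 0) -> list[int]:
    """Grow the apex's tree to complexity ``k`` by attaching each new
    component to a uniformly chosen existing locus."""
    slots = [apex_slot]
    for _ in range(k - 1):
        parent = slots[int(rng.integers(len(slots)))]
        slots.append(registry.add_component(parent, t))
    return slots


def _seed_alleles(com, slots, density: float, rng: np.random.Generator) -> None:
    n = com.n
    carriers = int(round(density * n))
    if carriers < 1:
        raise ValueError(
            f"unsatisfiable allele density: {density} * {n} members < 1 carrier")
    for slot in slots:
        idx = rng.choice(n, size=min(carriers, n), replace=False)
        com.alleles_view[idx, slot] = True


def _populate(world: World, com, n: int, cfg: SimConfig,
              rng: np.random.Generator, adult_fraction: float | None = None) -> None:
    for i in range(n):
        if adult_fraction is not None and i < int(adult_fraction * n):
            age = float(rng.uniform(cfg.adult_age, cfg.adult_age + 20))
        else:
            age = float(np.clip(rng.exponential(14.0), 0.0, 44.0))
        com.add_agent(age=age, energy=cfg.cost_of_living,
                      buffer=float(rng.uniform(0, cfg.reproduction_threshold)),
                      rank=0.0, capacity=cfg.cognition_baseline)


def _claim_disc(world: World, com, center: tuple[float, float],
                n_cells: int) -> None:
    nrows, ncols = world.shape
    rr, cc = np.indices(world.shape)
    d2 = (rr - center[0]) ** 2 + (cc - center[1]) ** 2
    free = world.owner.ravel() == _world.UNOCCUPIED
    if n_cells > int(free.sum()):
        raise ValueError(
            f"fixture needs {n_cells} free cells; only {int(free.sum())} "
            f"available on grid {world.shape}")
    flat_order = np.argsort(d2.ravel() + np.where(free, 0, 1e12),
                            kind="stable")[:n_cells]
    com.set_cells(set(int(i) for i in flat_order))
    world.owner.ravel()[flat_order] = com.id


def make_fixture(kind: str, *, seed: int, k: int = 5, density: float = 0.85,
                 n_agents: int | None = None, cfg: SimConfig | None = None,
                 k2: int | None = None, k_boost: int = 0,
                 land_per_agent: float = 3.0) -> World:
    """Deterministic small world states.

    ``kind='community'``: one community carrying a complexity-``k``
    carnivory institution with allele density ``density`` in every tree
    locus (and the basic apex universal).

    ``kind='pair'``: two adjacent communities; the second carries only the
    first ``k2`` loci of the tree (a connected rooted subset).

    ``kind='split'``: a community primed to fission on the next update
    (adult count above the fission threshold).

    With ``boost_enabled`` and ``k_boost`` > 0 the community additionally
    carries an SLR-boosting institution of that complexity at the same
    allele density.
    """
    if kind not in ("community", "pair", "split", "tiled"):
        raise ValueError(f"unknown fixture kind {kind!r}")
    cfg = cfg if cfg is not None else harness_config()
    rng = np.random.default_rng(seed)
    w = World(cfg, rng)
    basic = w.registry.add_apex("basic", 0)
    igut = w.registry.add_apex("igut", 0)
    boost_tree: list[int] = []
    if cfg.boost_enabled:
        boost_apex = w.registry.add_apex(_config.BOOST_TARGET, 0)
        if k_boost:
            boost_tree = _random_recursive_tree(w.registry, boost_apex,
                                                k_boost, rng)
    tree = _random_recursive_tree(w.registry, igut, k, rng)
    nrows, ncols = cfg.grid_size

    if kind == "pair":
        if k2 is None:
            k2 = max(1, k - 1)
        n = n_agents if n_agents is not None else \
            int(round(cfg.fission_threshold * 1.6))
        centers = [(nrows / 2.0, ncols * 0.25), (nrows / 2.0, ncols * 0.75)]
        trees = [tree, tree[:k2]]
        for center, slots in zip(centers, trees):
            com = w.new_community()
            com.ensure_width(w.registry.width)
            _populate(w, com, n, cfg, rng, adult_fraction=0.6)
            _claim_disc(w, com, center, 3 * n)
            com.alleles_view[:, basic] = True
            _seed_alleles(com, slots, density, rng)
        return w

    if kind == "tiled":
        # fill the arena with a grid of identical communities: the study
        # condition for group-level selection experiments
        n = n_agents if n_agents is not None else \
            int(round(cfg.fission_threshold * 1.6))
        tiles = max(2, int((nrows * ncols
                            / max(1.0, 1.3 * land_per_agent * n)) ** 0.5))
        for ti in range(tiles):
            for tj in range(tiles):
                center = (nrows * (ti + 0.5) / tiles,
                          ncols * (tj + 0.5) / tiles)
                com = w.new_community()
                com.ensure_width(w.registry.width)
                _populate(w, com, n, cfg, rng, adult_fraction=0.6)
                _claim_disc(w, com, center, int(land_per_agent * n))
                com.alleles_view[:, basic] = True
                _seed_alleles(com, tree, density, rng)
                if boost_tree:
                    _seed_alleles(com, boost_tree, density, rng)
        return w

    if kind == "split":
        n = n_agents if n_agents is not None else \
            int((cfg.fission_threshold + 2) / 0.6)
        adult_fraction = (cfg.fission_threshold + 2) / n
    else:
        n = n_agents if n_agents is not None else \
            int(round(cfg.fission_threshold * 1.6))
        adult_fraction = 0.6
    com = w.new_community()
    com.ensure_width(w.registry.width)
    _populate(w, com, n, cfg, rng, adult_fraction=min(1.0, adult_fraction))
    _claim_disc(w, com, ((nrows - 1) / 2.0, (ncols - 1) / 2.0),
                int(land_per_agent * n))
    com.alleles_view[:, basic] = True
    _seed_alleles(com, tree, density, rng)
    if boost_tree:
        _seed_alleles(com, boost_tree, density, rng)
    return w


# ---------------------------------------------------------------------------
# Split harness


@dataclass
class SplitHarnessResult:
    """Outcomes of repeated fission events at a fixed parent class."""

    target_class: int
    records: list[tuple[int, int | None, int | None]] = field(
        default_factory=list)          # (parent_class, class_a, class_b)
    off_class_splits: int = 0
    resets: int = 0
    updates_run: int = 0

    @property
    def n_splits(self) -> int:
        return len(self.records)

    @property
    def daughters(self) -> list[int]:
        out = []
        for _, a, b in self.records:
            out.extend(c for c in (a, b) if c is not None)
        return out

    @property
    def n_daughters(self) -> int:
        return len(self.daughters)

    @property
    def losses(self) -> int:
        return sum(1 for c in self.daughters if c < self.target_class)

    @property
    def loss_fraction(self) -> float:
        """Per-daughter probability of a complexity-class drop
        (1 - fidelity; the reduction in effective fecundity)."""
        n = self.n_daughters
        return self.losses / n if n else float("nan")

    @property
    def fidelity(self) -> float:
        return 1.0 - self.loss_fraction


def run_split_harness(k: int, n_splits: int, seed: int,
                      cfg: SimConfig | None = None, density: float = 0.85,
                      burn_in_splits: int = 3, per_lineage_cap: int = 12,
                      lineage_update_cap: int = 8000,
                      max_updates: int = 2_000_000) -> SplitHarnessResult:
    """Measure per-daughter inheritance fidelity at complexity class ``k``.

    Many independent lineages are simulated under the full update process
    (learning, demography, territory) with a fixed institution repertoire.
    Each lineage starts from a fresh fixture community, equilibrates for
    ``burn_in_splits`` fissions, and then contributes the settled classes
    of both daughters for every split whose parent measured class ``k`` —
    up to ``per_lineage_cap`` splits, or until the lineage loses the class
    (no daughter at class ``k`` remains to carry it on), after which the
    next lineage starts.  Measurement therefore always conditions on
    class-``k`` parents at the model's own steady-state allele densities.
    """
    cfg = cfg if cfg is not None else harness_config()
    result = SplitHarnessResult(target_class=k)
    lineage = 0
    while result.n_splits < n_splits:
        if result.updates_run >= max_updates:
            raise RuntimeError(
                f"split harness exceeded {max_updates} updates with "
                f"{result.n_splits}/{n_splits} splits recorded")
        w = make_fixture("community", seed=seed + 1009 * lineage, k=k,
                         density=density, cfg=cfg)
        lineage += 1
        result.resets += 1
        seen = 0
        burned = 0
        recorded_here = 0
        alive = True
        for _ in range(lineage_update_cap):
            step(w)
            result.updates_run += 1
            if len(w.split_events) == seen:
                if not w.communities:
                    alive = False
                    break
                continue
            new_events = w.split_events[seen:]
            seen = len(w.split_events)
            for ev in new_events:
                if burned < burn_in_splits:
                    burned += 1
                elif ev.parent_class == k:
                    result.records.append((ev.parent_class,
                                           ev.daughter_classes[0],
                                           ev.daughter_classes[1]))
                    recorded_here += 1
                else:
                    result.off_class_splits += 1
            # continue through one daughter that kept the class
            live = w.sorted_communities()
            keeper = None
            for com in live:
                if metrics.complexity_class(com, w).cls >= k:
                    keeper = com
                    break
            if keeper is None:
                if burned < burn_in_splits and live:
                    keeper = max(live, key=lambda c: c.n)
                else:
                    alive = False
                    break
            for com in list(live):
                if com.id != keeper.id:
                    disperse(w, com)
            if recorded_here >= per_lineage_cap \
                    or result.n_splits >= n_splits:
                break
        del alive
    result.resets -= 1   # count restarts beyond the first lineage
    return result


def _healthy(w: World, com, k: int) -> bool:
    """A community fit to anchor the lineage: measured class >= k and no
    tree locus drifted rare (an archive holding a nearly-extinct locus
    would make every restart replay a foregone loss)."""
    if metrics.complexity_class(com, w).cls < k:
        return False
    igut = w.registry.apex_by_target["igut"]
    slots = [igut] + [int(s) for s in w.registry.tree_components(igut)]
    floor = max(2.0, 0.25 * com.n)
    al = com.alleles_view
    return all(al[:, s].sum() >= floor for s in slots)
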