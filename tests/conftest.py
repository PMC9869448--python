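import numpy as np
import pytest

from sociont.config import SimConfig, override, preset
from sociont.world import World


@pytest.fixture
def base_cfg() -> SimConfig:
    return preset("BASE")


@pytest.fixture
def small_cfg() -> SimConfig:
    return override(preset("BASE"), grid_size=(24, 24))


def bare_world(cfg: SimConfig, seed: int = 0,
               targets: tuple[str, ...] = ("basic", "igut")) -> World:
    """World with apex loci registered but no communities."""
    w = World(cfg, np.random.default_rng(seed))
    for t in targets:
        w.registry.add_apex(t, 0)
    return w


def manual_community(world: World, ages, cells=None, energy=None):
    """Community with prescribed member ages and a simple territory."""
    cfg = world.cfg
    com = world.new_community()
    com.ensure_width(world.registry.width)
    for i, a in enumerate(ages):
        e = cfg.cost_of_living if energy is None else energy[i]
        com.add_agent(age=float(a), energy=float(e),
                      capacity=cfg.cognition_baseline)
    ncols = world.shape[1]
    if cells is None:
        k = max(3 * len(ages), cfg.min_territory)
        cells = [r * ncols + c for r in range(world.shape[0])
                 for c in range(ncols)][:k]
    com.set_cells(set(int(c) for c in cells))
    for c in com.territory:
        world.owner.ravel()[c] = com.id
    return com
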