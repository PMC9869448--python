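"""Resource access curves and harvesting with tolerated theft.

Extraction efficiency follows a saturating hyperbola of institutional
complexity (Michaelis–Menten shape): monotone increasing, concave,
approaching but never reaching the resource ceiling.  Harvested energy goes
first to the performer; the non-monopolizable fraction is split equally over
the whole community.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import ResourceSpec, SimConfig, default_resources

__all__ = ["access", "access_array", "harvest", "HarvestLedger",
           "default_resources"]


def access(curve: ResourceSpec, complexity: float) -> float:
    """Extraction efficiency at the given institutional complexity.

    ``access(0) == access_base``; strictly increasing; always below
    ``access_ceiling`` for finite complexity.
    """
    c = float(complexity)
    if c < 0:
        raise ValueError(f"complexity must be >= 0, got {complexity}")
    span = curve.access_ceiling - curve.access_base
    return curve.access_base + span * c / (c + curve.access_halfsat)


def access_array(curve: ResourceSpec, complexity: np.ndarray) -> np.ndarray:
    c = np.asarray(complexity, dtype=np.float64)
    span = curve.access_ceiling - curve.access_base
    return curve.access_base + span * c / (c + curve.access_halfsat)


@dataclass
class HarvestLedger:
    """Per-update energy credited, per agent and per resource."""

    per_agent: np.ndarray                     # (n,) total credit this update
    per_resource: dict[str, float] = field(default_factory=dict)
    gross: dict[str, float] = field(default_factory=dict)  # pre-division totals

    @property
    def total(self) -> float:
        return float(sum(self.per_resource.values()))


def harvest(community, best_realized: dict[str, np.ndarray],
            cfg: SimConfig) -> HarvestLedger:
    """Allocate this update's extraction across community members.

    ``best_realized[r]`` holds, per member, the best realized complexity of
    an apex performance targeting resource ``r`` this update (0 = none).
    For the basic resource non-performers claim the culture-free baseline
    (adults always; juveniles when ``juveniles_forage``).  Each member's
    gross extraction is ``density * (area / N) * efficiency`` per update;
    the performer keeps the monopolizable share and the rest is divided
    equally (tolerated theft).  Total credited equals total extracted.
    """
    n = community.n
    if n == 0:
        raise RuntimeError(
            f"harvest on empty community {community.id}; it should have dispersed")
    area = community.territory_size
    per_agent = np.zeros(n)
    ledger = HarvestLedger(per_agent=per_agent)
    per_capita_land = area / n
    for spec in cfg.resources:
        real = best_realized.get(spec.name)
        if real is None:
            real = np.zeros(n)
        # access(0) == access_base, so non-performers fall back to the
        # culture-free baseline (zero for carnivory) automatically
        e = access_array(spec, real)
        if spec.access_base > 0.0 and not cfg.juveniles_forage:
            juvenile = community.age < cfg.adult_age
            e = np.where(juvenile & (real == 0), 0.0, e)
        g = spec.density * per_capita_land * e * cfg.dt
        total = float(g.sum())
        credit = spec.monopolizability * g + (1.0 - spec.monopolizability) * total / n
        per_agent += credit
        ledger.per_resource[spec.name] = float(credit.sum())
        ledger.gross[spec.name] = total
    community.energy[:] += per_agent
    community.rank_score[:] += per_agent
    return ledger
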