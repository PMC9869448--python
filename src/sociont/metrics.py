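"""Measured quantities: complexity class, sociont-inheritance fidelity,
extraction efficiency, measured social-learning rate, class occupancy and
glass-ceiling (equilibrium complexity) detection.

A community's *complexity class* is the maximum complexity at which a high
and stable proportion of its adults successfully perform the carnivory
institution: the largest ``c`` such that the fraction of adults whose best
realized complexity over the trailing window reaches ``c`` is at least
``class_threshold``.  *Fidelity* at class ``k`` is the frequency with which
daughter communities of class-``k`` parents do not drop below ``k`` after
the settling window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "ComplexityClassEstimate", "complexity_class", "fidelity",
    "measured_slr", "efficiency", "class_occupancy", "glass_ceiling",
    "GlassCeilingEstimate", "sample_row",
]


@dataclass(frozen=True)
class ComplexityClassEstimate:
    community: int
    update: int
    cls: int
    supporting_fraction: float
    provisional: bool


def complexity_class(community, world) -> ComplexityClassEstimate:
    """Class of the carnivory institution from the trailing performance
    window (class 0 when no adult performed its apex)."""
    cfg = world.cfg
    adults = community.age >= cfg.adult_age
    n_adults = int(adults.sum())
    provisional = (world.t - community.birth_time) < cfg.class_window
    if n_adults == 0:
        return ComplexityClassEstimate(community.id, world.t, 0, 0.0,
                                       provisional)
    wbest = community.window_best()[adults]
    top = int(wbest.max())
    if top == 0:
        return ComplexityClassEstimate(community.id, world.t, 0, 0.0,
                                       provisional)
    counts = np.bincount(wbest, minlength=top + 1)
    frac_at_least = counts[::-1].cumsum()[::-1] / n_adults
    qualifying = np.flatnonzero(frac_at_least[1:] >= cfg.class_threshold) + 1
    if len(qualifying) == 0:
        return ComplexityClassEstimate(community.id, world.t, 0,
                                       float(frac_at_least[1]), provisional)
    cls = int(qualifying.max())
    return ComplexityClassEstimate(community.id, world.t, cls,
                                   float(frac_at_least[cls]), provisional)


def fidelity(split_events, per_split: bool = False) -> pd.DataFrame:
    """Fidelity curve grouped by parent complexity class.

    Per-daughter counting (default): fidelity(k) = fraction of settled
    daughters of class-k parents whose class is >= k.  ``per_split`` counts
    a split as faithful only when both daughters retained the class.
    Daughters that did not survive to settling are excluded from the
    fraction and reported in the ``unsettled`` column.  Wilson 95% CIs.
    """
    rows: dict[int, dict[str, int]] = {}
    for ev in split_events:
        if not ev.settled or ev.daughter_classes is None:
            continue
        k = ev.parent_class
        rec = rows.setdefault(k, {"events": 0, "obs": 0, "kept": 0,
                                  "unsettled": 0})
        rec["events"] += 1
        classes = [c for c in ev.daughter_classes if c is not None]
        rec["unsettled"] += 2 - len(classes)
        if per_split:
            if len(classes) == 2:
                rec["obs"] += 1
                rec["kept"] += int(all(c >= k for c in classes))
            else:
                rec["unsettled"] += 0
        else:
            rec["obs"] += len(classes)
            rec["kept"] += sum(int(c >= k) for c in classes)
    out = []
    for k in sorted(rows):
        rec = rows[k]
        obs, kept = rec["obs"], rec["kept"]
        fid = kept / obs if obs else np.nan
        if obs:
            lo, hi = proportion_confint(kept, obs, alpha=0.05,
                                        method="wilson")
        else:
            lo = hi = np.nan
        out.append({"parent_class": k, "events": rec["events"],
                    "observations": obs, "kept": kept,
                    "unsettled": rec["unsettled"], "fidelity": fid,
                    "ci_low": lo, "ci_high": hi})
    return pd.DataFrame(out, columns=["parent_class", "events",
                                      "observations", "kept", "unsettled",
                                      "fidelity", "ci_low", "ci_high"])


def measured_slr(successes: int, opportunities: int) -> float:
    """Successful learning events per 1000 observation opportunities."""
    if opportunities == 0:
        return 0.0
    return 1000.0 * successes / opportunities


def efficiency(total_energy: float, occupied_cells: float, population: float,
               years: float) -> float:
    """Average extraction per unit area, agent and year."""
    denom = occupied_cells * population * years
    if denom == 0:
        return 0.0
    return total_energy / denom


def class_occupancy(class_list, max_class: int | None = None) -> np.ndarray:
    """Fractions of communities in each complexity class (sums to 1)."""
    classes = np.asarray(class_list, dtype=int)
    if len(classes) == 0:
        return np.zeros(1 if max_class is None else max_class + 1)
    top = int(classes.max()) if max_class is None else max_class
    counts = np.bincount(classes, minlength=top + 1)
    return counts / counts.sum()


@dataclass(frozen=True)
class GlassCeilingEstimate:
    estimate: float
    converged: bool
    slope: float
    slope_ci: tuple[float, float]
    n_samples: int


def glass_ceiling(mean_class_series, min_samples: int = 12,
                  tail_fraction: float = 1.0 / 3.0) -> GlassCeilingEstimate:
    """Equilibrium complexity from the trailing part of a run.

    The estimate is the mean of the population-weighted class over the last
    ``tail_fraction`` of samples; it is flagged converged only when the
    95% CI of the linear trend over that tail contains zero (stationarity).
    A run too short for the test is explicitly not converged.
    """
    y = np.asarray(mean_class_series, dtype=float)
    y = y[~np.isnan(y)]
    n_tail = int(len(y) * tail_fraction)
    if n_tail < min_samples:
        return GlassCeilingEstimate(float(y[-1]) if len(y) else np.nan,
                                    False, np.nan, (np.nan, np.nan), n_tail)
    tail = y[-n_tail:]
    est = float(tail.mean())
    if np.allclose(tail, tail[0]):
        return GlassCeilingEstimate(est, True, 0.0, (0.0, 0.0), n_tail)
    res = stats.linregress(np.arange(n_tail), tail)
    tcrit = stats.t.ppf(0.975, n_tail - 2)
    ci = (res.slope - tcrit * res.stderr, res.slope + tcrit * res.stderr)
    converged = ci[0] <= 0.0 <= ci[1]
    return GlassCeilingEstimate(est, bool(converged), float(res.slope),
                                (float(ci[0]), float(ci[1])), n_tail)


# ---------------------------------------------------------------------------
# Time-series sampling

_MAX_OCC_CLASS = 12


def sample_row(world) -> dict:
    """One metrics row: demography, class structure, learning and
    harvesting rates over the sampling interval."""
    cfg = world.cfg
    registry = world.registry
    coms = world.sorted_communities()
    pops = np.array([c.n for c in coms], dtype=float)
    classes = np.array([complexity_class(c, world).cls for c in coms],
                       dtype=float)
    pop = float(pops.sum())
    mean_class = float((classes * pops).sum() / pop) if pop else np.nan
    occ = class_occupancy(classes.astype(int) if len(classes) else [],
                          max_class=_MAX_OCC_CLASS) \
        if len(classes) else np.zeros(_MAX_OCC_CLASS + 1)
    total_energy = float(sum(world.acc_energy.values()))
    years = cfg.metrics_interval * cfg.dt
    occupied = world.occupied_cells
    row = {
        "update": world.t,
        "n_communities": len(coms),
        "population": int(pop),
        "adults": int(sum((c.age >= cfg.adult_age).sum() for c in coms)),
        "occupied_cells": occupied,
        "mean_class": mean_class,
        "max_class": float(classes.max()) if len(classes) else np.nan,
        "measured_slr": measured_slr(world.acc_successes,
                                     world.acc_opportunities),
        "efficiency": efficiency(total_energy, occupied, pop, years),
        "igut_tree_size": _tree_size(registry, "igut"),
        "boost_tree_size": _tree_size(registry, "slr_boost"),
        "mean_capacity": float(np.mean(np.concatenate(
            [c.capacity for c in coms]))) if pop else np.nan,
        "splits": len(world.split_events) + len(world.pending_splits),
        "dispersals": world.dispersals,
        "births": world.births,
        "deaths": world.deaths,
    }
    for name, val in sorted(world.acc_energy.items()):
        row[f"energy_{name}"] = val
    for k in range(_MAX_OCC_CLASS + 1):
        row[f"occ_{k}"] = float(occ[k]) if k < len(occ) else 0.0
    return row


def _tree_size(registry, target: str) -> float:
    slot = registry.apex_by_target.get(target)
    if slot is None:
        return np.nan
    return float(registry.tree_complexity(slot))
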