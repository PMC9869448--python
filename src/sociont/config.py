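"""Scenario configuration: parameters, validation, presets and (de)serialization.

All rates are expressed per *year*; the scheduler divides them by
``updates_per_year`` so that one model update represents a fixed fraction of
a year.  The social learning rate (``slr``) is the expected number of
successful learning events per 1000 observation opportunities, so the
per-opportunity success probability is ``slr / 1000``.

The numeric defaults below define the BASE scenario.  They are surrogate
values chosen and calibrated by this package (see ``docs/methods.md``): an
unaided community equilibrates at roughly one agent per three cells and
splits every few hundred updates, and under the default learning rate the
equilibrium complexity class of the carnivory institution sits near 5.
"""

from __future__ import annotations

import dataclasses
import json
import pathlib
from dataclasses import dataclass, field
from typing import Any

import yaml

__all__ = [
    "ResourceSpec",
    "SimConfig",
    "ConfigError",
    "load_config",
    "preset",
    "config_to_dict",
    "save_config",
    "PRESET_NAMES",
]

BOOST_TARGET = "slr_boost"


class ConfigError(ValueError):
    """A configuration file or mapping violates the documented contract."""


@dataclass(frozen=True)
class ResourceSpec:
    """An extractable resource and its returns-to-complexity profile.

    ``access(c) = access_base + (access_ceiling - access_base) * c / (c + access_halfsat)``
    maps institutional complexity ``c`` to extraction efficiency.
    ``monopolizability`` is the share of an extraction kept by the performer;
    the remainder is shared equally within the community (tolerated theft).
    ``density`` is energy available per grid cell per year.
    """

    name: str
    density: float
    monopolizability: float
    access_base: float
    access_ceiling: float
    access_halfsat: float

    def validate(self) -> None:
        if not self.name:
            raise ConfigError("resource name must be non-empty")
        _check_range(f"resources[{self.name}].monopolizability",
                     self.monopolizability, 0.0, 1.0)
        if self.density <= 0:
            raise ConfigError(
                f"resources[{self.name}].density = {self.density}; must be > 0")
        if self.access_halfsat <= 0:
            raise ConfigError(
                f"resources[{self.name}].access_halfsat = {self.access_halfsat}; must be > 0")
        if not (0.0 <= self.access_base < self.access_ceiling <= 1.0):
            raise ConfigError(
                f"resources[{self.name}]: need 0 <= access_base < access_ceiling <= 1, "
                f"got base={self.access_base}, ceiling={self.access_ceiling}")


def default_resources() -> list[ResourceSpec]:
    """The two-resource setup: an opportunistic basic resource and carnivory.

    The basic resource is foragable without culture (positive baseline
    access), highly monopolizable, and its cultural returns level off almost
    immediately (halfsat 1).  The IGUT/carnivory resource (large animal
    carcasses) is inaccessible without socially learned strategies (zero
    baseline), poorly monopolizable, and rewards complexity steadily up to a
    high ceiling (halfsat 6).
    """
    return [
        ResourceSpec(name="basic", density=1.2, monopolizability=0.95,
                     access_base=0.30, access_ceiling=0.40, access_halfsat=1.0),
        ResourceSpec(name="igut", density=4.0, monopolizability=0.20,
                     access_base=0.0, access_ceiling=0.85, access_halfsat=8.0),
    ]


@dataclass
class SimConfig:
    # -- world ----------------------------------------------------------
    grid_size: tuple[int, int] = (200, 200)
    updates_per_year: int = 10
    seed: int = 0

    # -- social learning ------------------------------------------------
    slr: float = 50.0                 # successful learning events / 1000 opportunities
    rank_bias: float = 0.0            # multiplier on the model agent's rank percentile
    conformity_exponent: float = 0.45  # rarity-penalty exponent on relative expression density
    invention_rate: float = 3e-5      # new-locus probability per agent per update
    observation_rate: float = 1.3     # mean observation opportunities per agent per update
    invention_seed_fraction: float = 0.12   # share of the community co-adopting a fresh invention

    # -- energetics -----------------------------------------------------
    allele_expression_cost: float = 0.01    # energy per expression (per update)
    cost_of_living: float = 1.0             # energy per year
    reproduction_threshold: float = 9.0     # buffer energy needed to reproduce
    adult_age: float = 10.0                 # years

    # -- mortality (hazards per year) ------------------------------------
    mortality_baseline: float = 0.02
    mortality_age_coeff: float = 1.2
    mortality_age_exponent: float = 5.0
    senescence_age: float = 45.0            # age scale of the senescent term
    starvation_hazard: float = 1.0          # extra hazard while energy < 0

    # -- community lifecycle --------------------------------------------
    fission_mode: str = "population_threshold"  # or "constant_rate"
    fission_threshold: int = 16       # adults; split when strength exceeds this
    fission_rate: float = 0.004       # per community per update (constant_rate mode)
    min_population: int = 6           # adults; disperse below this
    min_territory: int = 8            # cells; disperse below this

    # -- territoriality -------------------------------------------------
    unoccupied_cell_power: float = 2.0
    contest_steepness: float = 4.0
    contest_rate: float = 0.25        # per-update probability scale of cell contest
    power_abatement: float = 0.05     # strength abatement per cell of distance

    # -- resources ------------------------------------------------------
    resources: list[ResourceSpec] = field(default_factory=default_resources)
    juveniles_forage: bool = True     # juveniles claim baseline basic access too

    # -- SLR-boosting institution ----------------------------------------
    boost_enabled: bool = False
    boost_coefficient: float = 2.0    # boost per unit of booster complexity

    # -- heritable cognitive capacity ------------------------------------
    genetics_enabled: bool = False
    cognition_baseline: float = 2.0
    cognition_cost_per_unit: float = 0.05   # energy per year per capacity unit
    cognition_mutation_sd: float = 0.25
    cognition_decoupled: bool = False       # capacity paid for but without effect

    # -- measurement ----------------------------------------------------
    class_threshold: float = 0.25     # supporting adult fraction defining a class
    class_window: int = 40            # trailing window (updates) for class estimation
    settling_window: int = 25         # updates before a daughter's class is recorded
    fidelity_per_split: bool = False  # count fidelity per split instead of per daughter
    metrics_interval: int = 10        # updates between metrics rows

    # -- declared sweep (SLR_SWEEP preset) -------------------------------
    sweep_parameter: str | None = None
    sweep_values: list[float] | None = None

    # ------------------------------------------------------------------
    def __post_init__(self) -> None:
        self.validate()

    @property
    def dt(self) -> float:
        """Years per update."""
        return 1.0 / self.updates_per_year

    @property
    def learn_prob(self) -> float:
        """Per-opportunity learning success probability."""
        return self.slr / 1000.0

    def resource(self, name: str) -> ResourceSpec:
        for r in self.resources:
            if r.name == name:
                return r
        raise KeyError(name)

    def apex_targets(self) -> list[str]:
        """Targets for which an apex locus exists from the start."""
        targets = [r.name for r in self.resources]
        if self.boost_enabled:
            targets.append(BOOST_TARGET)
        return targets

    # -- validation -----------------------------------------------------
    def validate(self) -> None:
        if isinstance(self.grid_size, list):
            self.grid_size = tuple(self.grid_size)  # type: ignore[assignment]
        if (len(self.grid_size) != 2
                or any(int(g) != g or g < 4 for g in self.grid_size)):
            raise ConfigError(
                f"grid_size = {self.grid_size!r}; must be a pair of integers >= 4")
        self.grid_size = (int(self.grid_size[0]), int(self.grid_size[1]))
        if self.updates_per_year < 1:
            raise ConfigError(
                f"updates_per_year = {self.updates_per_year}; must be >= 1")
        _check_range("slr/1000 (per-opportunity probability)",
                     self.learn_prob, 0.0, 1.0)
        for key in ("rank_bias", "conformity_exponent", "allele_expression_cost",
                    "cost_of_living", "reproduction_threshold", "adult_age",
                    "mortality_baseline", "mortality_age_coeff",
                    "mortality_age_exponent", "starvation_hazard",
                    "power_abatement", "boost_coefficient", "cognition_baseline",
                    "cognition_cost_per_unit", "cognition_mutation_sd"):
            v = getattr(self, key)
            if v < 0:
                raise ConfigError(f"{key} = {v}; must be >= 0")
        if self.observation_rate < 0:
            raise ConfigError(
                f"observation_rate = {self.observation_rate}; must be >= 0")
        for key in ("invention_rate", "fission_rate", "contest_rate",
                    "class_threshold", "invention_seed_fraction"):
            _check_range(key, getattr(self, key), 0.0, 1.0)
        for key in ("senescence_age", "unoccupied_cell_power",
                    "contest_steepness"):
            v = getattr(self, key)
            if v <= 0:
                raise ConfigError(f"{key} = {v}; must be > 0")
        if self.fission_mode not in ("population_threshold", "constant_rate"):
            raise ConfigError(
                f"fission_mode = {self.fission_mode!r}; must be "
                "'population_threshold' or 'constant_rate'")
        for key in ("fission_threshold", "min_population", "min_territory",
                    "class_window", "settling_window", "metrics_interval"):
            v = getattr(self, key)
            if int(v) != v or v < 1:
                raise ConfigError(f"{key} = {v}; must be a positive integer")
            setattr(self, key, int(v))
        if self.min_population >= self.fission_threshold:
            raise ConfigError(
                f"min_population = {self.min_population} must be < "
                f"fission_threshold = {self.fission_threshold}")
        if not self.resources:
            raise ConfigError("resources must be a non-empty list")
        self.resources = [r if isinstance(r, ResourceSpec)
                          else ResourceSpec(**r) for r in self.resources]
        names = [r.name for r in self.resources]
        if len(set(names)) != len(names):
            raise ConfigError(f"duplicate resource names: {names}")
        for r in self.resources:
            r.validate()


def _check_range(key: str, value: float, lo: float, hi: float) -> None:
    if not (lo <= value <= hi):
        raise ConfigError(f"{key} = {value}; must be in [{lo}, {hi}]")


# ---------------------------------------------------------------------------
# Presets

PRESET_NAMES = ("BASE", "SLR_SWEEP", "COEVO_BOOST", "COEVO_GENES")


def preset(name: str) -> SimConfig:
    """Return one of the four scenario presets.

    BASE: the reference configuration (slr 50, no booster, no genetics).
    SLR_SWEEP: BASE plus a declared sweep over slr.
    COEVO_BOOST: slr 30 with the SLR-boosting institution enabled.
    COEVO_GENES: COEVO_BOOST plus heritable cognitive capacity, 500x500 grid.
    """
    if name == "BASE":
        return SimConfig()
    if name == "SLR_SWEEP":
        return SimConfig(sweep_parameter="slr",
                         sweep_values=[20.0, 35.0, 50.0, 65.0, 80.0])
    if name == "COEVO_BOOST":
        return SimConfig(slr=30.0, boost_enabled=True)
    if name == "COEVO_GENES":
        return SimConfig(slr=30.0, boost_enabled=True, genetics_enabled=True,
                         grid_size=(500, 500))
    raise ConfigError(
        f"unknown preset {name!r}; expected one of {PRESET_NAMES}")


# ---------------------------------------------------------------------------
# Loading / serialization

_FIELD_NAMES = {f.name for f in dataclasses.fields(SimConfig)}


def _config_from_mapping(mapping: dict[str, Any]) -> SimConfig:
    if not isinstance(mapping, dict):
        raise ConfigError(
            f"configuration must be a mapping, got {type(mapping).__name__}")
    unknown = sorted(set(mapping) - _FIELD_NAMES)
    if unknown:
        raise ConfigError(f"unknown configuration keys: {unknown}")
    kwargs = dict(mapping)
    if "resources" in kwargs and kwargs["resources"] is not None:
        specs = []
        for item in kwargs["resources"]:
            if isinstance(item, ResourceSpec):
                specs.append(item)
            elif isinstance(item, dict):
                extra = set(item) - {f.name for f in
                                     dataclasses.fields(ResourceSpec)}
                if extra:
                    raise ConfigError(
                        f"unknown resource keys: {sorted(extra)}")
                specs.append(ResourceSpec(**item))
            else:
                raise ConfigError(
                    f"resource entries must be mappings, got {item!r}")
        kwargs["resources"] = specs
    return SimConfig(**kwargs)


def load_config(path: str | pathlib.Path) -> SimConfig:
    """Load and validate a YAML or JSON scenario file.

    Unspecified keys take BASE defaults; unknown keys are an error (this
    guards against silently ignored typos).  An empty file yields the BASE
    preset verbatim.
    """
    path = pathlib.Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    try:
        if path.suffix == ".json":
            mapping = json.loads(text) if text.strip() else {}
        else:
            mapping = yaml.safe_load(text)
    except (yaml.YAMLError, json.JSONDecodeError) as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if mapping is None:
        mapping = {}
    return _config_from_mapping(mapping)


def config_to_dict(cfg: SimConfig) -> dict[str, Any]:
    d = dataclasses.asdict(cfg)
    d["grid_size"] = list(cfg.grid_size)
    return d


def save_config(cfg: SimConfig, path: str | pathlib.Path) -> None:
    path = pathlib.Path(path)
    with path.open("w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=True)


def override(cfg: SimConfig, **overrides: Any) -> SimConfig:
    """Return a validated copy of ``cfg`` with fields replaced."""
    d = config_to_dict(cfg)
    d.update(overrides)
    return _config_from_mapping(d)
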