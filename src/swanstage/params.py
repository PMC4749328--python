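"""Model parameters, domain types, and configuration I/O.

The parameter set describes autumn-staging Bewick's swans (*Cygnus columbianus
bewickii*) foraging on fennel pondweed (*Potamogeton pectinatus*) tubers in a
shallow managed lake.  All energies are in joules, rates in SI units, water
levels in metres relative to the Dutch NAP datum, and tuber densities in grams
dry mass per square metre.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

SEDIMENTS = ("sand", "clay")
DEPTH_CLASSES = ("shallow", "deep")

#: Flock size represented by one super-individual.
SUPER_INDIVIDUAL_SIZE = 20

#: Class-mean standardized water depths (m) at the reference water level.
DEFAULT_STD_DEPTH = {"shallow": 0.33, "deep": 0.62}

#: Body masses (g) corresponding to abdominal profile index 2 (arrival) and
#: 5 (departure), used to convert body condition to energy stores.
ARRIVAL_MASS_G = 5182.0
TARGET_MASS_G = 6441.0

#: Alternative fixed cost of one between-inlet flight (J): the value obtained
#: when rounding the flight distance up to 3317 m during intermediate steps.
FLIGHT_COST_TABLE_J = 52699.0


class ConfigError(ValueError):
    """Raised for unparseable or unknown configuration keys."""


class ValidationError(ValueError):
    """Raised when a parameter value violates its physical bounds."""


@dataclass(frozen=True)
class ModelParams:
    """All scalar model parameters with field defaults.

    Patch-type-specific values carry a ``_sand``/``_clay`` or patch-type
    suffix.  ``target_level_m`` is the reference water level at which
    standardized patch depths were measured; scenario sweeps vary the sluice
    target separately while keeping this reference fixed.
    """

    # -- tuber foraging -----------------------------------------------------
    beta_sand: float = 0.00077   # tuber burial-depth shape factor (-)
    beta_clay: float = 0.00090
    e: float = 16866.0           # energy density of tubers (J g^-1)
    f: float = 0.66              # proportion of time spent foraging (-)
    phi_sand: float = 0.76       # proportion of foraging time underwater (-)
    phi_clay: float = 0.72
    a_sand: float = 0.00102      # attack rate (m^2 s^-1)
    a_clay: float = 0.000612
    h: float = 1.82              # handling time (s g^-1)
    b: float = 1.38              # benefit from area-restricted search (-)
    q: float = 0.9               # assimilation efficiency (-)
    c_f_sandy_shallow: float = 45.1   # metabolic rate while foraging (J s^-1)
    c_f_sandy_deep: float = 56.7
    c_f_clayey_shallow: float = 58.6
    c_f_clayey_deep: float = 73.7
    c_r: float = 22.2            # metabolic rate while resting (J s^-1)
    c_p: float = 33.8            # metabolic rate while preening (J s^-1)
    # -- travel -------------------------------------------------------------
    flight_power: float = 204.0        # metabolic rate while flying (J s^-1)
    flight_speed: float = 12.8         # m s^-1
    travel_threshold_m: float = 3316.0  # free movement below this distance (m)
    # fixed cost of one between-inlet flight: distance / speed x power
    flight_cost_J: float = 3316.0 / 12.8 * 204.0
    # -- energy stores ------------------------------------------------------
    lean_mass_g: float = 4660.0
    store_energy_density_J_per_g: float = 27.5e3
    initial_store_J: float = 14.3e6
    target_store_J: float = 49.0e6
    # -- beet fields (emigration alternative) -------------------------------
    p: float = 0.65              # fraction of field gain at switch (-)
    MEI_b: float = 7.50e6        # daily metabolizable intake on fields (J d^-1)
    DEE_b: float = 2.61e6        # daily expenditure on fields (J d^-1)
    # -- water depths and management ----------------------------------------
    depth_min: float = 0.10          # minimum depth suitable for foraging (m)
    depth_headdip_max: float = 0.51  # maximum depth for head-dipping (m)
    depth_reach_max: float = 0.86    # maximum reachable depth (m)
    target_level_m: float = -0.93    # reference target water level (m NAP)
    # -- discretization -----------------------------------------------------
    super_individual_size: int = SUPER_INDIVIDUAL_SIZE
    timestep_s: float = 3600.0

    def __post_init__(self) -> None:
        unit = {"f": self.f, "q": self.q, "phi_sand": self.phi_sand,
                "phi_clay": self.phi_clay}
        for name, v in unit.items():
            if not 0 < v <= 1:
                raise ValidationError(f"{name} must be in (0, 1], got {v}")
        if not 0 <= self.p <= 1:
            raise ValidationError(f"p must be in [0, 1], got {self.p}")
        nonneg = ("beta_sand", "beta_clay", "e", "a_sand", "a_clay", "h",
                  "c_f_sandy_shallow", "c_f_sandy_deep", "c_f_clayey_shallow",
                  "c_f_clayey_deep", "c_r", "c_p", "flight_power",
                  "flight_speed", "travel_threshold_m", "flight_cost_J",
                  "lean_mass_g", "store_energy_density_J_per_g",
                  "MEI_b", "DEE_b", "timestep_s")
        for name in nonneg:
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValidationError(f"{name} must be >= 0, got {v}")
        if self.b < 1:
            raise ValidationError(f"b must be >= 1, got {self.b}")
        if not self.depth_min < self.depth_headdip_max < self.depth_reach_max:
            raise ValidationError("require depth_min < depth_headdip_max < depth_reach_max")
        if not self.initial_store_J < self.target_store_J:
            raise ValidationError("initial_store_J must be below target_store_J")
        if self.super_individual_size <= 0:
            raise ValidationError("super_individual_size must be positive")

    def replace(self, **changes) -> "ModelParams":
        return dataclasses.replace(self, **changes)

    def foraging_cost(self, sediment: str, depth_class: str) -> float:
        """Foraging metabolic rate c_f (J s^-1) for a patch type."""
        key = f"c_f_{'sandy' if sediment == 'sand' else 'clayey'}_{depth_class}"
        return getattr(self, key)


OFF_LAKE = None  # sentinel location for a super-individual not on a patch


@dataclass
class Patch:
    """One inlet x sediment x depth-class foraging unit.

    ``tuber_density_g_m2`` is the state variable depleted during a run.
    """

    inlet_id: str
    sediment: str
    depth_class: str
    area_m2: float
    tuber_density_g_m2: float
    standardized_depth_m: float = float("nan")

    def __post_init__(self) -> None:
        if self.sediment not in SEDIMENTS:
            raise ValidationError(f"sediment must be one of {SEDIMENTS}")
        if self.depth_class not in DEPTH_CLASSES:
            raise ValidationError(f"depth_class must be one of {DEPTH_CLASSES}")
        if np.isnan(self.standardized_depth_m):
            self.standardized_depth_m = DEFAULT_STD_DEPTH[self.depth_class]
        if not self.area_m2 > 0:
            raise ValidationError(f"area_m2 must be > 0, got {self.area_m2}")
        if self.tuber_density_g_m2 < 0:
            raise ValidationError("tuber_density_g_m2 must be >= 0")
        if not 0.10 <= self.standardized_depth_m <= 0.86:
            raise ValidationError(
                f"standardized_depth_m {self.standardized_depth_m} outside [0.10, 0.86]")

    @property
    def patch_type(self) -> str:
        return f"{'sandy' if self.sediment == 'sand' else 'clayey'}-{self.depth_class}"


@dataclass
class SuperIndividual:
    """A flock of swans sharing one state; ``store_J`` is per swan."""

    id: int
    n_swans: int = SUPER_INDIVIDUAL_SIZE
    arrival_step: Optional[int] = None
    arrival_peak: int = 1
    location: Optional[int] = OFF_LAKE  # patch index, or OFF_LAKE
    store_J: float = 0.0
    departure_step: Optional[int] = None
    departure_reason: Optional[str] = None  # target_reached | emigrated_to_fields | never_arrived

    def __post_init__(self) -> None:
        if self.store_J < 0:
            raise ValidationError("store_J must be >= 0")


@dataclass
class WaterLevelSeries:
    """Hourly water levels (m NAP) starting at ``start``."""

    start: pd.Timestamp
    levels: np.ndarray

    def __post_init__(self) -> None:
        self.start = pd.Timestamp(self.start)
        self.levels = np.asarray(self.levels, dtype=float)
        if self.levels.ndim != 1 or len(self.levels) == 0:
            raise ValidationError("levels must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.levels)):
            raise ValidationError("levels must be finite (no gaps)")

    def __len__(self) -> int:
        return len(self.levels)

    @property
    def index(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start, periods=len(self.levels), freq="h")

    def to_series(self) -> pd.Series:
        return pd.Series(self.levels, index=self.index, name="level_m")

    def to_csv(self, path) -> None:
        df = pd.DataFrame({"timestamp": self.index, "level_m": self.levels})
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "WaterLevelSeries":
        df = pd.read_csv(path, parse_dates=["timestamp"])
        if df.empty:
            raise ValidationError(f"empty level series: {path}")
        dt = df["timestamp"].diff().dropna()
        if len(dt) and not (dt == pd.Timedelta(hours=1)).all():
            raise ValidationError(
                f"level series {path} is not strictly hourly (gaps > 1 h rejected)")
        return cls(start=df["timestamp"].iloc[0], levels=df["level_m"].to_numpy())


# ---------------------------------------------------------------------------
# patch table I/O

PATCH_COLUMNS = ["inlet", "sediment", "depth_class", "area_m2", "tuber_density_g_m2"]


def patches_from_frame(df: pd.DataFrame) -> list[Patch]:
    missing = [c for c in PATCH_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigError(f"patch table missing columns: {missing}")
    out = []
    for _, row in df.iterrows():
        std = float(row["standardized_depth_m"]) if "standardized_depth_m" in df.columns \
            else float("nan")
        out.append(Patch(inlet_id=str(row["inlet"]), sediment=row["sediment"],
                         depth_class=row["depth_class"], area_m2=float(row["area_m2"]),
                         tuber_density_g_m2=float(row["tuber_density_g_m2"]),
                         standardized_depth_m=std))
    return out


def patches_to_frame(patches: list[Patch]) -> pd.DataFrame:
    return pd.DataFrame({
        "inlet": [p.inlet_id for p in patches],
        "sediment": [p.sediment for p in patches],
        "depth_class": [p.depth_class for p in patches],
        "area_m2": [p.area_m2 for p in patches],
        "tuber_density_g_m2": [p.tuber_density_g_m2 for p in patches],
        "standardized_depth_m": [p.standardized_depth_m for p in patches],
    })


def read_patch_table(path) -> list[Patch]:
    return patches_from_frame(pd.read_csv(path))


def write_patch_table(patches: list[Patch], path) -> None:
    patches_to_frame(patches).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# flat key=value configuration files

_PARAM_FIELDS = {f.name: f.type for f in fields(ModelParams)}
_SCHEDULE_KEYS = {"peak1_date", "total_swans", "sd_days", "window_start", "window_days"}
_SCENARIO_KEYS = {"target_levels", "replicates", "census_hour", "year", "seed"}


@dataclass
class ConfigBundle:
    params: ModelParams
    patches: Optional[list[Patch]]
    schedule: Optional[dict]
    scenario: dict


def _parse_scalar(raw: str):
    raw = raw.strip()
    try:
        return int(raw)
    except ValueError:
        pass
    try:
        return float(raw)
    except ValueError:
        return raw


def load_config(path) -> ConfigBundle:
    """Load a flat ``key = value`` config file.

    Recognized keys: every :class:`ModelParams` field name; ``schedule.*``
    (``peak1_date``, ``total_swans``, ``sd_days``, ``window_start``,
    ``window_days``); ``scenario.*``; and ``patches`` (path to a patch CSV,
    relative to the config file).  Lines starting with ``#`` are comments.
    Unspecified parameters take their defaults.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    overrides: dict = {}
    schedule: dict = {}
    scenario: dict = {}
    patches_path = None
    for lineno, line in enumerate(path.read_text().splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigError(f"{path}:{lineno}: expected 'key = value', got {line!r}")
        key, raw = (s.strip() for s in line.split("=", 1))
        if key == "patches":
            patches_path = (path.parent / raw).resolve() if not Path(raw).is_absolute() \
                else Path(raw)
        elif key.startswith("schedule."):
            sub = key[len("schedule."):]
            if sub not in _SCHEDULE_KEYS:
                raise ConfigError(f"unknown schedule key: {key}")
            schedule[sub] = _parse_scalar(raw)
        elif key.startswith("scenario."):
            sub = key[len("scenario."):]
            if sub not in _SCENARIO_KEYS:
                raise ConfigError(f"unknown scenario key: {key}")
            if sub == "target_levels":
                scenario[sub] = [float(v) for v in raw.split(",") if v.strip()]
            else:
                scenario[sub] = _parse_scalar(raw)
        elif key in _PARAM_FIELDS:
            overrides[key] = _parse_scalar(raw)
        else:
            raise ConfigError(f"unknown configuration key: {key}")
    params = ModelParams(**overrides)  # raises ValidationError on bad values
    if schedule:
        for req in ("peak1_date", "total_swans"):
            if req not in schedule:
                raise ConfigError(f"schedule requires key 'schedule.{req}'")
    patches = read_patch_table(patches_path) if patches_path else None
    return ConfigBundle(params=params, patches=patches,
                        schedule=schedule or None, scenario=scenario)


def write_config(params: ModelParams, path) -> None:
    """Write every parameter as ``key = value`` (round-trips exactly)."""
    lines = [f"{f.name} = {getattr(params, f.name)!r}" for f in fields(params)]
    Path(path).write_text("\n".join(lines) + "\n")
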