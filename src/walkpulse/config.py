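"""Configuration dataclasses for every pipeline stage.

Defaults encode the analysis rules: 2 m/s walking-speed ceiling, 50 m
minimum bout distance, 20 m pedestrian buffer, 25 m POI match radius and
the 750 m utilitarian/leisure distance threshold, plus the synthetic
world and behavior settings the built-in generator uses as its study
conditions.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Mapping, Tuple


class ConfigurationError(ValueError):
    """Raised when a configuration violates its invariants."""


#: POI category mix for the synthetic world (field taxonomy: venue
#: categories used for destination inference; city/outdoors marks
#: residential/outdoor space and is the leisure destination class).
DEFAULT_POI_WEIGHTS: Mapping[str, float] = {
    "food": 0.25,
    "service": 0.20,
    "transportation": 0.16,
    "shopping": 0.12,
    "school": 0.07,
    "health": 0.06,
    "coffee/tea": 0.05,
    "work": 0.04,
    "outdoors": 0.02,
    "city/outdoors": 0.03,
}


@dataclass(frozen=True)
class WorldConfig:
    """Geometry of the synthetic toy world (grid streets, parks, POIs)."""

    n_tracts: int = 36
    n_msas: int = 4
    grid_extent_m: float = 6000.0
    road_spacing_m: float = 250.0
    n_pois: int = 400
    poi_category_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_POI_WEIGHTS))
    park_fraction: float = 0.05
    #: every k-th vertical half-spacing line is a motorway (excluded class)
    highway_every: int = 8
    origin_lat: float = 42.36
    origin_lon: float = -71.06
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tracts <= 0 or self.n_msas <= 0 or self.n_pois < 0:
            raise ConfigurationError("counts must be positive")
        if self.grid_extent_m <= 0 or self.road_spacing_m <= 0:
            raise ConfigurationError("dimensions must be positive")
        if self.n_msas > self.n_tracts:
            raise ConfigurationError("n_msas must not exceed n_tracts")
        if not 0.0 <= self.park_fraction <= 1.0:
            raise ConfigurationError("park_fraction must lie in [0, 1]")
        total = sum(self.poi_category_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(
                f"poi_category_weights must sum to 1 (got {total})")


@dataclass(frozen=True)
class BehaviorConfig:
    """Behavioral model for synthetic users.

    Rates are bouts/user/day; the intervention multiplies them from
    ``intervention_day`` on (utilitarian drops, leisure persists).  Speed
    ranges keep planted walks strictly below and drives strictly above
    the 2 m/s detection threshold so planted labels are recoverable.
    """

    n_users: int = 200
    n_days: int = 120
    start_date: dt.date = dt.date(2020, 2, 1)
    intervention_day: int = 43  # 2020-03-15 with the default start
    utilitarian_rate_pre: float = 0.4
    leisure_rate_pre: float = 0.12
    utilitarian_post_multiplier: float = 0.3
    leisure_post_multiplier: float = 1.0
    walk_speed_range: Tuple[float, float] = (0.7, 1.4)
    drive_rate: float = 0.3
    drive_speed_range: Tuple[float, float] = (6.0, 15.0)
    utilitarian_length_range: Tuple[float, float] = (100.0, 700.0)
    leisure_length_range: Tuple[float, float] = (850.0, 2500.0)
    drive_length_range: Tuple[float, float] = (2000.0, 8000.0)
    ping_interval_s: float = 60.0
    stationary_interval_s: float = 600.0
    gps_noise_sd_m: float = 3.5
    timezone: str = "America/New_York"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_users < 0 or self.n_days <= 0:
            raise ConfigurationError("n_users >= 0 and n_days > 0 required")
        if not self.walk_speed_range[1] < 2.0:
            raise ConfigurationError(
                "walk_speed_range max must be strictly below 2.0 m/s")
        if not self.drive_speed_range[0] > 2.0:
            raise ConfigurationError(
                "drive_speed_range min must be strictly above 2.0 m/s")
        if not 0.0 <= self.utilitarian_post_multiplier <= 1.0:
            raise ConfigurationError(
                "utilitarian_post_multiplier must lie in [0, 1]")
        if self.leisure_post_multiplier < 0:
            raise ConfigurationError("leisure_post_multiplier must be >= 0")
        if self.ping_interval_s <= 0 or self.stationary_interval_s <= 0:
            raise ConfigurationError("ping intervals must be positive")
        if self.gps_noise_sd_m < 0:
            raise ConfigurationError("gps_noise_sd_m must be >= 0")


@dataclass(frozen=True)
class DetectConfig:
    """Walk-bout detection thresholds."""

    speed_threshold_mps: float = 2.0
    min_bout_distance_m: float = 50.0
    pedestrian_buffer_m: float = 20.0
    poi_match_radius_m: float = 25.0
    max_ping_gap_s: float = 180.0
    min_pings_per_bout: int = 2
    #: 'all' = every ping must be in a pedestrian area; 'fraction' =
    #: at least pedestrian_min_fraction of pings must be.
    pedestrian_rule: str = "all"
    pedestrian_min_fraction: float = 1.0

    def __post_init__(self) -> None:
        for name in ("speed_threshold_mps", "min_bout_distance_m",
                     "pedestrian_buffer_m", "poi_match_radius_m",
                     "max_ping_gap_s"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be strictly positive")
        if self.min_pings_per_bout < 2:
            raise ConfigurationError("min_pings_per_bout must be >= 2")
        if self.pedestrian_rule not in ("all", "fraction"):
            raise ConfigurationError("pedestrian_rule must be 'all' or 'fraction'")


@dataclass(frozen=True)
class ClassifyConfig:
    """Utilitarian/leisure labelling rules."""

    distance_threshold_m: float = 750.0
    poi_match_radius_m: float = 25.0
    leisure_categories: frozenset = frozenset({"city/outdoors"})
    #: a bout of exactly distance_threshold_m goes to the utilitarian class
    boundary_to_utilitarian: bool = True

    def __post_init__(self) -> None:
        if self.distance_threshold_m <= 0 or self.poi_match_radius_m <= 0:
            raise ConfigurationError("thresholds must be positive")


@dataclass(frozen=True)
class PeriodWindows:
    """Pre/post comparison windows around the intervention date.

    The default post window ends on 2020-05-30, the last *fully
    observed* local day of the default 120-day panel: the final
    simulated day's night pings spill a few early-morning fixes into
    May 31, which would otherwise enter the panel as a spurious
    near-zero-walking active day and bias the post-period mean down.
    """

    pre_start: dt.date = dt.date(2020, 2, 15)
    pre_end: dt.date = dt.date(2020, 3, 14)
    intervention_date: dt.date = dt.date(2020, 3, 15)
    post_start: dt.date = dt.date(2020, 5, 1)
    post_end: dt.date = dt.date(2020, 5, 30)

    def __post_init__(self) -> None:
        if not (self.pre_start <= self.pre_end < self.intervention_date):
            raise ConfigurationError(
                "pre window must precede the intervention date")
        if not (self.intervention_date <= self.post_start <= self.post_end):
            raise ConfigurationError(
                "post window must start at or after the intervention date")
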