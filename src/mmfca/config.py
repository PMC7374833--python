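"""Scenario and run configuration.

The default scenario is a stylised four-city region modelled on the part of
Ondo State, Nigeria served by the Mother and Child Hospital in Ondo City:
four urban settlements (Ondo City, Akure, Okitipupa, Ore) embedded in a
sparse rural matrix, five screening facilities with the published staff
counts, and the published class-by-city mean travel speeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

ROAD_CLASSES = ("highway", "major", "residential")

#: Mean travel speeds (km/h) per road class, by city, from local GPS tracking.
DEFAULT_SPEED_TABLE: dict[str, dict[str, float]] = {
    "Ondo City": {"highway": 53.00, "major": 38.00, "residential": 29.80},
    "Akure": {"highway": 37.00, "major": 48.67, "residential": 27.40},
    "Okitipupa": {"highway": 53.33, "major": 31.00, "residential": 11.35},
    "Ore": {"highway": 63.00, "major": 17.68, "residential": 7.78},
}

DEFAULT_CITY_NAMES = ("Ondo City", "Akure", "Okitipupa", "Ore")
DEFAULT_CITY_POPULATIONS = (315_473, 424_900, 108_140, 90_401)
#: (city index, screening-professional count); Ondo City hosts two facilities.
DEFAULT_FACILITY_SPEC = ((0, 26), (0, 7), (1, 10), (2, 10), (3, 2))

#: City centers as fractions of the region extent, mirroring the real
#: arrangement: Akure ~40 km northeast of Ondo City, Ore ~45 km southeast,
#: Okitipupa ~40 km beyond Ore so it sits about 1.5 h of travel from Ondo
#: City's screening services.
DEFAULT_CITY_POSITIONS = ((0.30, 0.55), (0.62, 0.82), (0.32, 0.08), (0.65, 0.28))


class ConfigurationError(ValueError):
    """Raised when a scenario or run configuration violates its contract."""


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameters of a synthetic study region.

    Coordinates are planar metres.  ``cell_size`` emulates the ~1 km
    resolution of gridded population rasters such as LandScan.
    """

    region_extent: tuple[float, float, float, float] = (0.0, 0.0, 100_000.0, 100_000.0)
    n_cities: int = 4
    city_populations: tuple[int, ...] = DEFAULT_CITY_POPULATIONS
    city_names: tuple[str, ...] = DEFAULT_CITY_NAMES
    cell_size: float = 1000.0
    speed_table: dict[str, dict[str, float]] = field(
        default_factory=lambda: {z: dict(r) for z, r in DEFAULT_SPEED_TABLE.items()}
    )
    facility_spec: tuple[tuple[int, int], ...] = DEFAULT_FACILITY_SPEC
    n_clients: int = 400
    urban_client_fraction: float = 0.69
    urban_density_per_km2: float = 5000.0
    #: rural settlement sampling: keep probability for candidate cells near
    #: rural roads, and the village-scale population range per kept cell
    #: (defaults put the rural share of regional population near the ~30% of
    #: a predominantly rural state)
    rural_keep_p: float = 0.55
    rural_pop_range: tuple[int, int] = (600, 2400)
    #: city centers as (fx, fy) fractions of the region extent; None picks
    #: the stylised four-city arrangement when n_cities == 4, otherwise a
    #: seed-jittered block lattice
    city_positions: tuple[tuple[float, float], ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        xmin, ymin, xmax, ymax = self.region_extent
        if not (xmax > xmin and ymax > ymin):
            raise ConfigurationError("region_extent must be a non-empty box")
        if self.n_cities < 1:
            raise ConfigurationError("n_cities must be >= 1")
        if len(self.city_populations) != self.n_cities:
            raise ConfigurationError(
                f"expected {self.n_cities} city populations, got {len(self.city_populations)}"
            )
        if any(p <= 0 for p in self.city_populations):
            raise ConfigurationError("city_populations must all be > 0")
        if len(self.city_names) != self.n_cities:
            raise ConfigurationError("city_names must match n_cities")
        if self.cell_size <= 0:
            raise ConfigurationError("cell_size must be > 0")
        if not 0.0 <= self.urban_client_fraction <= 1.0:
            raise ConfigurationError("urban_client_fraction must lie in [0, 1]")
        if self.n_clients < 0:
            raise ConfigurationError("n_clients must be >= 0")
        if not 0.0 <= self.rural_keep_p <= 1.0:
            raise ConfigurationError("rural_keep_p must lie in [0, 1]")
        lo, hi = self.rural_pop_range
        if not 0 < lo <= hi:
            raise ConfigurationError("rural_pop_range must be positive and ascending")
        if self.city_positions is not None:
            if len(self.city_positions) != self.n_cities:
                raise ConfigurationError("city_positions must match n_cities")
            for fx, fy in self.city_positions:
                if not (0.0 <= fx <= 1.0 and 0.0 <= fy <= 1.0):
                    raise ConfigurationError("city_positions are fractions in [0, 1]")
        for idx, staff in self.facility_spec:
            if not 0 <= idx < self.n_cities:
                raise ConfigurationError(f"facility city index {idx} out of range")
            if staff < 0:
                raise ConfigurationError("facility staff counts must be >= 0")

    def with_seed(self, seed: int) -> "ScenarioConfig":
        return replace(self, seed=seed)


@dataclass(frozen=True)
class RunConfig:
    """Model parameters for an end-to-end access run."""

    d0_urban_min: float = 40.0
    d0_rural_min: float = 90.0
    epsilon: float = 0.01
    urban_threshold: int = 20_000
    minibus_penalty_min: float = 15.0
    urban_split: dict[str, float] = field(
        default_factory=lambda: {"taxi": 0.80, "minibus": 0.20}
    )
    rural_split: dict[str, float] = field(
        default_factory=lambda: {"taxi": 0.20, "minibus": 0.80}
    )
    n_zones: int = 6
    endpoint_snap_m: float = 1.0
    point_snap_m: float = 500.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d0_urban_min <= 0 or self.d0_rural_min <= 0:
            raise ConfigurationError("catchment thresholds must be positive")
        if not 0.0 < self.epsilon < 1.0:
            raise ConfigurationError("epsilon must lie in (0, 1)")
        if self.urban_threshold <= 0:
            raise ConfigurationError("urban_threshold must be positive")
        if self.minibus_penalty_min < 0:
            raise ConfigurationError("minibus_penalty_min must be >= 0")
        for name, split in (("urban_split", self.urban_split), ("rural_split", self.rural_split)):
            if abs(sum(split.values()) - 1.0) > 1e-9:
                raise ConfigurationError(f"{name} fractions must sum to 1")
            if any(v < 0 for v in split.values()):
                raise ConfigurationError(f"{name} fractions must be >= 0")
        if self.n_zones < 1:
            raise ConfigurationError("n_zones must be >= 1")
        if self.endpoint_snap_m < 0 or self.point_snap_m < 0:
            raise ConfigurationError("snap tolerances must be >= 0")

    def to_dict(self) -> dict:
        return {
            "d0_urban_min": self.d0_urban_min,
            "d0_rural_min": self.d0_rural_min,
            "epsilon": self.epsilon,
            "urban_threshold": self.urban_threshold,
            "minibus_penalty_min": self.minibus_penalty_min,
            "urban_split": dict(self.urban_split),
            "rural_split": dict(self.rural_split),
            "n_zones": self.n_zones,
            "endpoint_snap_m": self.endpoint_snap_m,
            "point_snap_m": self.point_snap_m,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}  # type: ignore[attr-defined]
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)
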