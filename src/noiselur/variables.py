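"""The candidate predictor grid for the noise LUR model.

Variable *types* (length of a road-class combination, an inverse distance,
household density, a land-use area, mean NDVI) are crossed with the buffer
radii customary for each category, giving 105 candidate variables. Each type
carries an a-priori expected coefficient sign: sources of noise (roads,
traffic infrastructure, households, commercial/industrial/built land) are
positive, green-space surrogates (NDVI, nature) and quieter residential
fabric are negative.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "CandidateVariable",
    "ROAD_CLASSES",
    "ROAD_COMPOSITES",
    "LANDUSE_CLASSES",
    "POINT_CATEGORIES",
    "ROAD_BUFFERS",
    "DENSITY_BUFFERS",
    "LANDUSE_BUFFERS",
    "NDVI_BUFFERS",
    "EXPECTED_SIGNS",
    "table1_variables",
]

ROAD_CLASSES = ("large", "medium", "small", "very_small")

#: Road-length variable types: the four single classes plus the customary
#: combinations. Composite lengths are sums of the class-specific lengths.
ROAD_COMPOSITES: dict[str, tuple[str, ...]] = {
    "road_large": ("large",),
    "road_medium": ("medium",),
    "road_small": ("small",),
    "road_very_small": ("very_small",),
    "road_large_medium": ("large", "medium"),
    "road_large_medium_small": ("large", "medium", "small"),
    "road_all": ("large", "medium", "small", "very_small"),
    "road_medium_small": ("medium", "small"),
    "road_medium_small_very_small": ("medium", "small", "very_small"),
    "road_small_very_small": ("small", "very_small"),
}

LANDUSE_CLASSES = ("residential", "commercial", "industrial", "buildings", "nature")

#: Point-feature categories with an inverse-distance variable. The road
#: inverse distance is computed from the road network, not a point set.
POINT_CATEGORIES = (
    "airport",
    "railway_active",
    "railway_any",
    "church",
    "police",
    "hospital",
)

ROAD_BUFFERS = (25, 50, 100, 200, 500)
DENSITY_BUFFERS = (25, 50, 100, 200, 500, 750, 1000)
LANDUSE_BUFFERS = (25, 50, 100, 200, 500, 750, 1000)
NDVI_BUFFERS = (30, 100, 150, 200, 500, 750)

#: Expected coefficient sign per variable category.
EXPECTED_SIGNS: dict[str, int] = {
    "roads": +1,
    "inverse_distance": +1,
    "household_density": +1,
    "landuse_residential": -1,
    "landuse_commercial": +1,
    "landuse_industrial": +1,
    "landuse_buildings": +1,
    "landuse_nature": -1,
    "ndvi": -1,
}


@dataclass(frozen=True)
class CandidateVariable:
    """One candidate predictor: a variable type at one buffer radius."""

    name: str
    var_type: str
    category: str
    buffer_m: float | None
    expected_sign: int  # +1 / -1; 0 disables the sign constraint
    unit: str

    def __post_init__(self) -> None:
        if self.expected_sign not in (-1, 0, +1):
            raise ValueError("expected_sign must be -1, 0 or +1")
        if self.buffer_m is not None and self.buffer_m <= 0:
            raise ValueError("buffer radius must be positive")


def _sign_for(category: str, landuse_class: str | None = None) -> int:
    if category == "landuse":
        return EXPECTED_SIGNS[f"landuse_{landuse_class}"]
    return EXPECTED_SIGNS[category]


def table1_variables() -> list[CandidateVariable]:
    """The full 105-variable candidate grid.

    50 road lengths (10 class combinations x 5 radii), 7 inverse distances,
    7 household densities, 35 land-use areas (5 classes x 7 radii) and
    6 NDVI means.
    """
    out: list[CandidateVariable] = []
    for var_type in ROAD_COMPOSITES:
        for r in ROAD_BUFFERS:
            out.append(
                CandidateVariable(
                    name=f"{var_type}_{r}m",
                    var_type=var_type,
                    category="roads",
                    buffer_m=float(r),
                    expected_sign=_sign_for("roads"),
                    unit="m",
                )
            )
    for target in ("road",) + POINT_CATEGORIES:
        out.append(
            CandidateVariable(
                name=f"inv_dist_{target}",
                var_type=f"inv_dist_{target}",
                category="inverse_distance",
                buffer_m=None,
                expected_sign=_sign_for("inverse_distance"),
                unit="1/m",
            )
        )
    for r in DENSITY_BUFFERS:
        out.append(
            CandidateVariable(
                name=f"hh_density_{r}m",
                var_type="hh_density",
                category="household_density",
                buffer_m=float(r),
                expected_sign=_sign_for("household_density"),
                unit="households/m^2",
            )
        )
    for use in LANDUSE_CLASSES:
        for r in LANDUSE_BUFFERS:
            out.append(
                CandidateVariable(
                    name=f"landuse_{use}_{r}m",
                    var_type=f"landuse_{use}",
                    category="landuse",
                    buffer_m=float(r),
                    expected_sign=_sign_for("landuse", use),
                    unit="m^2",
                )
            )
    for r in NDVI_BUFFERS:
        out.append(
            CandidateVariable(
                name=f"ndvi_{r}m",
                var_type="ndvi",
                category="ndvi",
                buffer_m=float(r),
                expected_sign=_sign_for("ndvi"),
                unit="index",
            )
        )
    return out
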