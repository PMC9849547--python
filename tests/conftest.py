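"""Shared fixtures: criteria matrix, handcrafted polygons, synthetic cities."""
from __future__ import annotations

import pytest
from shapely.geometry import box

from urbanros import (
    BiotopePolygon,
    BiotopeType,
    CityConfig,
    CriteriaMatrix,
    NoiseProfile,
    generate_city,
)
from urbanros.synthetic_city import REGIME_PROFILES, REGIME_SLOPES

QUIET = REGIME_PROFILES["quiet"]
MODERATE = REGIME_PROFILES["moderate"]
LOUD = REGIME_PROFILES["loud"]
FLAT = REGIME_SLOPES["flat"]
STEEP = REGIME_SLOPES["steep"]


def make_polygon(
    pid: str,
    geometry,
    biotope_type: BiotopeType = BiotopeType.FOREST,
    noise: NoiseProfile = QUIET,
    slopes=FLAT,
    nature_reserve: bool = False,
) -> BiotopePolygon:
    return BiotopePolygon(
        id=pid,
        geometry=geometry,
        biotope_type=biotope_type,
        nature_reserve=nature_reserve,
        noise=noise,
        slope_samples=tuple(slopes),
    )


def square_ha(area_ha: float, x0: float = 0.0, y0: float = 0.0):
    side = (area_ha * 10_000.0) ** 0.5
    return box(x0, y0, x0 + side, y0 + side)


@pytest.fixture(scope="session")
def matrix() -> CriteriaMatrix:
    return CriteriaMatrix.default()


@pytest.fixture(scope="session")
def city():
    return generate_city(CityConfig(seed=1))
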