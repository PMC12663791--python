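"""Cruise-track geometry, SST-based region classification, nutrient interpolation.

A transect cruise is modelled as an ordered chain of stations.  Nutrient
concentrations at an arbitrary observation point are obtained by projecting
the point onto the nearest inter-station segment (great-circle distances,
haversine) and interpolating linearly; beyond the track ends values are
clamped to the terminal station.  Regions follow the 10 degC / 20 degC
sea-surface isotherms: subtropical (> 20), front ([10, 20]), subantarctic (< 10).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime
from enum import Enum
from typing import Sequence

import numpy as np

from .diffusion import NutrientField
from .errors import ConfigurationError, DomainError, MissingDataError
from .physchem import SeawaterState

__all__ = [
    "EARTH_RADIUS_KM",
    "Region",
    "Station",
    "UnderwayObservation",
    "great_circle_distance",
    "classify_region",
    "build_track",
    "interpolate_nutrients",
    "nearest_observation",
]

EARTH_RADIUS_KM = 6371.0

_SOLUTES = ("ammonium", "nitrite", "nitrate", "phosphate", "urea")


class Region(str, Enum):
    SUBTROPICAL = "subtropical"
    FRONT = "front"
    SUBANTARCTIC = "subantarctic"


@dataclass
class Station:
    """A georeferenced sampling station with seawater state and nutrients (nmol/L)."""

    id: str
    latitude: float
    longitude: float
    temperature: float
    salinity: float
    nutrients: NutrientField
    along_track_km: float | None = None

    def __post_init__(self) -> None:
        _check_coords(self.latitude, self.longitude)

    @property
    def seawater_state(self) -> SeawaterState:
        return SeawaterState(self.temperature, self.salinity)


@dataclass(frozen=True)
class UnderwayObservation:
    """A continuous underway record: time, position, SST (degC), salinity."""

    timestamp: datetime
    latitude: float
    longitude: float
    sst: float
    salinity: float

    def __post_init__(self) -> None:
        _check_coords(self.latitude, self.longitude)

    @property
    def seawater_state(self) -> SeawaterState:
        return SeawaterState(self.sst, self.salinity)


def _check_coords(lat: float, lon: float) -> None:
    if not (np.isfinite(lat) and abs(lat) <= 90):
        raise DomainError(f"latitude {lat} outside [-90, 90]")
    if not (np.isfinite(lon) and abs(lon) <= 180):
        raise DomainError(f"longitude {lon} outside [-180, 180]")


def great_circle_distance(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Haversine great-circle distance in km (Earth radius 6371 km)."""
    _check_coords(lat1, lon1)
    _check_coords(lat2, lon2)
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dphi = p2 - p1
    dlam = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dlam / 2) ** 2
    return 2.0 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(a)))


def classify_region(sst: float) -> Region:
    """Region from SST: > 20 subtropical, < 10 subantarctic, boundary-inclusive front."""
    if not np.isfinite(sst):
        raise DomainError(f"SST must be finite, got {sst}")
    if sst > 20.0:
        return Region.SUBTROPICAL
    if sst < 10.0:
        return Region.SUBANTARCTIC
    return Region.FRONT


def build_track(stations: Sequence[Station]) -> list[Station]:
    """Assign cumulative along-track distances (km) to an ordered station list."""
    if len(stations) < 2:
        raise ConfigurationError("a track needs at least 2 stations")
    dist = 0.0
    stations = list(stations)
    stations[0].along_track_km = 0.0
    for prev, cur in zip(stations, stations[1:]):
        dist += great_circle_distance(
            prev.latitude, prev.longitude, cur.latitude, cur.longitude
        )
        cur.along_track_km = dist
    return stations


def _segment_fraction(
    lat: float, lon: float, s_a: Station, s_b: Station
) -> tuple[float, float]:
    """(detour, clamped fraction) of a point projected on segment a->b."""
    da = great_circle_distance(lat, lon, s_a.latitude, s_a.longitude)
    db = great_circle_distance(lat, lon, s_b.latitude, s_b.longitude)
    seg = great_circle_distance(s_a.latitude, s_a.longitude, s_b.latitude, s_b.longitude)
    if seg == 0.0:
        return da, 0.0
    # for a point on the segment da + db == seg and f = da/seg; the form below
    # extends that continuously and clamps beyond either endpoint
    f = (da + seg - db) / (2.0 * seg)
    return da + db - seg, min(1.0, max(0.0, f))


def interpolate_nutrients(
    obs: UnderwayObservation | tuple[float, float],
    stations: Sequence[Station],
    *,
    fill_missing: bool = False,
) -> NutrientField:
    """Nutrient field at an observation point by along-track linear interpolation.

    The two bracketing stations are the endpoints of the nearest track
    segment; weights derive from great-circle distances.  Points beyond the
    track extent take the terminal station's values.  A station missing a
    solute raises MissingDataError unless ``fill_missing`` leaves that solute
    unset in the output.
    """
    if not stations:
        raise ConfigurationError("empty station list")
    if len(stations) == 1:
        return stations[0].nutrients
    lat, lon = (obs.latitude, obs.longitude) if isinstance(obs, UnderwayObservation) else obs

    best = None
    for s_a, s_b in zip(stations, stations[1:]):
        detour, f = _segment_fraction(lat, lon, s_a, s_b)
        if best is None or detour < best[0]:
            best = (detour, f, s_a, s_b)
    _, f, s_a, s_b = best

    values: dict[str, float | None] = {}
    for solute in _SOLUTES:
        va, vb = getattr(s_a.nutrients, solute), getattr(s_b.nutrients, solute)
        if va is None or vb is None:
            if solute == "urea" or fill_missing:
                values[solute] = None
                continue
            missing_at = s_a.id if va is None else s_b.id
            raise MissingDataError(f"station {missing_at} has no {solute} value")
        values[solute] = (1.0 - f) * va + f * vb
    return NutrientField(**values)


def nearest_observation(
    timestamp: datetime, underway: Sequence[UnderwayObservation]
) -> UnderwayObservation:
    """Underway record nearest in time to ``timestamp``."""
    if not underway:
        raise ConfigurationError("empty underway table")
    return min(underway, key=lambda o: abs((o.timestamp - timestamp).total_seconds()))
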