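"""Flight/stationary classification, takeoff counting and land use.

Ground speed above a threshold (default 15 km/h) marks flight; a takeoff
is a stationary-to-flight switch between consecutive fixes.  Land
utilization is the percentage of 1-min resampled trip fixes that are both
in flight phase and over land.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import shapely
from shapely.geometry import shape
from shapely.ops import unary_union

FLIGHT_SPEED_KMH = 15.0


@dataclass
class FlightClassification:
    """Binary phase per fix: True = flight (speed >= threshold)."""

    phase: np.ndarray  # bool, True = flight
    threshold_kmh: float


def classify_flight(speeds, threshold: float = FLIGHT_SPEED_KMH) -> FlightClassification:
    """Classify each speed as stationary or flight.

    The boundary speed (exactly ``threshold``) counts as flight: the >=
    convention, fixed here because "more than"/"less than" phrasing leaves
    equality undefined.
    """
    speeds = np.asarray(speeds, dtype=float)
    if np.any(~np.isfinite(speeds)) or np.any(speeds < 0):
        raise ValueError("speeds must be finite and non-negative")
    return FlightClassification(phase=speeds >= threshold, threshold_kmh=threshold)


def count_takeoffs(phases) -> int:
    """Number of stationary->flight transitions between consecutive points."""
    if isinstance(phases, FlightClassification):
        phases = phases.phase
    phases = np.asarray(phases, dtype=bool)
    if phases.size < 1:
        raise ValueError("need at least one phase")
    return int(np.sum(~phases[:-1] & phases[1:]))


class LandMask:
    """Land polygons in WGS84; point membership includes the boundary."""

    def __init__(self, geometry) -> None:
        self.geometry = geometry
        shapely.prepare(self.geometry)

    @classmethod
    def from_geojson(cls, path) -> "LandMask":
        with open(path) as fh:
            gj = json.load(fh)
        if gj.get("type") == "FeatureCollection":
            geoms = [shape(f["geometry"]) for f in gj["features"]]
        elif gj.get("type") == "Feature":
            geoms = [shape(gj["geometry"])]
        else:
            geoms = [shape(gj)]
        if not geoms:
            raise ValueError("empty GeoJSON land mask")
        return cls(unary_union(geoms))

    def contains(self, lat, lon) -> np.ndarray:
        """Vectorized point-in-polygon test (lon = x, lat = y)."""
        pts = shapely.points(np.asarray(lon, dtype=float), np.asarray(lat, dtype=float))
        return np.atleast_1d(shapely.covers(self.geometry, pts))


def land_utilization(
    lat,
    lon,
    speeds_kmh,
    in_trip,
    mask: LandMask,
    threshold_kmh: float = FLIGHT_SPEED_KMH,
    flight_only: bool = True,
) -> float:
    """Percent of resampled trip fixes over land.

    Inputs are parallel arrays for the 1-min resampled track: positions,
    ground speeds, and a boolean marking fixes inside foraging trips.
    Numerator: trip fixes over land that are also in flight phase (the
    default, literal reading); with ``flight_only=False`` all over-land
    trip fixes count.  Denominator: all trip fixes.  Returns NaN when no
    fix lies inside a trip.
    """
    in_trip = np.asarray(in_trip, dtype=bool)
    denom = int(in_trip.sum())
    if denom == 0:
        return float("nan")
    on_land = mask.contains(np.asarray(lat)[in_trip], np.asarray(lon)[in_trip])
    if flight_only:
        fl = classify_flight(np.asarray(speeds_kmh)[in_trip], threshold_kmh).phase
        num = int(np.sum(on_land & fl))
    else:
        num = int(np.sum(on_land))
    return 100.0 * num / denom
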