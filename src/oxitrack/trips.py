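"""Central-place foraging trip segmentation and trip metrics.

A foraging trip is a maximal run of consecutive fixes farther from the
colony than a species-specific distance threshold, lasting longer than a
species-specific duration: more than 1 km and 1 h for gulls, more than
3 km and 6 h for shearwaters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import flight
from .geo import haversine_km
from .trajectory import Trajectory, compute_steps

GULL_RULE_KM_H = (1.0, 1.0)
SHEARWATER_RULE_KM_H = (3.0, 6.0)


@dataclass(frozen=True)
class TripRule:
    """Distance/duration thresholds defining a foraging trip (strict >)."""

    min_colony_km: float
    min_duration_h: float

    def __post_init__(self) -> None:
        if self.min_colony_km <= 0 or self.min_duration_h <= 0:
            raise ValueError("trip thresholds must be positive")

    @classmethod
    def for_species(cls, species: str) -> "TripRule":
        if species == "gull":
            return cls(*GULL_RULE_KM_H)
        if species == "shearwater":
            return cls(*SHEARWATER_RULE_KM_H)
        raise ValueError(f"no default trip rule for species {species!r}")


@dataclass(frozen=True)
class Trip:
    """A colony-departure episode: fix indices [start_idx, end_idx] inclusive."""

    individual_id: str
    start_idx: int
    end_idx: int
    start_time: float
    end_time: float

    @property
    def duration_h(self) -> float:
        return (self.end_time - self.start_time) / 3600.0


@dataclass
class TripMetrics:
    trip: Trip
    duration_h: float
    total_flight_distance_km: float
    max_colony_distance_km: float
    n_takeoffs: int
    takeoff_freq_per_h: float


@dataclass
class IndividualMetrics:
    """Per-individual foraging summary aggregated over trips.

    Averages are NaN (missing, not zero) when the individual has no trip.
    ``avg_takeoff_freq_per_h`` is the unweighted mean of per-trip takeoff
    frequencies — deliberately not total takeoffs / total duration.
    """

    individual_id: str
    n_trips: int
    total_trip_duration_h: float
    total_flight_distance_km: float
    avg_max_distance_km: float
    avg_takeoff_freq_per_h: float
    total_takeoffs: int
    foraging_duration_h: float
    pct_foraging: float
    pct_land: float  # NaN unless computed (gulls with a land mask)


def colony_distance_series(traj: Trajectory) -> np.ndarray:
    """Haversine distance (km) of every fix to the colony."""
    clat, clon = traj.colony
    return np.atleast_1d(
        haversine_km((traj.lat, traj.lon), (np.full(len(traj), clat), np.full(len(traj), clon)))
    )


def segment_trips(
    traj: Trajectory,
    rule: TripRule,
    max_gap_h: float | None = None,
    include_boundary: bool = False,
) -> list[Trip]:
    """Find foraging trips: maximal away-from-colony runs exceeding the rule.

    A run is consecutive fixes with colony distance strictly greater than
    ``rule.min_colony_km``; it qualifies as a trip iff its first-to-last
    time span strictly exceeds ``rule.min_duration_h``.  A recording gap
    longer than ``max_gap_h`` inside a run splits it (we cannot certify the
    bird stayed away).  ``include_boundary`` extends each trip by the
    colony-side crossing fixes on either end.
    """
    dist = colony_distance_series(traj)
    away = dist > rule.min_colony_km
    trips: list[Trip] = []
    n = len(traj)
    i = 0
    while i < n:
        if not away[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and away[j + 1]:
            if max_gap_h is not None and (traj.time[j + 1] - traj.time[j]) / 3600.0 > max_gap_h:
                break
            j += 1
        s, e = i, j
        if include_boundary:
            s = max(0, s - 1)
            e = min(n - 1, e + 1)
        if (traj.time[e] - traj.time[s]) / 3600.0 > rule.min_duration_h:
            trips.append(
                Trip(
                    individual_id=traj.individual_id,
                    start_idx=s,
                    end_idx=e,
                    start_time=float(traj.time[s]),
                    end_time=float(traj.time[e]),
                )
            )
        i = j + 1
    return trips


def trip_metrics(
    traj: Trajectory, trip: Trip, speed_threshold_kmh: float = flight.FLIGHT_SPEED_KMH
) -> TripMetrics:
    """Duration, path length, max colony distance and takeoffs for one trip."""
    if not (0 <= trip.start_idx <= trip.end_idx < len(traj)):
        raise ValueError("trip indices out of range")
    sub = traj.slice(trip.start_idx, trip.end_idx + 1)
    duration_h = trip.duration_h
    if duration_h <= 0:
        raise ValueError("zero-duration trip")
    if len(sub) >= 2:
        steps = compute_steps(sub)
        total_km = float(steps.step_km.sum())
        phases = flight.classify_flight(steps.speed_kmh, speed_threshold_kmh)
        n_takeoffs = flight.count_takeoffs(phases)
    else:
        total_km = 0.0
        n_takeoffs = 0
    max_dist = float(colony_distance_series(sub).max())
    return TripMetrics(
        trip=trip,
        duration_h=duration_h,
        total_flight_distance_km=total_km,
        max_colony_distance_km=max_dist,
        n_takeoffs=n_takeoffs,
        takeoff_freq_per_h=n_takeoffs / duration_h,
    )


def individual_metrics(
    individual_id: str,
    metrics: list[TripMetrics],
    foraging_duration_h: float,
    recorded_duration_h: float,
    pct_land: float = float("nan"),
) -> IndividualMetrics:
    """Aggregate trip metrics to the individual level.

    Totals are sums over trips; the average maximum distance is the sum of
    per-trip maxima divided by the number of trips, and the average takeoff
    frequency is the plain mean of per-trip frequencies.  Percent foraging
    is 100 x foraging duration / logger-recorded duration.
    """
    if recorded_duration_h <= 0:
        raise ValueError("recorded_duration_h must be positive")
    n = len(metrics)
    nan = float("nan")
    return IndividualMetrics(
        individual_id=individual_id,
        n_trips=n,
        total_trip_duration_h=sum(m.duration_h for m in metrics),
        total_flight_distance_km=sum(m.total_flight_distance_km for m in metrics),
        avg_max_distance_km=(sum(m.max_colony_distance_km for m in metrics) / n) if n else nan,
        avg_takeoff_freq_per_h=(sum(m.takeoff_freq_per_h for m in metrics) / n) if n else nan,
        total_takeoffs=sum(m.n_takeoffs for m in metrics),
        foraging_duration_h=foraging_duration_h,
        pct_foraging=100.0 * foraging_duration_h / recorded_duration_h,
        pct_land=pct_land,
    )
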