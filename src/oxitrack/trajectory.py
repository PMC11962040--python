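"""GPS track containers and time-series primitives.

A :class:`Trajectory` holds one individual's time-ordered fixes together
with its colony location and species.  Operations here are the plumbing
every downstream analysis relies on: step/turn extraction, the 90 km/h
ground-speed spike filter, and regular-grid resampling by piecewise-linear
interpolation in geographic coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np
import pandas as pd

from .geo import haversine_km, initial_bearing_rad, wrap_angle

logger = logging.getLogger(__name__)

SPECIES = ("gull", "shearwater")


class GpsFix(NamedTuple):
    """A single timestamped position (epoch seconds UTC, decimal degrees)."""

    time: float
    lat: float
    lon: float


@dataclass
class Trajectory:
    """Time-ordered GPS fixes for one individual.

    ``time`` is epoch seconds (UTC); ``lat``/``lon`` are decimal degrees.
    Fixes must be strictly increasing in time (no duplicate timestamps).
    """

    individual_id: str
    species: str
    colony: tuple[float, float]
    time: np.ndarray
    lat: np.ndarray
    lon: np.ndarray
    sampling_note: str = ""

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.lat = np.asarray(self.lat, dtype=float)
        self.lon = np.asarray(self.lon, dtype=float)
        if self.species not in SPECIES:
            raise ValueError(f"unknown species {self.species!r}; expected one of {SPECIES}")
        if self.time.size < 1:
            raise ValueError("trajectory needs at least one fix")
        if not (self.time.size == self.lat.size == self.lon.size):
            raise ValueError("time/lat/lon length mismatch")
        if not np.all(np.isfinite(self.time)):
            raise ValueError("non-finite timestamps")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("fixes must be strictly increasing in time")
        if np.any(np.abs(self.lat) > 90) or np.any(np.abs(self.lon) > 180):
            raise ValueError("coordinates out of bounds")
        clat, clon = self.colony
        if abs(clat) > 90 or abs(clon) > 180:
            raise ValueError("colony coordinates out of bounds")

    def __len__(self) -> int:
        return int(self.time.size)

    @property
    def duration_h(self) -> float:
        return float(self.time[-1] - self.time[0]) / 3600.0

    def fix(self, i: int) -> GpsFix:
        return GpsFix(float(self.time[i]), float(self.lat[i]), float(self.lon[i]))

    def slice(self, start: int, stop: int) -> "Trajectory":
        """Sub-trajectory over fix indices [start, stop)."""
        return replace(
            self, time=self.time[start:stop], lat=self.lat[start:stop], lon=self.lon[start:stop]
        )


@dataclass
class StepSeries:
    """Per-pair step geometry of a trajectory with n fixes.

    Arrays of length n-1, aligned so element i describes the move from fix
    i to fix i+1.  ``turn_rad[i]`` is the signed change of bearing between
    step i-1 and step i (positive = counterclockwise / left turn), wrapped
    to (-pi, pi]; it is NaN for the first step and wherever an adjacent
    step has zero length.
    """

    step_km: np.ndarray
    dt_h: np.ndarray
    speed_kmh: np.ndarray
    turn_rad: np.ndarray

    def __len__(self) -> int:
        return int(self.step_km.size)


def compute_steps(traj: Trajectory) -> StepSeries:
    """Step lengths, durations, speeds and turning angles of a trajectory.

    Step length is the great-circle (net) distance between consecutive
    fixes; the turning angle at an interior fix is the signed angle between
    the incoming and outgoing step bearings.
    """
    if len(traj) < 2:
        raise ValueError("compute_steps needs at least 2 fixes")
    a = (traj.lat[:-1], traj.lon[:-1])
    b = (traj.lat[1:], traj.lon[1:])
    step_km = np.atleast_1d(haversine_km(a, b))
    dt_h = np.diff(traj.time) / 3600.0
    speed = step_km / dt_h
    bearing = np.atleast_1d(initial_bearing_rad(a, b))
    turn = np.full(step_km.size, np.nan)
    if step_km.size >= 2:
        # compass bearings increase clockwise; left (CCW) turn => positive
        raw = wrap_angle(-(bearing[1:] - bearing[:-1]))
        zero_adjacent = (step_km[1:] == 0.0) | (step_km[:-1] == 0.0)
        turn[1:] = np.where(zero_adjacent, np.nan, raw)
    return StepSeries(step_km=step_km, dt_h=dt_h, speed_kmh=speed, turn_rad=turn)


def speed_filter(traj: Trajectory, vmax_kmh: float = 90.0) -> tuple[Trajectory, int]:
    """Remove fixes implying ground speed above ``vmax_kmh``.

    Single forward sweep: the first fix is always kept; each later fix is
    kept iff the speed from the *last kept* fix does not exceed ``vmax_kmh``
    (strictly-greater removal).  Idempotent by construction.  Returns the
    filtered trajectory and the number of removed fixes.
    """
    n = len(traj)
    if n == 1:
        return traj, 0
    keep = [0]
    last = 0
    for i in range(1, n):
        d = haversine_km((traj.lat[last], traj.lon[last]), (traj.lat[i], traj.lon[i]))
        dt = (traj.time[i] - traj.time[last]) / 3600.0
        if d / dt <= vmax_kmh:
            keep.append(i)
            last = i
    idx = np.asarray(keep)
    removed = n - idx.size
    if removed:
        logger.info("speed_filter: removed %d/%d fixes (> %g km/h)", removed, n, vmax_kmh)
    out = replace(traj, time=traj.time[idx], lat=traj.lat[idx], lon=traj.lon[idx])
    return out, removed


def resample(
    traj: Trajectory, interval_min: float, max_gap_min: float | None = None
) -> list[Trajectory]:
    """Resample to a regular grid t0, t0+dt, ... by linear interpolation.

    Latitude and longitude are interpolated independently in geographic
    coordinates; longitudes are unwrapped first so tracks crossing the
    antimeridian interpolate along the short way.  Grid points falling in a
    recording gap larger than ``max_gap_min`` (default 3x the interval) are
    not fabricated: the output is split into gap-free segments.
    """
    if len(traj) < 2:
        raise ValueError("resample needs at least 2 fixes")
    if interval_min <= 0:
        raise ValueError("interval must be positive")
    if max_gap_min is None:
        max_gap_min = 3.0 * interval_min
    dt = interval_min * 60.0
    n_steps = int(np.floor((traj.time[-1] - traj.time[0]) / dt + 1e-6))
    grid = traj.time[0] + dt * np.arange(n_steps + 1)
    grid = grid[grid <= traj.time[-1] + 1e-6]

    lon_unwrapped = np.degrees(np.unwrap(np.radians(traj.lon)))
    glat = np.interp(grid, traj.time, traj.lat)
    glon = np.interp(grid, traj.time, lon_unwrapped)
    glon = np.degrees(np.angle(np.exp(1j * np.radians(glon))))  # re-wrap to (-180, 180]

    # a grid point is valid unless it lies strictly inside an oversized gap
    gap_start = traj.time[:-1]
    gap_end = traj.time[1:]
    big = (gap_end - gap_start) > max_gap_min * 60.0
    valid = np.ones(grid.size, dtype=bool)
    for s, e in zip(gap_start[big], gap_end[big]):
        valid &= ~((grid > s) & (grid < e))

    segments: list[Trajectory] = []
    if not valid.any():
        return segments
    breaks = np.flatnonzero(np.diff(np.flatnonzero(valid)) > 1)
    vidx = np.flatnonzero(valid)
    bounds = np.split(vidx, breaks + 1)
    for part in bounds:
        if part.size < 1:
            continue
        segments.append(
            replace(traj, time=grid[part], lat=glat[part], lon=glon[part])
        )
    return segments


def read_gps_csv(path) -> pd.DataFrame:
    """Read a GPS fix table with columns individual_id,time_iso8601,lat,lon.

    Malformed rows (unparseable time, out-of-range or missing coordinates)
    are logged and skipped; the returned frame has columns
    ``individual_id``, ``time`` (epoch seconds) , ``lat``, ``lon`` sorted by
    individual then time.
    """
    df = pd.read_csv(path, dtype={"individual_id": str})
    required = {"individual_id", "time_iso8601", "lat", "lon"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"GPS CSV missing columns: {sorted(missing)}")
    t = pd.to_datetime(df["time_iso8601"], errors="coerce", utc=True, format="ISO8601")
    lat = pd.to_numeric(df["lat"], errors="coerce")
    lon = pd.to_numeric(df["lon"], errors="coerce")
    ok = t.notna() & lat.between(-90, 90) & lon.between(-180, 180)
    n_bad = int((~ok).sum())
    if n_bad:
        logger.warning("read_gps_csv: skipped %d malformed rows of %d", n_bad, len(df))
    out = pd.DataFrame(
        {
            "individual_id": df.loc[ok, "individual_id"],
            "time": t[ok].astype("int64") / 1e9,
            "lat": lat[ok],
            "lon": lon[ok],
        }
    ).sort_values(["individual_id", "time"], kind="stable")
    out.attrs["n_skipped"] = n_bad
    return out.reset_index(drop=True)


def write_gps_csv(df: pd.DataFrame, path) -> None:
    """Write the mirror of :func:`read_gps_csv` (ISO-8601 UTC timestamps)."""
    out = pd.DataFrame(
        {
            "individual_id": df["individual_id"],
            "time_iso8601": pd.to_datetime(df["time"], unit="s", utc=True).dt.strftime(
                "%Y-%m-%dT%H:%M:%SZ"
            ),
            "lat": df["lat"].map(lambda v: f"{v:.6f}"),
            "lon": df["lon"].map(lambda v: f"{v:.6f}"),
        }
    )
    out.to_csv(path, index=False)


def trajectory_from_frame(
    df: pd.DataFrame, individual_id: str, species: str, colony: tuple[float, float]
) -> Trajectory:
    """Build a Trajectory for one individual from a read_gps_csv frame.

    Duplicate timestamps keep the first occurrence (logged).
    """
    sub = df[df["individual_id"] == individual_id]
    if sub.empty:
        raise ValueError(f"no fixes for individual {individual_id!r}")
    t = sub["time"].to_numpy()
    keep = np.concatenate(([True], np.diff(t) > 0))
    if not keep.all():
        logger.warning(
            "%s: dropped %d duplicate-timestamp fixes", individual_id, int((~keep).sum())
        )
    return Trajectory(
        individual_id=individual_id,
        species=species,
        colony=colony,
        time=t[keep],
        lat=sub["lat"].to_numpy()[keep],
        lon=sub["lon"].to_numpy()[keep],
    )
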