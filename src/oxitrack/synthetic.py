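"""Ground-truth-known synthetic data for the whole pipeline.

The track generator emulates a central-place forager: an individual
alternates colony dwell periods (resting near the colony) with foraging
trips.  Within a trip, a 3-state Markov chain (resting / foraging /
flight) drives gamma step lengths and von Mises turning angles at the
logger sampling interval; the heading is additionally pulled away from the
colony on the outbound leg and back toward it on the return leg, which is
the minimal mechanism that produces clean, countable trips.  Local planar
steps are converted to latitude/longitude by a small-step equirectangular
approximation (error far below GPS noise for steps up to ~10 km).

Assay values are linearly driven by per-individual behavioral covariates:
deployment levels are Gaussian baselines and the retrieval value adds a
configured linear effect of the covariates plus Gaussian noise, then the
analyzer detection limits flag censoring.  True states, trips, and effect
sizes are emitted alongside so recovery can be scored.

Default scales follow the field system the pipeline targets: gull-like
baselines (d-ROMs ~ 130 U. CARR, BAP ~ 1,440 uM/L), 5-min logger interval,
multi-day deployments with a handful of trips per bird.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import hmm as hmm_mod
from .geo import destination_point, haversine_km, initial_bearing_rad, wrap_angle
from .hmm import HmmModel
from .trajectory import Trajectory


def well_separated_model() -> HmmModel:
    """A cleanly separated 3-state model used for parameter-recovery studies.

    Step means 0.05 / 1 / 5 km, angular concentrations 1 / 0.5 / 10:
    resting (short steps), foraging (medium steps, diffuse headings),
    flight (long, straight steps).
    """
    return HmmModel(
        step_mean=[0.05, 1.0, 5.0],
        step_sd=[0.04, 0.7, 2.0],
        angle_mean=[0.0, 0.0, 0.0],
        angle_kappa=[1.0, 0.5, 10.0],
        tpm=[[0.90, 0.08, 0.02], [0.10, 0.80, 0.10], [0.05, 0.10, 0.85]],
        delta=[1 / 3, 1 / 3, 1 / 3],
    )


def default_track_model(interval_min: float = 5.0) -> HmmModel:
    """Movement states at the logger interval for the track generator.

    Means are per-interval step lengths; at 5 min, the flight mean of
    2.5 km implies ~30 km/h ground speed (well under the 90 km/h filter)
    and the resting mean of 20 m is effectively stationary.
    """
    scale = interval_min / 5.0
    return HmmModel(
        step_mean=np.array([0.01, 0.6, 2.5]) * scale,
        step_sd=np.array([0.008, 0.35, 0.9]) * scale,
        angle_mean=[0.0, 0.0, 0.0],
        angle_kappa=[0.5, 0.3, 15.0],
        tpm=[[0.95, 0.04, 0.01], [0.05, 0.90, 0.05], [0.02, 0.08, 0.90]],
        delta=[1.0, 0.0, 0.0],
    )


@dataclass
class SimConfig:
    """Study conditions for the synthetic bundle."""

    n_individuals: int = 40
    species: str = "gull"
    colony: tuple[float, float] = (39.3, 141.9)
    interval_min: float = 5.0
    duration_days: float = 7.0
    dropout_prob: float = 0.0
    year: int = 2021
    # trip machinery
    dwell_mean_h: float = 4.0
    trip_mean_h: float = 7.0
    trip_sd_log: float = 0.5  # within-bird lognormal spread of trip length
    bird_sd_log: float = 0.7  # per-bird spread of dwell/trip tendencies
    flight_rate_sd_log: float = 0.8  # per-bird spread of flight-initiation rate
    outbound_bias: float = 0.55  # 0..1 pull toward the drift bearing
    home_radius_km: float = 0.3
    movement: HmmModel = field(default_factory=default_track_model)
    # assay model
    baseline_drom_mean: float = 131.5
    baseline_drom_sd: float = 76.5
    baseline_bap_mean: float = 1437.5
    baseline_bap_sd: float = 416.7
    drom_effects: dict = field(
        default_factory=lambda: {"total_flight_distance_km": 0.06, "sex_male": 50.0}
    )
    drom_intercept: float = -10.0
    drom_noise_sd: float = 30.0
    bap_effects: dict = field(
        default_factory=lambda: {"avg_takeoff_freq_per_h": -450.0, "sex_male": 600.0}
    )
    bap_intercept: float = 45.0
    bap_noise_sd: float = 120.0


def simulate_states(tpm, n: int, rng: np.random.Generator, delta=None) -> np.ndarray:
    """Sample a Markov state chain of length n from transition matrix tpm."""
    tpm = np.asarray(tpm, dtype=float)
    K = tpm.shape[0]
    if delta is None:
        delta = np.full(K, 1.0 / K)
    states = np.empty(n, dtype=int)
    states[0] = rng.choice(K, p=np.asarray(delta, float))
    cum = tpm.cumsum(axis=1)
    u = rng.random(n)
    for t in range(1, n):
        states[t] = int(np.searchsorted(cum[states[t - 1]], u[t]))
    return states


def simulate_hmm_series(
    model: HmmModel, T: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw (steps, angles, true_states) directly from the emission model.

    The first angle is missing (NaN), as in real step/turn series.
    """
    states = simulate_states(model.tpm, T, rng, model.delta)
    shape, scale = model._gamma_shape_scale()
    steps = rng.gamma(shape[states], scale[states])
    angles = np.array(
        [rng.vonmises(model.angle_mean[s], model.angle_kappa[s]) for s in states]
    )
    angles[0] = np.nan
    return steps, angles, states


def simulate_track(
    cfg: SimConfig,
    individual_id: str,
    rng: np.random.Generator,
    start_time: float = 1_600_000_000.0,
) -> tuple[Trajectory, np.ndarray]:
    """Simulate one individual's trajectory; returns (trajectory, true states).

    True states are indices into the generator's movement model
    (0 = resting, 1 = foraging, 2 = flight); colony dwell periods are
    resting.
    """
    mdl = cfg.movement
    dt_s = cfg.interval_min * 60.0
    n = int(cfg.duration_days * 24.0 * 60.0 / cfg.interval_min) + 1
    shape, scale = mdl._gamma_shape_scale()

    # per-bird heterogeneity in trip tendencies and flight-initiation rate
    # widens across-individual covariate spread, as field deployments do
    bird_trip_h = cfg.trip_mean_h * rng.lognormal(0.0, cfg.bird_sd_log)
    bird_dwell_h = cfg.dwell_mean_h * rng.lognormal(0.0, cfg.bird_sd_log)
    tpm = np.asarray(mdl.tpm, dtype=float).copy()
    f = rng.lognormal(0.0, cfg.flight_rate_sd_log)
    for row in range(tpm.shape[0]):
        if row != 2:
            tpm[row, 2] = min(tpm[row, 2] * f, 0.5)
        tpm[row] /= tpm[row].sum()
    cum = tpm.cumsum(axis=1)

    lat = np.empty(n)
    lon = np.empty(n)
    states = np.empty(n, dtype=int)
    clat, clon = cfg.colony
    lat[0], lon[0] = clat, clon
    states[0] = 0

    mode = "dwell"
    mode_left = rng.exponential(bird_dwell_h) * 3600.0
    trip_total = 0.0
    heading = rng.uniform(-np.pi, np.pi)
    out_bearing = heading
    state = 0
    for t in range(1, n):
        if mode == "dwell":
            state = 0
            # resting walk: gamma steps, uniform heading, homing pull so the
            # bird stays within a few hundred meters of the colony
            step = rng.gamma(shape[0], scale[0])
            if haversine_km((lat[t - 1], lon[t - 1]), (clat, clon)) > 0.3:
                ang = float(initial_bearing_rad((lat[t - 1], lon[t - 1]), (clat, clon)))
            else:
                ang = rng.uniform(-np.pi, np.pi)
            lat[t], lon[t] = destination_point(lat[t - 1], lon[t - 1], ang, step)
            mode_left -= dt_s
            if mode_left <= 0:
                mode = "outbound"
                trip_total = max(rng.lognormal(np.log(bird_trip_h), cfg.trip_sd_log), 1.0)
                mode_left = 0.5 * trip_total * 3600.0
                out_bearing = rng.uniform(-np.pi, np.pi)
                heading = out_bearing
                state = 2  # leave in flight
        else:
            state = int(np.searchsorted(cum[state], rng.random()))
            step = rng.gamma(shape[state], scale[state])
            turn = rng.vonmises(mdl.angle_mean[state], mdl.angle_kappa[state])
            if mode == "outbound":
                target = out_bearing
            else:  # return
                target = float(
                    initial_bearing_rad((lat[t - 1], lon[t - 1]), (clat, clon))
                )
            free = heading + turn
            # only directed (flight) movement is pulled along the trip drift;
            # searching and resting keep their own tortuosity
            b = cfg.outbound_bias if state == 2 else 0.0
            heading = float(
                np.angle((1.0 - b) * np.exp(1j * free) + b * np.exp(1j * target))
            )
            lat[t], lon[t] = destination_point(lat[t - 1], lon[t - 1], heading, step)
            mode_left -= dt_s
            if mode == "outbound" and mode_left <= 0:
                mode = "return"
                mode_left = np.inf
            elif mode == "return":
                if haversine_km((lat[t], lon[t]), (clat, clon)) < cfg.home_radius_km:
                    lat[t], lon[t] = clat, clon
                    mode = "dwell"
                    state = 0
                    mode_left = rng.exponential(bird_dwell_h) * 3600.0
        states[t] = state

    time = start_time + dt_s * np.arange(n)
    if cfg.dropout_prob > 0:
        keep = rng.random(n) >= cfg.dropout_prob
        keep[0] = keep[-1] = True
        time, lat, lon, states = time[keep], lat[keep], lon[keep], states[keep]
    traj = Trajectory(
        individual_id=individual_id,
        species=cfg.species,
        colony=cfg.colony,
        time=time,
        lat=lat,
        lon=lon,
        sampling_note=f"synthetic, {cfg.interval_min:g}-min interval",
    )
    return traj, states


def simulate_assays(
    cfg: SimConfig, individual_metrics: pd.DataFrame, rng: np.random.Generator
) -> tuple[pd.DataFrame, dict]:
    """Draw paired assay records driven by per-individual covariates.

    ``individual_metrics`` needs one row per individual with the covariate
    columns named in ``cfg.drom_effects`` / ``cfg.bap_effects``.  Returns
    the long-format assay table and the truth dict of generating effects.
    """
    rows = []
    for _, r in individual_metrics.iterrows():
        d0 = max(rng.normal(cfg.baseline_drom_mean, cfg.baseline_drom_sd), 1.0)
        b0 = max(rng.normal(cfg.baseline_bap_mean, cfg.baseline_bap_sd), 1.0)
        dd = cfg.drom_intercept + rng.normal(0.0, cfg.drom_noise_sd)
        for cov, beta in cfg.drom_effects.items():
            dd += beta * float(r[cov])
        db = cfg.bap_intercept + rng.normal(0.0, cfg.bap_noise_sd)
        for cov, beta in cfg.bap_effects.items():
            db += beta * float(r[cov])
        rows.append((r["individual_id"], "deploy", d0, b0))
        rows.append((r["individual_id"], "retrieve", max(d0 + dd, 0.0), max(b0 + db, 0.0)))
    records = pd.DataFrame(
        rows, columns=["individual_id", "timepoint", "drom_ucarr", "bap_umol_l"]
    )
    truth = {
        "drom_effects": dict(cfg.drom_effects),
        "drom_intercept": cfg.drom_intercept,
        "bap_effects": dict(cfg.bap_effects),
        "bap_intercept": cfg.bap_intercept,
    }
    return records, truth


def true_covariates(
    traj: Trajectory, true_states: np.ndarray, rule, run_min: int = 2
) -> dict:
    """Generator-truth behavioral covariates for one simulated individual.

    Trip metrics come from the package's own segmentation on the simulated
    track; foraging duration comes from the *true* state labels, so the
    covariates are ground truth rather than HMM estimates.
    """
    from . import trips as trips_mod

    trip_list = trips_mod.segment_trips(traj, rule)
    tms = [trips_mod.trip_metrics(traj, tr) for tr in trip_list]
    labels = [hmm_mod.STATE_LABELS[s] for s in true_states]
    seq = hmm_mod.StateSequence(
        states=np.asarray(true_states), times=traj.time, decode_method="truth"
    )
    seq.labels = labels
    _, forage_h = hmm_mod.foraging_phases(seq, run_min=run_min)
    im = trips_mod.individual_metrics(
        traj.individual_id, tms, forage_h, traj.duration_h
    )
    return {
        "individual_id": traj.individual_id,
        "n_trips": im.n_trips,
        "total_flight_distance_km": im.total_flight_distance_km,
        "total_takeoffs": im.total_takeoffs,
        "avg_max_distance_km": im.avg_max_distance_km,
        "avg_takeoff_freq_per_h": im.avg_takeoff_freq_per_h,
        "foraging_duration_h": im.foraging_duration_h,
        "pct_foraging": im.pct_foraging,
    }


def simulate_bundle(cfg: SimConfig, seed: int) -> dict:
    """Simulate the full study: tracks, true states, metadata and assays.

    Returns a dict with keys ``trajectories`` (list), ``true_states``
    (list of arrays), ``gps`` / ``assays`` / ``meta`` (DataFrames in the
    pipeline's CSV dialects), ``covariates`` (generator-truth table) and
    ``truth`` (generating coefficients).  Byte-identical for a given
    (cfg, seed).
    """
    from . import trips as trips_mod

    rng = np.random.default_rng(seed)
    rule = trips_mod.TripRule.for_species(cfg.species)
    trajs: list[Trajectory] = []
    all_states: list[np.ndarray] = []
    cov_rows = []
    meta_rows = []
    gps_frames = []
    for i in range(cfg.n_individuals):
        iid = f"bird{i:03d}"
        traj, st = simulate_track(cfg, iid, rng)
        trajs.append(traj)
        all_states.append(st)
        cov = true_covariates(traj, st, rule)
        sex = int(rng.random() < 0.5)
        cov["sex_male"] = sex
        cov_rows.append(cov)
        meta_rows.append(
            {
                "individual_id": iid,
                "species": cfg.species,
                "sex": "male" if sex else "female",
                "year": cfg.year,
            }
        )
        gps_frames.append(
            pd.DataFrame(
                {
                    "individual_id": iid,
                    "time": traj.time,
                    "lat": traj.lat,
                    "lon": traj.lon,
                }
            )
        )
    covariates = pd.DataFrame(cov_rows)
    assays, truth = simulate_assays(cfg, covariates, rng)
    return {
        "trajectories": trajs,
        "true_states": all_states,
        "gps": pd.concat(gps_frames, ignore_index=True),
        "assays": assays,
        "meta": pd.DataFrame(meta_rows),
        "covariates": covariates,
        "truth": truth,
    }
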