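"""End-to-end orchestration: ingest -> filter -> trips -> HMM -> statistics.

`run_pipeline` reads GPS fixes, per-individual metadata (species, sex,
year) and paired assay values, derives per-trip and per-individual
foraging metrics, fits and decodes the 3-state movement HMM, and relates
behavior to oxidative-stress changes with Tobit / linear / Bayesian
models after VIF pruning.  Every stage logs what it kept and dropped;
reruns with the same config are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import __version__, flight, hmm, oxidative, trips
from .flight import LandMask
from .trajectory import Trajectory, compute_steps, read_gps_csv, resample, speed_filter, trajectory_from_frame

logger = logging.getLogger(__name__)

BEHAVIOR_COVARIATES = [
    "total_flight_distance_km",
    "total_takeoffs",
    "avg_max_distance_km",
    "avg_takeoff_freq_per_h",
    "foraging_duration_h",
    "pct_foraging",
]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class TripRuleConfig(_Strict):
    min_colony_km: float = Field(gt=0)
    min_duration_h: float = Field(gt=0)


class HmmConfig(_Strict):
    n_states: int = 3
    n_restarts: int = 10
    run_min: int = 2
    decode: str = "viterbi"  # or "local"
    resample_min: float = 10.0
    seed: int = 0


class RegressionConfig(_Strict):
    vif_threshold: float = 3.0
    n_draws: int = 4000
    seed: int = 0
    exclude_below_detection: bool = True


class LimitsConfig(_Strict):
    drom: tuple[float, float] = oxidative.DROM_LIMITS
    bap: tuple[float, float] = oxidative.BAP_LIMITS


class PipelineConfig(_Strict):
    """Schema-validated pipeline configuration; unknown keys are rejected."""

    gps_csv: str
    assay_csv: str
    meta_csv: str
    out_dir: str
    colony_lat: float
    colony_lon: float
    land_mask: str | None = None
    speed_filter_vmax_kmh: float = 90.0
    flight_threshold_kmh: float = 15.0
    land_resample_min: float = 1.0
    land_flight_only: bool = True
    trip_rules: dict[str, TripRuleConfig] = Field(
        default_factory=lambda: {
            "gull": TripRuleConfig(min_colony_km=1.0, min_duration_h=1.0),
            "shearwater": TripRuleConfig(min_colony_km=3.0, min_duration_h=6.0),
        }
    )
    hmm: HmmConfig = Field(default_factory=HmmConfig)
    regression: RegressionConfig = Field(default_factory=RegressionConfig)
    detection_limits: LimitsConfig = Field(default_factory=LimitsConfig)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh))


def _steps_for_segments(segments: list[Trajectory]):
    out = []
    for seg in segments:
        if len(seg) < 2:
            continue
        ss = compute_steps(seg)
        out.append((seg, ss))
    return out


def make_table1(
    fits_by_year: dict, all_params: list[str]
) -> pd.DataFrame:
    """Sign-summary matrix: rows = parameters, columns = years.

    Each cell is "+" or "-" when the 95% credible interval excludes zero,
    "N.S." otherwise, and blank when the parameter was removed by VIF
    pruning (or never available) that year.
    """
    years = sorted(fits_by_year)
    table = pd.DataFrame("", index=all_params, columns=[str(y) for y in years])
    sym = {"positive": "+", "negative": "-", "none": "N.S."}
    for y in years:
        fit = fits_by_year[y]
        if fit is None:
            continue
        for name, call in zip(fit.coef_names, fit.sign_call):
            if name in all_params:
                table.loc[name, str(y)] = sym[call]
    table.index.name = "parameter"
    return table


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; writes the report bundle and returns it.

    Returns a dict with the per-trip table, per-individual metrics, decoded
    states, model fits, sign tables and the record-accounting log.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    accounting: list[dict] = []

    def account(stage: str, **kw) -> None:
        accounting.append({"stage": stage, **kw})
        logger.info("%s: %s", stage, kw)

    gps = read_gps_csv(config.gps_csv)
    account("read_gps", n_rows=len(gps), n_skipped=gps.attrs.get("n_skipped", 0))
    meta = pd.read_csv(config.meta_csv, dtype={"individual_id": str})
    for col in ("individual_id", "species", "sex", "year"):
        if col not in meta.columns:
            raise ValueError(f"metadata CSV missing column {col!r}")
    records = oxidative.read_assay_csv(config.assay_csv)
    account("read_assays", n_rows=len(records))

    colony = (config.colony_lat, config.colony_lon)
    mask = LandMask.from_geojson(config.land_mask) if config.land_mask else None

    ids = sorted(gps["individual_id"].unique())
    meta_idx = meta.set_index("individual_id")

    trip_rows = []
    indiv_rows = []
    state_rows = []
    hmm_tracks = []  # (individual_id, segment, StepSeries)
    per_indiv: dict[str, dict] = {}

    for iid in ids:
        if iid not in meta_idx.index:
            account("skip_individual", individual_id=iid, reason="missing metadata")
            continue
        species = str(meta_idx.loc[iid, "species"])
        traj = trajectory_from_frame(gps, iid, species, colony)
        traj_f, n_removed = speed_filter(traj, config.speed_filter_vmax_kmh)
        account("speed_filter", individual_id=iid, n_removed=n_removed, n_kept=len(traj_f))
        rule_cfg = config.trip_rules[species]
        rule = trips.TripRule(rule_cfg.min_colony_km, rule_cfg.min_duration_h)
        trip_list = trips.segment_trips(traj_f, rule)
        tms = [
            trips.trip_metrics(traj_f, tr, config.flight_threshold_kmh) for tr in trip_list
        ]
        account("segment_trips", individual_id=iid, n_trips=len(trip_list))
        for k, tm in enumerate(tms):
            trip_rows.append(
                {
                    "individual_id": iid,
                    "trip": k,
                    "start_time": tm.trip.start_time,
                    "end_time": tm.trip.end_time,
                    "duration_h": tm.duration_h,
                    "total_flight_distance_km": tm.total_flight_distance_km,
                    "max_colony_distance_km": tm.max_colony_distance_km,
                    "n_takeoffs": tm.n_takeoffs,
                    "takeoff_freq_per_h": tm.takeoff_freq_per_h,
                }
            )
        if len(traj_f) >= 2:
            segs = resample(traj_f, config.hmm.resample_min)
            seg_steps = _steps_for_segments(segs)
        else:
            seg_steps = []
        hmm_tracks.extend((iid, seg, ss) for seg, ss in seg_steps)
        per_indiv[iid] = {
            "species": species,
            "traj_f": traj_f,
            "rule": rule,
            "trip_list": trip_list,
            "tms": tms,
        }

    # one shared HMM across individuals
    model = None
    mapping = None
    if hmm_tracks:
        fit = hmm.fit_hmm(
            [(ss.step_km, ss.turn_rad) for _, _, ss in hmm_tracks],
            K=config.hmm.n_states,
            n_restarts=config.hmm.n_restarts,
            seed=config.hmm.seed,
        )
        model = fit.model
        mapping = hmm.label_states(model)
        account("fit_hmm", loglik=fit.loglik, converged=fit.converged)
        (out_dir / "hmm_model.txt").write_text(model.to_text())

    forage_by_id: dict[str, float] = {}
    for iid, seg, ss in hmm_tracks:
        decode = hmm.viterbi if config.hmm.decode == "viterbi" else hmm.local_decode
        seq = decode(model, ss.step_km, ss.turn_rad, times=seg.time[1:])
        hmm.apply_labels(seq, mapping)
        _, fh = hmm.foraging_phases(seq, run_min=config.hmm.run_min)
        forage_by_id[iid] = forage_by_id.get(iid, 0.0) + fh
        for t, s, lab in zip(seq.times, seq.states, seq.labels):
            state_rows.append(
                {"individual_id": iid, "time": t, "state": int(s), "label": lab}
            )

    for iid, d in per_indiv.items():
        traj_f = d["traj_f"]
        pct_land = float("nan")
        if mask is not None and d["species"] == "gull" and len(traj_f) >= 2:
            segs1 = resample(traj_f, config.land_resample_min)
            lats, lons, speeds, in_trip = [], [], [], []
            windows = [(tr.start_time, tr.end_time) for tr in d["trip_list"]]
            for seg in segs1:
                if len(seg) < 2:
                    continue
                ss = compute_steps(seg)
                lats.append(seg.lat[1:])
                lons.append(seg.lon[1:])
                speeds.append(ss.speed_kmh)
                tmid = seg.time[1:]
                inw = np.zeros(tmid.size, dtype=bool)
                for s, e in windows:
                    inw |= (tmid >= s) & (tmid <= e)
                in_trip.append(inw)
            if lats:
                pct_land = flight.land_utilization(
                    np.concatenate(lats),
                    np.concatenate(lons),
                    np.concatenate(speeds),
                    np.concatenate(in_trip),
                    mask,
                    config.flight_threshold_kmh,
                    config.land_flight_only,
                )
        im = trips.individual_metrics(
            iid,
            d["tms"],
            forage_by_id.get(iid, 0.0),
            traj_f.duration_h,
            pct_land=pct_land,
        )
        indiv_rows.append(
            {
                "individual_id": iid,
                "species": d["species"],
                "sex": str(meta_idx.loc[iid, "sex"]),
                "year": int(meta_idx.loc[iid, "year"]),
                "n_trips": im.n_trips,
                "total_trip_duration_h": im.total_trip_duration_h,
                "total_flight_distance_km": im.total_flight_distance_km,
                "avg_max_distance_km": im.avg_max_distance_km,
                "avg_takeoff_freq_per_h": im.avg_takeoff_freq_per_h,
                "total_takeoffs": im.total_takeoffs,
                "foraging_duration_h": im.foraging_duration_h,
                "pct_foraging": im.pct_foraging,
                "pct_land": im.pct_land,
            }
        )

    trips_df = pd.DataFrame(trip_rows)
    indiv_df = pd.DataFrame(indiv_rows).sort_values("individual_id").reset_index(drop=True)
    states_df = pd.DataFrame(state_rows)

    # ---- assay statistics -------------------------------------------------
    limits = oxidative.DetectionLimits(
        drom=tuple(config.detection_limits.drom), bap=tuple(config.detection_limits.bap)
    )
    changes = oxidative.compute_changes(records)
    n_unpaired = int(changes["delta_drom"].isna().sum())
    account("compute_changes", n_individuals=len(changes), n_unpaired=n_unpaired)

    levels = records.merge(meta, on="individual_id", how="left")
    # reproduce the below-detection exclusion for d-ROMs analyses
    drom_excluded: set[str] = set()
    if config.regression.exclude_below_detection:
        low = levels.groupby("individual_id")["drom_ucarr"].min() <= limits.drom[0]
        drom_excluded = set(low[low].index)
        if drom_excluded:
            account(
                "exclude_below_detection",
                assay="drom",
                n_excluded=len(drom_excluded),
            )

    species_levels = sorted(levels["species"].dropna().unique())
    tobit_fits = {}
    linear_fits = {}
    if len(species_levels) == 2:
        ref, other = species_levels
        for assay, lim in (("drom_ucarr", limits.drom), ("bap_umol_l", limits.bap)):
            sub = levels.dropna(subset=[assay, "species"])
            if assay == "drom_ucarr":
                sub = sub[~sub["individual_id"].isin(drom_excluded)]
            if sub["species"].nunique() < 2 or len(sub) < 4:
                account("tobit_skip", assay=assay, reason="insufficient data")
                continue
            y = sub[assay].to_numpy(dtype=float)
            X = np.column_stack(
                [np.ones(len(sub)), (sub["species"] == other).to_numpy(float)]
            )
            tobit_fits[assay] = oxidative.tobit_fit(
                y, X, lim, coef_names=["intercept", f"species[{other}]"]
            )
        ch = changes.merge(meta, on="individual_id", how="left")
        for assay, resp in (("drom", "delta_drom"), ("bap", "delta_bap")):
            sub = ch.dropna(subset=[resp, "species"])
            if assay == "drom":
                sub = sub[~sub["individual_id"].isin(drom_excluded)]
            if sub["species"].nunique() < 2 or len(sub) < 4:
                account("linear_skip", assay=assay, reason="insufficient data")
                continue
            y = sub[resp].to_numpy(dtype=float)
            X = np.column_stack(
                [np.ones(len(sub)), (sub["species"] == other).to_numpy(float)]
            )
            linear_fits[resp] = oxidative.linear_fit(
                y, X, coef_names=["intercept", f"species[{other}]"]
            )

    # ---- per species x year Bayesian fits --------------------------------
    analysis = indiv_df.merge(changes, on="individual_id", how="left")
    analysis["sex_male"] = (analysis["sex"].str.lower() == "male").astype(float)
    bayes_fits: dict[str, dict] = {"delta_drom": {}, "delta_bap": {}}
    vif_tables = []
    all_params = BEHAVIOR_COVARIATES + ["pct_land", "sex_male"]
    rng_seq = np.random.SeedSequence(config.regression.seed)
    for (species, year), grp in analysis.groupby(["species", "year"], sort=True):
        covs = list(BEHAVIOR_COVARIATES)
        if species == "gull" and grp["pct_land"].notna().all() and grp["pct_land"].nunique() > 1:
            covs.append("pct_land")
        for resp in ("delta_drom", "delta_bap"):
            sub = grp.dropna(subset=[resp] + covs)
            if resp == "delta_drom":
                sub = sub[~sub["individual_id"].isin(drom_excluded)]
            sub = sub[sub["n_trips"] > 0]
            n_skipped = len(grp) - len(sub)
            if n_skipped:
                account(
                    "bayes_skip_rows",
                    species=species,
                    year=int(year),
                    response=resp,
                    n_skipped=n_skipped,
                    reason="missing response/covariates or zero trips",
                )
            usable = [c for c in covs if sub[c].std() > 0]
            if len(sub) < len(usable) + 3 or len(usable) < 2:
                account(
                    "bayes_skip_model",
                    species=species,
                    year=int(year),
                    response=resp,
                    reason="too few usable rows/predictors",
                )
                bayes_fits[resp][(species, int(year))] = None
                continue
            retained, vif_table = oxidative.vif_prune(
                sub[usable + ["sex_male"]], config.regression.vif_threshold
            )
            vif_table.insert(0, "response", resp)
            vif_table.insert(0, "year", int(year))
            vif_table.insert(0, "species", species)
            vif_tables.append(vif_table)
            y = sub[resp].to_numpy(dtype=float)
            X = np.column_stack(
                [np.ones(len(sub))] + [sub[c].to_numpy(dtype=float) for c in retained]
            )
            child_seed = int(rng_seq.spawn(1)[0].generate_state(1)[0] % (2**31))
            fit = oxidative.bayes_lm(
                y,
                X,
                coef_names=["intercept"] + retained,
                n_draws=config.regression.n_draws,
                seed=child_seed,
            )
            bayes_fits[resp][(species, int(year))] = fit
            account(
                "bayes_fit",
                species=species,
                year=int(year),
                response=resp,
                n=len(sub),
                retained=",".join(retained),
            )

    tables1 = {}
    for resp in ("delta_drom", "delta_bap"):
        by_year: dict[int, object] = {}
        for (species, year), fit in bayes_fits[resp].items():
            by_year[year] = fit  # one species per run is the common case
        if by_year:
            tables1[resp] = make_table1(by_year, all_params)

    # ---- write the bundle -------------------------------------------------
    fmt = "%.6g"
    if not trips_df.empty:
        trips_df.to_csv(out_dir / "trips.csv", index=False, float_format=fmt)
    indiv_df.to_csv(out_dir / "individuals.csv", index=False, float_format=fmt)
    if not states_df.empty:
        states_df.to_csv(out_dir / "states.csv", index=False, float_format=fmt)
    changes.to_csv(out_dir / "changes.csv", index=False, float_format=fmt)
    _write_fit_tables(out_dir, tobit_fits, linear_fits, bayes_fits, fmt)
    if vif_tables:
        pd.concat(vif_tables, ignore_index=True).to_csv(
            out_dir / "vif.csv", index=False, float_format=fmt
        )
    for resp, tbl in tables1.items():
        tbl.to_csv(out_dir / f"table1_{resp}.csv")
    pd.DataFrame(accounting).to_csv(out_dir / "record_log.csv", index=False)
    _write_manifest(out_dir, config)

    return {
        "trips": trips_df,
        "individuals": indiv_df,
        "states": states_df,
        "changes": changes,
        "hmm_model": model,
        "tobit_fits": tobit_fits,
        "linear_fits": linear_fits,
        "bayes_fits": bayes_fits,
        "table1": tables1,
        "accounting": accounting,
    }


def _write_fit_tables(out_dir: Path, tobit_fits, linear_fits, bayes_fits, fmt) -> None:
    rows = []
    for assay, fit in tobit_fits.items():
        df = fit.summary()
        df.insert(0, "model", f"tobit_{assay}")
        rows.append(df)
    for resp, fit in linear_fits.items():
        df = fit.summary()
        df.insert(0, "model", f"linear_{resp}")
        rows.append(df)
    if rows:
        pd.concat(rows, ignore_index=True).to_csv(
            out_dir / "species_models.csv", index=False, float_format=fmt
        )
    brows = []
    for resp, d in bayes_fits.items():
        for (species, year), fit in d.items():
            if fit is None:
                continue
            df = fit.summary().drop(columns=["rhat"])
            df.insert(0, "year", year)
            df.insert(0, "species", species)
            df.insert(0, "response", resp)
            brows.append(df)
    if brows:
        pd.concat(brows, ignore_index=True).to_csv(
            out_dir / "bayes_models.csv", index=False, float_format=fmt
        )


def _write_manifest(out_dir: Path, config: PipelineConfig) -> None:
    cfg_json = json.dumps(config.model_dump(), sort_keys=True, default=str)
    digest = hashlib.sha256(cfg_json.encode()).hexdigest()[:16]
    lines = [
        f"oxitrack version: {__version__}",
        f"config sha256: {digest}",
        "config:",
        cfg_json,
    ]
    (out_dir / "manifest.txt").write_text("\n".join(lines) + "\n")
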