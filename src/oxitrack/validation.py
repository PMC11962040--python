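"""Validation studies: oracle checks, recovery simulations, calibration.

These routines quantify how well the pipeline's estimators behave under
known ground truth: exact-enumeration checks of the HMM recursions,
parameter-recovery and decoding-accuracy simulations, Tobit correctness
against ordinary least squares, credible-interval calibration of the
Bayesian regression, and a full synthetic-study round trip through
``run_pipeline``.  They are used by the test suite and by the acceptance
script; each takes an explicit seed and returns plain dictionaries.
"""

from __future__ import annotations

import itertools
from pathlib import Path

import numpy as np
import pandas as pd

from . import hmm as hmm_mod
from . import oxidative
from .hmm import HmmModel, fit_hmm, hmm_loglik, prepare_series, viterbi
from .pipeline import PipelineConfig, run_pipeline
from .synthetic import SimConfig, simulate_bundle, simulate_hmm_series, well_separated_model
from .trajectory import write_gps_csv


def _random_hmm(rng: np.random.Generator, K: int = 3) -> HmmModel:
    return HmmModel(
        step_mean=rng.uniform(0.05, 5.0, K),
        step_sd=rng.uniform(0.03, 2.0, K),
        angle_mean=rng.uniform(-np.pi, np.pi, K),
        angle_kappa=rng.uniform(0.0, 8.0, K),
        tpm=rng.dirichlet(np.ones(K) * 2, size=K),
        delta=rng.dirichlet(np.ones(K)),
    )


def _enumerate_paths(model: HmmModel, steps, angles):
    """Brute-force total log-likelihood and best path over all K^T paths."""
    steps, angles = prepare_series(steps, angles)
    logb = model.log_emissions(steps, angles)
    T, K = logb.shape
    with np.errstate(divide="ignore"):
        lt = np.log(model.tpm)
        ld = np.log(model.delta)
    total = -np.inf
    best, best_lp = None, -np.inf
    for path in itertools.product(range(K), repeat=T):
        lp = ld[path[0]] + logb[0, path[0]]
        for t in range(1, T):
            lp += lt[path[t - 1], path[t]] + logb[t, path[t]]
        total = np.logaddexp(total, lp)
        if lp > best_lp:
            best, best_lp = path, lp
    return total, np.asarray(best)


def hmm_oracle_check(n_models: int = 50, t_max: int = 8, seed: int = 0) -> dict:
    """Forward/Viterbi vs exhaustive enumeration on short random sequences.

    Returns the maximum relative log-likelihood discrepancy and the
    fraction of models whose Viterbi path equals the enumerated argmax.
    """
    rng = np.random.default_rng(seed)
    max_rel = 0.0
    matches = 0
    for i in range(n_models):
        m = _random_hmm(rng)
        T = int(rng.integers(3, t_max + 1))
        steps, angles, _ = simulate_hmm_series(m, T, rng)
        ll = hmm_loglik(m, steps, angles)
        oracle_ll, oracle_path = _enumerate_paths(m, steps, angles)
        max_rel = max(max_rel, abs(ll - oracle_ll) / abs(oracle_ll))
        matches += int(np.array_equal(viterbi(m, steps, angles).states, oracle_path))
    return {"max_rel_err": max_rel, "viterbi_match_frac": matches / n_models}


def hmm_recovery_study(
    n_seeds: int = 10,
    n_tracks: int = 20,
    track_len: int = 500,
    n_restarts: int = 5,
    seed: int = 0,
) -> dict:
    """Parameter recovery and decoding accuracy for the well-separated model.

    For each replicate, tracks are simulated from the known 3-state model,
    the HMM is refit from scratch, and states are decoded by Viterbi.
    Reports the median (over replicates) worst-state relative error of the
    step-length means, the median decoding accuracy, and the median
    maximum absolute error of transition-matrix rows.
    """
    true = well_separated_model()
    rel_errs, accs, tpm_errs = [], [], []
    root = np.random.SeedSequence(seed)
    for child in root.spawn(n_seeds):
        rng = np.random.default_rng(child)
        tracks, truths = [], []
        for _ in range(n_tracks):
            s, a, st = simulate_hmm_series(true, track_len, rng)
            tracks.append((s, a))
            truths.append(st)
        fit = fit_hmm(
            tracks, K=3, n_restarts=n_restarts, seed=int(child.generate_state(1)[0] % 2**31)
        )
        order = np.argsort(fit.model.step_mean)
        est_means = fit.model.step_mean[order]
        rel_errs.append(float(np.max(np.abs(est_means - true.step_mean) / true.step_mean)))
        perm_tpm = fit.model.tpm[np.ix_(order, order)]
        tpm_errs.append(float(np.max(np.abs(perm_tpm - true.tpm))))
        rank = np.empty(3, dtype=int)
        rank[order] = np.arange(3)
        n_ok = n_tot = 0
        for (s, a), st in zip(tracks, truths):
            decoded = rank[viterbi(fit.model, s, a).states]
            n_ok += int(np.sum(decoded == st))
            n_tot += st.size
        accs.append(n_ok / n_tot)
    return {
        "median_step_mean_rel_err": float(np.median(rel_errs)),
        "median_decoding_accuracy": float(np.median(accs)),
        "median_tpm_max_abs_err": float(np.median(tpm_errs)),
    }


def tobit_study(seed: int = 0, n: int = 500) -> dict:
    """Tobit vs OLS without censoring; truth recovery with ~20% censoring."""
    rng = np.random.default_rng(seed)
    x = rng.normal(0, 1, n)
    X = np.column_stack([np.ones(n), x])
    y = 2.0 + 3.0 * x + rng.normal(0, 1.0, n)
    big = 1e12
    tob = oxidative.tobit_fit(y, X, (-big, big))
    ols = oxidative.linear_fit(y, X)
    uncens_diff = float(np.max(np.abs(tob.beta - ols.beta)))

    L = float(np.quantile(y, 0.2))
    yc = np.maximum(y, L)
    cens = oxidative.tobit_fit(yc, X, (L, big))
    z_dist = np.abs(cens.beta - np.array([2.0, 3.0])) / cens.se
    return {
        "uncensored_max_abs_diff_vs_ols": uncens_diff,
        "censored_frac": cens.n_censored_low / n,
        "beta_max_se_distance_from_truth": float(z_dist.max()),
        "beta_intercept": float(cens.beta[0]),
        "beta_slope": float(cens.beta[1]),
        "sigma": cens.sigma,
    }


def bayes_calibration_study(
    n_reps: int = 200, n: int = 50, n_draws: int = 2000, seed: int = 0
) -> dict:
    """False-sign rate under a null slope and power under a strong slope.

    Null: y ~ N(0, 1) independent of x, so the 95%-CI sign call should
    fire in about 5% of replicates.  Strong: slope 0.5 at noise sd 1 and
    n = 50 (slope z about 3.5), where power should exceed 80%.
    """
    root = np.random.SeedSequence(seed)
    null_hits = power_hits = 0
    children = root.spawn(2 * n_reps)
    for r in range(n_reps):
        rng = np.random.default_rng(children[r])
        x = rng.normal(0, 1, n)
        y = rng.normal(0, 1, n)
        X = np.column_stack([np.ones(n), x])
        fit = oxidative.bayes_lm(
            y, X, n_draws=n_draws, seed=int(children[r].generate_state(1)[0] % 2**31)
        )
        null_hits += fit.sign_call[1] != "none"
    for r in range(n_reps):
        child = children[n_reps + r]
        rng = np.random.default_rng(child)
        x = rng.normal(0, 1, n)
        y = 0.5 * x + rng.normal(0, 1.0, n)
        X = np.column_stack([np.ones(n), x])
        fit = oxidative.bayes_lm(
            y, X, n_draws=n_draws, seed=int(child.generate_state(1)[0] % 2**31)
        )
        power_hits += fit.sign_call[1] == "positive"
    return {
        "null_sign_rate": null_hits / n_reps,
        "power_strong_signal": power_hits / n_reps,
    }


def takeoff_oracle_check(n_seq: int = 1000, seed: int = 0) -> dict:
    """Vectorized takeoff counts vs a pairwise Python scan."""
    from .flight import count_takeoffs

    rng = np.random.default_rng(seed)
    mismatches = 0
    for _ in range(n_seq):
        phases = rng.random(int(rng.integers(1, 120))) < rng.uniform(0.1, 0.9)
        brute = sum(1 for a, b in zip(phases[:-1], phases[1:]) if (not a) and b)
        mismatches += int(count_takeoffs(phases) != brute)
    return {"mismatch_count": mismatches, "n_sequences": n_seq}


def end_to_end_study(
    workdir, seed: int = 0, n_individuals: int = 40, check_rerun: bool = True
) -> dict:
    """Full synthetic study through ``run_pipeline``.

    Simulates the configured study, writes its CSV bundle, runs the
    complete analysis, and scores (a) correlation between pipeline-derived
    and generator-truth covariates, (b) recovery of the generating effect
    signs by the credible-interval rule among VIF-retained covariates, and
    (c) byte-identical reruns under the same seeds.
    """
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    cfg = SimConfig(n_individuals=n_individuals)
    bundle = simulate_bundle(cfg, seed)
    write_gps_csv(bundle["gps"], workdir / "gps.csv")
    bundle["assays"].to_csv(workdir / "assays.csv", index=False, float_format="%.6g")
    bundle["meta"].to_csv(workdir / "meta.csv", index=False)
    config = PipelineConfig(
        gps_csv=str(workdir / "gps.csv"),
        assay_csv=str(workdir / "assays.csv"),
        meta_csv=str(workdir / "meta.csv"),
        out_dir=str(workdir / "report"),
        colony_lat=cfg.colony[0],
        colony_lon=cfg.colony[1],
    )
    config.hmm.seed = seed % 2**31
    config.regression.seed = seed % 2**31
    result = run_pipeline(config)

    merged = bundle["covariates"].merge(
        result["individuals"], on="individual_id", suffixes=("_true", "_rec")
    )
    corr_cols = [
        "total_flight_distance_km",
        "avg_max_distance_km",
        "avg_takeoff_freq_per_h",
        "pct_foraging",
    ]
    corrs = {
        c: float(np.corrcoef(merged[f"{c}_true"], merged[f"{c}_rec"])[0, 1])
        for c in corr_cols
    }

    truth_signs = {}
    for resp, effects in (
        ("delta_drom", bundle["truth"]["drom_effects"]),
        ("delta_bap", bundle["truth"]["bap_effects"]),
    ):
        for cov, beta in effects.items():
            truth_signs[(resp, cov)] = "positive" if beta > 0 else "negative"

    n_checked = n_correct = n_wrong = 0
    for resp in ("delta_drom", "delta_bap"):
        for (_, _), fit in result["bayes_fits"][resp].items():
            if fit is None:
                continue
            for name, call in zip(fit.coef_names, fit.sign_call):
                key = (resp, name)
                if key in truth_signs:
                    n_checked += 1
                    n_correct += int(call == truth_signs[key])
                    n_wrong += int(call not in ("none", truth_signs[key]))

    identical = None
    if check_rerun:
        config2 = config.model_copy(deep=True)
        config2.out_dir = str(workdir / "report2")
        run_pipeline(config2)
        identical = True
        for f in sorted(Path(config.out_dir).iterdir()):
            if f.name == "manifest.txt":
                continue  # embeds out_dir, which differs by construction
            g = Path(config2.out_dir) / f.name
            if not g.exists() or f.read_bytes() != g.read_bytes():
                identical = False
    return {
        "covariate_correlations": corrs,
        "min_covariate_correlation": float(min(corrs.values())),
        "n_causal_retained": n_checked,
        "n_sign_correct": n_correct,
        "n_sign_wrong_direction": n_wrong,
        "rerun_byte_identical": identical,
        "result": result,
        "bundle": bundle,
    }
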