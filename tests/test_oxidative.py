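"""Assay bookkeeping, Tobit/OLS/VIF/Bayes statistics.

Independent oracles: statsmodels for OLS and VIF; R survival::survreg
(gaussian, left-censored) for the Tobit likelihood.
"""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from oxitrack.oxidative import (
    ConvergenceError,
    bayes_lm,
    censor_flag,
    compute_changes,
    linear_fit,
    sign_call_from_ci,
    tobit_fit,
    ucarr_to_mg_h2o2_dl,
    vif_prune,
)

BIG = 1e12  # effectively uncensoring limits


class TestChanges:
    def make_records(self, rows):
        return pd.DataFrame(rows, columns=["individual_id", "timepoint", "drom_ucarr", "bap_umol_l"])

    def test_retrieve_minus_deploy(self):
        rec = self.make_records(
            [("a", "deploy", 100.0, 1500.0), ("a", "retrieve", 90.0, 1400.0)]
        )
        ch = compute_changes(rec)
        assert ch.loc[0, "delta_drom"] == pytest.approx(-10.0)
        assert ch.loc[0, "delta_bap"] == pytest.approx(-100.0)

    def test_identical_values_zero(self):
        rec = self.make_records([("a", "deploy", 80, 1600), ("a", "retrieve", 80, 1600)])
        ch = compute_changes(rec)
        assert ch.loc[0, "delta_drom"] == 0.0 and ch.loc[0, "delta_bap"] == 0.0

    def test_unpaired_reported_missing(self):
        rec = self.make_records([("a", "deploy", 80, 1600)])
        ch = compute_changes(rec)
        assert np.isnan(ch.loc[0, "delta_drom"])

    def test_duplicate_timepoint_rejected(self):
        rec = self.make_records(
            [("a", "deploy", 80, 1600), ("a", "deploy", 90, 1500)]
        )
        with pytest.raises(ValueError, match="duplicate"):
            compute_changes(rec)


class TestUnits:
    def test_one_ucarr(self):
        assert ucarr_to_mg_h2o2_dl(1.0) == pytest.approx(0.08)

    def test_zero(self):
        assert ucarr_to_mg_h2o2_dl(0.0) == 0.0

    def test_gull_scale_value(self):
        assert ucarr_to_mg_h2o2_dl(131.52) == pytest.approx(10.5216)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            ucarr_to_mg_h2o2_dl(-1.0)


class TestCensorFlag:
    @pytest.mark.parametrize(
        "value,expected",
        [(39.0, "below_lower"), (40.0, "below_lower"), (41.0, "in_range"),
         (999.0, "in_range"), (1000.0, "above_upper")],
    )
    def test_drom_limits(self, value, expected):
        assert censor_flag(value, (40.0, 1000.0)) == expected


class TestTobit:
    def simulate(self, rng, n=500, beta=(2.0, 3.0), sigma=1.0):
        x = rng.normal(0, 1, n)
        X = np.column_stack([np.ones(n), x])
        y = X @ np.asarray(beta) + rng.normal(0, sigma, n)
        return y, X

    def test_uncensored_equals_ols(self, rng):
        y, X = self.simulate(rng)
        tob = tobit_fit(y, X, (-BIG, BIG))
        ols = linear_fit(y, X)
        assert np.allclose(tob.beta, ols.beta, atol=1e-6)
        ml_sd = np.sqrt(np.mean((y - X @ ols.beta) ** 2))
        assert tob.sigma == pytest.approx(ml_sd, abs=1e-6)

    def test_intercept_only_mean(self, rng):
        y = rng.normal(10, 2, 80)
        tob = tobit_fit(y, np.ones((80, 1)), (-BIG, BIG))
        assert tob.beta[0] == pytest.approx(y.mean(), abs=1e-6)

    def test_censored_recovery_and_survreg_oracle(self, rng, tmp_path):
        y, X = self.simulate(rng, n=500)
        L = np.quantile(y, 0.2)
        yc = np.maximum(y, L)
        fit = tobit_fit(yc, X, (L, BIG))
        assert fit.n_censored_low == int(np.sum(y <= L))
        # truth within 3 standard errors
        assert abs(fit.beta[0] - 2.0) < 3 * fit.se[0]
        assert abs(fit.beta[1] - 3.0) < 3 * fit.se[1]
        rscript = shutil.which("Rscript")
        assert rscript, "Rscript required as the independent censored-regression oracle"
        data = tmp_path / "tob.csv"
        pd.DataFrame({"y": yc, "x": X[:, 1]}).to_csv(data, index=False)
        script = tmp_path / "tob.R"
        script.write_text(
            "suppressMessages(library(survival))\n"
            f"d <- read.csv('{data}')\n"
            f"event <- as.numeric(d$y > {float(L)!r})\n"
            "f <- survreg(Surv(y, event, type='left') ~ x, data=d, dist='gaussian')\n"
            "cat(sprintf('%.10f %.10f %.10f', coef(f)[1], coef(f)[2], f$scale))\n"
        )
        out = subprocess.run(
            [rscript, "--vanilla", str(script)], capture_output=True, text=True, check=True
        )
        b0, b1, scale = map(float, out.stdout.split())
        assert fit.beta[0] == pytest.approx(b0, abs=1e-4)
        assert fit.beta[1] == pytest.approx(b1, abs=1e-4)
        assert fit.sigma == pytest.approx(scale, abs=1e-4)

    def test_local_maximum(self, rng):
        y, X = self.simulate(rng, n=200)
        L = np.quantile(y, 0.25)
        yc = np.maximum(y, L)
        fit = tobit_fit(yc, X, (L, BIG))
        from oxitrack.oxidative import _tobit_negloglik_grad

        cl = yc <= L
        ch = yc >= BIG
        cu = ~(cl | ch)
        theta = np.concatenate([fit.beta, [np.log(fit.sigma)]])
        nll_hat, _ = _tobit_negloglik_grad(theta, yc, X, L, BIG, cl, ch, cu)
        for _ in range(300):
            pert = theta + rng.normal(0, 0.05, theta.size)
            nll, _ = _tobit_negloglik_grad(pert, yc, X, L, BIG, cl, ch, cu)
            assert nll >= nll_hat - 1e-9

    def test_all_censored_rejected(self, rng):
        y = np.full(50, 10.0)
        X = np.ones((50, 1))
        with pytest.raises(ValueError, match="censored"):
            tobit_fit(y, X, (20.0, 30.0))


class TestLinear:
    def test_two_group_difference(self):
        y = np.array([10.0] * 5 + [14.0] * 5)
        X = np.column_stack([np.ones(10), np.repeat([0, 1], 5)])
        fit = linear_fit(y, X)
        assert fit.beta[1] == pytest.approx(4.0)

    def test_exact_fit(self, rng):
        x = rng.normal(0, 1, 30)
        fit = linear_fit(x.copy(), x[:, None])
        assert fit.beta[0] == pytest.approx(1.0)
        assert fit.sigma == pytest.approx(0.0, abs=1e-10)

    def test_matches_statsmodels(self, rng):
        import statsmodels.api as sm

        X = np.column_stack([np.ones(20), rng.normal(0, 1, (20, 2))])
        y = rng.normal(0, 1, 20)
        fit = linear_fit(y, X)
        ref = sm.OLS(y, X).fit()
        assert np.allclose(fit.beta, ref.params, atol=1e-10)
        assert np.allclose(fit.se, ref.bse, atol=1e-10)
        assert np.allclose(fit.p, ref.pvalues, atol=1e-10)

    def test_rank_deficient_rejected(self, rng):
        x = rng.normal(0, 1, 20)
        X = np.column_stack([np.ones(20), x, 2 * x])
        with pytest.raises(ValueError, match="rank"):
            linear_fit(rng.normal(0, 1, 20), X)


class TestVif:
    def test_orthogonal_untouched(self):
        n = 8
        X = pd.DataFrame(np.eye(n)[:, :3], columns=["a", "b", "c"])
        retained, table = vif_prune(X)
        assert retained == ["a", "b", "c"]
        assert not table["dropped"].any()

    def test_duplicate_column_dropped_first_round(self, rng):
        a = rng.normal(0, 1, 40)
        X = pd.DataFrame({"a": a, "dup": a, "c": rng.normal(0, 1, 40)})
        retained, table = vif_prune(X)
        assert "dup" not in retained  # later column dropped on the tie
        assert table.loc[table["round"] == 1, "dropped"].sum() == 1
        assert np.isinf(table.loc[(table["round"] == 1) & table["dropped"], "vif"]).all()

    def test_iterative_rule_matches_statsmodels_oracle(self, rng):
        from statsmodels.stats.outliers_influence import variance_inflation_factor

        n = 60
        z = rng.normal(0, 1, n)
        X = pd.DataFrame(
            {
                "a": z + rng.normal(0, 0.4, n),
                "b": z + rng.normal(0, 0.4, n),
                "c": z + rng.normal(0, 0.4, n),
                "d": rng.normal(0, 1, n),
            }
        )
        retained, _ = vif_prune(X, threshold=3.0)

        def oracle(cols):
            Z = X[cols].to_numpy()
            Z = (Z - Z.mean(0)) / Z.std(0)
            A = np.column_stack([np.ones(n), Z])
            return [variance_inflation_factor(A, j + 1) for j in range(len(cols))]

        cols = list(X.columns)
        while len(cols) >= 2:
            vifs = oracle(cols)
            if max(vifs) < 3.0:
                break
            worst = len(vifs) - 1 - int(np.argmax(np.asarray(vifs)[::-1]))
            del cols[worst]
        assert retained == cols

    def test_terminates_with_all_below_threshold(self, rng):
        n, p = 50, 6
        base = rng.normal(0, 1, (n, 2))
        X = pd.DataFrame(
            base @ rng.normal(0, 1, (2, p)) + rng.normal(0, 0.3, (n, p)),
            columns=list("abcdef"),
        )
        retained, table = vif_prune(X, threshold=3.0)
        n_rounds = table["round"].max()
        assert n_rounds <= p - 1 + 1
        if len(retained) >= 2:
            last = table[(table["round"] == n_rounds) & (~table["dropped"])]
            assert (last["vif"] < 3.0).all()

    def test_needs_two_columns(self):
        with pytest.raises(ValueError):
            vif_prune(pd.DataFrame({"a": [1.0, 2.0, 3.0]}))


class TestSignCall:
    @pytest.mark.parametrize(
        "lo,hi,expected",
        [(0.01, 0.12, "positive"), (-27.08, -2.00, "negative"), (-1.0, 1.0, "none"),
         (0.0, 1.0, "none"), (-1.0, 0.0, "none")],
    )
    def test_ci_rule(self, lo, hi, expected):
        assert sign_call_from_ci(lo, hi) == expected


class TestBayes:
    def test_strong_signal_positive(self, rng):
        n = 200
        x = rng.normal(0, 1, n)
        y = 5.0 * x + rng.normal(0, 0.5, n)
        X = np.column_stack([np.ones(n), x])
        fit = bayes_lm(y, X, coef_names=["intercept", "x"], seed=7)
        assert fit.sign_call[1] == "positive"
        assert fit.ci_low[1] > 4.5 and fit.ci_high[1] < 5.5

    def test_posterior_mean_tracks_ols(self, rng):
        n = 150
        X = np.column_stack([np.ones(n), rng.normal(0, 1, n)])
        y = X @ np.array([1.0, 2.0]) + rng.normal(0, 1, n)
        fit = bayes_lm(y, X, n_draws=8000, seed=3)
        ols = linear_fit(y, X)
        mc_se = fit.draws.std(axis=0) / np.sqrt(2000)  # conservative ESS
        assert np.all(np.abs(fit.mean - ols.beta) < 5 * mc_se + 1e-3)

    def test_ci_width_shrinks_like_sqrt_n(self, rng):
        widths = []
        for n in (50, 200, 800):
            x = rng.normal(0, 1, n)
            y = 1.0 + 0.5 * x + rng.normal(0, 1.0, n)
            X = np.column_stack([np.ones(n), x])
            fit = bayes_lm(y, X, n_draws=4000, seed=n)
            widths.append(fit.ci_high[1] - fit.ci_low[1])
        assert widths[0] / widths[1] == pytest.approx(2.0, rel=0.35)
        assert widths[1] / widths[2] == pytest.approx(2.0, rel=0.35)

    def test_null_calibration_modest(self):
        # quick 60-replicate version; the full calibration runs in the
        # acceptance suite
        hits = 0
        for r in range(60):
            rr = np.random.default_rng(5000 + r)
            x = rr.normal(0, 1, 50)
            y = rr.normal(0, 1, 50)
            X = np.column_stack([np.ones(50), x])
            fit = bayes_lm(y, X, n_draws=1500, seed=r)
            hits += fit.sign_call[1] != "none"
        assert hits / 60 < 0.18  # ~5% expected; generous binomial bound
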