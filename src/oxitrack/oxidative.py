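"""Oxidative-stress bookkeeping and the statistical models of the pipeline.

Assays: d-ROMs (derivatives of reactive oxygen metabolites, a plasma
hydroperoxide proxy in Carratelli units, 1 U. CARR = 0.08 mg H2O2/dL) and
BAP (biological antioxidant potential, uM/L).  Each individual is sampled
at logger deployment and retrieval; the change is retrieval minus
deployment.

Models:

* Tobit — Gaussian regression with interval censoring of the response at
  the analyzer detection limits (40-1,000 U. CARR for d-ROMs, 500-6,000
  uM/L for BAP), fit by maximum likelihood.
* Ordinary least squares with classical standard errors.
* Iterative variance-inflation-factor pruning: repeatedly drop the
  predictor with the highest VIF until all VIFs fall below 3.
* Bayesian Gaussian regression by a conjugate Gibbs sampler; a predictor
  whose 95% equal-tailed credible interval excludes zero is called
  positive or negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

UCARR_TO_MG_H2O2_DL = 0.08

DROM_LIMITS = (40.0, 1000.0)  # U. CARR
BAP_LIMITS = (500.0, 6000.0)  # uM/L

TIMEPOINTS = ("deploy", "retrieve")


@dataclass(frozen=True)
class DetectionLimits:
    drom: tuple[float, float] = DROM_LIMITS
    bap: tuple[float, float] = BAP_LIMITS

    def __post_init__(self) -> None:
        for lo, hi in (self.drom, self.bap):
            if not lo < hi:
                raise ValueError("detection limits must satisfy lower < upper")


def censor_flag(value: float, limits: tuple[float, float]) -> str:
    """Classify an assay value against detection limits.

    Values at or beyond a limit are censored at it; only values strictly
    inside (lower, upper) are in range.
    """
    lo, hi = limits
    if value <= lo:
        return "below_lower"
    if value >= hi:
        return "above_upper"
    return "in_range"


def ucarr_to_mg_h2o2_dl(x):
    """Convert d-ROMs Carratelli units to mg H2O2 per dL (x * 0.08)."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("U. CARR values must be non-negative")
    out = x * UCARR_TO_MG_H2O2_DL
    return float(out) if out.ndim == 0 else out


def read_assay_csv(path) -> pd.DataFrame:
    """Read the assay table `individual_id,timepoint,drom_ucarr,bap_umol_l`."""
    df = pd.read_csv(path, dtype={"individual_id": str})
    required = {"individual_id", "timepoint", "drom_ucarr", "bap_umol_l"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"assay CSV missing columns: {sorted(missing)}")
    bad = ~df["timepoint"].isin(TIMEPOINTS)
    if bad.any():
        raise ValueError(f"unknown timepoints: {sorted(df.loc[bad, 'timepoint'].unique())}")
    return df


def compute_changes(records: pd.DataFrame) -> pd.DataFrame:
    """Per-individual assay changes, retrieval minus deployment.

    ``records`` needs columns individual_id, timepoint, drom_ucarr,
    bap_umol_l.  Individuals missing either timepoint appear with NaN
    deltas; a duplicated timepoint for an individual is an error.
    """
    dup = records.duplicated(subset=["individual_id", "timepoint"])
    if dup.any():
        offenders = records.loc[dup, "individual_id"].unique()
        raise ValueError(f"duplicate timepoint for individuals: {sorted(offenders)}")
    wide = records.pivot(index="individual_id", columns="timepoint", values=["drom_ucarr", "bap_umol_l"])
    for col in ("deploy", "retrieve"):
        for assay in ("drom_ucarr", "bap_umol_l"):
            if (assay, col) not in wide.columns:
                wide[(assay, col)] = np.nan
    out = pd.DataFrame(
        {
            "individual_id": wide.index,
            "delta_drom": (wide[("drom_ucarr", "retrieve")] - wide[("drom_ucarr", "deploy")]).to_numpy(),
            "delta_bap": (wide[("bap_umol_l", "retrieve")] - wide[("bap_umol_l", "deploy")]).to_numpy(),
        }
    ).reset_index(drop=True)
    return out


# --- Tobit ----------------------------------------------------------------


@dataclass
class TobitFit:
    """Interval-censored Gaussian regression fit."""

    coef_names: list[str]
    beta: np.ndarray
    sigma: float
    se: np.ndarray  # for beta, then log-sigma last element dropped
    z: np.ndarray
    p: np.ndarray
    loglik: float
    n: int
    n_censored_low: int
    n_censored_high: int

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"coef": self.coef_names, "estimate": self.beta, "se": self.se, "z": self.z, "p": self.p}
        )


def _tobit_negloglik_grad(params, y, X, lo, hi, cl, ch, cu):
    beta, logsig = params[:-1], params[-1]
    sig = np.exp(logsig)
    mu = X @ beta
    nll = 0.0
    g_beta = np.zeros(X.shape[1])
    g_logsig = 0.0
    if cu.any():
        r = (y[cu] - mu[cu]) / sig
        nll -= np.sum(stats.norm.logpdf(r) - logsig)
        g_beta -= X[cu].T @ (r / sig)
        g_logsig -= np.sum(r**2 - 1.0)
    if cl.any():
        a = (lo - mu[cl]) / sig
        logF = stats.norm.logcdf(a)
        nll -= np.sum(logF)
        # d/dmu logPhi(a) = -phi(a)/Phi(a)/sig
        ratio = np.exp(stats.norm.logpdf(a) - logF)
        g_beta += X[cl].T @ (ratio / sig)
        g_logsig += np.sum(ratio * a)
    if ch.any():
        b = (hi - mu[ch]) / sig
        logS = stats.norm.logsf(b)
        nll -= np.sum(logS)
        ratio = np.exp(stats.norm.logpdf(b) - logS)
        g_beta -= X[ch].T @ (ratio / sig)
        g_logsig -= np.sum(ratio * b)
    return nll, np.concatenate([g_beta, [g_logsig]])


def tobit_fit(
    y, X, limits: tuple[float, float], coef_names: list[str] | None = None
) -> TobitFit:
    """Tobit (interval-censored Gaussian) regression by maximum likelihood.

    Observations at or below the lower limit contribute Phi((L-xb)/s),
    at or above the upper limit contribute 1-Phi((U-xb)/s), and in-range
    observations the Gaussian density.  Standard errors come from the
    observed information (numerical Hessian of the negative log-likelihood
    at the optimum).  With no censored observations the estimates coincide
    with ordinary least squares.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if n <= p:
        raise ValueError("need n > p observations")
    lo, hi = limits
    if not lo < hi:
        raise ValueError("limits must be ordered")
    cl = y <= lo
    ch = y >= hi
    cu = ~(cl | ch)
    if not cu.any():
        raise ValueError("all observations censored; model not identifiable")
    if cl.all() or ch.all():
        raise ValueError("all observations censored on one side")
    if coef_names is None:
        coef_names = [f"x{j}" for j in range(p)]

    beta0, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta0
    sig0 = max(np.sqrt(np.mean(resid**2)), 1e-6)
    x0 = np.concatenate([beta0, [np.log(sig0)]])
    res = optimize.minimize(
        _tobit_negloglik_grad,
        x0,
        args=(y, X, lo, hi, cl, ch, cu),
        jac=True,
        method="BFGS",
        options={"gtol": 1e-10, "maxiter": 500},
    )
    if not np.isfinite(res.fun):
        raise RuntimeError("Tobit likelihood did not evaluate finitely at the optimum")
    beta = res.x[:-1]
    sigma = float(np.exp(res.x[-1]))
    if sigma < 1e-8:
        raise RuntimeError("Tobit scale collapsed toward zero; fit not identifiable")

    # observed information via central differences of the analytic gradient
    k = res.x.size
    H = np.empty((k, k))
    eps = 1e-5 * np.maximum(np.abs(res.x), 1.0)
    for j in range(k):
        xp = res.x.copy()
        xm = res.x.copy()
        xp[j] += eps[j]
        xm[j] -= eps[j]
        _, gp = _tobit_negloglik_grad(xp, y, X, lo, hi, cl, ch, cu)
        _, gm = _tobit_negloglik_grad(xm, y, X, lo, hi, cl, ch, cu)
        H[j] = (gp - gm) / (2 * eps[j])
    H = 0.5 * (H + H.T)
    cov = np.linalg.inv(H)
    se = np.sqrt(np.clip(np.diag(cov)[:-1], 0.0, None))
    z = beta / se
    pvals = 2 * stats.norm.sf(np.abs(z))
    return TobitFit(
        coef_names=list(coef_names),
        beta=beta,
        sigma=sigma,
        se=se,
        z=z,
        p=pvals,
        loglik=-float(res.fun),
        n=n,
        n_censored_low=int(cl.sum()),
        n_censored_high=int(ch.sum()),
    )


# --- ordinary least squares -----------------------------------------------


@dataclass
class LinearFit:
    coef_names: list[str]
    beta: np.ndarray
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    sigma: float
    df_resid: int

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"coef": self.coef_names, "estimate": self.beta, "se": self.se, "t": self.t, "p": self.p}
        )


def linear_fit(y, X, coef_names: list[str] | None = None) -> LinearFit:
    """Ordinary least squares with classical (homoskedastic) inference."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if n <= p:
        raise ValueError("need n > p observations")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is rank deficient")
    if coef_names is None:
        coef_names = [f"x{j}" for j in range(p)]
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ y
    resid = y - X @ beta
    df = n - p
    s2 = float(resid @ resid) / df
    se = np.sqrt(s2 * np.diag(XtX_inv))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    pvals = 2 * stats.t.sf(np.abs(t), df)
    return LinearFit(
        coef_names=list(coef_names), beta=beta, se=se, t=t, p=pvals, sigma=np.sqrt(s2), df_resid=df
    )


# --- VIF pruning ----------------------------------------------------------


def _vif_one(Z: np.ndarray, j: int) -> float:
    """VIF of standardized column j regressed on the others plus intercept."""
    others = np.delete(Z, j, axis=1)
    A = np.column_stack([np.ones(Z.shape[0]), others])
    yj = Z[:, j]
    coef, *_ = np.linalg.lstsq(A, yj, rcond=None)
    resid = yj - A @ coef
    sst = float(((yj - yj.mean()) ** 2).sum())
    ssr = float(resid @ resid)
    if sst <= 0:
        return np.inf
    r2 = 1.0 - ssr / sst
    if r2 >= 1.0 - 1e-12:
        return np.inf
    return 1.0 / (1.0 - r2)


def vif_prune(X: pd.DataFrame, threshold: float = 3.0) -> tuple[list[str], pd.DataFrame]:
    """Iteratively drop the highest-VIF predictor until all VIFs < threshold.

    Columns are standardized internally for conditioning.  Ties on the
    maximum VIF drop the later column in input order.  Returns the retained
    column names (input order) and a per-round VIF table with columns
    round, column, vif, dropped.
    """
    if X.shape[1] < 2:
        raise ValueError("vif_prune needs at least 2 predictor columns")
    cols = list(X.columns)
    rows = []
    rnd = 0
    while len(cols) >= 2:
        rnd += 1
        Z = X[cols].to_numpy(dtype=float)
        sd = Z.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        Z = (Z - Z.mean(axis=0)) / sd
        vifs = np.array([_vif_one(Z, j) for j in range(len(cols))])
        if np.all(vifs < threshold):
            for c, v in zip(cols, vifs):
                rows.append({"round": rnd, "column": c, "vif": v, "dropped": False})
            break
        # argmax over the reversed order implements the drop-later tie-break
        worst = len(vifs) - 1 - int(np.argmax(vifs[::-1]))
        for j, (c, v) in enumerate(zip(cols, vifs)):
            rows.append({"round": rnd, "column": c, "vif": v, "dropped": j == worst})
        del cols[worst]
    else:
        # one column left: VIF undefined, trivially retained
        rows.append({"round": rnd + 1, "column": cols[0], "vif": 1.0, "dropped": False})
    retained = [c for c in X.columns if c in cols]
    return retained, pd.DataFrame(rows)


# --- Bayesian Gaussian regression -----------------------------------------


@dataclass
class BayesFit:
    """Posterior summary of a Gaussian linear model fit by Gibbs sampling."""

    coef_names: list[str]
    draws: np.ndarray  # (n_draws, p) pooled post-warmup
    sigma2_draws: np.ndarray
    mean: np.ndarray
    ci_low: np.ndarray  # 2.5%
    ci_high: np.ndarray  # 97.5%
    sign_call: list[str]  # positive | negative | none
    rhat: np.ndarray

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.coef_names,
                "mean": self.mean,
                "ci_2.5": self.ci_low,
                "ci_97.5": self.ci_high,
                "sign_call": self.sign_call,
                "rhat": self.rhat,
            }
        )


def sign_call_from_ci(lo: float, hi: float) -> str:
    """Credible-interval sign rule: positive iff lo > 0, negative iff hi < 0."""
    if lo > 0:
        return "positive"
    if hi < 0:
        return "negative"
    return "none"


def _split_rhat(chains: np.ndarray) -> float:
    """Split-Rhat of one scalar parameter; chains is (n_chains, n_iter)."""
    n_chains, n_iter = chains.shape
    half = n_iter // 2
    segs = np.concatenate([chains[:, :half], chains[:, half : 2 * half]], axis=0)
    m, n = segs.shape
    means = segs.mean(axis=1)
    B = n * means.var(ddof=1)
    W = segs.var(axis=1, ddof=1).mean()
    if W <= 0:
        return 1.0
    var_plus = (n - 1) / n * W + B / n
    return float(np.sqrt(var_plus / W))


class ConvergenceError(RuntimeError):
    pass


def bayes_lm(
    y,
    X,
    coef_names: list[str] | None = None,
    n_draws: int = 4000,
    seed: int | np.random.Generator | None = None,
    n_chains: int = 4,
    warmup_frac: float = 0.5,
    prior_a: float = 0.001,
    prior_b: float = 0.001,
    rhat_max: float = 1.05,
) -> BayesFit:
    """Bayesian Gaussian regression via a conjugate Gibbs sampler.

    Priors: improper flat on the coefficients, inverse-gamma(prior_a,
    prior_b) on the error variance, so the posterior mean of beta tracks
    OLS.  ``n_draws`` is the total number of retained draws pooled over
    ``n_chains`` chains after discarding ``warmup_frac`` of each chain.
    A coefficient is called positive/negative when its 95% equal-tailed
    credible interval excludes zero.  Raises ConvergenceError when any
    coefficient's split-Rhat exceeds ``rhat_max``.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if n <= p:
        raise ValueError("need n > p observations")
    if coef_names is None:
        coef_names = [f"x{j}" for j in range(p)]
    rng = np.random.default_rng(seed)
    per_chain = int(np.ceil(n_draws / n_chains / (1.0 - warmup_frac)))
    warm = int(per_chain * warmup_frac)

    XtX = X.T @ X
    XtX_inv = np.linalg.inv(XtX)
    L = np.linalg.cholesky(XtX_inv)
    beta_hat = XtX_inv @ X.T @ y
    resid_hat = y - X @ beta_hat
    s2_hat = float(resid_hat @ resid_hat) / max(n - p, 1)

    beta_chains = np.empty((n_chains, per_chain, p))
    sig2_chains = np.empty((n_chains, per_chain))
    for c in range(n_chains):
        # overdispersed start
        sig2 = s2_hat * rng.uniform(0.3, 3.0)
        for it in range(per_chain):
            beta = beta_hat + np.sqrt(sig2) * (L @ rng.standard_normal(p))
            r = y - X @ beta
            sig2 = 1.0 / rng.gamma(prior_a + n / 2.0, 1.0 / (prior_b + 0.5 * float(r @ r)))
            beta_chains[c, it] = beta
            sig2_chains[c, it] = sig2

    kept_b = beta_chains[:, warm:, :]
    kept_s = sig2_chains[:, warm:]
    rhat = np.array([_split_rhat(kept_b[:, :, j]) for j in range(p)])
    if np.any(rhat > rhat_max):
        bad = [coef_names[j] for j in np.flatnonzero(rhat > rhat_max)]
        raise ConvergenceError(f"split-Rhat > {rhat_max} for coefficients {bad}: {rhat}")
    draws = kept_b.reshape(-1, p)[:n_draws]
    sig2_draws = kept_s.reshape(-1)[:n_draws]
    lo = np.percentile(draws, 2.5, axis=0)
    hi = np.percentile(draws, 97.5, axis=0)
    return BayesFit(
        coef_names=list(coef_names),
        draws=draws,
        sigma2_draws=sig2_draws,
        mean=draws.mean(axis=0),
        ci_low=lo,
        ci_high=hi,
        sign_call=[sign_call_from_ci(a, b) for a, b in zip(lo, hi)],
        rhat=rhat,
    )
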