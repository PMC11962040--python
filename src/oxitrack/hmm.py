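"""Three-state movement hidden Markov model on steps and turning angles.

Each behavioral state emits a step length from a gamma distribution
(parameterized by mean and standard deviation, in km) and a turning angle
from a von Mises distribution (mean direction, concentration kappa).  The
latent state follows a first-order Markov chain.  States are fitted by
Baum-Welch EM with multiple seeded restarts and decoded by the Viterbi
algorithm (global) or posterior-maximum (local).  The three fitted states
are labeled by their step-length means: smallest = resting, middle =
foraging, largest = flight; a consistency check warns when the foraging
state is not also the least directionally concentrated.

Missing turning angles (track starts, post-gap points, angles adjacent to
zero-length steps) simply drop the angular emission term at that time.
Zero step lengths are floored at 1 m rather than modeled by a
zero-inflation mixture.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats
from scipy.optimize import brentq

STATE_LABELS = ("resting", "foraging", "flight")
STEP_FLOOR_KM = 1e-3  # 1 m


@dataclass
class HmmModel:
    """Parameters of a K-state gamma / von Mises movement HMM."""

    step_mean: np.ndarray  # km, per state
    step_sd: np.ndarray  # km
    angle_mean: np.ndarray  # rad in (-pi, pi]
    angle_kappa: np.ndarray  # >= 0
    tpm: np.ndarray  # K x K, row-stochastic
    delta: np.ndarray  # initial distribution

    def __post_init__(self) -> None:
        for name in ("step_mean", "step_sd", "angle_mean", "angle_kappa", "tpm", "delta"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        K = self.step_mean.size
        if np.any(self.step_mean <= 0) or np.any(self.step_sd <= 0):
            raise ValueError("gamma parameters must be positive")
        if np.any(self.angle_kappa < 0):
            raise ValueError("kappa must be non-negative")
        if self.tpm.shape != (K, K) or not np.allclose(self.tpm.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("transition matrix must be K x K row-stochastic")
        if np.any(self.tpm < 0) or np.any(self.delta < 0):
            raise ValueError("probabilities must be non-negative")
        if not np.isclose(self.delta.sum(), 1.0, atol=1e-8):
            raise ValueError("initial distribution must sum to 1")

    @property
    def n_states(self) -> int:
        return int(self.step_mean.size)

    def _gamma_shape_scale(self) -> tuple[np.ndarray, np.ndarray]:
        shape = (self.step_mean / self.step_sd) ** 2
        scale = self.step_sd**2 / self.step_mean
        return shape, scale

    def log_emissions(self, steps: np.ndarray, angles: np.ndarray) -> np.ndarray:
        """T x K matrix of per-time log emission densities.

        NaN steps or angles contribute no term for that component.
        """
        steps = np.asarray(steps, dtype=float)
        angles = np.asarray(angles, dtype=float)
        T, K = steps.size, self.n_states
        shape, scale = self._gamma_shape_scale()
        logb = np.zeros((T, K))
        s_obs = np.isfinite(steps)
        a_obs = np.isfinite(angles)
        with np.errstate(invalid="ignore", over="ignore"):
            for k in range(K):
                logb[s_obs, k] += stats.gamma.logpdf(steps[s_obs], shape[k], scale=scale[k])
                logb[a_obs, k] += stats.vonmises.logpdf(
                    angles[a_obs], self.angle_kappa[k], loc=self.angle_mean[k]
                )
        # overflowed observations (density 0 in a state) get -inf, not NaN
        return np.where(np.isnan(logb), -np.inf, logb)

    # --- flat key=value serialization -------------------------------------
    def to_text(self) -> str:
        lines = [f"n_states={self.n_states}"]
        for k in range(self.n_states):
            lines.append(f"state{k}.step_mean_km={self.step_mean[k]:.12g}")
            lines.append(f"state{k}.step_sd_km={self.step_sd[k]:.12g}")
            lines.append(f"state{k}.angle_mean_rad={self.angle_mean[k]:.12g}")
            lines.append(f"state{k}.angle_kappa={self.angle_kappa[k]:.12g}")
            for j in range(self.n_states):
                lines.append(f"tpm.{k}.{j}={self.tpm[k, j]:.12g}")
            lines.append(f"delta.{k}={self.delta[k]:.12g}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "HmmModel":
        kv = dict(
            line.split("=", 1) for line in text.strip().splitlines() if line.strip()
        )
        K = int(kv["n_states"])
        get = lambda key: float(kv[key])
        return cls(
            step_mean=[get(f"state{k}.step_mean_km") for k in range(K)],
            step_sd=[get(f"state{k}.step_sd_km") for k in range(K)],
            angle_mean=[get(f"state{k}.angle_mean_rad") for k in range(K)],
            angle_kappa=[get(f"state{k}.angle_kappa") for k in range(K)],
            tpm=[[get(f"tpm.{k}.{j}") for j in range(K)] for k in range(K)],
            delta=[get(f"delta.{k}") for k in range(K)],
        )


@dataclass
class StateSequence:
    """Decoded behavioral states for one resampled track."""

    states: np.ndarray  # raw state indices
    times: np.ndarray
    decode_method: str  # "viterbi" | "local"
    labels: list[str] | None = None  # semantic labels, after label_states


@dataclass
class ForagingPhase:
    start_time: float
    end_time: float
    n_points: int


def prepare_series(steps, angles, floor_km: float = STEP_FLOOR_KM):
    """Floor zero/negative observed steps at ``floor_km``; pass NaN through."""
    steps = np.asarray(steps, dtype=float).copy()
    obs = np.isfinite(steps)
    steps[obs] = np.maximum(steps[obs], floor_km)
    return steps, np.asarray(angles, dtype=float)


def hmm_loglik(model: HmmModel, steps, angles) -> float:
    """Log-likelihood by the scaled forward recursion."""
    logb = model.log_emissions(*prepare_series(steps, angles))
    return _forward(model, logb)[0]


def _forward(model: HmmModel, logb: np.ndarray):
    """Scaled forward pass; returns (loglik, alpha_hat, log_scale)."""
    T, K = logb.shape
    if T == 0:
        raise ValueError("empty sequence")
    # subtract rowwise max before exponentiating for stability
    m = logb.max(axis=1, keepdims=True)
    if not np.all(np.isfinite(m)):
        return -np.inf, np.empty((T, K)), np.empty(T)
    b = np.exp(logb - m)
    alpha = np.empty((T, K))
    logc = np.empty(T)
    a = model.delta * b[0]
    tot = a.sum()
    if tot <= 0:
        return -np.inf, alpha, logc
    alpha[0] = a / tot
    logc[0] = np.log(tot) + m[0, 0]
    for t in range(1, T):
        a = (alpha[t - 1] @ model.tpm) * b[t]
        tot = a.sum()
        if tot <= 0:
            return -np.inf, alpha, logc
        alpha[t] = a / tot
        logc[t] = np.log(tot) + m[t, 0]
    return float(logc.sum()), alpha, logc


def _forward_backward(model: HmmModel, logb: np.ndarray):
    """Posterior state probabilities and expected transition counts."""
    T, K = logb.shape
    ll, alpha, _ = _forward(model, logb)
    if not np.isfinite(ll):
        raise FloatingPointError("zero-probability observation in forward pass")
    m = logb.max(axis=1, keepdims=True)
    b = np.exp(logb - m)
    beta = np.empty((T, K))
    beta[-1] = 1.0
    xi_sum = np.zeros((K, K))
    for t in range(T - 2, -1, -1):
        bb = b[t + 1] * beta[t + 1]
        # unnormalized xi for step t -> t+1, then normalize jointly
        xi = model.tpm * np.outer(alpha[t], bb)
        xi_sum += xi / xi.sum()
        v = model.tpm @ bb
        beta[t] = v / v.sum()
    post = alpha * beta
    post /= post.sum(axis=1, keepdims=True)
    return ll, post, xi_sum


# --- weighted M-step solvers ----------------------------------------------


def _gamma_mle_from_stats(W: float, wx: float, wlogx: float) -> tuple[float, float]:
    """Weighted gamma MLE from sufficient statistics; returns (mean, sd).

    Solves log(k) - digamma(k) = log(mean) - mean(log x) by Newton from the
    standard generalized-Newton starting value.
    """
    m = wx / W
    s = max(np.log(m) - wlogx / W, 1e-12)
    k = (3.0 - s + np.sqrt((s - 3.0) ** 2 + 24.0 * s)) / (12.0 * s)
    for _ in range(50):
        f = np.log(k) - special.digamma(k) - s
        fp = 1.0 / k - special.polygamma(1, k)
        k_new = k - f / fp
        if k_new <= 0:
            k_new = k / 2.0
        if abs(k_new - k) < 1e-12 * k:
            k = k_new
            break
        k = k_new
    return m, m / np.sqrt(k)


def _gamma_weighted_mle(w: np.ndarray, x: np.ndarray) -> tuple[float, float]:
    """Weighted gamma MLE; returns (mean, sd)."""
    return _gamma_mle_from_stats(float(w.sum()), float(w @ x), float(w @ np.log(x)))


def _vonmises_kappa(rbar: float) -> float:
    """Solve A(kappa) = I1/I0 = rbar for kappa."""
    if rbar <= 1e-8:
        return 0.0
    A = lambda k: special.i1e(k) / special.i0e(k)
    hi = 1e4
    if rbar >= A(hi):
        return hi
    return brentq(lambda k: A(k) - rbar, 1e-10, hi, xtol=1e-10)


def _vonmises_weighted_mle(w: np.ndarray, theta: np.ndarray) -> tuple[float, float]:
    """Weighted von Mises MLE; returns (mean direction, kappa)."""
    C = float(w @ np.cos(theta))
    S = float(w @ np.sin(theta))
    W = w.sum()
    mu = float(np.arctan2(S, C))
    rbar = min(np.hypot(C, S) / W, 1.0 - 1e-12)
    return mu, _vonmises_kappa(rbar)


@dataclass
class FitResult:
    model: HmmModel
    loglik: float
    loglik_trace: np.ndarray
    n_restarts_used: int
    converged: bool


class StateCollapseWarning(UserWarning):
    pass


def _em_once(
    tracks, K: int, init: HmmModel, max_iter: int, tol: float, min_weight: float
) -> tuple[HmmModel, float, np.ndarray, bool]:
    model = init
    trace = []
    prev = -np.inf
    converged = False
    for _ in range(max_iter):
        trans = np.zeros((K, K))
        init_post = np.zeros(K)
        w_sum = np.zeros(K)
        ws_sum = np.zeros(K)
        wlogs_sum = np.zeros(K)
        wc = np.zeros(K)
        wsin = np.zeros(K)
        wcos = np.zeros(K)
        total_ll = 0.0
        n_total = 0
        for steps, angles in tracks:
            logb = model.log_emissions(steps, angles)
            ll, post, xi = _forward_backward(model, logb)
            total_ll += ll
            trans += xi
            init_post += post[0]
            s_obs = np.isfinite(steps)
            a_obs = np.isfinite(angles)
            w_sum += post[s_obs].sum(axis=0)
            ws_sum += post[s_obs].T @ steps[s_obs]
            wlogs_sum += post[s_obs].T @ np.log(steps[s_obs])
            wc += post[a_obs].sum(axis=0)
            wsin += post[a_obs].T @ np.sin(angles[a_obs])
            wcos += post[a_obs].T @ np.cos(angles[a_obs])
            n_total += int(s_obs.sum())
        trace.append(total_ll)
        if np.min(w_sum) < min_weight * n_total:
            warnings.warn(
                "HMM state collapsed below minimum occupancy; restarting",
                StateCollapseWarning,
                stacklevel=2,
            )
            return model, -np.inf, np.asarray(trace), False
        # M-step (exact weighted MLEs keep EM monotone)
        step_mean = np.empty(K)
        step_sd = np.empty(K)
        angle_mean = np.empty(K)
        angle_kappa = np.empty(K)
        for k in range(K):
            step_mean[k], step_sd[k] = _gamma_mle_from_stats(
                w_sum[k], ws_sum[k], wlogs_sum[k]
            )
            angle_mean[k] = np.arctan2(wsin[k], wcos[k])
            rbar = min(np.hypot(wsin[k], wcos[k]) / max(wc[k], 1e-300), 1.0 - 1e-12)
            angle_kappa[k] = _vonmises_kappa(rbar)
        tpm = trans / trans.sum(axis=1, keepdims=True)
        delta = init_post / init_post.sum()
        model = HmmModel(step_mean, step_sd, angle_mean, angle_kappa, tpm, delta)
        if total_ll - prev < tol * max(1.0, abs(total_ll)) and np.isfinite(prev):
            converged = True
            break
        prev = total_ll
    final_ll = hmm_total_loglik(model, tracks)
    trace.append(final_ll)
    return model, final_ll, np.asarray(trace), converged


def hmm_total_loglik(model: HmmModel, tracks) -> float:
    return float(sum(hmm_loglik(model, s, a) for s, a in tracks))


def _random_init(tracks, K: int, rng: np.random.Generator) -> HmmModel:
    """Initial parameters from pooled step-length quantile bins, jittered."""
    pooled = np.concatenate([np.asarray(s, float)[np.isfinite(s)] for s, _ in tracks])
    pooled = np.maximum(pooled, STEP_FLOOR_KM)
    qs = np.quantile(pooled, np.linspace(0, 1, K + 1))
    means = np.empty(K)
    sds = np.empty(K)
    for k in range(K):
        lo, hi = qs[k], qs[k + 1]
        grp = pooled[(pooled >= lo) & (pooled <= hi)]
        if grp.size < 2:
            grp = pooled
        means[k] = grp.mean()
        sds[k] = max(grp.std(), 0.2 * grp.mean())
    means = means * rng.lognormal(0.0, 0.3, K)
    sds = sds * rng.lognormal(0.0, 0.3, K)
    means = np.maximum(np.sort(means), STEP_FLOOR_KM / 2)
    kappa = rng.uniform(0.3, 3.0, K)
    if K == 1:
        tpm = np.ones((1, 1))
    else:
        tpm = np.full((K, K), 0.2 / (K - 1)) + np.eye(K) * (0.8 - 0.2 / (K - 1))
        tpm /= tpm.sum(axis=1, keepdims=True)
    return HmmModel(
        step_mean=means,
        step_sd=np.maximum(sds, 1e-4),
        angle_mean=np.zeros(K),
        angle_kappa=kappa,
        tpm=tpm,
        delta=np.full(K, 1.0 / K),
    )


def fit_hmm(
    tracks,
    K: int = 3,
    n_restarts: int = 10,
    seed: int | np.random.Generator | None = None,
    max_iter: int = 300,
    tol: float = 1e-8,
    min_obs: int = 50,
    min_weight: float = 1e-4,
    floor_km: float = STEP_FLOOR_KM,
) -> FitResult:
    """Fit the movement HMM by EM (Baum-Welch) with seeded random restarts.

    ``tracks`` is a list of (steps_km, turn_rad) array pairs, one per
    individual or gap-free segment; all share one parameter set but run
    independent forward passes.  Restarts are run short, then the best is
    refined to convergence; the returned trace is non-decreasing up to the
    stopping tolerance.
    """
    tracks = [prepare_series(s, a, floor_km) for s, a in tracks]
    n_obs = sum(int(np.isfinite(s).sum()) for s, _ in tracks)
    if n_obs < min_obs:
        raise ValueError(f"need at least {min_obs} observed steps, got {n_obs}")
    rng = np.random.default_rng(seed)
    best = None
    short_iter = min(40, max_iter)
    for _ in range(n_restarts):
        init = _random_init(tracks, K, rng)
        try:
            cand = _em_once(tracks, K, init, short_iter, tol, min_weight)
        except FloatingPointError:
            continue
        if best is None or cand[1] > best[1]:
            best = cand
    if best is None or not np.isfinite(best[1]):
        raise RuntimeError("all EM restarts failed or collapsed")
    model, ll, trace, converged = _em_once(tracks, K, best[0], max_iter, tol, min_weight)
    return FitResult(
        model=model,
        loglik=ll,
        loglik_trace=trace,
        n_restarts_used=n_restarts,
        converged=converged,
    )


def viterbi(model: HmmModel, steps, angles, times=None) -> StateSequence:
    """Jointly most probable state path (global decoding)."""
    steps, angles = prepare_series(steps, angles)
    logb = model.log_emissions(steps, angles)
    T, K = logb.shape
    if T == 0:
        raise ValueError("empty sequence")
    with np.errstate(divide="ignore"):
        log_tpm = np.log(model.tpm)
        log_delta = np.log(model.delta)
    score = log_delta + logb[0]
    back = np.zeros((T, K), dtype=int)
    for t in range(1, T):
        cand = score[:, None] + log_tpm
        back[t] = cand.argmax(axis=0)
        score = cand.max(axis=0) + logb[t]
    path = np.empty(T, dtype=int)
    path[-1] = int(score.argmax())
    for t in range(T - 2, -1, -1):
        path[t] = back[t + 1, path[t + 1]]
    if times is None:
        times = np.arange(T, dtype=float)
    return StateSequence(states=path, times=np.asarray(times, float), decode_method="viterbi")


def local_decode(model: HmmModel, steps, angles, times=None) -> StateSequence:
    """Pointwise posterior-maximum decoding."""
    steps, angles = prepare_series(steps, angles)
    logb = model.log_emissions(steps, angles)
    _, post, _ = _forward_backward(model, logb)
    if times is None:
        times = np.arange(logb.shape[0], dtype=float)
    return StateSequence(
        states=post.argmax(axis=1), times=np.asarray(times, float), decode_method="local"
    )


class LabelConsistencyWarning(UserWarning):
    pass


def label_states(model: HmmModel) -> dict[int, str]:
    """Map raw state indices to resting/foraging/flight by step-length rank.

    Smallest mean step = resting, middle = foraging, largest = flight.  The
    foraging state is expected to show the largest turning angles (lowest
    angular concentration); if the fitted kappas disagree, labels are still
    assigned by step length and a warning is emitted.
    """
    if model.n_states != 3:
        raise ValueError("semantic labels are defined for K = 3 only")
    means = model.step_mean
    if np.unique(means).size < 3:
        raise ValueError(f"tied step-length means {means}; cannot rank states")
    order = np.argsort(means)
    mapping = {int(order[i]): STATE_LABELS[i] for i in range(3)}
    if int(np.argmin(model.angle_kappa)) != int(order[1]):
        warnings.warn(
            "foraging state (middle step length) does not have the lowest angular "
            f"concentration (kappa = {model.angle_kappa}); labels assigned by step length",
            LabelConsistencyWarning,
            stacklevel=2,
        )
    return mapping


def apply_labels(seq: StateSequence, mapping: dict[int, str]) -> StateSequence:
    seq.labels = [mapping[int(s)] for s in seq.states]
    return seq


def foraging_phases(
    seq: StateSequence, run_min: int = 2
) -> tuple[list[ForagingPhase], float]:
    """Maximal foraging runs of at least ``run_min`` points and total hours.

    Phase duration is the time between its first and last points; the total
    foraging duration sums these spans over phases.
    """
    if seq.labels is None:
        raise ValueError("StateSequence has no semantic labels; call apply_labels first")
    is_forage = np.asarray([lab == "foraging" for lab in seq.labels], dtype=bool)
    phases: list[ForagingPhase] = []
    total_h = 0.0
    i = 0
    n = is_forage.size
    while i < n:
        if not is_forage[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and is_forage[j + 1]:
            j += 1
        if j - i + 1 >= run_min:
            start, end = float(seq.times[i]), float(seq.times[j])
            phases.append(ForagingPhase(start_time=start, end_time=end, n_points=j - i + 1))
            total_h += (end - start) / 3600.0
        i = j + 1
    return phases, total_h
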