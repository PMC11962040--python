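"""Movement HMM: forward/Viterbi oracles, EM fitting, labels, phases."""

import itertools

import numpy as np
import pytest

from oxitrack.hmm import (
    HmmModel,
    LabelConsistencyWarning,
    StateSequence,
    apply_labels,
    fit_hmm,
    foraging_phases,
    hmm_loglik,
    label_states,
    local_decode,
    prepare_series,
    viterbi,
)
from oxitrack.synthetic import simulate_hmm_series, well_separated_model


def random_model(rng, K=3):
    tpm = rng.dirichlet(np.ones(K) * 2, size=K)
    delta = rng.dirichlet(np.ones(K))
    return HmmModel(
        step_mean=rng.uniform(0.05, 5.0, K),
        step_sd=rng.uniform(0.03, 2.0, K),
        angle_mean=rng.uniform(-np.pi, np.pi, K),
        angle_kappa=rng.uniform(0.0, 8.0, K),
        tpm=tpm,
        delta=delta,
    )


def enumerate_loglik(model, steps, angles):
    """Brute-force log-likelihood: sum over all K^T state paths."""
    steps, angles = prepare_series(steps, angles)
    logb = model.log_emissions(steps, angles)
    T, K = logb.shape
    with np.errstate(divide="ignore"):
        lt = np.log(model.tpm)
        ld = np.log(model.delta)
    total = -np.inf
    for path in itertools.product(range(K), repeat=T):
        lp = ld[path[0]] + logb[0, path[0]]
        for t in range(1, T):
            lp += lt[path[t - 1], path[t]] + logb[t, path[t]]
        total = np.logaddexp(total, lp)
    return total


def enumerate_viterbi(model, steps, angles):
    steps, angles = prepare_series(steps, angles)
    logb = model.log_emissions(steps, angles)
    T, K = logb.shape
    with np.errstate(divide="ignore"):
        lt = np.log(model.tpm)
        ld = np.log(model.delta)
    best, best_lp = None, -np.inf
    for path in itertools.product(range(K), repeat=T):
        lp = ld[path[0]] + logb[0, path[0]]
        for t in range(1, T):
            lp += lt[path[t - 1], path[t]] + logb[t, path[t]]
        if lp > best_lp:
            best, best_lp = path, lp
    return np.array(best), best_lp


class TestForward:
    def test_single_state_chain_is_iid(self, rng):
        m = HmmModel([1.0], [0.5], [0.0], [2.0], [[1.0]], [1.0])
        steps = rng.gamma(4.0, 0.25, 20)
        angles = rng.vonmises(0, 2.0, 20)
        from scipy import stats

        shape, scale = m._gamma_shape_scale()
        expect = stats.gamma.logpdf(steps, shape[0], scale=scale[0]).sum()
        expect += stats.vonmises.logpdf(angles, 2.0, loc=0.0).sum()
        assert hmm_loglik(m, steps, angles) == pytest.approx(expect, rel=1e-12)

    def test_matches_exhaustive_enumeration(self, rng):
        for _ in range(5):
            m = random_model(rng)
            steps, angles, _ = simulate_hmm_series(m, 5, rng)
            ll = hmm_loglik(m, steps, angles)
            oracle = enumerate_loglik(m, steps, angles)
            assert ll == pytest.approx(oracle, rel=1e-10)

    def test_missing_angles_drop_emission_term(self, rng):
        m = random_model(rng)
        steps, angles, _ = simulate_hmm_series(m, 6, rng)
        angles[2:4] = np.nan
        assert hmm_loglik(m, steps, angles) == pytest.approx(
            enumerate_loglik(m, steps, angles), rel=1e-10
        )

    def test_impossible_observation_underflows(self):
        m = HmmModel([1.0], [0.5], [0.0], [2.0], [[1.0]], [1.0])
        steps = np.array([1.0, 1e308])  # density 0 in every state
        assert hmm_loglik(m, steps, np.full(2, np.nan)) == -np.inf

    def test_non_stochastic_tpm_rejected(self):
        with pytest.raises(ValueError):
            HmmModel([1, 2], [1, 1], [0, 0], [1, 1], [[0.5, 0.4], [0.5, 0.5]], [0.5, 0.5])


class TestViterbi:
    def test_matches_exhaustive_enumeration(self, rng):
        for _ in range(3):
            m = random_model(rng)
            steps, angles, _ = simulate_hmm_series(m, 8, rng)
            path = viterbi(m, steps, angles).states
            oracle, _ = enumerate_viterbi(m, steps, angles)
            assert np.array_equal(path, oracle)

    def test_overwhelming_emissions_constant_path(self):
        m = well_separated_model()
        steps = np.full(10, 5.0)  # squarely in the flight state
        path = viterbi(m, steps, np.full(10, np.nan)).states
        assert np.all(path == 2)

    def test_path_beats_random_paths(self, rng):
        m = random_model(rng)
        steps, angles, truth = simulate_hmm_series(m, 12, rng)
        steps, angles = prepare_series(steps, angles)
        logb = m.log_emissions(steps, angles)
        with np.errstate(divide="ignore"):
            lt, ld = np.log(m.tpm), np.log(m.delta)

        def path_lp(p):
            lp = ld[p[0]] + logb[0, p[0]]
            for t in range(1, len(p)):
                lp += lt[p[t - 1], p[t]] + logb[t, p[t]]
            return lp

        best = path_lp(viterbi(m, steps, angles).states)
        assert best >= path_lp(truth) - 1e-10
        for _ in range(200):
            assert best >= path_lp(rng.integers(0, 3, 12)) - 1e-10

    def test_empty_rejected(self, rng):
        with pytest.raises(ValueError):
            viterbi(random_model(rng), np.array([]), np.array([]))


class TestFit:
    def test_em_loglik_trace_nondecreasing(self, rng):
        m = well_separated_model()
        tracks = [simulate_hmm_series(m, 300, rng)[:2] for _ in range(3)]
        fit = fit_hmm(tracks, K=3, n_restarts=2, seed=1)
        diffs = np.diff(fit.loglik_trace)
        assert np.all(diffs >= -1e-6 * np.maximum(1.0, np.abs(fit.loglik_trace[1:])))

    def test_single_state_matches_moments(self, rng):
        steps = rng.gamma(4.0, 0.5, 4000)  # mean 2, sd 1
        angles = rng.vonmises(0.3, 3.0, 4000)
        fit = fit_hmm([(steps, angles)], K=1, n_restarts=1, seed=0, max_iter=50)
        m = fit.model
        assert m.step_mean[0] == pytest.approx(steps.mean(), rel=1e-6)
        # MLE sd close to sample sd within sampling error
        assert m.step_sd[0] == pytest.approx(steps.std(), rel=0.05)
        assert m.angle_mean[0] == pytest.approx(0.3, abs=0.1)
        assert m.angle_kappa[0] == pytest.approx(3.0, rel=0.1)

    def test_recovers_well_separated_parameters(self, rng):
        true = well_separated_model()
        tracks = [simulate_hmm_series(true, 400, rng)[:2] for _ in range(6)]
        fit = fit_hmm(tracks, K=3, n_restarts=4, seed=2)
        est = np.sort(fit.model.step_mean)
        assert np.all(np.abs(est - true.step_mean) / true.step_mean < 0.10)

    def test_too_few_observations_rejected(self, rng):
        with pytest.raises(ValueError, match="at least"):
            fit_hmm([(np.ones(10), np.full(10, np.nan))], K=3, seed=0)


class TestLabels:
    def test_ordered_means(self):
        m = well_separated_model()
        assert label_states(m) == {0: "resting", 1: "foraging", 2: "flight"}

    def test_permutation_invariance(self):
        m = well_separated_model()
        perm = [2, 0, 1]
        mp = HmmModel(
            m.step_mean[perm],
            m.step_sd[perm],
            m.angle_mean[perm],
            m.angle_kappa[perm],
            m.tpm[np.ix_(perm, perm)],
            m.delta[perm],
        )
        mapping = label_states(mp)
        assert mapping[1] == "resting" and mapping[2] == "foraging" and mapping[0] == "flight"

    def test_kappa_inconsistency_warns_but_labels_by_step(self):
        m = HmmModel(
            [0.05, 1.0, 5.0],
            [0.04, 0.7, 2.0],
            [0.0, 0.0, 0.0],
            [0.2, 5.0, 9.0],  # foraging not the most diffuse
            well_separated_model().tpm,
            [1 / 3, 1 / 3, 1 / 3],
        )
        with pytest.warns(LabelConsistencyWarning):
            mapping = label_states(m)
        assert mapping == {0: "resting", 1: "foraging", 2: "flight"}

    def test_tied_means_rejected(self):
        m = HmmModel(
            [1.0, 1.0, 5.0],
            [0.5, 0.5, 2.0],
            [0.0, 0.0, 0.0],
            [1.0, 0.5, 10.0],
            well_separated_model().tpm,
            [1 / 3, 1 / 3, 1 / 3],
        )
        with pytest.raises(ValueError, match="tied"):
            label_states(m)


def seq_from_labels(labels, dt_min=10.0):
    times = np.arange(len(labels)) * dt_min * 60.0
    seq = StateSequence(states=np.zeros(len(labels), int), times=times, decode_method="viterbi")
    seq.labels = list(labels)
    return seq


class TestForagingPhases:
    def test_no_foraging(self):
        phases, h = foraging_phases(seq_from_labels(["resting"] * 5))
        assert phases == [] and h == 0.0

    def test_twenty_minute_phase(self):
        labels = ["resting", "foraging", "foraging", "foraging", "resting"]
        phases, h = foraging_phases(seq_from_labels(labels))
        assert len(phases) == 1
        assert h == pytest.approx(20.0 / 60.0)

    def test_isolated_point_excluded(self):
        labels = ["resting", "foraging", "resting", "foraging", "foraging"]
        phases, h = foraging_phases(seq_from_labels(labels), run_min=2)
        assert len(phases) == 1 and phases[0].n_points == 2

    def test_run_min_three_reading(self):
        labels = ["foraging", "foraging", "resting", "foraging", "foraging", "foraging"]
        phases2, _ = foraging_phases(seq_from_labels(labels), run_min=2)
        phases3, _ = foraging_phases(seq_from_labels(labels), run_min=3)
        assert len(phases2) == 2 and len(phases3) == 1

    def test_duration_bounded_by_record(self, rng):
        labels = ["foraging" if rng.random() < 0.5 else "flight" for _ in range(200)]
        seq = seq_from_labels(labels)
        _, h = foraging_phases(seq)
        assert h <= (seq.times[-1] - seq.times[0]) / 3600.0 + 1e-9


class TestSerialization:
    def test_roundtrip(self, rng):
        m = random_model(rng)
        m2 = HmmModel.from_text(m.to_text())
        for attr in ("step_mean", "step_sd", "angle_mean", "angle_kappa", "tpm", "delta"):
            assert np.allclose(getattr(m, attr), getattr(m2, attr), rtol=1e-10)


class TestLocalDecode:
    def test_agrees_with_viterbi_on_clear_data(self, rng):
        m = well_separated_model()
        steps, angles, _ = simulate_hmm_series(m, 200, rng)
        v = viterbi(m, steps, angles).states
        l = local_decode(m, steps, angles).states
        assert np.mean(v == l) > 0.95
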