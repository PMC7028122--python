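"""Face engine: dissimilarity metric, morphing, psychometric function and
the Bayesian adaptive staircase."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tabvis.faces import (
    N_LANDMARKS,
    FaceSessionResult,
    LandmarkFace,
    NormalizationError,
    PsychometricParams,
    QuestConfig,
    QuestState,
    dissimilarity,
    morph,
    next_level,
    prob_correct,
    quest_update,
    run_face_session,
    threshold_estimate,
)
from tabvis.observers import ObserverModel


def _random_face(rng, face_id="f"):
    return LandmarkFace(rng.uniform(0, 200, size=(N_LANDMARKS, 2)), face_id)


class TestDissimilarity:
    def test_identity_is_zero(self, rng):
        f = _random_face(rng)
        assert dissimilarity(f, f) == 0.0

    def test_single_displaced_point_is_pythagorean(self, rng):
        f = _random_face(rng)
        pts = f.points.copy()
        pts[40] += (3.0, 4.0)
        assert dissimilarity(f, LandmarkFace(pts)) == pytest.approx(5.0)

    def test_matches_per_point_loop_both_orders(self, rng):
        a, b = _random_face(rng), _random_face(rng)
        ss = 0.0
        for (xa, ya), (xb, yb) in zip(a.points, b.points):
            ss += (xa - xb) ** 2 + (ya - yb) ** 2
        expect = math.sqrt(ss)
        assert dissimilarity(a, b) == pytest.approx(expect, abs=1e-12 * expect)
        assert dissimilarity(b, a) == dissimilarity(a, b)

    def test_point_count_is_enforced(self, rng):
        with pytest.raises(ValueError, match="127"):
            LandmarkFace(rng.uniform(0, 1, size=(126, 2)))


class TestMorph:
    def test_zero_percent_is_identity(self, rng):
        f, ref = _random_face(rng), _random_face(rng)
        assert np.array_equal(morph(f, ref, 0.0).points, f.points)

    def test_hundred_percent_doubles_displacement(self, rng):
        ref = _random_face(rng)
        f = LandmarkFace(ref.points + 1.5)
        out = morph(f, ref, 100.0)
        np.testing.assert_allclose(out.points - ref.points,
                                   2.0 * (f.points - ref.points))

    def test_dissimilarity_linear_in_percentage(self, rng):
        f, ref = _random_face(rng), _random_face(rng)
        d = [dissimilarity(ref, morph(f, ref, p)) for p in (0.0, 50.0, 100.0)]
        # collinear: midpoint value is the average of the endpoints
        assert d[1] == pytest.approx((d[0] + d[2]) / 2, rel=1e-12)


class TestProbCorrect:
    def test_zero_level_hits_guess_floor(self):
        p = PsychometricParams(lapse_rate=0.0)
        assert prob_correct(0.0, 3.5, p) == pytest.approx(0.25)

    def test_large_level_approaches_one_without_lapse(self):
        p = PsychometricParams(lapse_rate=0.0)
        assert prob_correct(1e3, 3.5, p) == pytest.approx(1.0)

    def test_value_at_threshold(self):
        # gamma + (1-gamma)*(1 - 1/e) for gamma=.25, no lapse
        p = PsychometricParams(lapse_rate=0.0, slope=3.5)
        expect = 0.25 + 0.75 * (1 - math.exp(-1))
        assert prob_correct(3.5, 3.5, p) == pytest.approx(expect)
        assert expect == pytest.approx(0.724, abs=5e-4)

    def test_monotone_and_bounded(self):
        p = PsychometricParams()
        levels = np.linspace(0, 12, 200)
        vals = prob_correct(levels, 3.3, p)
        assert np.all(np.diff(vals) >= 0)
        assert np.all((vals >= p.guess_rate) & (vals <= 1 - p.lapse_rate))

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            prob_correct(1.0, 0.0)


class TestQuestUpdate:
    def test_single_trial_from_uniform_prior_matches_bayes_loop(self):
        params = PsychometricParams()
        dom = np.linspace(0.5, 8.0, 61)
        state = QuestState(dom, np.full(61, 1 / 61), params)
        for correct in (True, False):
            new = quest_update(state, 3.1, correct)
            expect = np.empty(61)
            for i, t in enumerate(dom):
                lik = prob_correct(3.1, t, params)
                expect[i] = lik if correct else 1 - lik
            expect /= expect.sum()
            np.testing.assert_allclose(new.posterior, expect, atol=1e-12)

    def test_updates_commute(self):
        state = QuestState.from_config()
        a = quest_update(quest_update(state, 3.0, True), 3.6, False)
        b = quest_update(quest_update(state, 3.6, False), 3.0, True)
        np.testing.assert_allclose(a.posterior, b.posterior, atol=1e-12)

    def test_correct_response_never_raises_estimate(self):
        state = QuestState.from_config()
        for level in (2.0, 3.5, 5.0):
            after = quest_update(state, level, True)
            assert threshold_estimate(after) <= threshold_estimate(state) + 1e-12

    def test_mass_conserved_and_history_appended(self):
        state = QuestState.from_config()
        for i, (lvl, c) in enumerate([(3.0, True), (3.2, False), (2.9, True)], start=1):
            state = quest_update(state, lvl, c)
            assert abs(state.posterior.sum() - 1.0) < 1e-9
            assert len(state.history) == i

    def test_vanishing_likelihood_is_diagnosed(self):
        params = PsychometricParams(lapse_rate=0.0)
        cfg = QuestConfig(params=params)
        state = QuestState.from_config(cfg)
        # an incorrect response at an absurdly high level has likelihood
        # 1 - p = 0 (to machine precision) for every candidate threshold
        with pytest.raises(NormalizationError):
            quest_update(state, 1e6, False)


class TestThresholdEstimate:
    def test_uniform_posterior_symmetric_domain(self):
        dom = np.linspace(2.0, 6.0, 41)
        state = QuestState(dom, np.full(41, 1 / 41), PsychometricParams())
        assert threshold_estimate(state) == pytest.approx(4.0)

    def test_no_trials_returns_prior_mean(self):
        cfg = QuestConfig()
        state = QuestState.from_config(cfg)
        expect = float(np.sum(state.domain * state.posterior))  # truncated prior mean
        assert threshold_estimate(state) == expect
        assert next_level(state) == pytest.approx(expect)

    def test_matches_weighted_sum_loop(self, rng):
        dom = np.linspace(0.5, 8.0, 91)
        w = rng.random(91)
        w /= w.sum()
        state = QuestState(dom, w, PsychometricParams())
        expect = sum(d * p for d, p in zip(dom, w))
        assert threshold_estimate(state) == pytest.approx(expect, abs=1e-12)


class TestNextLevel:
    def test_descends_after_correct_streak(self):
        state = QuestState.from_config()
        start = next_level(state)
        for _ in range(10):
            state = quest_update(state, next_level(state), True)
        assert next_level(state) < start

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.booleans(), min_size=1, max_size=40))
    def test_always_within_domain(self, responses):
        state = QuestState.from_config()
        for correct in responses:
            lvl = next_level(state)
            assert state.domain[0] <= lvl <= state.domain[-1]
            state = quest_update(state, lvl, correct)
        assert state.domain[0] <= next_level(state) <= state.domain[-1]


class TestRunFaceSession:
    def test_same_seed_identical_results(self):
        obs = ObserverModel(face_true_threshold=3.4)
        a = run_face_session(obs, n_trials=30, seed=99)
        b = run_face_session(obs, n_trials=30, seed=99)
        assert a.trials == b.trials
        np.testing.assert_array_equal(a.threshold_by_trial, b.threshold_by_trial)
        assert a.final_threshold == b.final_threshold

    def test_oracle_observer_converges_to_one_grain(self):
        # step-function observer: correct iff level >= true threshold
        cfg = QuestConfig()
        obs = ObserverModel(face_true_threshold=3.37, deterministic=True)
        res = run_face_session(obs, n_trials=50, seed=0, config=cfg)
        assert abs(res.final_threshold - 3.37) <= cfg.grain

    def test_estimates_finite_and_in_domain_every_trial(self):
        cfg = QuestConfig()
        obs = ObserverModel(face_true_threshold=3.8)
        res = run_face_session(obs, n_trials=50, seed=5, config=cfg)
        assert np.all(np.isfinite(res.threshold_by_trial))
        assert np.all((res.threshold_by_trial >= cfg.domain_min)
                      & (res.threshold_by_trial <= cfg.domain_max))

    def test_short_run_mean_matches_large_sample_reference(self):
        """The 20-trial estimate is unbiased enough that a few hundred
        sessions agree with a 10x larger reference run to within 0.1 d."""
        obs = ObserverModel(face_true_threshold=3.4)

        def mean_estimate(n_sessions, seed):
            rng = np.random.default_rng(seed)
            return np.mean([
                run_face_session(obs, n_trials=20, rng=rng).final_threshold
                for _ in range(n_sessions)
            ])

        assert abs(mean_estimate(300, 11) - mean_estimate(3000, 12)) < 0.1

    def test_result_invariants_enforced(self):
        with pytest.raises(ValueError):
            FaceSessionResult(trials=((3.0, True),), threshold_by_trial=[3.0, 3.1],
                              final_threshold=3.1, n_trials=2)
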