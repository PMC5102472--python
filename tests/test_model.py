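"""Unit and property tests for the core decision model."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.special import ndtr, ndtri

from judgebias.model import (
    Choice,
    ModelSpec,
    Params,
    SubjectData,
    TrialRecord,
    alpha,
    decision_threshold,
    log_likelihood,
    p_rew,
    p_rew_session1,
    simulate_choices,
)

params_strategy = st.builds(
    Params,
    sigma=st.floats(0.05, 3.0),
    delta=st.floats(-0.8, 0.8),
    c_loss=st.floats(0.2, 5.0),
    p_lapse=st.floats(0.0, 0.6),
)


class TestAlpha:
    @pytest.mark.parametrize(
        "win,loss,c,expected",
        [
            (50, 50, 1.0, 0.5),
            (80, 0, 1.0, 1.0),
            (100, 50, 2.0, 0.5),   # 100 / (100 + 2*50)
            (0, 30, 1.0, 0.0),
            (25, 75, 1.0 / 3.0, 0.5),
        ],
    )
    def test_values(self, win, loss, c, expected):
        assert alpha(win, loss, c) == pytest.approx(expected)

    def test_both_stakes_zero_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            alpha(0, 0, 1.0)

    def test_vectorized(self):
        out = alpha(np.array([50.0, 80.0]), np.array([50.0, 0.0]), 1.0)
        np.testing.assert_allclose(out, [0.5, 1.0])


class TestDecisionThreshold:
    def test_symmetric_stakes_unbiased_is_zero(self):
        assert decision_threshold(0.5, 1.3, 0.0) == 0.0

    def test_pure_bias_shift(self):
        assert decision_threshold(0.5, 1.0, 0.2) == pytest.approx(-0.2)

    def test_matches_normal_quantile(self):
        # alpha = Phi(1) makes the threshold -sigma * 1
        assert decision_threshold(float(ndtr(1.0)), 1.0, 0.0) == pytest.approx(-1.0, abs=1e-9)

    @given(a=st.floats(0.01, 0.99), sigma=st.floats(0.1, 3.0), delta=st.floats(-1, 1))
    def test_closed_form(self, a, sigma, delta):
        assert decision_threshold(a, sigma, delta) == pytest.approx(
            -sigma * ndtri(a) - delta
        )

    def test_degenerate_alpha_signed_infinity(self):
        assert decision_threshold(0.0, 1.0, 0.0) == np.inf
        assert decision_threshold(1.0, 1.0, 0.0) == -np.inf

    @given(a1=st.floats(0.05, 0.45), a2=st.floats(0.55, 0.95))
    def test_decreasing_in_alpha(self, a1, a2):
        assert decision_threshold(a1, 1.0, 0.0) > decision_threshold(a2, 1.0, 0.0)


class TestPRew:
    def test_symmetric_indifference(self):
        p = Params(sigma=0.7, delta=0.0, c_loss=1.0, p_lapse=0.0)
        assert p_rew(0.0, p, 50, 50) == pytest.approx(0.5)

    def test_normal_cdf_value(self):
        p = Params(sigma=0.5, delta=0.0)
        assert p_rew(0.25, p, 50, 50) == pytest.approx(float(ndtr(0.5)))

    def test_pure_lapse_is_coin_flip(self):
        p = Params(sigma=0.5, delta=0.3, c_loss=2.0, p_lapse=1.0)
        for s in (-1.0, 0.0, 1.0):
            assert p_rew(s, p, 80, 20) == pytest.approx(0.5)

    @given(params=params_strategy, s=st.floats(-1, 1))
    def test_lapse_bounds(self, params, s):
        val = p_rew(s, params, 40, 60)
        assert params.p_lapse / 2 - 1e-12 <= val <= 1 - params.p_lapse / 2 + 1e-12

    @given(params=params_strategy, s1=st.floats(-1, 0), s2=st.floats(0.01, 1))
    def test_monotone_in_stimulus(self, params, s1, s2):
        assert p_rew(s1 + s2, params, 50, 50) >= p_rew(s1, params, 50, 50)

    @given(params=params_strategy, s=st.floats(-1, 1))
    def test_monotone_in_stakes(self, params, s):
        low_win = p_rew(s, params, 20, 50)
        high_win = p_rew(s, params, 80, 50)
        assert high_win >= low_win
        low_loss = p_rew(s, params, 50, 10)
        high_loss = p_rew(s, params, 50, 90)
        assert high_loss <= low_loss

    def test_saturation_limits(self):
        p = Params(sigma=0.4, delta=0.1, c_loss=1.5, p_lapse=0.2)
        # ndtr saturates well before |s/sigma| ~ 40
        assert p_rew(1.0, Params(sigma=0.01, delta=0.0, p_lapse=0.2), 50, 50) == pytest.approx(0.9)
        assert p_rew(-1.0, Params(sigma=0.01, delta=0.0, p_lapse=0.2), 50, 50) == pytest.approx(0.1)
        # degenerate stakes saturate at the lapse-bounded extremes
        assert p_rew(0.0, p, 50, 0) == pytest.approx(1 - 0.1)
        assert p_rew(0.0, p, 0, 50) == pytest.approx(0.1)

    @given(
        sigma=st.floats(0.1, 2.0), delta=st.floats(-0.5, 0.5),
        c=st.floats(0.25, 4.0), s=st.floats(-1, 1),
        win=st.integers(1, 100), loss=st.integers(1, 100),
    )
    def test_mirror_symmetry(self, sigma, delta, c, s, win, loss):
        """Swapping stakes, inverting c_loss and negating (s, delta) flips P."""
        p1 = p_rew(s, Params(sigma, delta, c), win, loss)
        p2 = p_rew(-s, Params(sigma, -delta, 1.0 / c), loss, win)
        assert p1 == pytest.approx(1.0 - p2, abs=1e-9)

    def test_agent_oracle_single_condition(self):
        """Percept-sampling agent reproduces the closed form (one condition)."""
        params = Params(sigma=0.6, delta=-0.2, c_loss=1.4, p_lapse=0.1)
        s, win, loss = 0.25, 70, 30
        rng = np.random.default_rng(42)
        n = 200_000
        x = rng.normal(s, params.sigma, n)
        thresh = decision_threshold(alpha(win, loss, params.c_loss),
                                    params.sigma, params.delta)
        choice = x > thresh
        lapse = rng.random(n) < params.p_lapse
        choice[lapse] = rng.random(int(lapse.sum())) < 0.5
        p_hat = choice.mean()
        p_true = p_rew(s, params, win, loss)
        assert abs(p_hat - p_true) < 3 * np.sqrt(p_true * (1 - p_true) / n)


class TestSession1Reduction:
    def test_indifference_points(self):
        assert p_rew_session1(0.0, 0.8, 0.0) == pytest.approx(0.5)
        assert p_rew_session1(0.3, 1.1, -0.3) == pytest.approx(0.5)

    def test_cdf_value(self):
        assert p_rew_session1(1.0, 1.0, 0.0) == pytest.approx(float(ndtr(1.0)))

    @given(s=st.floats(-1, 1), sigma=st.floats(0.1, 2), delta=st.floats(-0.5, 0.5))
    def test_equals_full_model_at_equal_stakes(self, s, sigma, delta):
        full = p_rew(s, Params(sigma=sigma, delta=delta), 50, 50)
        assert p_rew_session1(s, sigma, delta) == pytest.approx(full, abs=1e-12)


def _subject(trials):
    return SubjectData(subject_id="s", group="g", trials=trials)


class TestLogLikelihood:
    def test_single_indifferent_trial(self):
        subj = _subject([TrialRecord(0.0, 50, 50, choice=Choice.REW)])
        assert log_likelihood(subj, Params(sigma=1.0, delta=0.0)) == pytest.approx(
            math.log(0.5)
        )

    def test_split_pair_of_identical_trials(self):
        params = Params(sigma=0.5, delta=-0.1)
        subj = _subject([
            TrialRecord(0.25, 50, 50, choice=Choice.REW),
            TrialRecord(0.25, 50, 50, choice=Choice.SAFE),
        ])
        p = p_rew(0.25, params, 50, 50)
        assert log_likelihood(subj, params) == pytest.approx(math.log(p) + math.log(1 - p))

    def test_term_by_term_oracle(self):
        """Ten mixed trials match an independent per-trial product."""
        params = Params(sigma=0.45, delta=-0.15, c_loss=0.8, p_lapse=0.07)
        leans = [-1.0, -0.6, -0.25, -0.1, 0.0, 0.1, 0.25, 0.5, 0.8, 1.0]
        stakes = [(50, 50), (80, 20), (10, 90), (70, 0), (0, 40),
                  (33, 66), (100, 1), (5, 5), (60, 60), (45, 55)]
        choices = [Choice.REW, Choice.SAFE] * 5
        subj = _subject([
            TrialRecord(s, w, l, choice=c)
            for s, (w, l), c in zip(leans, stakes, choices)
        ])
        # independent route: scalar normal CDF per trial, plain math
        expected = 0.0
        for s, (w, l), c in zip(leans, stakes, choices):
            a = w / (w + params.c_loss * l)
            if a == 1.0:
                phi = 1.0
            elif a == 0.0:
                phi = 0.0
            else:
                phi = float(ndtr((s + params.sigma * ndtri(a) + params.delta) / params.sigma))
            p = (1 - params.p_lapse) * phi + params.p_lapse / 2
            expected += math.log(p if c is Choice.REW else 1 - p)
        assert log_likelihood(subj, params) == pytest.approx(expected, rel=1e-12)

    def test_requires_choices(self):
        with pytest.raises(ValueError):
            log_likelihood(_subject([]), Params(sigma=1, delta=0))
        with pytest.raises(ValueError):
            log_likelihood(_subject([TrialRecord(0.0, 50, 50)]), Params(sigma=1, delta=0))

    def test_spec_consistency_enforced(self):
        subj = _subject([TrialRecord(0.0, 50, 50, choice=Choice.REW)])
        with pytest.raises(ValueError, match="conflicts"):
            log_likelihood(subj, Params(sigma=1, delta=0, c_loss=2.0),
                           spec=ModelSpec.session1())

    def test_finite_for_impossible_choice(self):
        """Probability clipping keeps lapse-free likelihoods finite."""
        subj = _subject([TrialRecord(-1.0, 50, 50, choice=Choice.REW)])
        ll = log_likelihood(subj, Params(sigma=0.01, delta=0.0))
        assert np.isfinite(ll)
        assert ll == pytest.approx(math.log(1e-9), rel=1e-6)


class TestSimulateChoices:
    def test_noiseless_follows_sign(self, s1_design):
        params = Params(sigma=1e-4, delta=0.0)
        choices = simulate_choices(s1_design, params, seed=1)
        for t, c in zip(s1_design, choices):
            if abs(t.ambiguity) > 0.01:
                assert c is (Choice.REW if t.ambiguity > 0 else Choice.SAFE)

    def test_seed_determinism(self, s3_design):
        params = Params(sigma=0.5, delta=-0.1, c_loss=0.8, p_lapse=0.05)
        assert simulate_choices(s3_design, params, 9) == simulate_choices(s3_design, params, 9)

    def test_empirical_frequency_matches_closed_form(self):
        params = Params(sigma=0.5, delta=-0.2, c_loss=1.3, p_lapse=0.1)
        trial = TrialRecord(0.2, 60, 40)
        n = 100_000
        choices = simulate_choices([trial] * n, params, seed=3)
        p_hat = np.mean([c is Choice.REW for c in choices])
        p = p_rew(0.2, params, 60, 40)
        assert abs(p_hat - p) < 3 * np.sqrt(p * (1 - p) / n)


class TestModelSpec:
    def test_session_families(self):
        assert ModelSpec.session1().free == ("sigma", "delta")
        assert ModelSpec.session1().fixed_values == {"c_loss": 1.0, "p_lapse": 0.0}
        assert ModelSpec.session1_lapse().free == ("sigma", "delta", "p_lapse")
        assert ModelSpec.session3_full().free == ("sigma", "delta", "c_loss", "p_lapse")

    def test_free_set_must_be_non_empty(self):
        with pytest.raises(ValueError):
            ModelSpec(free=())

    def test_build_params_merges_fixed(self):
        spec = ModelSpec.session1()
        p = spec.build_params(np.array([0.5, -0.1]))
        assert p == Params(sigma=0.5, delta=-0.1, c_loss=1.0, p_lapse=0.0)

    def test_invalid_fixed_values_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec(free=("sigma", "delta"), fixed_values={"p_lapse": 1.5})


def test_group_gap_is_larger_opposite_to_shared_bias():
    """With a shared bias toward SAFE and differing noise, the group gap in
    risky choice is wider at the WIN extreme than at the LOSS extreme."""
    delta = -0.3
    gap_win = abs(p_rew_session1(1.0, 0.35, delta) - p_rew_session1(1.0, 0.7, delta))
    gap_loss = abs(p_rew_session1(-1.0, 0.35, delta) - p_rew_session1(-1.0, 0.7, delta))
    assert gap_win > gap_loss
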