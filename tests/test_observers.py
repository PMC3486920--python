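"""Observer models: memory-trace algebra, choice probabilities, oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from tonebias.observers import (
    BayesParams,
    ImplicitMemoryParams,
    MemoryTrace,
    NaiveParams,
    bayes_choice_prob,
    imm_choice_prob,
    imm_closed_form,
    imm_noise_sd,
    imm_respond,
    imm_signal,
    imm_update,
    log_uniform_moments,
    naive_choice_prob,
)


class TestMemoryTrace:
    def test_memoryless_update_copies_stimulus(self):
        params = ImplicitMemoryParams(sigma=0.1, gamma=0.0)
        out = imm_update(MemoryTrace(H=3.0, t=5), 6.9, params, noise=0.0)
        assert out.H == pytest.approx(6.9)
        assert out.t == 6

    def test_convex_update_is_midpoint_at_half(self):
        params = ImplicitMemoryParams(sigma=0.1, gamma=0.5)
        out = imm_update(MemoryTrace(H=7.0), 6.8, params, noise=0.0)
        assert out.H == pytest.approx(6.9)

    def test_constant_input_converges_geometrically(self):
        params = ImplicitMemoryParams(sigma=0.1, gamma=0.8)
        c, trace = math.log(1000.0), MemoryTrace(H=7.5)
        gaps = []
        for _ in range(30):
            trace = imm_update(trace, c, params, noise=0.0)
            gaps.append(abs(trace.H - c))
        ratios = np.array(gaps[1:]) / np.array(gaps[:-1])
        assert np.allclose(ratios, 0.8, atol=1e-9)

    def test_fixed_point_in_closed_form(self):
        c = math.log(1000.0)
        out = imm_closed_form([c] * 50, [0.0] * 50, gamma=0.8, H0=c)
        assert out == pytest.approx(c, rel=1e-12)

    def test_single_trial_memoryless_closed_form(self):
        assert imm_closed_form([6.9], [0.02], gamma=0.0, H0=5.0) == pytest.approx(
            6.92
        )

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            imm_closed_form([6.9, 7.0], [0.0], gamma=0.5, H0=6.9)

    @settings(derandomize=True, deadline=None, max_examples=60)
    @given(
        gamma=st.floats(min_value=0.0, max_value=0.999),
        h0=st.floats(min_value=6.0, max_value=8.0),
        data=st.lists(
            st.tuples(
                st.floats(min_value=6.5, max_value=7.3),
                st.floats(min_value=-0.3, max_value=0.3),
            ),
            min_size=1,
            max_size=40,
        ),
    )
    def test_iterated_update_equals_closed_form(self, gamma, h0, data):
        """The recursion and the exponentially weighted sum are identical."""
        params = ImplicitMemoryParams(sigma=1.0, gamma=gamma)
        trace = MemoryTrace(H=h0)
        for l1, eps in data:
            trace = imm_update(trace, l1, params, noise=eps)
        closed = imm_closed_form(
            [d[0] for d in data], [d[1] for d in data], gamma, h0
        )
        assert trace.H == pytest.approx(closed, rel=1e-10, abs=1e-10)


class TestImmChoice:
    def test_decision_rule(self, rng):
        assert imm_respond(MemoryTrace(H=7.0), 6.9, rng) == 1
        assert imm_respond(MemoryTrace(H=6.8), 6.9, rng) == 0

    def test_exact_tie_is_fair_coin(self, rng):
        n = 10_000
        mean = np.mean(
            [imm_respond(MemoryTrace(H=6.9), 6.9, rng) for _ in range(n)]
        )
        assert abs(mean - 0.5) < 3 * math.sqrt(0.25 / n)

    def test_signal_equals_noise_at_half_probability(self):
        params = ImplicitMemoryParams(sigma=0.1, gamma=0.4)
        history = [6.9] * 20
        s = imm_signal(history, params.gamma)[-1]
        assert imm_choice_prob(history, s, params) == pytest.approx(0.5)

    def test_memoryless_limit_is_naive_model(self):
        params = ImplicitMemoryParams(sigma=0.1, gamma=0.0)
        history = [6.8, 7.1, 6.95]
        got = imm_choice_prob(history, 6.9, params)
        want = naive_choice_prob(6.95, 6.9, NaiveParams(sigma=0.1))
        assert got == pytest.approx(want, rel=1e-12)

    def test_steady_state_noise_sd_value(self):
        # geometric series: 0.1 * sqrt(0.4/1.6) = 0.05
        assert imm_noise_sd(0.1, 0.6) == pytest.approx(0.05)

    def test_choice_prob_matches_monte_carlo(self, rng):
        """Frequency of H > l2 over noise draws matches the analytic form."""
        params = ImplicitMemoryParams(sigma=0.1, gamma=0.6)
        g, T = params.gamma, 50
        history = list(6.9 + 0.05 * rng.standard_normal(T))
        l2 = 6.93
        n = 100_000
        noises = rng.normal(0.0, params.sigma, size=(n, T))
        # trace weights: oldest trial initializes H, later ones enter with
        # the convex update, so w_i = (1-g)*g^(T-1-i), w_0 = g^(T-1)
        w = (1 - g) * g ** np.arange(T - 1, -1, -1, dtype=float)
        w[0] = g ** (T - 1)
        s = imm_signal(history, g)[-1]
        h = s + noises @ w
        mc = np.mean(h > l2)
        ana = imm_choice_prob(history, l2, params)
        se = math.sqrt(ana * (1 - ana) / n)
        # steady-state SD is exact only as t -> inf; 50 trials is deep burn-in
        assert abs(mc - ana) < 3 * se + 1e-3

    def test_gamma_one_rejected(self):
        with pytest.raises(ValueError):
            ImplicitMemoryParams(sigma=0.1, gamma=1.0)


class TestNaiveChoice:
    def test_equal_tones_are_chance(self):
        assert naive_choice_prob(6.9, 6.9, NaiveParams(0.1)) == 0.5

    def test_asymptote_value(self):
        # Phi(0.82) ~ 0.794: the staircase criterion in choice units
        got = naive_choice_prob(6.982, 6.9, NaiveParams(0.1))
        assert got == pytest.approx(0.7939, abs=1e-3)

    def test_heaviside_limit(self):
        assert naive_choice_prob(6.91, 6.9, NaiveParams(1e-6)) == pytest.approx(
            1.0
        )

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            NaiveParams(sigma=0.0)


class TestBayesChoice:
    def prior(self):
        mean, sd = log_uniform_moments(800.0, 1200.0)
        return mean, sd

    def test_symmetric_params_equal_tones_chance(self):
        mean, sd = self.prior()
        p = BayesParams(0.1, 0.1, mean, sd)
        assert bayes_choice_prob(7.0, 7.0, p) == pytest.approx(0.5)

    def test_contraction_sign_above_prior(self):
        """Noisier tone 1 is pulled toward the prior, hence judged lower."""
        mean, sd = self.prior()
        p = BayesParams(0.3, 0.01, mean, sd)
        assert bayes_choice_prob(mean + 0.1, mean + 0.1, p) < 0.5
        assert bayes_choice_prob(mean - 0.1, mean - 0.1, p) > 0.5

    def test_monotonicity_in_both_tones(self):
        mean, sd = self.prior()
        p = BayesParams(0.15, 0.05, mean, sd)
        l = np.linspace(6.7, 7.1, 9)
        probs_l1 = [bayes_choice_prob(x, 6.9, p) for x in l]
        probs_l2 = [bayes_choice_prob(6.9, x, p) for x in l]
        assert np.all(np.diff(probs_l1) > 0)
        assert np.all(np.diff(probs_l2) < 0)
        probs_naive = [naive_choice_prob(x, 6.9, NaiveParams(0.1)) for x in l]
        assert np.all(np.diff(probs_naive) > 0)
        imm_p = ImplicitMemoryParams(sigma=0.1, gamma=0.5)
        probs_imm = [imm_choice_prob([6.9, x], 6.9, imm_p) for x in l]
        assert np.all(np.diff(probs_imm) > 0)

    def test_nonpositive_sd_rejected(self):
        with pytest.raises(ValueError):
            BayesParams(0.0, 0.1, 6.9, 0.1)


def test_log_uniform_moments_match_numerical_integration():
    mean, sd = log_uniform_moments(800.0, 1200.0)
    x = np.linspace(800.0, 1200.0, 2_000_001)
    lx = np.log(x)
    num_mean = np.trapezoid(lx, x) / 400.0
    num_var = np.trapezoid((lx - num_mean) ** 2, x) / 400.0
    assert mean == pytest.approx(num_mean, rel=1e-9)
    assert sd == pytest.approx(math.sqrt(num_var), rel=1e-6)
    # centred just below ln(1000): E[ln X] < ln E[X] by Jensen
    assert mean < math.log(1000.0)
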