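"""First-passage mathematics: choice probabilities, densities, CDFs, simulator."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.integrate import quad

from pendiff import (
    DiffusionParams, ParameterError, SignedCDFGrid, choice_probability,
    fpt_cdf, fpt_density, predicted_signed_cdf, simulate_trials,
)

PARAM_CASES = [
    (1.5, 2.1, 0.72),
    (-2.0, 2.7, 0.31),
    (0.0, 1.0, 0.5),
    (4.0, 1.2, 0.6),
    (-6.0, 3.0, 0.9),
    (0.3, 0.4, 0.2),
]

valid_v = st.floats(-8, 8)
valid_a = st.floats(0.2, 6)
valid_zr = st.floats(0.05, 0.95)


class TestChoiceProbability:
    def test_zero_drift_equals_relative_start(self):
        assert choice_probability(0.0, 2.0, 0.3) == pytest.approx(0.3, abs=1e-12)

    def test_known_value(self):
        # closed form at v=1, a=1, zr=0.5 (cross-checked by simulation)
        assert choice_probability(1.0, 1.0, 0.5) == pytest.approx(0.7310586, abs=1e-6)

    @given(v=valid_v, a=valid_a, zr=valid_zr)
    def test_reflection_symmetry(self, v, a, zr):
        p = choice_probability(v, a, zr)
        assert p == pytest.approx(1.0 - choice_probability(-v, a, 1.0 - zr), abs=1e-10)

    @given(v=valid_v, a=valid_a, zr=valid_zr)
    def test_conservation(self, v, a, zr):
        p_up = choice_probability(v, a, zr)
        p_lo = 1.0 - p_up
        assert 0.0 <= p_up <= 1.0
        assert abs(p_up + p_lo - 1.0) < 1e-10

    def test_domain_errors(self):
        with pytest.raises(ParameterError):
            choice_probability(1.0, -1.0, 0.5)
        with pytest.raises(ParameterError):
            choice_probability(1.0, 1.0, 1.2)


class TestDensityAndCdf:
    def test_zero_drift_symmetry(self):
        t = np.linspace(0.05, 2.0, 20)
        up = fpt_density(t, 0.0, 1.0, 0.5, "upper")
        lo = fpt_density(t, 0.0, 1.0, 0.5, "lower")
        assert np.allclose(up, lo, atol=1e-12)

    @pytest.mark.parametrize("v,a,zr", PARAM_CASES[:4])
    def test_total_mass_is_one(self, v, a, zr):
        total = sum(
            quad(lambda t: fpt_density(t, v, a, zr, b), 1e-9, np.inf, limit=300)[0]
            for b in ("upper", "lower")
        )
        assert total == pytest.approx(1.0, abs=1e-8)

    @pytest.mark.parametrize("v,a,zr", PARAM_CASES)
    def test_cdf_matches_integrated_density(self, v, a, zr):
        for b in ("upper", "lower"):
            for t in (0.1, 0.6, 2.0):
                integral = quad(
                    lambda s: fpt_density(s, v, a, zr, b), 1e-12, t, limit=300
                )[0]
                assert fpt_cdf(t, v, a, zr, b) == pytest.approx(integral, abs=1e-6)

    @pytest.mark.parametrize("v,a,zr", PARAM_CASES)
    def test_cdf_density_consistency_by_differentiation(self, v, a, zr):
        h = 1e-5
        for t in (0.2, 0.9):
            num = (fpt_cdf(t + h, v, a, zr, "lower") - fpt_cdf(t - h, v, a, zr, "lower")) / (2 * h)
            assert num == pytest.approx(fpt_density(t, v, a, zr, "lower"), abs=1e-5)

    @pytest.mark.parametrize("v,a,zr", PARAM_CASES)
    def test_cdf_limits(self, v, a, zr):
        assert fpt_cdf(1e-8, v, a, zr, "upper") == pytest.approx(0.0, abs=1e-9)
        t_inf = 200.0 * max(1.0, a * a / 4)
        assert fpt_cdf(t_inf, v, a, zr, "upper") == pytest.approx(
            choice_probability(v, a, zr), abs=1e-8
        )

    @given(v=valid_v, a=valid_a, zr=valid_zr)
    def test_cdf_monotone(self, v, a, zr):
        t = np.geomspace(1e-3, 8.0, 60)
        F = fpt_cdf(t, v, a, zr, "lower")
        assert np.all(np.diff(F) >= -1e-12)

    def test_nonpositive_time_rejected(self):
        with pytest.raises(ParameterError):
            fpt_density(-0.1, 1.0, 1.0, 0.5)
        with pytest.raises(ParameterError):
            fpt_cdf(0.0, 1.0, 1.0, 0.5)


class TestPredictedSignedCdf:
    def test_degenerate_mixture_equals_plain_construction(self, younger_means):
        p = younger_means.replace(s_v=0.0, s_zr=0.0, s_t0=0.0)
        x = np.linspace(-3.0, 3.0, 101)
        G = predicted_signed_cdf(p, "word", x)
        p_low = 1.0 - choice_probability(p.v_word, p.a, p.zr_word)
        expected = np.empty_like(x)
        for i, xi in enumerate(x):
            td = abs(xi) - p.t0
            if xi < 0:
                expected[i] = p_low - (
                    fpt_cdf(td, p.v_word, p.a, p.zr_word, "lower") if td > 0 else 0.0
                )
            else:
                expected[i] = p_low + (
                    fpt_cdf(td, p.v_word, p.a, p.zr_word, "upper") if td > 0 else 0.0
                )
        assert np.allclose(G, expected, atol=1e-12)

    def test_limits_and_monotonicity(self, younger_means):
        x = np.concatenate([[-np.inf], np.linspace(-4, 4, 201), [np.inf]])
        for cond in ("word", "nonword"):
            G = predicted_signed_cdf(younger_means, cond, x)
            assert G[0] == 0.0 and G[-1] == 1.0
            assert np.all(np.diff(G) >= -1e-9)

    def test_grid_evaluator_matches_exact(self, older_means):
        x = np.concatenate([np.linspace(-3.4, -0.26, 60), np.linspace(0.26, 3.4, 60)])
        for cond in ("word", "nonword"):
            exact = predicted_signed_cdf(older_means, cond, x)
            fast = SignedCDFGrid(older_means, cond)(x)
            assert np.max(np.abs(exact - fast)) < 1e-3


class TestSimulator:
    def test_strong_drift_dominates(self, rng):
        p = DiffusionParams(v_word=6.0, v_nonword=-6.0, a=1.0, zr_word=0.5,
                            zr_nonword=0.5, t0=0.2)
        up, rt = simulate_trials(p, "word", 1000, rng)
        assert up.mean() >= 0.99

    def test_nondecision_floor(self, rng):
        p = DiffusionParams(v_word=1.0, v_nonword=-1.0, a=1.5, zr_word=0.5,
                            zr_nonword=0.5, t0=0.3, s_t0=0.1)
        _, rt = simulate_trials(p, "word", 2000, rng)
        assert rt.min() >= 0.3 - 0.05 - 1e-9

    def test_choice_fraction_matches_quadrature(self, younger_means, rng):
        up, _ = simulate_trials(younger_means, "word", 20_000, rng)
        grid = SignedCDFGrid(younger_means, "word")
        p_up = 1.0 - grid.p_lower
        se = np.sqrt(p_up * (1 - p_up) / 20_000)
        assert abs(up.mean() - p_up) < 4 * se + 5e-3

    def test_ecdf_close_to_analytic_cdf(self, older_means, rng):
        up, rt = simulate_trials(older_means, "nonword", 20_000, rng)
        s = np.sort(np.where(up, rt, -rt))
        G = SignedCDFGrid(older_means, "nonword")(s)
        n = s.size
        ecdf = np.arange(1, n + 1) / n
        D = max(np.max(np.abs(ecdf - G)), np.max(np.abs(ecdf - 1 / n - G)))
        assert D < 0.015  # MC noise ~1/sqrt(n) plus small discretization bias
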