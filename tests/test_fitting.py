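"""Signed samples, KS statistics, starting values, and parameter recovery."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstwobign

from pendiff import (
    DataError, DiffusionParams, EstimationError, FitConfig, fit_participant,
    initial_values, ks_distance, ks_pvalue, signed_sample,
)
from pendiff.fitting import ks_log_pvalue, _ks_lambda

SIMPLE = DiffusionParams(v_word=1.2, v_nonword=-1.2, a=1.6, zr_word=0.5,
                         zr_nonword=0.5, t0=0.3)


def _frame(rows):
    return pd.DataFrame(
        rows,
        columns=["participant_id", "condition", "is_reference", "is_practice",
                 "response", "rt_s"],
    ).assign(session=3, page=1, slot=2)


class TestSignedSample:
    def test_signs_and_sorting(self):
        trials = _frame([
            ("P1", "word", False, False, "word", 0.7),
            ("P1", "word", False, False, "nonword", 0.9),
        ])
        s = signed_sample(trials, "word")
        assert np.allclose(s, [-0.9, 0.7])

    def test_single_response_type_single_sign(self):
        trials = _frame([("P1", "word", False, False, "word", rt)
                         for rt in (0.5, 0.6, 0.7)])
        assert (signed_sample(trials, "word") > 0).all()

    def test_length_preserved_references_excluded(self):
        trials = _frame([
            ("P1", "word", True, False, "word", 0.5),
            ("P1", "word", False, False, "word", 0.6),
            ("P1", "word", False, False, "word", 0.8),
        ])
        assert signed_sample(trials, "word").size == 2

    def test_empty_condition_raises(self):
        trials = _frame([("P1", "word", False, False, "word", 0.5)])
        with pytest.raises(DataError):
            signed_sample(trials, "nonword")


class TestKsStatistics:
    def test_single_point(self):
        assert ks_distance(np.array([1.0]), np.array([0.5])) == pytest.approx(0.5)

    def test_optimal_quantile_placement(self):
        n = 20
        g = (np.arange(1, n + 1) - 0.5) / n  # G at the sample points
        assert ks_distance(np.arange(n, dtype=float), g) == pytest.approx(1 / (2 * n))

    def test_sample_against_its_own_ecdf(self, rng):
        x = np.sort(rng.normal(size=57))
        ecdf = np.arange(1, 58) / 57.0
        assert ks_distance(x, ecdf) <= 1 / 57 + 1e-12

    def test_pvalue_extremes_and_example(self):
        assert ks_pvalue(0.0, 10) == 1.0
        # frozen value from the Kolmogorov series at D=0.5, n=10
        assert ks_pvalue(0.5, 10) == pytest.approx(0.0081, abs=3e-4)

    def test_pvalue_monotone_in_D(self):
        ps = [ks_pvalue(d, 50) for d in np.linspace(0.01, 0.6, 25)]
        assert all(a >= b - 1e-12 for a, b in zip(ps, ps[1:]))

    @pytest.mark.parametrize("D,n", [(0.08, 200), (0.15, 100), (0.3, 30)])
    def test_matches_scipy_kolmogorov_tail(self, D, n):
        lam = _ks_lambda(D, n)
        assert ks_pvalue(D, n) == pytest.approx(float(kstwobign.sf(lam)), rel=1e-6)

    def test_log_pvalue_consistent(self):
        for D, n in ((0.05, 500), (0.2, 80)):
            assert np.exp(ks_log_pvalue(D, n)) == pytest.approx(ks_pvalue(D, n))


class TestInitialValues:
    def test_symmetric_data_neutral_start(self, rng):
        rows = []
        for cond in ("word", "nonword"):
            for i in range(100):
                resp = "word" if i % 2 == 0 else "nonword"
                rows.append(("P1", cond, False, False, resp, 0.5 + 0.002 * i))
        p = initial_values(_frame(rows))
        assert abs(p.v_word) <= 0.1 and abs(p.v_nonword) <= 0.1
        assert p.zr_word == pytest.approx(0.5, abs=0.02)

    def test_deterministic(self, make_trials_fn):
        t = make_trials_fn(SIMPLE, 100, 100, np.random.default_rng(5))
        assert initial_values(t) == initial_values(t)

    def test_within_factor_two_of_truth(self, make_trials_fn):
        t = make_trials_fn(SIMPLE, 2500, 2500, np.random.default_rng(8))
        p = initial_values(t)
        for est, true in ((p.v_word, SIMPLE.v_word), (-p.v_nonword, -SIMPLE.v_nonword),
                          (p.a, SIMPLE.a)):
            assert true / 2 <= est <= true * 2

    def test_too_few_trials(self):
        rows = [("P1", "word", False, False, "word", 0.5)] * 30 + [
            ("P1", "nonword", False, False, "nonword", 0.6)
        ] * 5
        with pytest.raises(EstimationError):
            initial_values(_frame(rows))


class TestFitParticipant:
    def test_recovery_without_variabilities(self, make_trials_fn):
        trials = make_trials_fn(SIMPLE, 5000, 5000, np.random.default_rng(21))
        cfg = FitConfig(fix_variabilities_at_zero=True, n_restarts=2,
                        max_iterations=300, seed=0, window=None)
        fr = fit_participant(trials, cfg)
        assert fr.estimate.v_word == pytest.approx(SIMPLE.v_word, abs=0.1)
        assert fr.estimate.v_nonword == pytest.approx(SIMPLE.v_nonword, abs=0.15)
        assert fr.estimate.a == pytest.approx(SIMPLE.a, rel=0.1)
        assert fr.estimate.t0 == pytest.approx(SIMPLE.t0, abs=0.03)

    def test_degenerate_single_boundary_no_crash(self):
        rng = np.random.default_rng(0)
        rows = [("P1", c, False, False, "word", float(rt))
                for c in ("word", "nonword")
                for rt in rng.uniform(0.4, 1.2, size=40)]
        cfg = FitConfig(n_restarts=1, max_iterations=40, seed=0,
                        fix_variabilities_at_zero=True)
        fr = fit_participant(_frame(rows), cfg)
        assert fr.n_word == 40 and fr.n_nonword == 40
        assert 0.0 <= fr.ks_p_word <= 1.0

    def test_share_zr_control_model(self, make_trials_fn):
        # the control model with a single relative starting point must
        # return identical zr estimates for both conditions
        trials = make_trials_fn(SIMPLE, 300, 300, np.random.default_rng(9))
        cfg = FitConfig(share_zr=True, fix_variabilities_at_zero=True,
                        n_restarts=1, max_iterations=120, seed=0, window=None)
        fr = fit_participant(trials, cfg)
        assert fr.estimate.zr_word == fr.estimate.zr_nonword

    def test_multiple_participants_rejected(self, make_trials_fn):
        a = make_trials_fn(SIMPLE, 30, 30, np.random.default_rng(1), pid="A")
        b = make_trials_fn(SIMPLE, 30, 30, np.random.default_rng(2), pid="B")
        with pytest.raises(DataError):
            fit_participant(pd.concat([a, b]), FitConfig(n_restarts=1))
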