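"""Error metrics, correlation, AAMI logic, rank tests and the γ sweep."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from patbp.calibration import CalibPair, CalibrationPlan
from patbp.evaluation import (
    PairedSeries,
    aami_verdict,
    default_gamma_grid,
    dunn_posthoc,
    error_summary,
    gamma_sensitivity_sweep,
    kruskal_wallis,
    pearson_correlation,
)
from patbp.models import estimate_bp
from patbp.synth import SubjectProfile, generating_params


def _naive_summary(est, cuf):
    """Independent re-implementation of the error statistics, term by term."""
    x = [e - c for e, c in zip(est, cuf)]
    n = len(x)
    me = sum(x) / n
    mad = sum(abs(v) for v in x) / n
    sse = sum(v * v for v in x)
    sigma = math.sqrt(sse / (n - 1))
    sd = math.sqrt(sum((v - me) ** 2 for v in x) / n)
    rmse = math.sqrt(sse / n)
    cv = None if me == 0 else sigma / me
    return me, mad, sse, sigma, cv, sd, rmse


class TestErrorSummary:
    def test_worked_example(self):
        s = error_summary(PairedSeries([120.0, 125.0, 130.0],
                                       [122.0, 121.0, 131.0]))
        assert s.me == pytest.approx(0.3333, abs=1e-4)
        assert s.mad == pytest.approx(2.3333, abs=1e-4)
        assert s.sse == pytest.approx(21.0)
        assert s.sigma == pytest.approx(3.2404, abs=1e-4)
        assert s.cv == pytest.approx(9.7211, abs=1e-4)
        assert s.sd == pytest.approx(2.6247, abs=1e-4)
        assert s.rmse == pytest.approx(2.6458, abs=1e-4)

    def test_zero_error_case(self):
        s = error_summary(PairedSeries([120.0, 130.0], [120.0, 130.0]))
        assert s.me == s.mad == s.sse == s.sd == s.rmse == 0.0
        assert s.cv is None

    def test_symmetric_errors(self):
        s = error_summary(PairedSeries([123.0, 117.0], [120.0, 120.0]))
        assert s.me == 0.0 and s.cv is None
        assert s.mad == 3.0 and s.sd == 3.0

    def test_internal_consistency(self):
        rng = np.random.default_rng(5)
        s = error_summary(PairedSeries(rng.normal(120, 10, 50),
                                       rng.normal(120, 10, 50)))
        assert s.rmse * math.sqrt(s.n) == pytest.approx(math.sqrt(s.sse), rel=1e-12)
        assert s.sigma * math.sqrt(s.n - 1) == pytest.approx(math.sqrt(s.sse), rel=1e-12)
        assert s.mad >= abs(s.me)

    def test_shift_invariance(self):
        rng = np.random.default_rng(8)
        est = rng.normal(120, 10, 30)
        cuf = rng.normal(120, 10, 30)
        a = error_summary(PairedSeries(est, cuf))
        b = error_summary(PairedSeries(est + 37.0, cuf + 37.0))
        for fld in ("me", "mad", "sse", "sigma", "sd", "rmse"):
            assert getattr(a, fld) == pytest.approx(getattr(b, fld), rel=1e-9)

    @settings(deadline=None, max_examples=500, derandomize=True)
    @given(st.lists(st.tuples(st.floats(60, 200), st.floats(60, 200)),
                    min_size=2, max_size=40))
    def test_oracle_equivalence(self, pairs):
        est, cuf = zip(*pairs)
        s = error_summary(PairedSeries(list(est), list(cuf)))
        me, mad, sse, sigma, cv, sd, rmse = _naive_summary(est, cuf)
        scale = max(1.0, abs(sse))
        assert abs(s.me - me) < 1e-12 * max(1, abs(me))
        assert abs(s.mad - mad) < 1e-12 * max(1, mad)
        assert abs(s.sse - sse) < 1e-9 * scale
        assert abs(s.sigma - sigma) < 1e-12 * max(1, sigma)
        assert abs(s.sd - sd) < 1e-12 * max(1, sd)
        assert abs(s.rmse - rmse) < 1e-12 * max(1, rmse)
        if cv is None:
            assert s.cv is None
        else:
            assert abs(s.cv - cv) < 1e-9 * max(1, abs(cv))

    def test_single_pair_rejected(self):
        with pytest.raises(ValueError):
            error_summary(PairedSeries([120.0], [121.0]))


class TestPearson:
    def test_perfect_positive(self):
        x = np.array([110.0, 120.0, 130.0, 140.0])
        assert pearson_correlation(PairedSeries(x, x)) == pytest.approx(1.0)

    def test_perfect_negative(self):
        x = np.array([110.0, 120.0, 130.0])
        assert pearson_correlation(PairedSeries(x, -x + 250.0)) == pytest.approx(-1.0)

    def test_three_point_value(self):
        r = pearson_correlation(PairedSeries([1.0, 2.0, 3.0], [1.0, 2.0, 4.0]))
        assert r == pytest.approx(0.9820, abs=1e-4)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            pearson_correlation(PairedSeries([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]))


class TestAAMI:
    @pytest.mark.parametrize("me,sd,expected", [
        (-0.01, 5.90, True),   # the best-performing nonlinear model's figures
        (-5.89, 12.74, False),  # the linear model's figures: fails both
        (5.0, 8.0, True),       # boundary inclusive
        (5.01, 8.0, False),
        (0.0, 8.01, False),
    ])
    def test_verdicts(self, me, sd, expected):
        class S:
            pass
        s = S(); s.me = me; s.sd = sd
        assert aami_verdict(s).passed is expected

    def test_fail_reasons_split(self):
        class S:
            pass
        s = S(); s.me = -5.89; s.sd = 12.74
        v = aami_verdict(s)
        assert not v.mean_ok and not v.sd_ok


class TestKruskalWallis:
    def test_three_group_hand_example(self):
        h, df, p = kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert h == pytest.approx(7.2, abs=1e-12)
        assert df == 2
        assert p == pytest.approx(0.02732, abs=1e-5)

    def test_identical_groups_null(self):
        h, _, p = kruskal_wallis([[1, 2, 3], [1, 2, 3]])
        assert h == pytest.approx(0.0, abs=1e-12)

    def test_all_constant(self):
        h, _, p = kruskal_wallis([[5, 5], [5, 5]])
        assert h == 0.0 and p == 1.0

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.lists(st.lists(st.floats(-50, 50), min_size=3, max_size=15),
                    min_size=2, max_size=5))
    def test_matches_scipy_reference(self, groups):
        try:
            with np.errstate(invalid="ignore"):
                expected = stats.kruskal(*groups)
        except ValueError:
            return  # scipy rejects all-identical data; our H=0,p=1 covers it
        if not np.isfinite(expected.statistic):
            return  # all-identical data: scipy yields nan, we define H=0,p=1
        h, _, p = kruskal_wallis(groups)
        assert h == pytest.approx(expected.statistic, abs=1e-10)
        assert p == pytest.approx(expected.pvalue, abs=1e-10)


class TestDunn:
    def test_hand_example_pair_one_vs_three(self):
        table = dunn_posthoc([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        z = table.attrs["z"].iloc[0, 2]
        assert abs(z) == pytest.approx(2.6833, abs=1e-4)
        assert table.iloc[0, 2] == pytest.approx(0.0219, abs=1e-4)
        uncorrected = dunn_posthoc([[1, 2, 3], [4, 5, 6], [7, 8, 9]],
                                   correction="none")
        assert uncorrected.iloc[0, 2] == pytest.approx(0.00729, abs=1e-5)

    def test_identical_groups_all_one(self):
        table = dunn_posthoc([[1, 2, 3], [1, 2, 3], [1, 2, 3]])
        assert np.allclose(table.to_numpy()[~np.eye(3, dtype=bool)], 1.0)

    def test_correction_monotone(self):
        rng = np.random.default_rng(2)
        groups = [rng.normal(i, 1, 8).tolist() for i in range(4)]
        none = dunn_posthoc(groups, correction="none").to_numpy()
        bonf = dunn_posthoc(groups, correction="bonferroni").to_numpy()
        holm = dunn_posthoc(groups, correction="holm").to_numpy()
        assert np.all(bonf >= none - 1e-15)
        assert np.all(holm >= none - 1e-15)
        assert np.all(bonf >= holm - 1e-15)


class TestGammaSweep:
    def _subject_inputs(self, gamma_true=0.031):
        prof = SubjectProfile("S", 124.0, 81.0, 0.255, gamma=gamma_true,
                              pat_jitter_sd=0.0, pat_slow_sd=0.0)
        gen = generating_params(prof)
        pairs = [CalibPair(0.255, 124.0, 81.0, t_start=i * 30.0) for i in range(16)]
        plan = CalibrationPlan.from_pairs(pairs, "dMK-BH", gamma=gamma_true)
        pat = np.linspace(0.22, 0.25, 30)
        est = estimate_bp(gen, pat)
        return (plan, pat, np.asarray(est.sbp_est), np.asarray(est.dbp_est))

    def test_noiseless_argmin_at_true_gamma(self):
        res = gamma_sensitivity_sweep([self._subject_inputs()],
                                      grid=default_gamma_grid())
        assert res.argmin_sbp == pytest.approx(0.031)
        assert res.argmin_dbp == pytest.approx(0.031)
        assert np.nanmin(res.mad_sbp) < 1e-6
        assert np.nanmin(res.mad_dbp) < 1e-6

    def test_single_point_grid(self):
        res = gamma_sensitivity_sweep([self._subject_inputs()],
                                      grid=np.array([0.02]))
        assert res.argmin_sbp == 0.02 and res.argmin_dbp == 0.02

    def test_deterministic_curve(self):
        grid = np.array([0.01, 0.02, 0.031, 0.04])
        a = gamma_sensitivity_sweep([self._subject_inputs()], grid=grid)
        b = gamma_sensitivity_sweep([self._subject_inputs()], grid=grid)
        assert np.array_equal(a.mad_sbp, b.mad_sbp)

    def test_wrong_model_rejected(self):
        plan, pat, s, d = self._subject_inputs()
        bad = CalibrationPlan(rounds=plan.rounds, model="L-MK")
        with pytest.raises(ValueError, match="dMK-BH"):
            gamma_sensitivity_sweep([(bad, pat, s, d)], grid=np.array([0.02]))

    def test_out_of_range_grid_rejected(self):
        with pytest.raises(ValueError):
            gamma_sensitivity_sweep([self._subject_inputs()],
                                    grid=np.array([0.2]))
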