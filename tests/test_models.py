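"""Forward evaluation and exact calibration of the five BP-PAT models."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from patbp.models import (
    MODEL_IDS,
    BaselineState,
    DegenerateCalibrationError,
    ModelParams,
    NoRealSolutionError,
    calibrate_from_points,
    estimate_bp,
    required_calibration_points,
)


@pytest.mark.parametrize("model,expected", [
    ("MK-EE", 2), ("L-MK", 2), ("MK-BH", 1), ("dMK-BH", 1), ("M-M", 3),
])
def test_required_calibration_points(model, expected):
    assert required_calibration_points(model) == expected


def test_unknown_model_rejected():
    with pytest.raises(ValueError, match="unknown model"):
        required_calibration_points("PTT-XYZ")


class TestForwardEvaluation:
    def test_baseline_anchor_identity(self, baseline_params):
        """MK-BH and dMK-BH collapse to (SBP0, DBP0) at PAT = PAT0."""
        for model in ("MK-BH", "dMK-BH"):
            params = ModelParams(model, baseline=baseline_params.baseline)
            est = estimate_bp(params, 0.25)
            assert est.sbp_est == pytest.approx(120.0, abs=1e-12)
            assert est.dbp_est == pytest.approx(80.0, abs=1e-12)

    def test_dmk_bh_at_shorter_pat(self, baseline_params):
        """Hand-computed dMK-BH value at PAT 0.20 s from the 120/80 anchor."""
        est = estimate_bp(baseline_params, 0.20)
        assert est.sbp_est == pytest.approx(149.3964, abs=1e-4)
        assert est.dbp_est == pytest.approx(86.8964, abs=1e-4)

    def test_mk_bh_at_shorter_pat(self, baseline_params):
        params = ModelParams("MK-BH", baseline=baseline_params.baseline)
        est = estimate_bp(params, 0.20)
        assert est.sbp_est == pytest.approx(132.9032, abs=1e-4)
        assert est.dbp_est == pytest.approx(70.4032, abs=1e-4)

    def test_mm_closed_form(self):
        params = ModelParams("M-M", (60.0, 2000.0, 100.0), (60.0, 2000.0, 100.0))
        est = estimate_bp(params, 0.25)
        # 60 + sqrt(2000 + 100/0.0625) = 60 + sqrt(3600) = 120 exactly
        assert est.sbp_est == pytest.approx(120.0, abs=1e-12)

    def test_mm_negative_radicand_raises(self):
        params = ModelParams("M-M", (60.0, -2000.0, 100.0), (60.0, -2000.0, 100.0))
        with pytest.raises(NoRealSolutionError):
            estimate_bp(params, 1.0)

    def test_dmk_bh_pulse_pressure_identity(self, baseline_params):
        """SBP - DBP == PP0 * (PAT0/PAT)^2 on a dense PAT grid."""
        pat = np.linspace(0.15, 0.40, 1000)
        est = estimate_bp(baseline_params, pat)
        pp = np.asarray(est.sbp_est) - np.asarray(est.dbp_est)
        assert np.max(np.abs(pp - 40.0 * (0.25 / pat) ** 2)) < 1e-10

    def test_mm_monotone_and_bounded(self):
        """With c > 0 the M-M SBP curve falls with PAT toward a + sqrt(b)."""
        params = ModelParams("M-M", (60.0, 2000.0, 100.0), (20.0, 2000.0, 100.0))
        pat = np.linspace(0.1, 5.0, 500)
        sbp = np.asarray(estimate_bp(params, pat).sbp_est)
        assert np.all(np.diff(sbp) < 0)
        assert np.all(sbp > 60.0 + math.sqrt(2000.0))

    def test_unit_invariance_of_anchored_models(self, baseline_params):
        """Jointly rescaling PAT and PAT0 leaves MK-BH/dMK-BH SBP... changed
        only through the explicit 2/(gamma*PAT0) term for MK-BH; dMK-BH
        depends on PAT only through PAT0/PAT so it is fully invariant."""
        scale = 1000.0  # seconds -> milliseconds
        b = baseline_params.baseline
        scaled = ModelParams("dMK-BH", baseline=BaselineState(
            sbp0=b.sbp0, dbp0=b.dbp0, pat0=b.pat0 * scale, gamma=b.gamma))
        for pat in (0.18, 0.22, 0.30):
            ref = estimate_bp(baseline_params, pat)
            alt = estimate_bp(scaled, pat * scale)
            assert alt.sbp_est == pytest.approx(ref.sbp_est, rel=1e-12)
            assert alt.dbp_est == pytest.approx(ref.dbp_est, rel=1e-12)

    def test_nonpositive_pat_rejected(self, baseline_params):
        with pytest.raises(ValueError):
            estimate_bp(baseline_params, 0.0)


class TestCalibration:
    def test_mk_ee_two_point_closed_form(self):
        params = calibrate_from_points(
            "MK-EE", [(0.25, 120.0, 80.0), (0.20, 135.0, 88.0)])
        a, b = params.sbp_coeffs
        assert a == pytest.approx(-67.2213, abs=1e-4)
        assert b == pytest.approx(26.8115, abs=1e-4)

    def test_l_mk_line_through_points(self):
        params = calibrate_from_points(
            "L-MK", [(0.25, 120.0, 80.0), (0.20, 135.0, 88.0)])
        a, b = params.sbp_coeffs
        assert a == pytest.approx(195.0, abs=1e-9)
        assert b == pytest.approx(-300.0, abs=1e-9)

    def test_dmk_bh_baseline_identities(self):
        params = calibrate_from_points("dMK-BH", [(0.25, 120.0, 80.0)],
                                       gamma=0.031)
        b = params.baseline
        assert b.pp0 == pytest.approx(40.0)
        assert b.mbp0 == pytest.approx(93.3333, abs=1e-4)

    def test_mm_recovers_generating_coefficients(self):
        truth = (60.0, 2000.0, 100.0)
        pairs = [(pat, truth[0] + math.sqrt(truth[1] + truth[2] / pat**2),
                  20.0 + math.sqrt(1500.0 + 80.0 / pat**2))
                 for pat in (0.20, 0.25, 0.30)]
        params = calibrate_from_points("M-M", pairs)
        assert np.allclose(params.sbp_coeffs, truth, rtol=1e-6)
        assert np.allclose(params.dbp_coeffs, (20.0, 1500.0, 80.0), rtol=1e-6)

    def test_duplicate_pats_degenerate(self):
        with pytest.raises(DegenerateCalibrationError):
            calibrate_from_points("MK-EE", [(0.25, 120, 80), (0.25, 130, 85)])

    def test_mm_spurious_branch_rejected(self):
        # points consistent only with BP = a - sqrt(...): below-anchor data
        pairs = [(pat, 200.0 - math.sqrt(1500.0 + 80.0 / pat**2),
                  190.0 - math.sqrt(1500.0 + 80.0 / pat**2) - 30.0)
                 for pat in (0.20, 0.25, 0.30)]
        with pytest.raises(NoRealSolutionError):
            calibrate_from_points("M-M", pairs)

    def test_wrong_pair_count_rejected(self):
        with pytest.raises(ValueError, match="exactly"):
            calibrate_from_points("M-M", [(0.25, 120, 80)])


@settings(deadline=None, max_examples=200, derandomize=True)
@given(
    model=st.sampled_from(MODEL_IDS),
    pats=st.lists(st.floats(0.12, 0.45), min_size=3, max_size=3, unique=True),
    sbps=st.lists(st.floats(95.0, 180.0), min_size=3, max_size=3),
    dbp_gap=st.lists(st.floats(20.0, 60.0), min_size=3, max_size=3),
)
def test_calibration_round_trip_property(model, pats, sbps, dbp_gap):
    """estimate_bp(calibrate_from_points(...)) reproduces every calibration
    point to <=1e-9 relative error, for every model."""
    k = required_calibration_points(model)
    pats = sorted(pats)[:k]
    if min(np.diff(pats), default=1.0) < 1e-3:
        return  # nearly-duplicate PATs are legitimately degenerate
    pairs = [(p, s, s - g) for p, s, g in zip(pats, sbps, dbp_gap)]
    try:
        params = calibrate_from_points(model, pairs)
    except NoRealSolutionError:
        return  # M-M legitimately has no real solution for some point sets
    except DegenerateCalibrationError:
        return  # near-singular point geometry
    for pat, sbp, dbp in pairs:
        est = estimate_bp(params, pat)
        assert est.sbp_est == pytest.approx(sbp, rel=1e-9, abs=1e-9)
        assert est.dbp_est == pytest.approx(dbp, rel=1e-9, abs=1e-9)


def test_params_json_round_trip(baseline_params):
    text = baseline_params.to_json()
    assert ModelParams.from_json(text) == baseline_params
    mm = ModelParams("M-M", (60.0, 2000.0, 100.0), (20.0, 1500.0, 80.0))
    assert ModelParams.from_json(mm.to_json()) == mm
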