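import math

import numpy as np
import pytest

from membrox.dose import (
    LN2,
    calibrate_to_molarity,
    competition_slopes,
    estimate_asymptotes,
    fit_inhibition,
    inhibition_ordinate,
)
from membrox.svd import OmegaScores, ScoreMode
from membrox.workflows import analyze_titration
from membrox.synth import InhibitionTruth, TbarsModel, gen_tbars_titration


def scores_of(omega, conditions):
    return OmegaScores(np.asarray(omega, float), ScoreMode.optical, conditions)


class TestOrdinate:
    def test_known_values_and_censoring(self):
        res = inhibition_ordinate([10.0, 5.5, 0.9], omega0=10.0, omega_inf=1.0)
        assert res.values[0] == pytest.approx(0.0)           # omega = omega0
        assert res.values[1] == pytest.approx(LN2)           # half range
        assert res.censored[2] and np.isnan(res.values[2])   # below omega_inf
        assert not res.censored[:2].any()

    def test_equal_asymptotes_rejected(self):
        with pytest.raises(ValueError):
            inhibition_ordinate([1.0], 2.0, 2.0)


class TestFit:
    def test_through_origin_ic50_is_ln2_over_slope(self):
        concs = np.array([0.1, 0.2, 0.3, 0.4])
        fit = fit_inhibition(concs, 2.0 * concs, through_origin=True, unit="mM")
        assert fit.ic50 == pytest.approx(LN2 / 2.0)
        assert fit.r2 == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "ic50_uM,expected_pI50", [(5.01, 5.30), (10.0, 5.0)]
    )
    def test_pI50_conversion_to_molar_scale(self, ic50_uM, expected_pI50):
        concs = np.array([2.0, 4.0, 6.0, 8.0])
        slope = LN2 / ic50_uM
        fit = fit_inhibition(concs, slope * concs, unit="uM")
        assert fit.pI50 == pytest.approx(expected_pI50, abs=0.005)

    def test_unit_change_moves_ic50_but_not_pI50(self):
        concs_mM = np.array([0.1, 0.2, 0.3, 0.4])
        y = 3.0 * concs_mM
        fit_mM = fit_inhibition(concs_mM, y, unit="mM")
        fit_uM = fit_inhibition(concs_mM * 1e3, y, unit="uM")
        assert fit_uM.ic50 == pytest.approx(fit_mM.ic50 * 1e3)
        assert fit_uM.pI50 == pytest.approx(fit_mM.pI50, abs=1e-12)

    def test_non_positive_slope_leaves_potency_undefined(self):
        concs = np.array([1.0, 2.0, 3.0, 4.0])
        fit = fit_inhibition(concs, -0.5 * concs)
        assert not fit.defined and math.isnan(fit.pI50)

    def test_censored_points_are_dropped_not_clipped(self):
        concs = np.array([1.0, 2.0, 3.0, 4.0])
        ordinate = inhibition_ordinate([9.0, 8.0, 7.0, 0.5], omega0=10.0, omega_inf=1.0)
        fit = fit_inhibition(concs, ordinate)
        assert fit.n_censored == 1
        assert fit.concentrations.size == 3

    def test_upward_convex_curve_warns_but_still_fits(self):
        concs = np.linspace(0.5, 4.0, 8)
        with pytest.warns(UserWarning, match="upward-convex"):
            fit = fit_inhibition(concs, np.sqrt(concs))
        assert fit.curvature_warning and fit.defined

    def test_crossing_rule_accounts_for_intercept(self):
        concs = np.array([1.0, 2.0, 3.0, 4.0])
        y = 0.2 * concs + 0.1
        fit = fit_inhibition(concs, y, ic50_from="crossing")
        assert fit.ic50 == pytest.approx((LN2 - 0.1) / 0.2)


class TestAsymptotes:
    def test_single_and_duplicated_zero_columns(self):
        conds = [
            {"IMP_mM": 0.0, "TRO_uM": 0.0, "role": "zero"},
            {"IMP_mM": 0.0, "TRO_uM": 0.0, "role": "zero"},
            {"IMP_mM": 0.2, "TRO_uM": 0.0, "role": "sample"},
            {"role": "full"},
        ]
        w0, winf = estimate_asymptotes(scores_of([10.0, 12.0, 6.0, 1.0], conds))
        assert w0 == pytest.approx(11.0)
        assert winf == pytest.approx(1.0)

    def test_missing_designation_is_an_error(self):
        with pytest.raises(ValueError, match="designated"):
            estimate_asymptotes(scores_of([1.0], [{"IMP_mM": 0.2}]))


class TestCalibration:
    def test_exact_point_and_linearity(self):
        scores = np.array([1.0, 2.0, 4.0])
        concs = np.array([5.0, 10.0, 20.0])
        out = calibrate_to_molarity(scores, concs, [2.0])
        assert out[0] == pytest.approx(10.0)
        halved = calibrate_to_molarity(2 * scores, concs, [4.0])
        assert halved[0] == pytest.approx(10.0)

    def test_degenerate_calibration_rejected_and_extrapolation_warned(self):
        with pytest.raises(ValueError, match="degenerate"):
            calibrate_to_molarity([1.0, 1.0], [0.0, 5.0], [1.0])
        with pytest.warns(UserWarning, match="extrapolat"):
            calibrate_to_molarity([1.0, 2.0], [5.0, 10.0], [8.0])

    def test_noiseless_standard_series_recovered_within_one_percent(self):
        model = TbarsModel(noise_sd=0.0, coupling_jitter=0.0, seed=2)
        mat = gen_tbars_titration(
            InhibitionTruth(), [0.0, 0.1, 0.2], [0.0], model,
            calib_concs=[0.0, 5.0, 10.0, 20.0],
        )
        from membrox.svd import decompose, omega_scores

        sc = omega_scores(decompose(mat), "optical")
        calib = [(j, c["MDA_uM"]) for j, c in enumerate(sc.conditions) if c.get("role") == "calib"]
        idx, truth = zip(*calib)
        est = calibrate_to_molarity(sc.omega[list(idx)], np.array(truth), sc.omega[list(idx)])
        np.testing.assert_allclose(est, truth, atol=0.01 * max(truth) + 1e-9)


class TestCompetition:
    def make_fit(self, pI50):
        concs = np.array([1.0, 2.0, 3.0])
        ic50 = 10 ** (-pI50) * 1e3  # mM
        return fit_inhibition(concs * ic50, LN2 * concs, unit="mM")

    def test_constant_pI50_gives_zero_slope(self):
        groups = {t: self.make_fit(3.7) for t in (0.0, 10.0, 20.0)}
        res = competition_slopes(groups)
        assert res.slope == pytest.approx(0.0, abs=1e-9)
        assert res.intercept == pytest.approx(3.7, abs=1e-9)

    def test_reversed_modifier_axis_negates_slope(self):
        groups = {t: self.make_fit(3.7 - 0.048 * t) for t in (0.0, 10.0, 20.0)}
        fwd = competition_slopes(groups)
        rev = competition_slopes({-t: f for t, f in groups.items()})
        assert fwd.slope == pytest.approx(-0.048, abs=1e-6)
        assert rev.slope == pytest.approx(+0.048, abs=1e-6)

    def test_requires_three_defined_levels(self):
        groups = {0.0: self.make_fit(3.7), 10.0: self.make_fit(3.5)}
        with pytest.raises(ValueError, match=">= 3"):
            competition_slopes(groups)


class TestPipelineRecovery:
    """Generator/analyzer round trips on noiseless synthetic titrations."""

    @pytest.mark.parametrize("pI50_true", [2.5, 3.7, 5.3])
    def test_pI50_recovered_within_005(self, pI50_true):
        ic50_mM = 10 ** (-pI50_true) * 1e3
        concs = ic50_mM * np.array([0.0, 0.4, 0.8, 1.2, 1.6, 2.0])
        truth = InhibitionTruth(pI50_drug=pI50_true)
        model = TbarsModel(noise_sd=0.0, coupling_jitter=0.0, seed=1)
        mat = gen_tbars_titration(truth, concs, [0.0], model)
        analysis = analyze_titration(mat)
        assert abs(analysis.pI50_at_zero_modifier - pI50_true) < 0.05

    def test_asymptotes_recovered_from_synthetic_titration(self, noiseless_titration):
        analysis = analyze_titration(noiseless_titration)
        # scores scale with the generated amplitudes; the full-inhibition
        # column sits at the omega_inf amplitude (0 here), the zero column at
        # omega0; check their ratio rather than the arbitrary scale
        assert analysis.omega_inf == pytest.approx(0.0, abs=1e-9 * abs(analysis.omega0))
        assert analysis.omega0 > 0

    def test_noiseless_cross_slope_recovered_within_ten_percent(self):
        truth = InhibitionTruth(pI50_drug=3.7, cross_slope_drug_per_tro=-48e-3)
        model = TbarsModel(noise_sd=0.0, coupling_jitter=0.0, seed=1)
        mat = gen_tbars_titration(
            truth, [0.0, 0.08, 0.16, 0.24, 0.32, 0.40],
            [0.0, 5.0, 10.0, 15.0, 20.0, 25.0], model,
        )
        analysis = analyze_titration(mat)
        assert analysis.competition is not None
        assert analysis.competition.slope == pytest.approx(-48e-3, rel=0.10)

    def test_cross_slope_sign_recovered_at_realistic_noise(self):
        negatives = 0
        for seed in range(20):
            model = TbarsModel(noise_sd=0.01, seed=seed)
            mat = gen_tbars_titration(
                InhibitionTruth(), [0.0, 0.08, 0.16, 0.24, 0.32, 0.40],
                [0.0, 5.0, 10.0, 15.0, 20.0, 25.0], model,
            )
            analysis = analyze_titration(mat)
            if analysis.competition and analysis.competition.slope < 0:
                negatives += 1
        assert negatives >= 19  # >= 95 % of 20 seeds
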