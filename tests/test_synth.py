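import numpy as np
import pytest
from scipy.signal import find_peaks

from membrox.dose import LN2
from membrox.io import AxisKind
from membrox.synth import (
    EprModel,
    InhibitionTruth,
    TbarsModel,
    gen_epr_decay_series,
    gen_epr_spectrum,
    gen_polarized_pair,
    gen_tbars_spectrum,
    gen_tbars_titration,
    gen_thermogram,
)


class TestTbars:
    def test_zero_concentration_noiseless_is_zero(self, noiseless_model):
        spec = gen_tbars_spectrum(noiseless_model, 0.0)
        assert np.all(spec.intensity == 0)

    def test_530_amplitude_proportional_to_concentration(self, noiseless_model):
        i530 = int(np.argmin(np.abs(noiseless_model.wavelengths() - 530)))
        a = gen_tbars_spectrum(noiseless_model, 5.0).intensity[i530]
        b = gen_tbars_spectrum(noiseless_model, 10.0).intensity[i530]
        assert b == pytest.approx(2 * a, rel=1e-12)

    def test_negative_concentration_rejected(self, noiseless_model):
        with pytest.raises(ValueError):
            gen_tbars_spectrum(noiseless_model, -1.0)

    def test_standard_shape_has_495_shoulder_lipid_has_455(self, noiseless_model):
        wl = noiseless_model.wavelengths()
        std = gen_tbars_spectrum(noiseless_model, 10.0, is_lipid=False).intensity
        lip = gen_tbars_spectrum(noiseless_model, 10.0, is_lipid=True).intensity
        i455 = int(np.argmin(np.abs(wl - 455)))
        assert lip[i455] > std[i455]
        # shoulder: standard exceeds a pure 530 nm Gaussian near 495 nm
        pure = noiseless_model.response * 10.0 * np.exp(-0.5 * ((wl - 530) / 22) ** 2)
        i495 = int(np.argmin(np.abs(wl - 495)))
        assert std[i495] > pure[i495]

    def test_standard_series_calibration_line_through_origin(self):
        model = TbarsModel(noise_sd=0.001, seed=5)
        concs = np.array([2.0, 5.0, 10.0, 15.0, 20.0])
        i530 = int(np.argmin(np.abs(model.wavelengths() - 530)))
        absorbance = np.array(
            [gen_tbars_spectrum(model, c, is_lipid=False).intensity[i530] for c in concs]
        )
        r = np.corrcoef(concs, absorbance)[0, 1]
        assert r**2 > 0.999

    def test_generators_deterministic_given_seed(self):
        model = TbarsModel(noise_sd=0.01, seed=9)
        a = gen_tbars_spectrum(model, 7.0)
        b = gen_tbars_spectrum(model, 7.0)
        np.testing.assert_array_equal(a.intensity, b.intensity)


class TestTitration:
    def test_empty_grids_rejected(self, noiseless_model):
        with pytest.raises(ValueError):
            gen_tbars_titration(InhibitionTruth(), [], [0.0], noiseless_model)

    def test_all_zero_concentrations_give_equal_columns(self, noiseless_model):
        mat = gen_tbars_titration(
            InhibitionTruth(), [0.0], [0.0, 0.0, 0.0], noiseless_model, calib_concs=None
        )
        samples = mat.select(lambda c: c.get("role") in ("sample", "zero"))
        for j in range(1, samples.n):
            np.testing.assert_allclose(samples.intensities[:, j], samples.intensities[:, 0])

    def test_truth_ordinate_is_additive_and_ln2_at_ic50(self):
        truth = InhibitionTruth(pI50_drug=3.7, pI50_tro=4.9, cross_slope_drug_per_tro=0.0)
        ic50_mM = 10**-3.7 * 1e3
        assert truth.ordinate(ic50_mM, 0.0) == pytest.approx(LN2)
        both = truth.ordinate(ic50_mM, 10.0)
        assert both == pytest.approx(truth.ordinate(ic50_mM, 0.0) + truth.ordinate(0.0, 10.0))

    def test_roles_and_truth_metadata_present(self, noiseless_titration):
        roles = {c.get("role") for c in noiseless_titration.conditions}
        assert {"zero", "sample", "full", "calib"} <= roles
        assert noiseless_titration.meta["truth_pI50_drug"] == 3.7


class TestEpr:
    def test_zero_radical_fraction_is_zero_spectrum(self, dpph_model):
        assert not np.any(gen_epr_spectrum(dpph_model, 0.0).intensity)

    def test_noiseless_spectrum_antisymmetric_about_center(self, dpph_model):
        spec = gen_epr_spectrum(dpph_model, 1.0)
        c = dpph_model.center_offset
        x = np.linspace(0.0, 10.0, 301)
        right = np.interp(c + x, spec.abscissa, spec.intensity)
        left = np.interp(c - x, spec.abscissa, spec.intensity)
        np.testing.assert_allclose(right, -left, atol=1e-10)

    @pytest.mark.parametrize("maker,n_lines", [(EprModel.dpph, 5), (EprModel.glv, 2)])
    def test_integrated_curve_has_expected_equidistant_peaks(self, maker, n_lines):
        model = maker()
        spec = gen_epr_spectrum(model, 1.0)
        absorption = np.cumsum(spec.intensity) * model.step
        idx, _ = find_peaks(absorption, prominence=0.05 * absorption.max())
        assert idx.size == n_lines
        spacing = np.diff(spec.abscissa[idx])
        np.testing.assert_allclose(spacing, model.splitting, atol=0.05)

    def test_decay_series_shares_grid_and_orders_columns(self):
        series = gen_epr_decay_series(EprModel.dpph(), [1.0, 0.5, 0.25])
        assert series.axis_kind == AxisKind.field_offset
        assert [c["radical_frac"] for c in series.conditions] == [1.0, 0.5, 0.25]


class TestPolarizedPair:
    def test_r_zero_means_auc_vv_equals_g_times_auc_vh(self):
        vv, vh = gen_polarized_pair(0.0, total=1000.0, G=7.31)
        auc_vv = np.trapezoid(vv.intensity, vv.abscissa)
        auc_vh = np.trapezoid(vh.intensity, vh.abscissa)
        assert auc_vv == pytest.approx(7.31 * auc_vh, rel=1e-6)

    def test_total_scaling_leaves_r_invariant(self):
        for total in (100.0, 1e5):
            vv, vh = gen_polarized_pair(0.25, total=total, G=7.31)
            auc_vv = np.trapezoid(vv.intensity, vv.abscissa)
            auc_vh = np.trapezoid(vh.intensity, vh.abscissa)
            R = (auc_vv - 7.31 * auc_vh) / (auc_vv + 2 * 7.31 * auc_vh)
            assert R == pytest.approx(0.25, abs=1e-6)

    def test_unphysical_r_rejected(self):
        with pytest.raises(ValueError):
            gen_polarized_pair(0.5)
        with pytest.raises(ValueError):
            gen_polarized_pair(-0.3)


class TestThermogram:
    def test_zero_enthalpy_is_pure_baseline(self):
        tg = gen_thermogram(380.0, 0.0, baseline=(0.2, 0.001), width=2.0)
        fit = np.polyfit(tg.temperature, tg.heat_flow, 1)
        resid = tg.heat_flow - np.polyval(fit, tg.temperature)
        assert np.max(np.abs(resid)) < 1e-9

    def test_doubling_dh_doubles_peak_area(self):
        def area(dH):
            tg = gen_thermogram(380.0, dH, baseline=(0.0, 0.0), width=2.0)
            return np.trapezoid(tg.heat_flow, tg.temperature)

        assert area(20000.0) == pytest.approx(2 * area(10000.0), rel=1e-9)

    def test_truth_metadata_records_onset(self):
        tg = gen_thermogram(380.0, 17000.0, width=2.0)
        assert tg.meta["true_onset_K"] == pytest.approx(376.0)
        assert tg.meta["true_dH_J_mol"] == 17000.0
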