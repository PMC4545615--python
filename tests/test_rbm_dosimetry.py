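"""RBM dose methods, Lea-Catcheside G-factor, and BED."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

import voxdose as vd
from voxdose.datamodel_io import ValidationError
from voxdose.kinetics import HybridFit, fit_hybrid, integrate_voi
from voxdose.rbm_dosimetry import (bed, lea_catcheside_G, rbm_dose_blood,
                                   rbm_dose_cranium, rbm_dose_lv3d, RbmDoseReport)

LAMBDA_LU = math.log(2) / 161.04
MU = 0.46


class TestGFactor:
    @pytest.mark.parametrize("lam", [LAMBDA_LU, 0.01, 0.05, 0.2, 1.0])
    @pytest.mark.parametrize("mu", [0.1, MU, 2.0])
    def test_monoexponential_closed_form(self, lam, mu):
        """G = lambda / (lambda + mu) for a mono-exponential dose rate."""
        fit = HybridFit.exponential(1.0, lam)
        assert lea_catcheside_G(fit, mu) == pytest.approx(lam / (lam + mu), abs=1e-4)

    def test_instantaneous_limit_is_one(self):
        fit = HybridFit.exponential(1.0, 1e6)     # essentially a delta pulse
        assert lea_catcheside_G(fit, MU) == pytest.approx(1.0, abs=1e-5)

    def test_infinite_repair_rate_limit_is_zero(self):
        fit = HybridFit.exponential(1.0, LAMBDA_LU)
        assert lea_catcheside_G(fit, 1e6) < 1e-5

    def test_hybrid_fit_against_double_quadrature_oracle(self):
        """Brute-force nested quadrature of the defining double integral."""
        fit = fit_hybrid([0.5, 3, 24, 72], [1.0, 0.8, 0.4, 0.2], LAMBDA_LU)
        mu = MU
        ad = fit.integral

        def inner(t):
            pts = [p for p in (0.5, 3.0, 24.0) if p < t]
            val, _ = quad(lambda u: float(fit(np.array(u))) * math.exp(-mu * (t - u)),
                          0.0, t, points=pts or None, limit=400,
                          epsabs=1e-12, epsrel=1e-10)
            return val

        body, _ = quad(lambda t: float(fit(np.array(t))) * inner(t), 0.0, 500.0,
                       points=[0.5, 3.0, 24.0, 72.0, 200.0], limit=500,
                       epsabs=1e-13, epsrel=1e-9)
        oracle = 2.0 * body / ad ** 2
        assert lea_catcheside_G(fit, mu) == pytest.approx(oracle, rel=1e-5)

    def test_zero_dose_is_an_error(self):
        fit = fit_hybrid([0.5, 3, 24, 72], [0, 0, 0, 0], LAMBDA_LU)
        with pytest.raises(ValidationError):
            lea_catcheside_G(fit, MU)


class TestBed:
    def test_zero_dose(self):
        assert bed(0.0, 1.0, 10.0) == 0.0

    def test_direct_evaluation(self):
        assert bed(0.46, 1.0, 10.0) == pytest.approx(0.481160, rel=1e-6)

    def test_protracted_delivery_excess_is_tiny(self):
        """At the repair and decay rates of this protocol the BED exceeds the
        absorbed dose by well under a percent."""
        g = lea_catcheside_G(HybridFit.exponential(1.0, LAMBDA_LU), MU)
        b = bed(0.46, g, 10.0)
        assert 0.46 < b < 0.46 * 1.0011
        assert (b / 0.46 - 1) == pytest.approx(g * 0.46 / 10.0, rel=1e-9)

    @given(ad=st.floats(0, 50), g=st.floats(0, 1))
    @settings(max_examples=100, deadline=None)
    def test_bed_never_below_ad(self, ad, g):
        assert bed(ad, g, 10.0) >= ad

    def test_report_rejects_bed_below_ad(self):
        with pytest.raises(ValidationError):
            RbmDoseReport(method="lv_3d", ad_Gy=1.0, bed_Gy=0.9)


def _uniform_series(values, shape=(6, 6, 6), times=(0.5, 3.0, 24.0, 72.0)):
    grid = vd.VoxelGrid(shape=shape)
    vols = [vd.ScalarVolume(grid, np.full(shape, v), "doserate_Gy_h") for v in values]
    return vd.TimeSeriesVolumes(times_h=times, volumes=vols)


class TestLv3d:
    def test_identical_masks_match_integrate_voi(self, config):
        series = _uniform_series((1.0, 0.8, 0.4, 0.2))
        mask = vd.VoiMask(grid=series.grid, mask=np.ones(series.grid.shape, bool))
        rep = rbm_dose_lv3d(series, [mask] * 4, config, LAMBDA_LU)
        assert rep.ad_Gy == pytest.approx(
            integrate_voi(series, mask, LAMBDA_LU), rel=1e-12)
        assert rep.bed_Gy >= rep.ad_Gy

    def test_mask_size_irrelevant_on_uniform_field(self, config):
        series = _uniform_series((1.0, 0.8, 0.4, 0.2))
        small = np.zeros(series.grid.shape, bool); small[1, 1, 1] = True
        masks_small = [vd.VoiMask(grid=series.grid, mask=small)] * 4
        big = np.ones(series.grid.shape, bool)
        masks_big = [vd.VoiMask(grid=series.grid, mask=big)] * 4
        r1 = rbm_dose_lv3d(series, masks_small, config, LAMBDA_LU)
        r2 = rbm_dose_lv3d(series, masks_big, config, LAMBDA_LU)
        assert r1.ad_Gy == pytest.approx(r2.ad_Gy, rel=1e-12)

    def test_per_time_point_masks_are_used(self, config):
        """Shifting the mask at one time point onto a hotter region changes
        the integrated dose."""
        grid = vd.VoxelGrid(shape=(6, 6, 6))
        vols = []
        for v in (1.0, 0.8, 0.4, 0.2):
            arr = np.full(grid.shape, v)
            arr[4:, :, :] = 3 * v
            vols.append(vd.ScalarVolume(grid, arr, "doserate_Gy_h"))
        series = vd.TimeSeriesVolumes(times_h=(0.5, 3, 24, 72), volumes=vols)
        cold = np.zeros(grid.shape, bool); cold[0, 0, 0] = True
        hot = np.zeros(grid.shape, bool); hot[5, 0, 0] = True
        base = rbm_dose_lv3d(series, [vd.VoiMask(grid=grid, mask=cold)] * 4,
                             config, LAMBDA_LU)
        mixed_masks = [vd.VoiMask(grid=grid, mask=hot)] + \
                      [vd.VoiMask(grid=grid, mask=cold)] * 3
        mixed = rbm_dose_lv3d(series, mixed_masks, config, LAMBDA_LU)
        assert mixed.ad_Gy > base.ad_Gy

    def test_wrong_mask_count_is_an_error(self, config):
        series = _uniform_series((1.0, 0.8, 0.4, 0.2))
        mask = vd.VoiMask(grid=series.grid, mask=np.ones(series.grid.shape, bool))
        with pytest.raises(ValidationError, match="one LV mask per time point"):
            rbm_dose_lv3d(series, [mask] * 3, config, LAMBDA_LU)


class TestBlood:
    def test_zero_series_zero_dose(self, config):
        blood = vd.BloodSeries(times_h=(0.1, 1, 24), concentration_MBq_per_mL=(0, 0, 0),
                               whole_body_MBq=(0, 0, 0))
        rep = rbm_dose_blood(blood, config, 5000.0, LAMBDA_LU)
        assert rep.ad_Gy == 0.0

    def test_monoexponential_closed_form(self, config):
        """c0 exp(-le t) at the 7 standard draw times, no whole-body term:
        A_rbm ~ c0 mass / le and dose = A_rbm S_self."""
        le = 0.02
        c0 = 1.0
        times = (2 / 60, 0.5, 1.0, 2.0, 4.0, 24.0, 72.0)
        conc = tuple(c0 * math.exp(-le * t) for t in times)
        blood = vd.BloodSeries(times_h=times, concentration_MBq_per_mL=conc)
        rep = rbm_dose_blood(blood, config, 5000.0, le)
        a_rbm = rep.intermediates["a_rbm_MBq_h"]
        assert a_rbm == pytest.approx(c0 * config.rbm_mass_g / le, rel=0.04)
        assert rep.ad_Gy == pytest.approx(
            a_rbm * config.s_rbm_self_mGy_per_MBq_h / 1000.0, rel=1e-12)

    def test_ratio_scales_self_term_exactly(self, config):
        times = (0.1, 1.0, 24.0)
        blood = vd.BloodSeries(times_h=times,
                               concentration_MBq_per_mL=(1.0, 0.8, 0.1))
        r1 = rbm_dose_blood(blood, config, 5000.0, LAMBDA_LU)
        r2 = rbm_dose_blood(blood, config.replace(rbm_to_blood_ratio=0.5),
                            5000.0, LAMBDA_LU)
        assert r1.ad_Gy == pytest.approx(2.0 * r2.ad_Gy, rel=1e-12)

    def test_remainder_floored_when_marrow_exceeds_whole_body(self, config):
        times = (0.1, 1.0, 24.0)
        blood = vd.BloodSeries(times_h=times,
                               concentration_MBq_per_mL=(1.0, 0.8, 0.1),
                               whole_body_MBq=(1.0, 0.8, 0.1))  # tiny whole body
        rep = rbm_dose_blood(blood, config, 5000.0, LAMBDA_LU)
        assert rep.intermediates["remainder_floored"]
        assert rep.intermediates["a_remainder_MBq_h"] == 0.0

    def test_whole_body_remainder_adds_cross_dose(self, config):
        times = (0.1, 1.0, 24.0)
        conc = (0.01, 0.008, 0.001)
        no_wb = rbm_dose_blood(vd.BloodSeries(times, conc), config, 5000.0, LAMBDA_LU)
        with_wb = rbm_dose_blood(
            vd.BloodSeries(times, conc, whole_body_MBq=(5000.0, 4500.0, 2000.0)),
            config, 5000.0, LAMBDA_LU)
        assert with_wb.ad_Gy > no_wb.ad_Gy


class TestCranium:
    def _planars(self, activity, config, T_cm=20.0, times=(0.5, 3.0, 24.0, 72.0),
                 decay=LAMBDA_LU):
        """Synthetic conjugate-view count images of a midline point source."""
        out = []
        for t in times:
            a = activity * math.exp(-decay * t)
            counts = a * math.exp(-config.attenuation_cm_inv * T_cm / 2) \
                / config.calibration_MBq_per_count
            img = np.zeros((8, 8)); img[4, 4] = counts
            out.append((t, img, img.copy()))
        return out

    def test_zero_counts_reports_zero_with_flag(self, config):
        planars = [(t, np.zeros((4, 4)), np.zeros((4, 4))) for t in (1.0, 24.0)]
        rep = rbm_dose_cranium(planars, np.ones((4, 4), bool), 20.0, config,
                               5000.0, LAMBDA_LU)
        assert rep.ad_Gy == 0.0
        assert rep.intermediates["zero_counts"]

    def test_conjugate_view_recovery_is_exact(self, config):
        """Geometric mean x exp(+mu T/2) undoes the attenuation exactly for a
        midline source; the correction factor at T=20 cm is e^1.3."""
        planars = self._planars(100.0, config)
        rep = rbm_dose_cranium(planars, np.ones((8, 8), bool), 20.0, config,
                               5000.0, LAMBDA_LU)
        assert rep.intermediates["attenuation_correction"] == pytest.approx(
            math.exp(1.3), rel=1e-9)
        acts = rep.intermediates["cranium_activities_MBq"]
        for (t, _, _), a in zip(planars, acts):
            assert a == pytest.approx(100.0 * math.exp(-LAMBDA_LU * t), rel=1e-9)

    def test_halving_cranium_fraction_doubles_dose(self, config):
        planars = self._planars(100.0, config)
        roi = np.ones((8, 8), bool)
        r1 = rbm_dose_cranium(planars, roi, 20.0, config, 5000.0, LAMBDA_LU)
        r2 = rbm_dose_cranium(planars, roi, 20.0,
                              config.replace(cranium_rbm_fraction=0.119 / 2),
                              5000.0, LAMBDA_LU)
        assert r2.ad_Gy == pytest.approx(2.0 * r1.ad_Gy, rel=1e-12)

    def test_linear_in_administered_activity(self, config):
        roi = np.ones((8, 8), bool)
        r1 = rbm_dose_cranium(self._planars(100.0, config), roi, 20.0, config,
                              5000.0, LAMBDA_LU)
        r2 = rbm_dose_cranium(self._planars(200.0, config), roi, 20.0, config,
                              10000.0, LAMBDA_LU)
        assert r2.ad_Gy == pytest.approx(2.0 * r1.ad_Gy, rel=1e-12)

    def test_empty_roi_is_an_error(self, config):
        with pytest.raises(ValidationError, match="ROI"):
            rbm_dose_cranium(self._planars(1.0, config), np.zeros((8, 8), bool),
                             20.0, config, 100.0, LAMBDA_LU)


class TestMethodComparison:
    def test_late_marrow_accumulation_underestimated_by_blood(self, study, config,
                                                              lu177_beta):
        """With marrow uptake outlasting blood clearance, the image-based
        marrow dose exceeds the blood-based one — the core qualitative
        finding the 3D method exists to capture."""
        from voxdose.mc_dose import derive_composition, run_mc
        from voxdose.phantom import sample_blood
        spec, build = study
        rates = [run_mc(v, build.density, build.composition, lu177_beta,
                        60_000, seed=50 + i).doserate
                 for i, v in enumerate(build.activity.volumes)]
        series = vd.TimeSeriesVolumes(build.activity.times_h, rates)
        lv = rbm_dose_lv3d(series, [build.mask("marrow")] * 4, config,
                           spec.nuclide.decay_const_per_h, density=build.density)
        blood = rbm_dose_blood(sample_blood(spec), config,
                               spec.administered_activity_MBq,
                               spec.nuclide.decay_const_per_h)
        assert lv.ad_Gy > blood.ad_Gy
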