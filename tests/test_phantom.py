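"""Synthetic phantom generator: conservation, truth ledger, projections,
blood sampling and toxicity labels."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

import voxdose as vd
from voxdose.datamodel_io import ValidationError
from voxdose.phantom import (BloodKinetics, Box, Compartment, CompartmentKinetics,
                             PhantomSpec, Sphere, ToxicityModel, assign_toxicity,
                             build_phantom, example_study_phantom, project_planar,
                             sample_blood, DEFAULT_BLOOD_DRAW_TIMES_H)


class TestBuildPhantom:
    def test_activity_conservation_per_time_point(self, study):
        spec, build = study
        lam = spec.nuclide.decay_const_per_h
        for t, vol in zip(build.activity.times_h, build.activity.volumes):
            analytic = sum(spec.administered_activity_MBq * float(c.kinetics.retention(t))
                           * math.exp(-lam * t) for c in spec.compartments)
            assert vol.total() == pytest.approx(analytic, rel=1e-9)

    def test_total_t0_activity_below_administration(self, study):
        spec, build = study
        t0 = build.activity.times_h[0]
        assert build.activity.volumes[0].total() <= spec.administered_activity_MBq

    def test_truth_integrals_match_adaptive_quadrature(self, study):
        spec, build = study
        lam = spec.nuclide.decay_const_per_h
        for c in spec.compartments:
            f = lambda t: float(c.kinetics.retention(t)) * math.exp(-lam * t)
            num = 0.0
            for a, b in [(0, 100), (100, 1000), (1000, 20000)]:
                num += quad(f, a, b, limit=300)[0]
            want = build.truth["compartments"][c.name]["tia_analytic_MBq_h"]
            assert spec.administered_activity_MBq * num == pytest.approx(want, rel=1e-6)

    def test_marrow_uptake_gives_late_accumulation(self, study):
        """The marrow compartment's activity at 72 h exceeds the 3 h value
        when uptake dominates early clearance (evaluated analytically)."""
        k = CompartmentKinetics(share=0.002, lambda_fast_per_h=0.2,
                                uptake=0.01, uptake_rate_per_h=0.05)
        lam = math.log(2) / 161.04
        a3 = float(k.retention(3.0)) * math.exp(-lam * 3.0)
        a72 = float(k.retention(72.0)) * math.exp(-lam * 72.0)
        assert a72 > a3

    def test_static_compartment_without_decay_is_constant(self):
        stable = vd.Nuclide(name="stable-ish", half_life_h=1e12)
        grid = vd.VoxelGrid(shape=(10, 10, 10), voxel_size_mm=10.0)
        comp = Compartment("blob", Sphere((50, 50, 50), 30), 1.0,
                           CompartmentKinetics(share=1.0))
        spec = PhantomSpec(grid=grid, compartments=(comp,),
                           administered_activity_MBq=100.0, nuclide=stable)
        b = build_phantom(spec, seed=0)
        for vol in b.activity.volumes[1:]:
            np.testing.assert_allclose(vol.values, b.activity.volumes[0].values,
                                       rtol=1e-9)

    def test_overlap_resolved_by_listed_priority(self):
        grid = vd.VoxelGrid(shape=(10, 10, 10), voxel_size_mm=10.0)
        inner = Compartment("inner", Sphere((50, 50, 50), 15), 2.0,
                            CompartmentKinetics(share=0.1))
        outer = Compartment("outer", Sphere((50, 50, 50), 35), 1.0,
                            CompartmentKinetics(share=0.1))
        b = build_phantom(PhantomSpec(grid=grid, compartments=(inner, outer),
                                      administered_activity_MBq=10.0,
                                      nuclide=vd.load_nuclide("lu177")), seed=0)
        assert not np.any(b.mask("inner").mask & b.mask("outer").mask)
        assert b.density.values[5, 5, 5] == 2.0

    def test_degenerate_and_out_of_grid_geometry(self):
        grid = vd.VoxelGrid(shape=(8, 8, 8), voxel_size_mm=10.0)
        lu = vd.load_nuclide("lu177")
        tiny = Compartment("dot", Sphere((9, 9, 9), 0.1), 1.0,
                           CompartmentKinetics(share=0.1))
        with pytest.raises(ValidationError, match="zero voxels"):
            build_phantom(PhantomSpec(grid=grid, compartments=(tiny,),
                                      administered_activity_MBq=1.0, nuclide=lu), 0)
        outside = Compartment("out", Sphere((75, 75, 75), 20), 1.0,
                              CompartmentKinetics(share=0.1))
        with pytest.raises(ValidationError, match="outside"):
            PhantomSpec(grid=grid, compartments=(outside,),
                        administered_activity_MBq=1.0, nuclide=lu)

    def test_shares_above_unity_rejected(self):
        grid = vd.VoxelGrid(shape=(8, 8, 8), voxel_size_mm=10.0)
        c = Compartment("big", Sphere((40, 40, 40), 20), 1.0,
                        CompartmentKinetics(share=0.8))
        with pytest.raises(ValidationError, match="> 1"):
            PhantomSpec(grid=grid, compartments=(c, c),
                        administered_activity_MBq=1.0,
                        nuclide=vd.load_nuclide("lu177"))

    def test_build_is_deterministic(self, lu177):
        spec = example_study_phantom(shape=(16, 16, 12), nuclide=lu177)
        b1 = build_phantom(spec, seed=7)
        b2 = build_phantom(spec, seed=7)
        for v1, v2 in zip(b1.activity.volumes, b2.activity.volumes):
            np.testing.assert_array_equal(v1.values, v2.values)
        np.testing.assert_array_equal(b1.density.values, b2.density.values)

    def test_composition_labels_follow_compartment_densities(self, study):
        spec, build = study
        from voxdose.datamodel_io import MATERIALS
        marrow = build.mask("marrow")
        assert np.all(build.composition.labels[marrow.mask]
                      == MATERIALS.index("bone"))  # marrow box density 1.3
        tumor = build.mask("tumor")
        assert np.all(build.composition.labels[tumor.mask]
                      == MATERIALS.index("soft_tissue"))


class TestPlanarProjection:
    def point_source(self, depth_idx, n=9, vox_mm=10.0, activity=2.0):
        grid = vd.VoxelGrid(shape=(n, n, n), voxel_size_mm=vox_mm)
        a = np.zeros(grid.shape)
        a[4, depth_idx, 4] = activity
        act = vd.ScalarVolume(grid, a, "activity_MBq")
        den = vd.ScalarVolume(grid, np.ones(grid.shape), "density_g_cm3")
        return act, den

    def test_no_attenuation_single_voxel(self, config):
        act, den = self.point_source(4)
        cfg = config.replace(attenuation_cm_inv=1e-12)
        ant = project_planar(act, den, cfg, "anterior")
        post = project_planar(act, den, cfg, "posterior")
        assert ant[4, 4] == pytest.approx(2.0, rel=1e-9)
        np.testing.assert_allclose(ant, post, rtol=1e-9)
        assert np.count_nonzero(ant) == 1

    @pytest.mark.parametrize("depth", [1, 4, 7])
    def test_conjugate_view_identity_independent_of_depth(self, config, depth):
        """sqrt(ant * post) = A exp(-mu T / 2) for any source depth."""
        act, den = self.point_source(depth)
        ant = project_planar(act, den, config, "anterior")
        post = project_planar(act, den, config, "posterior")
        gm = math.sqrt(ant[4, 4] * post[4, 4])
        T = 9 * 1.0  # cm
        assert gm == pytest.approx(2.0 * math.exp(-config.attenuation_cm_inv * T / 2),
                                   rel=1e-9)

    def test_zero_activity_zero_image(self, config):
        act, den = self.point_source(4, activity=0.0)
        act = vd.ScalarVolume(act.grid, np.zeros(act.grid.shape), "activity_MBq")
        assert project_planar(act, den, config, "anterior").sum() == 0.0

    def test_poisson_noise_reproducible(self, config):
        act, den = self.point_source(4, activity=500.0)
        i1 = project_planar(act, den, config, "anterior", poisson_seed=3)
        i2 = project_planar(act, den, config, "anterior", poisson_seed=3)
        np.testing.assert_array_equal(i1, i2)
        assert i1[4, 4] == int(i1[4, 4])


class TestBlood:
    def test_t0_equals_c0(self, lu177):
        spec = example_study_phantom(shape=(16, 16, 12), nuclide=lu177)
        series = sample_blood(spec, [0.0, 1.0])
        assert series.concentration_MBq_per_mL[0] == pytest.approx(
            spec.blood.c0_MBq_per_mL)

    def test_monoexponential_is_log_linear(self, lu177):
        blood = BloodKinetics(c0_MBq_per_mL=2.0, f_fast=1.0,
                              lambda_fast_per_h=0.1, lambda_slow_per_h=0.1)
        spec = example_study_phantom(shape=(16, 16, 12), nuclide=lu177)
        spec = PhantomSpec(grid=spec.grid, compartments=spec.compartments,
                           administered_activity_MBq=spec.administered_activity_MBq,
                           nuclide=lu177, blood=blood)
        t = np.array([1.0, 2.0, 4.0, 8.0])
        series = sample_blood(spec, t)
        logs = np.log(series.concentration_MBq_per_mL)
        slopes = np.diff(logs) / np.diff(t)
        np.testing.assert_allclose(slopes, -(0.1 + lu177.decay_const_per_h), rtol=1e-9)

    def test_default_draw_schedule_has_seven_samples(self, lu177):
        spec = example_study_phantom(shape=(16, 16, 12), nuclide=lu177)
        series = sample_blood(spec)
        assert len(series.times_h) == 7
        assert series.times_h[0] == pytest.approx(2.0 / 60.0)
        assert series.whole_body_MBq is not None


class TestToxicity:
    def test_zero_dose_zero_noise_grade_zero(self):
        model = ToxicityModel(noise_sd_Gy=0.0)
        assert assign_toxicity(0.0, model, seed=0) == (0, 0)

    def test_far_above_top_breakpoint_is_grade_four(self):
        model = ToxicityModel(noise_sd_Gy=0.0)
        assert assign_toxicity(100.0, model, seed=0) == (4, 4)

    def test_at_threshold_half_exceed(self):
        """With symmetric noise, a dose exactly at threshold crosses it half
        the time (binomial check at n=1000)."""
        model = ToxicityModel(threshold_Gy=0.4, noise_sd_Gy=0.05)
        hits = sum(assign_toxicity(0.4, model, seed=s)[0] >= 1 for s in range(1000))
        # 3-sigma binomial band around 500
        assert abs(hits - 500) < 3 * math.sqrt(1000 * 0.25)

    def test_breakpoints_must_increase(self):
        with pytest.raises(ValidationError):
            ToxicityModel(grade_breakpoints_Gy=(0.3, 0.2, 0.5))
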