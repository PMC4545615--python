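# voxdose

Voxel Monte Carlo dosimetry for radionuclide therapy: tumor and red bone
marrow (RBM) absorbed doses from serial quantitative SPECT, with
¹⁷⁷Lu / ⁹⁰Y matched-pair comparison and dose–toxicity analysis.

## The problem

In radioimmunotherapy and peptide-receptor therapy the red bone marrow is
usually the dose-limiting organ, yet the conventional ways of estimating
its absorbed dose — from blood samples, or from planar images of the
cranium — often fail to separate patients who develop hematologic toxicity
from those who do not.  When the radiopharmaceutical is *retained* in the
marrow (visible as late accumulation in the vertebrae), both conventional
methods systematically underestimate the marrow dose.  A 3D image-based
approach — Monte Carlo transport on serial SPECT activity maps with a
lumbar-vertebrae VOI — tracks the actual marrow kinetics and also yields
tumor doses and dose-volume histograms, which planar imaging cannot.

`voxdose` implements that full comparison pipeline for physicists working
on treatment planning in targeted radionuclide therapy:

* **`datamodel_io`** — voxel grids, scalar volumes (NIfTI + JSON sidecar),
  nuclide decay data, blood series, cohort tables, configuration.
* **`phantom`** — a synthetic digital phantom generator (compartment
  geometry + biexponential kinetics with late marrow uptake, planar
  conjugate-view projections, blood curves, toxicity labels) with an
  analytic truth ledger for end-to-end validation.
* **`quantify`** — SPECT calibration (counts → MBq), paralyzable dead-time
  bounds, body-contour thresholding.
* **`mc_dose`** — the Monte Carlo dose-rate engine: decays sampled from the
  activity map; photons transported by Woodcock tracking with Klein–Nishina
  Compton sampling; betas deposited locally (¹⁷⁷Lu) or through a radial
  CSDA kernel (⁹⁰Y); exact energy ledger per run.
* **`kinetics`** — the hybrid trapezoidal–exponential time integration:
  trapezoids over the early time points, an exponential tail fitted to the
  final two, voxel-wise and VOI-wise; time-integrated activity
  coefficients.
* **`rbm_dosimetry`** — the three RBM dose methods (3D lumbar-vertebrae,
  blood-based, 2D cranium conjugate-view) and the biologically effective
  dose, BED = AD·(1 + G(∞)·AD/(α/β)) with the Lea–Catcheside protraction
  factor G(∞) and repair rate μ.
* **`tumor_dosimetry`** — tumor VOI mean dose, DVH, and the unit-density
  sphere-model comparison.
* **`matched_pair_report`** — half-life rescaling of activity series for
  matched-pair ⁹⁰Y simulation, tumor-to-RBM ratio tables, cohort summary
  statistics, and dose–toxicity separation reports.

A bundled 13-patient cohort table (¹⁷⁷Lu pretargeted radioimmunotherapy of
colorectal cancer; administered activities 2.5–7.4 GBq) drives the
reporting layer.

## Worked example

```python
import dataclasses
import voxdose as vd
from voxdose.rbm_dosimetry import rbm_dose_lv3d, rbm_dose_blood
from voxdose.phantom import sample_blood
from voxdose.kinetics import integrate_voi

# --- cohort reporting from the bundled table ---
cohort = vd.packaged_cohort()
m = vd.cohort_summary(cohort, ndigits=2)
print(f"mean tumor dose (3D):     {m['ad_tumor_3d_Gy']} Gy")
print(f"mean RBM dose (3D):       {m['ad_rbm_3d_Gy']} Gy")
print(f"mean tumor dose (sphere): {m['ad_tumor_sphere_Gy']} Gy")
sep = vd.toxicity_separation(cohort, "ad_rbm_3d_Gy", "any_toxicity")
print(f"highest RBM dose without toxicity: {sep.max_dose_no_toxicity_Gy} Gy")
print(f"lowest RBM dose with toxicity:     {sep.min_dose_toxicity_Gy} Gy")
print(f"separating threshold:              {sep.separating_threshold_Gy:.2f} Gy")
lu_, y_, pct = vd.matched_pair_summary(
    vd.matched_pair_from_table(vd.packaged_matched_pair()))
print(f"tumor-to-RBM ratio: {lu_:.2f} (177Lu) -> {y_:.2f} (90Y), +{pct:.0f}% mean gain")

# --- synthetic end-to-end pipeline: phantom -> MC -> doses ---
lu = vd.load_nuclide("lu177")
lu_beta = dataclasses.replace(lu, photon_lines=())   # electron-only transport
spec = vd.example_study_phantom(nuclide=lu)          # 5 GBq, marrow accumulation
build = vd.build_phantom(spec, seed=1)
cfg = vd.DosimetryConfig()
rates = [vd.run_mc(v, build.density, build.composition, lu_beta,
                   100_000, seed=10 + i).doserate
         for i, v in enumerate(build.activity.volumes)]
series = vd.TimeSeriesVolumes(build.activity.times_h, rates)
lv = rbm_dose_lv3d(series, [build.mask("marrow")] * 4, cfg,
                   lu.decay_const_per_h, density=build.density)
blood = rbm_dose_blood(sample_blood(spec), cfg,
                       spec.administered_activity_MBq, lu.decay_const_per_h)
d_tumor = integrate_voi(series, build.mask("tumor"), lu.decay_const_per_h,
                        density=build.density)
truth = build.truth["compartments"]["tumor"]["local_beta_dose_hybrid_Gy"]
print(f"marrow dose, 3D image-based: {lv.ad_Gy:.2f} Gy (BED {lv.bed_Gy:.2f} Gy)")
print(f"marrow dose, blood-based:    {blood.ad_Gy:.2f} Gy")
print(f"tumor dose, 3D:              {d_tumor:.2f} Gy (ledger truth {truth:.2f} Gy)")
```

Output:

```
mean tumor dose (3D):     1.77 Gy
mean RBM dose (3D):       0.46 Gy
mean tumor dose (sphere): 1.72 Gy
highest RBM dose without toxicity: 0.39 Gy
lowest RBM dose with toxicity:     0.43 Gy
separating threshold:              0.41 Gy
tumor-to-RBM ratio: 4.68 (177Lu) -> 5.41 (90Y), +25% mean gain

marrow dose, 3D image-based: 1.50 Gy (BED 1.51 Gy)
marrow dose, blood-based:    0.43 Gy
tumor dose, 3D:              3.14 Gy (ledger truth 3.18 Gy)
```

Reading it: the cohort's 3D RBM doses fully separate toxic from non-toxic
patients around 0.41 Gy, and switching the therapy nuclide from ¹⁷⁷Lu to
⁹⁰Y would raise the tumor-to-marrow dose ratio by 25 % on average.  On the
synthetic patient, the blood-based method reports less than a third of the
image-based marrow dose — the underestimation expected when marrow
accumulates activity that the blood has already cleared — and the pipeline
tumor dose agrees with the generator's analytic truth to about one percent.

A command-line interface mirrors the pipeline stages
(`voxdose phantom|quantify|dose|integrate|rbm|tumor|matched-pair|report`);
run `voxdose --help` for details.

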