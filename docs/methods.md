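# Methods

This note documents the models, numerical choices and validation logic of
`voxdose` in one place.  The package computes absorbed doses to tumors and
red bone marrow (RBM) from serial 3D activity maps, compares three RBM dose
methods, and simulates a therapy-nuclide swap (¹⁷⁷Lu → ⁹⁰Y) by matched-pair
rescaling.

## Dose calculation chain

A study consists of four co-registered activity volumes (MBq per voxel) at
roughly 0.5, 3, 24 and 72 h after administration, a density volume
(g/cm³), and VOI masks, all on one isotropic grid (4.795 mm voxels;
128×128×78 at full scale, smaller grids for tests).  Composition (lung /
soft tissue / bone) is thresholded from density at 0.5 and 1.2 g/cm³.  For
each time point the Monte Carlo engine produces a dose-rate map (Gy/h);
the hybrid time-integration rule turns dose rates into absorbed dose, per
voxel or per VOI.

### Monte Carlo transport

Each history samples a source voxel proportionally to its activity and a
uniform position inside it, and carries the weight
(total decays per hour)/n_histories.

* **Beta emission** is summarised by the mean energy per decay.  For
  ¹⁷⁷Lu (mean beta 0.1335 MeV, CSDA range ≈ 0.3 mm) the energy is
  deposited in the source voxel — sub-voxel transport at 4.8 mm voxels.
  For ⁹⁰Y (mean 0.9337 MeV, endpoint 2.2801 MeV, ranges up to ≈ 11 mm)
  each history deposits its beta energy at a radius drawn from a
  precomputed kernel: an allowed-shape spectrum (Fermi screening omitted;
  it only shapes a radial profile) is combined with the Katz–Penfold
  range–energy relation R = 0.412·E^(1.265−0.0954 ln E) g/cm², assuming
  straight paths and uniform stopping power in water; the sampled radius
  is divided by the local density.  Bremsstrahlung is not transported.
* **Photons** (the ¹⁷⁷Lu 113 and 208 keV lines) are tracked with Woodcock
  (delta) tracking against a majorant cross-section from bundled
  mass-attenuation tables (water for soft tissue and lung, ICRU-44-style
  cortical bone; coherent scattering excluded).  At a real interaction the
  photoelectric branch absorbs locally; the Compton branch samples the
  Klein–Nishina distribution with Kahn's rejection scheme, deposits the
  recoil-electron energy locally (kerma approximation — electron ranges at
  ≤ 208 keV are far sub-voxel), and continues the scattered photon until
  it falls below 20 keV (local deposit) or leaves the grid (escape).

Every run returns an energy ledger with emitted = deposited + escaped
holding to floating-point rounding; this is asserted in the tests for all
three transport modes.  Voxel masses use the density map with a floor of
0.05 g/cm³ so near-air voxels cannot produce infinite dose.  Decay data
live in a versioned YAML file (values from the standard MIRD/ICRP-107
compendia; half-lives use the conventional 6.71 d and 2.66 d figures that
also drive the matched-pair arithmetic).

The engine is validated against a closed form: in an infinite uniform
beta-only medium the equilibrium dose rate is
a·10⁶·Ē_β·(1.602×10⁻¹³ J/MeV)·3600 / (ρ·10⁻³ kg/cm³) Gy/h for
concentration a MBq/cm³.  With local deposition the voxel tallies are
binomial counts, so the standard error of a central-block mean is exact
and the test bound (3 SE at 10⁵ histories) involves no fitted tolerance.

### Hybrid trapezoidal–exponential integration

Given samples y₁…y₄ at t₁…t₄, the cumulative quantity is

* a leading rectangle holding y₁ back to t = 0 (the first scan follows
  administration closely; the alternative `zero` rule is available),
* trapezoids over [t₁,t₂] and [t₂,t₃],
* an exponential tail anchored exactly at (t₃, y₃) with rate
  k = ln(y₃/y₄)/(t₄−t₃), integrating to y₃/k over [t₃,∞).

Anchoring at y₃ is the two-point reading of "fit the tail to the final two
samples"; it makes the rule linear in the data except through k.  When the
curve is flat or rising at the end (y₄ ≥ y₃), k falls back to the
nuclide's physical decay constant — the fastest clearance physically
guaranteed — and the event is flagged.  A zero anchor with a positive
final sample is rejected as non-physical in the scalar fit; the voxel-wise
map integrator tolerates such voxels by default (they are ordinary Monte
Carlo tally noise, and the tail integral is zero there anyway) and offers
`strict=True` for analytic inputs.

Accuracy: the rule is exact for piecewise-linear-plus-exponential truth
and reproduces ∫D₀e^(−λt) to ≈ 2×10⁻⁴ relative at the standard times for
λ equal to the ¹⁷⁷Lu physical constant.  For kinetics fast relative to the
sampling grid (whole-body clearance half-times of a few hours) the
trapezoid inevitably deviates by several percent from the analytic
integral — a property of the protocol, not of the implementation — which
is why the phantom truth ledger records *both* the analytic integral and
the hybrid-rule value of the exactly-evaluated samples.  Pipeline recovery
is judged against the latter, isolating transport noise from sampling
error.

VOI integration averages the per-time-point dose rate over the mask
(mass-weighted when a density map is supplied) and fits the four scalars;
this matches summing deposited energy in the VOI and integrating.

### BED and the Lea–Catcheside factor

BED = AD·(1 + G(∞)·AD/(α/β)) with α/β = 10 Gy and repair rate
μ = 0.46 h⁻¹ by default.  G(∞) is computed on the fitted dose-rate curve:
the inner convolution X(t) = ∫₀ᵗ Ḋ(t′)e^(−μ(t−t′))dt′ satisfies
X′ = Ḋ − μX and is advanced *exactly* across each linear piece (linear
forcing has a closed-form update); the outer integral ∫ḊX dt accumulates
by fine trapezoids (0.01 h substeps), and the exponential tail contributes
the closed form X_a·y/(k+μ) + y²/(2k(k+μ)), which is regular at k = μ.
For a pure mono-exponential the result equals λ/(λ+μ) to ≈ 10⁻¹⁶; a
nested adaptive-quadrature oracle checks the piecewise case to 10⁻⁵.  At
the protocol's rates G ≈ λ/(λ+μ) ≈ 0.009, so BED exceeds AD by well under
a percent at sub-Gy marrow doses — protraction makes the quadratic term
nearly irrelevant, which is itself a finding the tests lock in
(BED ≥ AD always).

## The three RBM methods

* **3D lumbar-vertebrae (`lv_3d`)** — VOI mean dose rates per time point,
  one mask per scan (per-scan delineation side-steps co-registration error
  but precludes voxel-wise marrow dose), hybrid integration, BED attached.
* **Blood-based** — marrow time-integrated activity =
  (RBM-to-blood concentration ratio, default 1) × (blood concentration
  integral) × (marrow mass).  With seven draws from 2 min to 72 h the
  integral uses plain trapezoids plus a physical-decay tail rather than
  the 4-point hybrid rule.  Dose = Ã_RBM·S_self + Ã_remainder·S_cross.
  The S-values and the 1170 g marrow mass are *reference-phantom
  placeholders*: the self-S default (6.58×10⁻² mGy/MBq·h) is the
  beta-only electron self-dose for that mass and the bundled ¹⁷⁷Lu beta
  energy, the cross term a small photon-order placeholder.  Model-based
  dosimetry software would supply anatomy-specific values; every report
  embeds the numbers used.
* **2D cranium-based** — conjugate-view quantification: per time point the
  cranium activity is √(anterior×posterior counts)·e^(+μT/2)·calibration
  (μ = 0.13 cm⁻¹, T the body thickness; the geometric mean cancels source
  depth exactly for a point source).  Its time-integrated activity
  coefficient divided by the cranium's share of total skeletal RBM mass
  (reference value 0.119) gives the whole-marrow coefficient; the self
  S-value converts to dose.  A remainder-of-body cross term is
  deliberately omitted — the method is a self-dose estimate.

All three are linear in administered activity.  On phantoms with late
marrow accumulation the blood method underestimates the image-based dose —
the central qualitative comparison — because it assumes marrow tracks
blood at all times.

## Tumor dosimetry

The 3D tumor dose is the mass-weighted mean voxel dose over the mask.  The
DVH is the cumulative fraction of VOI volume receiving at least each dose
edge; with edges at every distinct dose value its right-rectangle area
reproduces the mean dose exactly, with the default 100 uniform bins to one
bin width.  The sphere model computes the VOI mass from the density map,
the VOI time-integrated activity by the hybrid rule, and multiplies by a
self-S-value log-log interpolated from a table of uniform unit-density
spheres simulated *with the same transport engine*.  Using one engine for
both routes is deliberate: their difference then isolates geometry
(surrounding activity, shape) rather than physics differences between
codes.  With zero background the two routes agree within Monte Carlo
error; with a hot background the 3D dose is systematically higher, since
the isolated-sphere model ignores cross-fire from outside the VOI.

## Matched-pair ⁹⁰Y simulation

The measured series is multiplied per time point by
exp(−(λ_Y − λ_Lu)·t), which removes ¹⁷⁷Lu physical decay and applies
⁹⁰Y's while keeping the biological kinetics and administered activity;
transport is re-run with the ⁹⁰Y emission data.  The figure of merit is
AD_tumor/AD_RBM; percentage changes are quoted relative to the ¹⁷⁷Lu
ratio.  Because the kinetic gain competes with geometry effects (the
long-range ⁹⁰Y betas leak out of small VOIs and in from the surroundings),
the directional tests drive both nuclides with the same random seeds —
common random numbers — so source-sampling noise cancels from the
comparison.

## The synthetic phantom

The generator emulates what the pipeline would receive from a patient
study: compartments (sphere/box/ellipsoid) with biological retention
r(t) = share·(f·e^(−λ₁t) + (1−f)·e^(−λ₂t)) + uptake·(1−e^(−λᵤt)),
physical decay on top, uniform intra-compartment activity, density-derived
composition, attenuated anterior/posterior parallel projections (in-body
path length per voxel, so the conjugate-view identity holds exactly for a
midline source), a biexponential blood curve, and threshold-plus-
breakpoint toxicity grades with Gaussian dose noise.

The reference study (`example_study_phantom`) fixes the conditions used
throughout the tests and the acceptance script: a 32×32×28 grid at
4.795 mm (full-scale 128×128×78 available by argument), 5 GBq
administered, first scan at 0.5 h then 3/24/72 h, a body clearing with a
~14 h biological half-time (55 % of the administration), a 26 mL tumor
retaining 0.3 % with a slow 0.01 h⁻¹ clearance (few-Gy tumor dose), and a
70 g vertebral compartment with a small initial share (0.08 %) plus slow
accumulation to 0.14 % at 0.1 h⁻¹ — the at-risk marrow-retention pattern,
yielding an image-based marrow dose of order 1 Gy while the fast-clearing
blood (90 % with a ~20 min half-time) reports a small fraction of it.
These are choices of a representative patient, set once; the truth ledger
makes them auditable.

What the phantom does **not** model: collimator blur, scatter windows and
reconstruction artifacts, partial-volume effects, anatomical texture,
activity heterogeneity inside compartments, and patient motion.  Passing
the recovery tests therefore demonstrates correctness of the dosimetry
chain given quantitative activity maps — not robustness to SPECT
quantification error, which the calibration/dead-time module only bounds.

## Validation design

Tests prefer independent oracles over frozen outputs: adaptive quadrature
for the hybrid rule and the G-factor, binomial error bounds for the
equilibrium phantom, conservation identities (energy ledger, activity
bookkeeping, DVH mean), scale/permutation invariances, and the analytic
truth ledger for end-to-end recovery (batch-replicated Monte Carlo
estimates compared at 3 standard errors, with the batch spread absorbing
the nonlinear noise amplification of the fitted tail rate).  The cohort
reporting layer is checked against the bundled per-patient tables at their
printed precision.  Statistical assertions use fixed seeds; history counts
(10⁵ per map for recovery, a few 10⁴ for directional checks) were sized so
the assertions test physics, not luck.

## Known limitations

* No coupled electron–photon condensed-history transport; ⁹⁰Y
  bremsstrahlung and coherent scattering are ignored (sub-percent effects
  at these energies and voxel sizes).
* The ⁹⁰Y kernel assumes straight electron paths with uniform stopping
  power and density-scaled ranges; it is a convolution surrogate, adequate
  at 4.8 mm voxels but not for sub-mm dosimetry.
* Blood and cranium methods inherit reference-phantom S-values and masses;
  absolute doses from them are only as patient-specific as those inputs.
* The photon cross-section grid spans 20–500 keV; emitters outside that
  band need extended tables.
* Image registration, reconstruction and partial-volume correction are out
  of scope; activity maps are taken as quantitative inputs.
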