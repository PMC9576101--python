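# Methods

## Model

`muscalib` treats a CT scan as monoenergetic: all attenuation contrast is
summarised by a single effective energy `E*` (keV). For a material `m` with
mass attenuation curve `(μ/ρ)_m(E)` (cm²/g) and mass density `ρ_m` (g/cm³),
the linear attenuation is `μ_m(E) = (μ/ρ)_m(E)·ρ_m` (1/cm), and the ideal
Hounsfield value is

    HU_m(E) = 1000 · (μ_m − μ_water) / (μ_water − μ_air),

so water is exactly 0 HU and air exactly −1000 HU at every energy. This is an
abstraction of a polychromatic scanner beam: beam hardening, scatter and
detector effects are folded into whatever single `E*` best explains the
observed tissue contrast, which is the premise of internal calibration.

Internal calibration proceeds in three steps:

1. **Measure** mean HU of segmented reference ROIs (air, adipose, blood,
   skeletal muscle, cortical bone — any subset of two or more).
2. **Estimate `E*`** (below).
3. **Fit** `μ_m(E*) = a·h_m + b` by OLS over the ROI set (exact interpolation
   for two ROIs) and convert every voxel:
   `ρ_weq = (a·HU + b) / (μ/ρ)_water(E*)` — water-equivalent density, g/cm³.

Negative output densities (air regions) are preserved, never clamped:
downstream muscle masks exclude air, and clamping would bias agreement
statistics.

## Effective-energy objectives

* `mu_residual` (default for ≥ 3 ROIs): `E*` minimises the residual sum of
  squares of the OLS fit of `μ_m(E)` on measured HU. OLS residuals are
  unchanged under any invertible affine transform of the predictor, so this
  objective — and everything downstream — is exactly invariant to scanner HU
  gain/offset miscalibration. For noise-free data it has an exact zero at the
  true energy, because the ideal HU definition makes `μ_m(E0)` affine in
  `HU_m(E0)`.
* `hu_sse` (default for 2-ROI sets): minimises `Σ (h_m − ĥ_m(E))²` against
  the ideal water/air-anchored prediction. With two measurements the affine
  map `(gain, offset, E)` is under-determined — no data-driven objective can
  separate a gain error from an energy shift — so this objective assumes the
  scanner's HU gain is nominally calibrated (routine daily QC). The measured
  air ROI re-anchors the offset before comparison, so a pure HU offset is
  still absorbed exactly. Consequence worth knowing: two-ROI calibration is
  exactly offset-invariant but only approximately gain-robust; use three or
  more ROIs when gain distortion is plausible.
* `r2`: maximises R² of the μ-vs-HU fit (equivalent to `mu_residual` up to
  normalisation; degenerate for two ROIs). Config-selectable for comparison.

Search: a 1 keV grid over the energy window (default 30–200 keV, clipped to
the tabulated 10–200 keV grid), ties broken toward the lower energy, then
bounded scalar minimisation (±1.5 keV around the grid minimum) to an
absolute tolerance of 1e−6 keV. The documented guarantee is |E*−E0| ≤ 0.01
keV on noise-free data; the refinement is run much tighter because
water-equivalent density through a 2-ROI air/adipose map moves by roughly
0.1% per keV of energy error, and the round-trip contract is 1e−6 relative.

## Reference data

Mass attenuation tables are NIST (Hubbell & Seltzer) values for dry air and
liquid water and ICRU-44 tissue compositions for adipose, whole blood,
skeletal muscle and cortical bone, shipped as delimited text on the standard
10–200 keV grid with provenance headers, and interpolated log-log linearly
(standard for attenuation data; no extrapolation; tables with duplicate
energies — absorption edges — are rejected, since these tissues have none in
range). Nominal densities are the ICRU-44 values (air 0.001205, water 1.000,
adipose 0.95, blood 1.06, muscle 1.05, cortical bone 1.92 g/cm³),
overridable per material via `load_material_library(density_overrides=...)`.

ROI HU aggregation is the arithmetic mean over mask voxels (conventional QCT
practice); median is available as an option for contaminated ROIs.

## Phantom calibration

The comparator fits known vial densities on measured vial HU by OLS and
rescales the image affinely. Sucrose-water vials (1.00, 1.01, 1.04, 1.06,
1.11 g/ml) are modelled — both in the synthetic generator and in the fit's
validation — as water's mass attenuation scaled by solution density, an
adequate approximation for dilute sucrose at diagnostic energies; a true
sucrose-solution curve can be supplied as a custom material. A
hydroxyapatite phantom uses the identical fit with `mgHA/cm³` units.

## Synthetic scans

The generator renders labelled homogeneous regions (axis-aligned boxes and
spheres) on a small voxel grid: each region's ideal HU is its monoenergetic
value at the scenario's true energy `E0`; the stored value is
`gain·ideal + offset + N(0, noise_sd)`, reproducible under the scenario
seed. Fat-infiltrated muscle is modelled as voxel-wise linear mixing of
muscle and adipose attenuation by volume fraction (monotone between the pure
endpoints). The ground-truth table records each region's `μ(E0)` and
water-equivalent density.

The default study layout mirrors the validation design: five calibration
ROIs, ten muscle samples with fat fractions spanning 0–15% (mild
myosteatosis; pure muscle ≈ 1.053 g/cm³ water-equivalent at 70 keV, falling
toward adipose ≈ 0.92 with infiltration), and a five-vial sucrose phantom,
as 6×6×4-voxel boxes on a 64×64×6 grid — deliberately desk-scale so that
every test and the acceptance script run in seconds on one CPU. A *condition
battery* re-renders the same geometry under N (gain, offset, noise) triples
(default 10, standing in for two protocols × five bore positions), with
gains drawn uniformly from [0.93, 1.07] and offsets from [−30, +30] HU.
These distortions are deliberately exaggerated — they produce raw muscle-HU
CVs of tens of percent rather than the few percent seen across real
protocol/position changes — so that the stability contrast between raw HU
and calibrated density is unmistakable rather than borderline.

What the generator does **not** emulate: projection/reconstruction physics,
beam hardening, scatter, partial-volume blurring, anatomical texture or
inhomogeneity, and scanner-specific noise correlation. Passing round-trip
and invariance tests therefore demonstrates the *calibration mathematics* is
correct and self-consistent, not that segmented-ROI noise, tissue
inhomogeneity (the known failure mode of the bone ROI) or composition
differences in real patients are harmless. The bone-perturbation sweep
probes exactly that failure mode synthetically: biasing the assumed
cortical-bone density by +5% degrades only the bone-containing ROI subsets.

## Statistics

Bland-Altman: differences `d = x − y`, bias = mean(d), 95% limits of
agreement bias ± 1.96·SD(d) (sample SD; the 1.96 multiplier is fixed), plus
an OLS trend of `d` on the pairwise means to flag proportional error.
Method comparison uses OLS with R²; the percent difference between two
methods is `100·mean((reference − other)/reference)` over paired samples.
Coefficient of variation is `100·SD/mean` per sample across conditions
(sample SD), with the mean CV an arithmetic mean over samples; series with
non-positive means raise rather than return a sign-corrupted CV (raw HU
series near zero are the textbook case — and one reason HU itself is a poor
density surrogate). Within-subject ANOVA machinery is intentionally out of
scope; the reproducible quantities are the CV tables and paired differences
themselves.

The supplementary-densities reader accepts either a tidy long sheet
(sample/condition/method/value) or one wide sheet per method, normalising
method names to {HU, internal, sucrose_phantom, HA_phantom}; anything else
raises a schema error listing what was found.

## Degenerate inputs and edge cases

* Air-only (or any single-material) ROI sets raise a degeneracy error: air's
  predicted HU is −1000 at every energy and carries no energy information.
* Identical ROI mean HUs raise a singular-fit error, as does a non-positive
  fitted slope.
* Empty energy windows (after clipping to table coverage) raise.
* Overlapping synthetic regions raise at generation time.
* Masks must be grid-aligned with the image; no resampling is performed.

## Known limitations

* One effective energy per scan: strongly position-dependent spectral
  effects within a single field of view are not representable.
* Two-ROI calibrations inherit the scanner's HU gain accuracy (see above).
* The shipped attenuation tables are 3–4 significant-figure transcriptions
  of the published NIST values on the coarse standard grid; log-log
  interpolation between 60 and 80 keV is smooth but not spectroscopically
  exact. All validation here is self-consistent against the same tables.
* Sucrose vials as density-scaled water is an approximation that breaks down
  for concentrated solutions or low (< 30 keV) energies.
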