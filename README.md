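# muscalib

Phantomless ("internal") CT density calibration for muscle.

Clinically acquired CT scans almost never include a density calibration
phantom, so muscle quality is usually reported in raw Hounsfield units (HU) —
which drift with scan protocol, object position in the bore, and scanner
state, and therefore compare poorly across scans. `muscalib` converts HU to
water-equivalent mass density (g/cm³) using only tissues inside the
field of view (air, adipose, blood, skeletal muscle, cortical bone), making
quantitative muscle density — and the fat infiltration it reflects —
accessible from opportunistic CT without any phantom.

## Method

For a set of segmented reference ROIs with measured mean HU values
`h_m`, and tabulated NIST mass attenuation curves `(μ/ρ)_m(E)` with nominal
densities `ρ_m`, the scan's **effective energy** `E*` is the monoenergetic
energy that makes the measured HU contrast consistent with the physics:

1. For each candidate energy `E`, compute each material's linear attenuation
   `μ_m(E) = (μ/ρ)_m(E) · ρ_m` and fit the affine map `μ = a·h + b` by
   ordinary least squares. `E*` minimises the residual of that fit (with ≥ 3
   ROIs; the residual is invariant to any affine HU miscalibration, which is
   what makes the method robust across protocols and positions). With
   exactly 2 ROIs the fit is exact at every energy, so `E*` instead
   minimises the anchored HU prediction error, using the measured air ROI to
   absorb any HU offset.
2. At `E*`, the fitted `(a, b)` convert every voxel to water-equivalent
   density `ρ_weq = (a·HU + b) / (μ/ρ)_water(E*)`, so water maps to
   1.000 g/cm³ by construction.

The package also implements the validation machinery around the method: a
reference-phantom calibration (sucrose-water vials in g/cm³, hydroxyapatite
rods in mgHA/cm³), a synthetic-scan generator with exact ground truth, an
ROI-combination sweep (all five subsets from {air, adipose, blood, muscle,
bone} down to {air, adipose}), and Bland-Altman / regression / coefficient-
of-variation statistics.

## Worked example

```python
import numpy as np
from muscalib import (default_scenario, generate_scan, internal_calibrate,
                      default_conditions, generate_condition_battery,
                      cv_across_conditions)

# a digital scan: 5 calibration ROIs, 10 muscle samples with 0-15% fat
# infiltration, a 5-vial sucrose phantom, imaged at E0 = 70 keV
scan = generate_scan(default_scenario(true_energy=70.0, seed=1))
cal, density = internal_calibrate(scan.image, scan.mask, scan.roi_map,
                                  roi_set=("air", "adipose"))
print(f"E* = {cal.effective_energy:.2f} keV")
print(f"mu = {cal.slope_a:.3e} * HU + {cal.intercept_b:.4f}  [1/cm]")
labels = scan.sample_labels
rho = [density.voxels[scan.mask == l].mean() for l in labels]
print(f"mean muscle-sample density = {np.mean(rho):.4f} g/cm^3")

# robustness: the same geometry under 10 gain/offset scan conditions
battery = generate_condition_battery(default_scenario(true_energy=70.0, seed=1),
                                     default_conditions(10, seed=1))
rows_raw, rows_cal = [], []
for s in battery:
    _, d = internal_calibrate(s.image, s.mask, s.roi_map, ("air", "adipose", "blood"))
    rows_cal.append([d.voxels[s.mask == l].mean() for l in labels])
    rows_raw.append([s.image.voxels[s.mask == l].mean() for l in labels])
print(f"raw HU mean CV      = {cv_across_conditions(np.array(rows_raw).T).mean_cv:.2f} %")
print(f"calibrated mean CV  = {cv_across_conditions(np.array(rows_cal).T).mean_cv:.2e} %")
```

prints

```
E* = 70.00 keV
mu = 1.935e-04 * HU + 0.1937  [1/cm]
mean muscle-sample density = 1.0433 g/cm^3
raw HU mean CV      = 37.65 %
calibrated mean CV  = 1.68e-14 %
```

The estimated effective energy matches the simulated 70 keV exactly; the
pure-muscle sample comes out at its water-equivalent value (≈ 1.053 g/cm³,
lowered toward adipose with increasing fat fraction); and across ten
deliberately miscalibrated scan conditions the calibrated density is stable
to machine precision while raw HU varies by tens of percent.

A command-line interface mirrors the library:

```sh
muscalib simulate --out-dir sim --conditions 10
muscalib internal --image sim/scan.nii.gz --mask sim/mask.nii.gz \
    --roi-map sim/roi_map.json --rois air,adipose \
    --out-density density.nii.gz --out-report report.json
muscalib stats cv --input per_sample.csv --out cv.json
```

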