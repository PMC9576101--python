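"""Internal (phantomless) CT density calibration.

The method estimates the scan's effective energy E* from the measured HU of
tissue regions of interest (air, adipose, blood, skeletal muscle, cortical
bone), using tabulated mass-attenuation physics; fits the affine map from HU
to linear attenuation, mu = a*HU + b, at E*; and converts the image to
water-equivalent density rho_weq = mu / (mu/rho)_water(E*), in g/cm^3.

Effective-energy objectives
---------------------------
``mu_residual``
    Residual sum of squares of the ordinary-least-squares fit of the
    materials' linear attenuation mu_m(E) on their measured mean HU.  Because
    OLS residuals are unchanged under any invertible affine transform of the
    predictor, this objective — and hence E* and the density output — is
    invariant to scanner HU gain/offset miscalibration.  It needs at least
    three ROIs to be informative.
``hu_sse``
    Sum of squared differences between measured mean HU and the ideal HU
    predicted at energy E (water = 0, air = -1000 anchors).  Well-posed for
    two-ROI sets, but assumes the scanner's HU *gain* is nominally correct
    (routine daily QC); a common HU offset is absorbed exactly whenever an
    air ROI is supplied, because measured air re-anchors the scale before
    comparison.
``r2``
    1 - R^2 of the mu-vs-HU fit, minimised; equivalent to ``mu_residual`` up
    to scaling, degenerate for 2-ROI sets.  Provided for comparison.
``auto`` (default)
    ``mu_residual`` when >= 3 distinct ROIs are supplied, else ``hu_sse``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .materials import (
    MaterialSpec,
    canonical_material_name,
    interpolate_mass_attenuation,
    linear_attenuation,
    load_material_library,
    predicted_hu,
)
from .volumes import DensityVolume, HUVolume, roi_statistics

__all__ = [
    "RoiSample",
    "InternalCalibration",
    "CalibrationError",
    "DegenerateRoiSetError",
    "SingularFitError",
    "DEFAULT_ENERGY_RANGE",
    "PAPER_ROI_COMBINATIONS",
    "extract_roi_samples",
    "estimate_effective_energy",
    "fit_hu_to_attenuation",
    "calibrate_to_water_density",
    "internal_calibrate",
    "roi_combination_sweep",
]

#: Default effective-energy search window, keV (within the tabulated grid).
DEFAULT_ENERGY_RANGE = (30.0, 200.0)

#: The five ROI combinations evaluated for muscle calibration, largest first.
PAPER_ROI_COMBINATIONS: tuple[tuple[str, ...], ...] = (
    ("air", "adipose", "blood", "skeletal_muscle", "cortical_bone"),
    ("air", "adipose", "blood", "skeletal_muscle"),
    ("air", "adipose", "blood"),
    ("air", "blood"),
    ("air", "adipose"),
)


class CalibrationError(ValueError):
    """Base class for calibration failures."""


class DegenerateRoiSetError(CalibrationError):
    """ROI set carries no energy information (e.g. air alone)."""


class SingularFitError(CalibrationError):
    """HU values do not span a line (all identical)."""


@dataclass(frozen=True)
class RoiSample:
    """Summary of one region of interest's HU distribution."""

    material: str
    mean_hu: float
    sd_hu: float = 0.0
    n_voxels: int = 1

    def __post_init__(self) -> None:
        if self.n_voxels < 1:
            raise ValueError("n_voxels must be >= 1")
        if self.sd_hu < 0:
            raise ValueError("sd_hu must be >= 0")


@dataclass
class InternalCalibration:
    """Fitted internal calibration: E*, affine HU->mu map, diagnostics."""

    effective_energy: float  # keV
    slope_a: float  # (1/cm) per HU
    intercept_b: float  # 1/cm
    water_mass_attenuation: float  # cm^2/g at E*
    roi_set: tuple[str, ...]
    roi_residuals_hu: dict[str, float] = field(default_factory=dict)
    objective: str = "auto"
    objective_value: float = float("nan")

    def density_of_hu(self, hu):
        """Water-equivalent density (g/cm^3) for HU value(s)."""
        return (self.slope_a * np.asarray(hu, dtype=float) + self.intercept_b) / (
            self.water_mass_attenuation
        )

    def to_dict(self) -> dict:
        return {
            "effective_energy_kev": self.effective_energy,
            "slope_a_per_hu": self.slope_a,
            "intercept_b_per_cm": self.intercept_b,
            "water_mass_attenuation_cm2_g": self.water_mass_attenuation,
            "roi_set": list(self.roi_set),
            "roi_residuals_hu": dict(self.roi_residuals_hu),
            "objective": self.objective,
            "objective_value": self.objective_value,
        }


# ---------------------------------------------------------------------------
# ROI extraction
# ---------------------------------------------------------------------------

def extract_roi_samples(
    image: HUVolume,
    mask: np.ndarray,
    roi_map: Mapping[int, str],
    roi_set: Sequence[str],
    aggregate: str = "mean",
) -> list[RoiSample]:
    """Measure mean/SD HU for each material in ``roi_set``.

    ``roi_map`` maps mask label -> material name (aliases such as "muscle"
    and "bone" are accepted).  Raises listing every requested material that
    has no labelled voxels.
    """
    wanted = [canonical_material_name(m) for m in roi_set]
    by_material: dict[str, list[int]] = {}
    for label, material in roi_map.items():
        by_material.setdefault(canonical_material_name(material), []).append(int(label))

    present = set(np.unique(mask))
    samples, missing = [], []
    for material in wanted:
        labels = [l for l in by_material.get(material, []) if l in present]
        if not labels:
            missing.append(material)
            continue
        values = np.concatenate(
            [image.voxels[mask == l].ravel() for l in labels]
        )
        if aggregate == "mean":
            centre = float(values.mean())
        elif aggregate == "median":
            centre = float(np.median(values))
        else:
            raise ValueError(f"unknown aggregate '{aggregate}'")
        sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
        samples.append(RoiSample(material, centre, sd, int(values.size)))
    if missing:
        raise CalibrationError(
            f"materials missing from mask/roi_map: {', '.join(sorted(missing))}"
        )
    return samples


# ---------------------------------------------------------------------------
# effective-energy estimation
# ---------------------------------------------------------------------------

def _mu_vs_hu_fit(hu: np.ndarray, mu: np.ndarray) -> tuple[float, float, float]:
    """OLS of mu on HU -> (slope, intercept, residual sum of squares)."""
    spread = hu.max() - hu.min()
    if spread == 0:
        raise SingularFitError("all ROI mean HU values identical; cannot fit a line")
    # centred normal equations; exact for the 2-point case
    hu_c = hu - hu.mean()
    slope = float(hu_c @ (mu - mu.mean()) / (hu_c @ hu_c))
    intercept = float(mu.mean() - slope * hu.mean())
    resid = mu - (slope * hu + intercept)
    return slope, intercept, float(resid @ resid)


def _resolve_objective(objective: str, n_rois: int) -> str:
    if objective == "auto":
        return "mu_residual" if n_rois >= 3 else "hu_sse"
    if objective == "sse":  # CLI spelling
        return "hu_sse"
    if objective not in ("mu_residual", "hu_sse", "r2"):
        raise ValueError(f"unknown objective '{objective}'")
    return objective


def _validate_roi_set(rois: Sequence[RoiSample]) -> None:
    if not rois:
        raise CalibrationError("empty ROI list")
    names = {r.material for r in rois}
    if len(names) < 2:
        if names == {"air"}:
            raise DegenerateRoiSetError(
                "air alone is energy-insensitive (predicted HU is -1000 at all "
                "energies); supply at least one tissue ROI"
            )
        raise DegenerateRoiSetError(
            f"need >= 2 distinct materials, got {sorted(names)}"
        )
    if names <= {"air"}:
        raise DegenerateRoiSetError("ROI set contains no energy-sensitive material")


def energy_objective(
    rois: Sequence[RoiSample],
    materials: Mapping[str, MaterialSpec] | None = None,
    objective: str = "auto",
):
    """Return ``f(E) -> scalar`` for the chosen effective-energy objective."""
    materials = materials if materials is not None else load_material_library()
    _validate_roi_set(rois)
    kind = _resolve_objective(objective, len({r.material for r in rois}))
    specs = [materials[canonical_material_name(r.material)] for r in rois]
    hu = np.array([r.mean_hu for r in rois], dtype=float)
    air, water = materials["air"], materials["water"]

    if kind == "hu_sse":
        # the measured air ROI anchors the HU offset: predicted air is -1000
        # at every energy, so any common shift is removed before comparison
        air_hu = [h for h, m in zip(hu, specs) if m.name == "air"]
        shift = float(np.mean(air_hu) + 1000.0) if air_hu else 0.0

        def f(energy: float) -> float:
            pred = np.array(
                [predicted_hu(m, energy, air, water) for m in specs]
            )
            d = (hu - shift) - pred
            return float(d @ d)
    else:
        if len(rois) < 3:
            raise DegenerateRoiSetError(
                f"objective '{kind}' needs >= 3 ROIs (affine-invariant fit); "
                f"got {len(rois)} — use 'hu_sse' for 2-ROI sets"
            )

        def f(energy: float) -> float:
            mu = np.array([linear_attenuation(m, energy) for m in specs])
            _, _, rss = _mu_vs_hu_fit(hu, mu)
            if kind == "r2":
                tss = float(((mu - mu.mean()) ** 2).sum())
                return rss / tss if tss > 0 else 1.0
            return rss

    return f


def estimate_effective_energy(
    rois: Sequence[RoiSample],
    materials: Mapping[str, MaterialSpec] | None = None,
    search_range: tuple[float, float] = DEFAULT_ENERGY_RANGE,
    objective: str = "auto",
    refine_tol: float = 1e-6,
) -> float:
    """Estimate the effective scan energy E* (keV) from ROI HU measurements.

    A 1 keV grid scan over ``search_range`` locates the basin (ties broken
    toward the lower energy), followed by bounded scalar minimisation of the
    objective to well below 0.01 keV.
    """
    materials = materials if materials is not None else load_material_library()
    f = energy_objective(rois, materials, objective)

    lo, hi = float(search_range[0]), float(search_range[1])
    emin = max(m.curve.emin for m in materials.values())
    emax = min(m.curve.emax for m in materials.values())
    lo, hi = max(lo, emin), min(hi, emax)
    if not lo < hi:
        raise ValueError(f"empty energy search range [{lo}, {hi}] keV")

    grid = np.arange(lo, hi + 1e-9, 1.0)
    if grid[-1] < hi:
        grid = np.append(grid, hi)
    values = np.array([f(e) for e in grid])
    best = float(grid[int(np.argmin(values))])  # argmin -> first == lowest E

    a, b = max(lo, best - 1.5), min(hi, best + 1.5)
    res = minimize_scalar(f, bounds=(a, b), method="bounded", options={"xatol": refine_tol})
    e_star = float(res.x) if res.fun <= f(best) else best
    return e_star


# ---------------------------------------------------------------------------
# HU -> attenuation fit and density conversion
# ---------------------------------------------------------------------------

def fit_hu_to_attenuation(
    rois: Sequence[RoiSample],
    e_star: float,
    materials: Mapping[str, MaterialSpec] | None = None,
) -> tuple[float, float]:
    """OLS fit mu_m(E*) = a * mean_hu_m + b over the ROI set.

    Exactly interpolates when two ROIs are given.  Raises
    :class:`SingularFitError` when the HU values are all identical.
    """
    materials = materials if materials is not None else load_material_library()
    if len(rois) < 2:
        raise CalibrationError("need >= 2 ROIs to fit the HU->attenuation line")
    hu = np.array([r.mean_hu for r in rois], dtype=float)
    mu = np.array(
        [linear_attenuation(materials[canonical_material_name(r.material)], e_star) for r in rois]
    )
    slope, intercept, _ = _mu_vs_hu_fit(hu, mu)
    if slope <= 0:
        raise SingularFitError(
            f"fitted HU->attenuation slope is non-positive ({slope:g}); "
            "check ROI material assignments"
        )
    return slope, intercept


def build_calibration(
    rois: Sequence[RoiSample],
    materials: Mapping[str, MaterialSpec] | None = None,
    search_range: tuple[float, float] = DEFAULT_ENERGY_RANGE,
    objective: str = "auto",
) -> InternalCalibration:
    """Estimate E*, fit the affine map and assemble diagnostics."""
    materials = materials if materials is not None else load_material_library()
    e_star = estimate_effective_energy(rois, materials, search_range, objective)
    slope, intercept = fit_hu_to_attenuation(rois, e_star, materials)
    water_mu_rho = interpolate_mass_attenuation(materials["water"].curve, e_star)
    residuals = {}
    for r in rois:
        mu_m = linear_attenuation(materials[canonical_material_name(r.material)], e_star)
        residuals[r.material] = float(r.mean_hu - (mu_m - intercept) / slope)
    f = energy_objective(rois, materials, objective)
    return InternalCalibration(
        effective_energy=e_star,
        slope_a=slope,
        intercept_b=intercept,
        water_mass_attenuation=float(water_mu_rho),
        roi_set=tuple(r.material for r in rois),
        roi_residuals_hu=residuals,
        objective=objective,
        objective_value=float(f(e_star)),
    )


def calibrate_to_water_density(image: HUVolume, cal: InternalCalibration) -> DensityVolume:
    """Convert an HU volume to water-equivalent density, g/cm^3.

    rho_weq = (a*HU + b) / (mu/rho)_water(E*).  Negative values (air) are
    preserved — clamping would bias downstream agreement statistics.
    """
    rho = cal.density_of_hu(image.voxels)
    return DensityVolume(
        rho,
        spacing=image.spacing,
        affine=image.affine,
        units="g/cm^3",
        provenance={"method": "internal", **cal.to_dict()},
    )


def internal_calibrate(
    image: HUVolume,
    mask: np.ndarray,
    roi_map: Mapping[int, str],
    roi_set: Sequence[str] = ("air", "adipose"),
    materials: Mapping[str, MaterialSpec] | None = None,
    search_range: tuple[float, float] = DEFAULT_ENERGY_RANGE,
    objective: str = "auto",
    aggregate: str = "mean",
) -> tuple[InternalCalibration, DensityVolume]:
    """Full internal calibration of one scan.

    Measures ROI HU under the label mask, estimates E*, fits the HU->mu map
    and returns the calibration together with the water-equivalent density
    volume.
    """
    materials = materials if materials is not None else load_material_library()
    rois = extract_roi_samples(image, mask, roi_map, roi_set, aggregate)
    cal = build_calibration(rois, materials, search_range, objective)
    return cal, calibrate_to_water_density(image, cal)


# ---------------------------------------------------------------------------
# ROI-combination sweep
# ---------------------------------------------------------------------------

def roi_combination_sweep(
    image: HUVolume,
    mask: np.ndarray,
    roi_map: Mapping[int, str],
    sample_labels: Sequence[int],
    reference_densities: Sequence[float],
    combinations: Iterable[Sequence[str]] = PAPER_ROI_COMBINATIONS,
    materials: Mapping[str, MaterialSpec] | None = None,
    search_range: tuple[float, float] = DEFAULT_ENERGY_RANGE,
    objective: str = "auto",
    aggregate: str = "mean",
) -> pd.DataFrame:
    """Calibrate with each ROI combination and score against a reference.

    For every combination the scan is internally calibrated, sample-region
    mean densities are measured, and Bland-Altman bias and 95% limits of
    agreement versus ``reference_densities`` are reported.  One row per
    combination: roi_set, effective_energy_kev, bias, loa_halfwidth,
    mean_abs_error.
    """
    from .stats import bland_altman  # deferred: stats imports nothing from here

    reference = np.asarray(reference_densities, dtype=float)
    if len(sample_labels) != reference.size:
        raise ValueError("sample_labels and reference_densities lengths differ")
    rows = []
    for combo in combinations:
        cal, density = internal_calibrate(
            image, mask, roi_map, combo, materials, search_range, objective, aggregate
        )
        measured = np.array(
            [roi_statistics(density.voxels, mask, int(l))[0] for l in sample_labels]
        )
        report = bland_altman(measured, reference)
        rows.append(
            {
                "roi_set": ",".join(combo),
                "n_rois": len(combo),
                "effective_energy_kev": cal.effective_energy,
                "bias": report.bias,
                "loa_halfwidth": report.loa_halfwidth,
                "mean_abs_error": float(np.abs(measured - reference).mean()),
            }
        )
    return pd.DataFrame(rows)
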