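"""Reference-phantom density calibration.

The comparator for the internal method: a phantom with vials/rods of known
density scanned in the field of view.  HU is regressed on known density and
the resulting line rescales the whole image.  Two phantom flavours are
relevant here: a custom sucrose-water phantom (five vials, 1.00-1.11 g/ml,
output in g/cm^3) and a hydroxyapatite bone phantom (output in mgHA/cm^3 —
same fit, different units and scale).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .calibration import SingularFitError
from .volumes import DensityVolume, HUVolume, roi_statistics

__all__ = [
    "PhantomSpec",
    "PhantomCalibration",
    "SUCROSE_VIAL_DENSITIES",
    "fit_phantom_line",
    "apply_phantom_calibration",
    "phantom_calibrate",
]

#: Densities of the five sucrose-water vials, g/ml.
SUCROSE_VIAL_DENSITIES = (1.00, 1.01, 1.04, 1.06, 1.11)


@dataclass(frozen=True)
class PhantomSpec:
    """Known vial densities of a reference phantom and their mask labels."""

    vial_labels: tuple[int, ...]
    known_values: tuple[float, ...]
    units: str = "g/cm^3"
    name: str = "sucrose_water"

    def __post_init__(self) -> None:
        if len(self.vial_labels) < 2:
            raise ValueError("a phantom needs >= 2 vials")
        if len(self.vial_labels) != len(self.known_values):
            raise ValueError("vial_labels and known_values lengths differ")
        if len(set(self.vial_labels)) != len(self.vial_labels):
            raise ValueError("vial labels must be distinct")
        if any(b <= a for a, b in zip(self.known_values, self.known_values[1:])):
            raise ValueError("known_values must be strictly increasing")

    @classmethod
    def from_json(cls, path: str | Path) -> "PhantomSpec":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(
            vial_labels=tuple(int(l) for l in raw["vial_labels"]),
            known_values=tuple(float(v) for v in raw["known_values"]),
            units=raw.get("units", "g/cm^3"),
            name=raw.get("name", "phantom"),
        )

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "name": self.name,
                    "units": self.units,
                    "vial_labels": list(self.vial_labels),
                    "known_values": list(self.known_values),
                },
                fh,
                indent=2,
                sort_keys=True,
            )


@dataclass(frozen=True)
class PhantomCalibration:
    """Fitted phantom line: density = slope * HU + intercept."""

    slope: float
    intercept: float
    r_squared: float
    units: str = "g/cm^3"

    def to_dict(self) -> dict:
        return {
            "slope_per_hu": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "units": self.units,
        }


def fit_phantom_line(
    vial_samples: Sequence[tuple[float, float]],
    units: str = "g/cm^3",
) -> PhantomCalibration:
    """OLS of known density on mean vial HU.

    ``vial_samples`` is a sequence of (mean_hu, known_density) pairs.
    """
    if len(vial_samples) < 2:
        raise ValueError("need >= 2 vials to fit the phantom line")
    hu = np.array([s[0] for s in vial_samples], dtype=float)
    rho = np.array([s[1] for s in vial_samples], dtype=float)
    if hu.max() - hu.min() == 0:
        raise SingularFitError("all vial HU values identical; cannot fit phantom line")
    hu_c = hu - hu.mean()
    slope = float(hu_c @ (rho - rho.mean()) / (hu_c @ hu_c))
    intercept = float(rho.mean() - slope * hu.mean())
    resid = rho - (slope * hu + intercept)
    tss = float(((rho - rho.mean()) ** 2).sum())
    r2 = 1.0 if tss == 0 else 1.0 - float(resid @ resid) / tss
    return PhantomCalibration(slope, intercept, r2, units=units)


def apply_phantom_calibration(image: HUVolume, cal: PhantomCalibration) -> DensityVolume:
    """Rescale an HU volume with the fitted phantom line."""
    return DensityVolume(
        cal.slope * image.voxels + cal.intercept,
        spacing=image.spacing,
        affine=image.affine,
        units=cal.units,
        provenance={"method": "phantom", **cal.to_dict()},
    )


def phantom_calibrate(
    image: HUVolume,
    mask: np.ndarray,
    spec: PhantomSpec,
    aggregate: str = "mean",
) -> tuple[PhantomCalibration, DensityVolume]:
    """Measure vial HU under the mask, fit the line, rescale the image."""
    samples = []
    for label, rho in zip(spec.vial_labels, spec.known_values):
        mean_hu, _, _ = roi_statistics(image, mask, int(label), aggregate)
        samples.append((mean_hu, rho))
    cal = fit_phantom_line(samples, units=spec.units)
    return cal, apply_phantom_calibration(image, cal)
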