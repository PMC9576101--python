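"""Digital-scan generator with known ground truth.

Emulates the validation design used throughout the package: a field of view
containing calibration ROIs (air, adipose, blood, skeletal muscle, cortical
bone), a set of muscle samples spanning a range of fat infiltration, and an
optional sucrose-water phantom — imaged at a chosen true effective energy E0,
then distorted by a scanner-specific affine HU miscalibration (gain, offset)
plus additive Gaussian noise.  A battery of such (gain, offset, noise)
conditions stands in for the two-protocol x five-position acquisition design;
only the HU distortion varies across the battery, never the geometry or the
ground truth.

Simplifications relative to real CT: regions are homogeneous boxes/spheres
(no anatomy), there is no beam hardening, scatter or partial-volume blurring,
and sucrose solutions are modelled as water's mass attenuation scaled by the
solution density (adequate for dilute sucrose at diagnostic energies).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .materials import (
    MaterialSpec,
    canonical_material_name,
    interpolate_mass_attenuation,
    linear_attenuation,
    load_material_library,
)
from .phantom import SUCROSE_VIAL_DENSITIES, PhantomSpec
from .volumes import HUVolume

__all__ = [
    "Region",
    "ScanScenario",
    "SyntheticScan",
    "generate_scan",
    "generate_condition_battery",
    "default_scenario",
    "default_conditions",
]


@dataclass(frozen=True)
class Region:
    """One homogeneous labelled region in a synthetic scan.

    ``density`` overrides the material's nominal mass density (used for the
    sucrose vials: water attenuation scaled by solution density).
    ``fat_fraction`` linearly mixes adipose into the region's linear
    attenuation, modelling fat-infiltrated muscle by volume fraction.
    ``role`` tags how the region is used downstream: "roi" (calibration ROI),
    "sample" (measured muscle sample), "vial" (phantom vial).
    """

    label: int
    material: str
    center: tuple[float, float, float]
    size: tuple[float, float, float] | float
    shape: str = "box"  # box (size = half-extents, voxels) | sphere (radius)
    density: float | None = None
    fat_fraction: float = 0.0
    role: str = "roi"
    name: str = ""

    def __post_init__(self) -> None:
        if self.label <= 0:
            raise ValueError("region labels must be positive (0 is background)")
        if self.shape not in ("box", "sphere"):
            raise ValueError(f"unknown shape '{self.shape}'")
        if not 0.0 <= self.fat_fraction <= 1.0:
            raise ValueError("fat_fraction must be in [0, 1]")
        if self.density is not None and self.density <= 0:
            raise ValueError("explicit density must be > 0")


@dataclass(frozen=True)
class ScanScenario:
    """Everything needed to render one synthetic scan deterministically."""

    regions: tuple[Region, ...]
    true_energy: float = 70.0  # keV
    hu_gain: float = 1.0
    hu_offset: float = 0.0  # HU
    noise_sd: float = 0.0  # HU
    seed: int = 0
    grid_shape: tuple[int, int, int] = (64, 64, 6)
    spacing: tuple[float, float, float] = (1.0, 1.0, 2.5)

    def __post_init__(self) -> None:
        if self.hu_gain <= 0:
            raise ValueError("hu_gain must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        labels = [r.label for r in self.regions]
        if len(set(labels)) != len(labels):
            raise ValueError("region labels must be unique")


@dataclass
class SyntheticScan:
    """Rendered scan plus its ground truth."""

    scenario: ScanScenario
    image: HUVolume
    mask: np.ndarray
    ground_truth: pd.DataFrame  # label, name, material, role, ideal_hu, mu, weq_density
    roi_map: dict[int, str]

    @property
    def sample_labels(self) -> list[int]:
        return [int(r.label) for r in self.scenario.regions if r.role == "sample"]

    @property
    def vial_labels(self) -> list[int]:
        return [int(r.label) for r in self.scenario.regions if r.role == "vial"]

    def phantom_spec(self, units: str = "g/cm^3") -> PhantomSpec:
        vials = [r for r in self.scenario.regions if r.role == "vial"]
        if len(vials) < 2:
            raise ValueError("scenario has no phantom (needs >= 2 vial regions)")
        vials = sorted(vials, key=lambda r: r.density)
        return PhantomSpec(
            vial_labels=tuple(r.label for r in vials),
            known_values=tuple(r.density for r in vials),
            units=units,
            name="synthetic_sucrose_water",
        )


def _region_mask(region: Region, shape: tuple[int, int, int]) -> np.ndarray:
    idx = np.indices(shape, dtype=float)
    c = np.asarray(region.center, dtype=float)
    if region.shape == "box":
        half = np.atleast_1d(np.asarray(region.size, dtype=float))
        if half.size == 1:
            half = np.repeat(half, 3)
        inside = np.all(
            [np.abs(idx[a] - c[a]) <= half[a] for a in range(3)], axis=0
        )
    else:
        r = float(np.asarray(region.size).ravel()[0])
        inside = sum((idx[a] - c[a]) ** 2 for a in range(3)) <= r**2
    if not inside.any():
        raise ValueError(f"region '{region.name or region.label}' covers no voxels")
    return inside


def region_linear_attenuation(
    region: Region, energy: float, materials: Mapping[str, MaterialSpec]
) -> float:
    """Ground-truth linear attenuation (1/cm) of a region at ``energy``."""
    mat = materials[canonical_material_name(region.material)]
    mu_rho = interpolate_mass_attenuation(mat.curve, energy)
    mu = mu_rho * (region.density if region.density is not None else mat.rho_ref)
    if region.fat_fraction > 0.0:
        mu_fat = linear_attenuation(materials["adipose"], energy)
        mu = (1.0 - region.fat_fraction) * mu + region.fat_fraction * mu_fat
    return float(mu)


def generate_scan(
    scenario: ScanScenario,
    materials: Mapping[str, MaterialSpec] | None = None,
) -> SyntheticScan:
    """Render a scenario into an HU volume, label mask and ground-truth table.

    Each region's ideal HU is its monoenergetic Hounsfield value at the true
    energy E0; the stored voxel value is
    ``hu_gain * ideal + hu_offset + N(0, noise_sd)``, reproducible under the
    scenario seed.  Background voxels are air.  Overlapping regions raise.
    The ground-truth table reports, per region, the ideal HU, the linear
    attenuation mu(E0) and the water-equivalent density mu(E0)/(mu/rho)_w(E0).
    """
    materials = materials if materials is not None else load_material_library()
    e0 = scenario.true_energy
    mu_w = linear_attenuation(materials["water"], e0)
    mu_a = linear_attenuation(materials["air"], e0)
    mu_rho_w = interpolate_mass_attenuation(materials["water"].curve, e0)

    mask = np.zeros(scenario.grid_shape, dtype=np.int32)
    ideal = np.full(scenario.grid_shape, -1000.0)  # background = air
    rows = []
    for region in scenario.regions:
        inside = _region_mask(region, scenario.grid_shape)
        if np.any(mask[inside] != 0):
            clashing = sorted(set(mask[inside].ravel()) - {0})
            raise ValueError(
                f"region '{region.name or region.label}' overlaps labels {clashing}"
            )
        mu = region_linear_attenuation(region, e0, materials)
        hu = 1000.0 * (mu - mu_w) / (mu_w - mu_a)
        mask[inside] = region.label
        ideal[inside] = hu
        rows.append(
            {
                "label": region.label,
                "name": region.name or canonical_material_name(region.material),
                "material": canonical_material_name(region.material),
                "role": region.role,
                "fat_fraction": region.fat_fraction,
                "ideal_hu": hu,
                "mu_per_cm": mu,
                "weq_density": mu / mu_rho_w,
            }
        )

    rng = np.random.default_rng(scenario.seed)
    stored = scenario.hu_gain * ideal + scenario.hu_offset
    if scenario.noise_sd > 0:
        stored = stored + rng.normal(0.0, scenario.noise_sd, size=stored.shape)

    roi_map = {
        int(r.label): canonical_material_name(r.material)
        for r in scenario.regions
        if r.role == "roi" and r.fat_fraction == 0.0 and r.density is None
    }
    image = HUVolume(stored, spacing=scenario.spacing)
    return SyntheticScan(scenario, image, mask, pd.DataFrame(rows), roi_map)


def generate_condition_battery(
    base: ScanScenario,
    conditions: Sequence[tuple[float, float, float]],
    materials: Mapping[str, MaterialSpec] | None = None,
) -> list[SyntheticScan]:
    """Render the same geometry under several (gain, offset, noise_sd) triples.

    Geometry, true energy and ground truth are shared; only the HU distortion
    and the noise stream differ (each condition gets its own derived seed).
    """
    if len(conditions) < 2:
        raise ValueError("a condition battery needs >= 2 conditions")
    materials = materials if materials is not None else load_material_library()
    scans = []
    for i, (gain, offset, noise_sd) in enumerate(conditions):
        scenario = replace(
            base,
            hu_gain=float(gain),
            hu_offset=float(offset),
            noise_sd=float(noise_sd),
            seed=(base.seed + 1009 * i) % (2**31 - 1),
        )
        scans.append(generate_scan(scenario, materials))
    return scans


# ---------------------------------------------------------------------------
# default study layout
# ---------------------------------------------------------------------------

def default_scenario(
    true_energy: float = 70.0,
    n_samples: int = 10,
    fat_fraction_range: tuple[float, float] = (0.0, 0.15),
    include_phantom: bool = True,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> ScanScenario:
    """A scan layout mirroring the validation setup.

    Five pure-material calibration ROIs, ``n_samples`` muscle samples whose
    fat infiltration spans ``fat_fraction_range`` (mild myosteatosis range),
    and optionally a five-vial sucrose-water phantom.  Regions are 6x6 voxel
    boxes on a 64x64x6 grid.
    """
    materials = ("air", "adipose", "blood", "skeletal_muscle", "cortical_bone")
    regions: list[Region] = []
    label = 1

    def place(i: int) -> tuple[float, float, float]:
        row, col = divmod(i, 8)
        return (8.0 * col + 4.0, 8.0 * row + 4.0, 2.5)

    slot = 0
    for mat in materials:
        regions.append(
            Region(
                label=label,
                material=mat,
                center=place(slot),
                size=(3.0, 3.0, 2.0),
                role="roi",
                name=mat,
            )
        )
        label += 1
        slot += 1
    fracs = np.linspace(*fat_fraction_range, n_samples)
    for i, f in enumerate(fracs):
        regions.append(
            Region(
                label=label,
                material="skeletal_muscle",
                center=place(slot),
                size=(3.0, 3.0, 2.0),
                fat_fraction=float(f),
                role="sample",
                name=f"sample_{i + 1:02d}",
            )
        )
        label += 1
        slot += 1
    if include_phantom:
        for i, rho in enumerate(SUCROSE_VIAL_DENSITIES):
            regions.append(
                Region(
                    label=label,
                    material="water",
                    center=place(slot),
                    size=(3.0, 3.0, 2.0),
                    density=float(rho),
                    role="vial",
                    name=f"vial_{i + 1}",
                )
            )
            label += 1
            slot += 1
    return ScanScenario(
        regions=tuple(regions),
        true_energy=true_energy,
        noise_sd=noise_sd,
        seed=seed,
    )


def scenario_to_dict(scenario: ScanScenario) -> dict:
    """Plain-dict form of a scenario (JSON/YAML-serialisable)."""
    return {
        "true_energy": float(scenario.true_energy),
        "hu_gain": float(scenario.hu_gain),
        "hu_offset": float(scenario.hu_offset),
        "noise_sd": float(scenario.noise_sd),
        "seed": int(scenario.seed),
        "grid_shape": [int(n) for n in scenario.grid_shape],
        "spacing": [float(s) for s in scenario.spacing],
        "regions": [
            {
                "label": int(r.label),
                "material": str(r.material),
                "center": [float(c) for c in r.center],
                "size": [float(s) for s in np.atleast_1d(r.size)],
                "shape": r.shape,
                "density": None if r.density is None else float(r.density),
                "fat_fraction": float(r.fat_fraction),
                "role": r.role,
                "name": r.name,
            }
            for r in scenario.regions
        ],
    }


def scenario_from_dict(raw: Mapping) -> ScanScenario:
    regions = tuple(
        Region(
            label=int(r["label"]),
            material=str(r["material"]),
            center=tuple(float(c) for c in r["center"]),
            size=tuple(float(s) for s in np.atleast_1d(r["size"])),
            shape=r.get("shape", "box"),
            density=None if r.get("density") is None else float(r["density"]),
            fat_fraction=float(r.get("fat_fraction", 0.0)),
            role=r.get("role", "roi"),
            name=r.get("name", ""),
        )
        for r in raw["regions"]
    )
    return ScanScenario(
        regions=regions,
        true_energy=float(raw.get("true_energy", 70.0)),
        hu_gain=float(raw.get("hu_gain", 1.0)),
        hu_offset=float(raw.get("hu_offset", 0.0)),
        noise_sd=float(raw.get("noise_sd", 0.0)),
        seed=int(raw.get("seed", 0)),
        grid_shape=tuple(int(n) for n in raw.get("grid_shape", (64, 64, 6))),
        spacing=tuple(float(s) for s in raw.get("spacing", (1.0, 1.0, 2.5))),
    )


def default_conditions(
    n: int = 10,
    noise_sd: float = 0.0,
    seed: int = 0,
    gain_range: tuple[float, float] = (0.93, 1.07),
    offset_range: tuple[float, float] = (-30.0, 30.0),
) -> list[tuple[float, float, float]]:
    """Draw ``n`` (gain, offset, noise_sd) scan conditions, reproducibly.

    The default ranges exaggerate real protocol/position effects so that the
    raw-HU instability is unmistakable next to calibrated density.
    """
    rng = np.random.default_rng(seed)
    gains = rng.uniform(*gain_range, size=n)
    offsets = rng.uniform(*offset_range, size=n)
    return [(float(g), float(o), float(noise_sd)) for g, o in zip(gains, offsets)]
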