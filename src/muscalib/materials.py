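"""Reference materials: mass-attenuation curves, densities and forward physics.

The forward model used throughout the package is monoenergetic: a scan is
summarised by a single *effective energy* E (keV), and a material's linear
attenuation at that energy is ``mu = (mu/rho)(E) * rho``.  Hounsfield units
follow the scanner definition, anchored so that water maps to 0 HU and air to
-1000 HU at the same energy.

Curves are tabulated NIST mass attenuation coefficients (cm^2/g) on a
10-200 keV grid and are interpolated log-log, the standard choice for
attenuation data, which vary by two orders of magnitude over the
photoelectric-dominated decade.  No extrapolation is performed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np

__all__ = [
    "AttenuationCurve",
    "MaterialSpec",
    "EnergyRangeError",
    "MATERIAL_NAMES",
    "interpolate_mass_attenuation",
    "linear_attenuation",
    "predicted_hu",
    "load_material_library",
    "canonical_material_name",
]

#: Canonical material names recognised by the packaged manifest.
MATERIAL_NAMES = (
    "air",
    "water",
    "adipose",
    "blood",
    "skeletal_muscle",
    "cortical_bone",
)


class EnergyRangeError(ValueError):
    """Requested energy lies outside a material's tabulated grid."""


@dataclass(frozen=True)
class AttenuationCurve:
    """Tabulated mass attenuation coefficient curve.

    Parameters
    ----------
    energies : ndarray
        Photon energies in keV, strictly increasing.
    mass_attenuation : ndarray
        mu/rho in cm^2/g at each grid energy, strictly positive.
    label : str
        Name used in error messages (usually the material name).
    """

    energies: np.ndarray
    mass_attenuation: np.ndarray
    label: str = "unnamed"

    def __post_init__(self) -> None:
        e = np.asarray(self.energies, dtype=float)
        mu = np.asarray(self.mass_attenuation, dtype=float)
        object.__setattr__(self, "energies", e)
        object.__setattr__(self, "mass_attenuation", mu)
        if e.ndim != 1 or mu.shape != e.shape or e.size < 2:
            raise ValueError("curve needs matching 1-D grids with >= 2 points")
        if np.any(e <= 0) or np.any(mu <= 0):
            raise ValueError(f"{self.label}: energies and mu/rho must be > 0")
        if np.any(np.diff(e) <= 0):
            # rejects duplicate energies too: soft-tissue tables have no
            # absorption edges in 10-200 keV, so duplicates are an input error
            raise ValueError(f"{self.label}: energy grid must be strictly increasing")
        if e[0] > 10.0 or e[-1] < 200.0:
            raise ValueError(
                f"{self.label}: grid must cover at least 10-200 keV "
                f"(got {e[0]:g}-{e[-1]:g})"
            )

    @property
    def emin(self) -> float:
        return float(self.energies[0])

    @property
    def emax(self) -> float:
        return float(self.energies[-1])


@dataclass(frozen=True)
class MaterialSpec:
    """A reference material: name, nominal density and attenuation curve."""

    name: str
    rho_ref: float  # g/cm^3
    curve: AttenuationCurve
    source: str = ""

    def __post_init__(self) -> None:
        if self.name == "air":
            if not 0.0 < self.rho_ref < 0.01:
                raise ValueError("air density must be in (0, 0.01) g/cm^3")
        elif self.name == "water":
            if self.rho_ref != 1.0:
                raise ValueError("water reference density must be exactly 1.000 g/cm^3")
        elif self.rho_ref <= 0:
            raise ValueError(f"{self.name}: rho_ref must be > 0")

    def with_density(self, rho_ref: float) -> "MaterialSpec":
        return replace(self, rho_ref=rho_ref)


def interpolate_mass_attenuation(curve: AttenuationCurve, energy) -> float | np.ndarray:
    """Interpolate mu/rho (cm^2/g) at ``energy`` keV, log-log linear.

    Exactly reproduces tabulated values at grid knots; raises
    :class:`EnergyRangeError` outside the grid (no extrapolation).
    Accepts a scalar or an array of energies.
    """
    e = np.asarray(energy, dtype=float)
    if np.any(e < curve.emin) or np.any(e > curve.emax):
        raise EnergyRangeError(
            f"energy {np.min(e):g}-{np.max(e):g} keV outside tabulated range "
            f"[{curve.emin:g}, {curve.emax:g}] keV for '{curve.label}'"
        )
    out = np.exp(
        np.interp(np.log(e), np.log(curve.energies), np.log(curve.mass_attenuation))
    )
    return float(out) if np.isscalar(energy) or e.ndim == 0 else out


def linear_attenuation(material: MaterialSpec, energy) -> float | np.ndarray:
    """Linear attenuation coefficient mu = (mu/rho) * rho_ref, in 1/cm."""
    return interpolate_mass_attenuation(material.curve, energy) * material.rho_ref


def predicted_hu(
    material: MaterialSpec,
    energy,
    air: MaterialSpec,
    water: MaterialSpec,
) -> float | np.ndarray:
    """Ideal Hounsfield value of ``material`` at ``energy`` keV.

    HU = 1000 * (mu_m - mu_water) / (mu_water - mu_air); by construction water
    is exactly 0 HU and air exactly -1000 HU at every in-range energy.
    """
    mu_m = linear_attenuation(material, energy)
    mu_w = linear_attenuation(water, energy)
    mu_a = linear_attenuation(air, energy)
    # ratio first: (mu_a-mu_w)/(mu_w-mu_a) is exactly -1 in IEEE arithmetic,
    # so the air anchor lands on -1000 to the last bit
    return 1000.0 * ((mu_m - mu_w) / (mu_w - mu_a))


# ---------------------------------------------------------------------------
# packaged material library
# ---------------------------------------------------------------------------

def _read_table(path: Path) -> tuple[np.ndarray, np.ndarray]:
    data = np.loadtxt(path, comments="#")
    return data[:, 0], data[:, 1]


def canonical_material_name(name: str, aliases: dict[str, str] | None = None) -> str:
    """Map common aliases ('muscle', 'bone', 'fat') onto canonical names."""
    aliases = aliases if aliases is not None else _default_aliases()
    name = name.strip().lower()
    return aliases.get(name, name)


def _manifest_dir() -> Path:
    return Path(resources.files("muscalib") / "data")


def _default_aliases() -> dict[str, str]:
    with open(_manifest_dir() / "materials.json") as fh:
        return json.load(fh).get("aliases", {})


def load_material_library(
    manifest_path: str | Path | None = None,
    density_overrides: dict[str, float] | None = None,
) -> dict[str, MaterialSpec]:
    """Load the material library from a JSON manifest.

    The manifest maps material name -> ``{"table": <tsv file>, "rho_ref": g/cm^3}``;
    table paths are resolved relative to the manifest.  Without arguments the
    packaged NIST/ICRU-44 library is returned.  ``density_overrides`` replaces
    nominal densities by material name (aliases accepted).
    """
    path = Path(manifest_path) if manifest_path is not None else _manifest_dir() / "materials.json"
    with open(path) as fh:
        manifest = json.load(fh)
    aliases = manifest.get("aliases", {})
    library: dict[str, MaterialSpec] = {}
    for name, entry in manifest["materials"].items():
        energies, mu = _read_table(path.parent / entry["table"])
        curve = AttenuationCurve(energies, mu, label=name)
        library[name] = MaterialSpec(
            name=name,
            rho_ref=float(entry["rho_ref"]),
            curve=curve,
            source=entry["table"],
        )
    if density_overrides:
        for name, rho in density_overrides.items():
            key = canonical_material_name(name, aliases)
            if key not in library:
                raise KeyError(f"unknown material '{name}' in density_overrides")
            library[key] = library[key].with_density(float(rho))
    return library
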