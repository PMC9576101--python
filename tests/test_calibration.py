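"""Internal calibration: effective energy, HU->mu fit, density conversion."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from muscalib import (
    DegenerateRoiSetError,
    HUVolume,
    RoiSample,
    SingularFitError,
    build_calibration,
    calibrate_to_water_density,
    default_scenario,
    estimate_effective_energy,
    fit_hu_to_attenuation,
    generate_scan,
    internal_calibrate,
    linear_attenuation,
    predicted_hu,
    roi_combination_sweep,
)
from muscalib.calibration import CalibrationError, extract_roi_samples

from conftest import sample_means


def ideal_rois(materials, names, energy, gain=1.0, offset=0.0):
    """Noise-free ROI samples forward-modelled at a given true energy."""
    air, water = materials["air"], materials["water"]
    return [
        RoiSample(n, gain * predicted_hu(materials[n], energy, air, water) + offset)
        for n in names
    ]


ROI_SETS = [
    ("air", "adipose"),
    ("air", "blood"),
    ("air", "adipose", "blood"),
    ("air", "adipose", "blood", "skeletal_muscle", "cortical_bone"),
]


@pytest.mark.parametrize("e0", [50.0, 55.0, 70.0, 90.0, 120.0, 140.0])
@pytest.mark.parametrize("roi_set", ROI_SETS, ids=lambda s: "+".join(s))
def test_effective_energy_recovered_from_ideal_rois(materials, e0, roi_set):
    rois = ideal_rois(materials, roi_set, e0)
    e_star = estimate_effective_energy(rois, materials)
    assert abs(e_star - e0) <= 0.02


def test_degenerate_roi_sets_raise(materials):
    with pytest.raises(DegenerateRoiSetError, match="air"):
        estimate_effective_energy([RoiSample("air", -1000.0)], materials)
    with pytest.raises(CalibrationError, match="empty"):
        estimate_effective_energy([], materials)
    with pytest.raises(DegenerateRoiSetError):
        estimate_effective_energy([RoiSample("skeletal_muscle", 55.0)], materials)


def test_two_point_fit_reproduces_both_materials_exactly(materials):
    e0 = 70.0
    rois = ideal_rois(materials, ("air", "adipose"), e0)
    slope, intercept = fit_hu_to_attenuation(rois, e0, materials)
    for r in rois:
        mu = linear_attenuation(materials[r.material], e0)
        assert slope * r.mean_hu + intercept == pytest.approx(mu, rel=1e-12)


def test_five_roi_fit_collapses_to_two_roi_fit_on_collinear_data(materials):
    """Noise-free ideal HUs lie on one line; OLS and 2-point fits coincide."""
    e0 = 80.0
    five = ideal_rois(materials, ROI_SETS[3], e0)
    two = ideal_rois(materials, ("air", "adipose"), e0)
    a5, b5 = fit_hu_to_attenuation(five, e0, materials)
    a2, b2 = fit_hu_to_attenuation(two, e0, materials)
    assert a5 == pytest.approx(a2, rel=1e-9)
    assert b5 == pytest.approx(b2, abs=1e-12)
    cal = build_calibration(five, materials)
    assert all(abs(r) < 1e-6 for r in cal.roi_residuals_hu.values())


def test_identical_hu_values_are_singular(materials):
    rois = [RoiSample("adipose", 50.0), RoiSample("blood", 50.0)]
    with pytest.raises(SingularFitError):
        fit_hu_to_attenuation(rois, 70.0, materials)


@pytest.mark.parametrize("e0", [40.0, 70.0, 140.0])
@pytest.mark.parametrize("roi_set", ROI_SETS, ids=lambda s: "+".join(s))
def test_roundtrip_density_recovery(materials, e0, roi_set):
    """Noise-free forward-simulated scans are inverted to machine precision."""
    scan = generate_scan(default_scenario(true_energy=e0), materials)
    cal, density = internal_calibrate(scan.image, scan.mask, scan.roi_map, roi_set, materials)
    assert abs(cal.effective_energy - e0) <= 0.02
    gt = scan.ground_truth.set_index("label")
    labels = scan.sample_labels
    got = sample_means(density.voxels, scan.mask, labels)
    want = gt.loc[labels, "weq_density"].to_numpy()
    assert np.max(np.abs(got / want - 1.0)) < 1e-6


@settings(max_examples=20, deadline=None, derandomize=True)
@given(
    gain=st.floats(0.85, 1.18, allow_nan=False),
    offset=st.floats(-40.0, 40.0, allow_nan=False),
)
def test_affine_miscalibration_is_absorbed_with_three_rois(gain, offset):
    """Scanner gain/offset distortion leaves the density output unchanged."""
    from muscalib import load_material_library

    materials = load_material_library()
    scenario = default_scenario(true_energy=70.0)
    clean = generate_scan(scenario, materials)
    warped = generate_scan(replace(scenario, hu_gain=gain, hu_offset=offset), materials)
    roi_set = ("air", "adipose", "blood")
    _, d0 = internal_calibrate(clean.image, clean.mask, clean.roi_map, roi_set, materials)
    _, d1 = internal_calibrate(warped.image, warped.mask, warped.roi_map, roi_set, materials)
    assert np.max(np.abs(d1.voxels - d0.voxels)) < 1e-6


@pytest.mark.parametrize("roi_set", [("air", "adipose"), ("air", "blood")])
def test_hu_offset_is_absorbed_by_the_air_anchor_with_two_rois(materials, roi_set):
    scenario = default_scenario(true_energy=70.0)
    clean = generate_scan(scenario, materials)
    shifted = generate_scan(replace(scenario, hu_offset=-18.0), materials)
    c0, d0 = internal_calibrate(clean.image, clean.mask, clean.roi_map, roi_set, materials)
    c1, d1 = internal_calibrate(shifted.image, shifted.mask, shifted.roi_map, roi_set, materials)
    assert abs(c1.effective_energy - c0.effective_energy) <= 0.02
    assert np.max(np.abs(d1.voxels - d0.voxels)) < 1e-6


def test_noise_perturbs_energy_estimate_continuously(materials):
    """Small ROI noise produces a bounded, centred spread of E* and density."""
    e0 = 70.0
    base = ideal_rois(materials, ("air", "adipose", "blood"), e0)
    rng = np.random.default_rng(2024)
    energies, densities = [], []
    for _ in range(120):
        noisy = [
            RoiSample(r.material, r.mean_hu + rng.normal(0.0, 0.5), 0.5, 196)
            for r in base
        ]
        cal = build_calibration(noisy, materials)
        energies.append(cal.effective_energy)
        densities.append(float(cal.density_of_hu(53.2)))
    energies, densities = np.asarray(energies), np.asarray(densities)
    assert np.all(np.abs(energies - e0) < 15.0)  # no wild jumps across seeds
    assert np.std(densities) < 0.02
    assert abs(np.mean(densities) - np.median(densities)) < 0.005


def test_water_hu_maps_to_unit_density(materials):
    rois = ideal_rois(materials, ("air", "adipose", "blood"), 70.0)
    cal = build_calibration(rois, materials)
    water_hu = predicted_hu(materials["water"], cal.effective_energy, materials["air"], materials["water"])
    assert float(cal.density_of_hu(water_hu)) == pytest.approx(1.0, abs=1e-9)


def test_all_air_volume_maps_to_near_zero_density(materials):
    rois = ideal_rois(materials, ("air", "adipose"), 70.0)
    cal = build_calibration(rois, materials)
    volume = HUVolume(np.full((8, 8, 4), -1000.0))
    density = calibrate_to_water_density(volume, cal)
    assert np.all(np.abs(density.voxels) < 0.01)
    assert density.units == "g/cm^3"
    assert density.voxels.shape == volume.shape


def test_missing_roi_material_is_reported(materials, scan70):
    with pytest.raises(CalibrationError, match="cortical_bone"):
        extract_roi_samples(
            scan70.image, scan70.mask, {1: "air", 2: "adipose"}, ("air", "adipose", "bone")
        )


def test_roi_aggregate_median_option(materials, scan70):
    samples = extract_roi_samples(
        scan70.image, scan70.mask, scan70.roi_map, ("air", "adipose"), aggregate="median"
    )
    assert {s.material for s in samples} == {"air", "adipose"}
    with pytest.raises(ValueError, match="aggregate"):
        extract_roi_samples(scan70.image, scan70.mask, scan70.roi_map, ("air",), aggregate="mode")


class TestRoiCombinationSweep:
    def test_ideal_scan_gives_zero_bias_for_all_five_subsets(self, materials, scan70):
        gt = scan70.ground_truth.set_index("label")
        labels = scan70.sample_labels
        reference = gt.loc[labels, "weq_density"].to_numpy()
        table = roi_combination_sweep(
            scan70.image, scan70.mask, scan70.roi_map, labels, reference, materials=materials
        )
        assert len(table) == 5
        assert np.all(np.abs(table["bias"]) < 1e-8)

    def test_biased_bone_reference_hurts_bone_containing_subsets(self, materials, scan70):
        from muscalib import load_material_library

        gt = scan70.ground_truth.set_index("label")
        labels = scan70.sample_labels
        reference = gt.loc[labels, "weq_density"].to_numpy()
        perturbed = load_material_library(
            density_overrides={"cortical_bone": materials["cortical_bone"].rho_ref * 1.05}
        )
        table = roi_combination_sweep(
            scan70.image, scan70.mask, scan70.roi_map, labels, reference, materials=perturbed
        )
        has_bone = table["roi_set"].str.contains("cortical_bone")
        assert np.abs(table.loc[has_bone, "bias"]).min() > np.abs(
            table.loc[~has_bone, "bias"]
        ).max()

    def test_reference_equal_to_own_output_is_perfect_agreement(self, materials, scan70):
        labels = scan70.sample_labels
        _, density = internal_calibrate(
            scan70.image, scan70.mask, scan70.roi_map, ("air", "adipose"), materials
        )
        own = sample_means(density.voxels, scan70.mask, labels)
        table = roi_combination_sweep(
            scan70.image, scan70.mask, scan70.roi_map, labels, own,
            combinations=[("air", "adipose")], materials=materials,
        )
        assert table["bias"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert table["loa_halfwidth"].iloc[0] == pytest.approx(0.0, abs=1e-12)
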