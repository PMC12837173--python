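"""ETDRS sector geometry: partition, analytic areas, laterality, extraction."""

import math

import numpy as np
import pytest

from octaquant.core import GridClippedError, ImageSpec
from octaquant.etdrs import (
    QUADRANTS,
    build_region_masks,
    center_grid,
    extract_region_densities,
    region_labels,
)
from octaquant.skeleton import skeletonize_mask
from octaquant.synthetic import VesselSimConfig, generate_angiogram


def test_onh_masks_partition_annulus(onh_spec):
    """The 8 ONH masks tile exactly the rasterized annulus, pairwise disjoint."""
    grid = center_grid(onh_spec)
    masks = build_region_masks(onh_spec, grid)
    assert len(masks) == 8
    dx, dy = onh_spec.pixel_centers_mm(grid.center_px)
    r = np.hypot(dx, dy)
    annulus = (r > grid.r_center) & (r <= grid.r_outer)
    union = np.zeros(onh_spec.shape, dtype=bool)
    total = 0
    for m in masks.values():
        assert not (union & m).any()
        union |= m
        total += m.sum()
    np.testing.assert_array_equal(union, annulus)
    assert total == annulus.sum()


def test_sector_areas_match_analytic_within_1pct():
    spec = ImageSpec(512, 512, 6.0, "onh")
    grid = center_grid(spec)
    masks = build_region_masks(spec, grid)
    inner_mm2 = math.pi * (grid.r_inner**2 - grid.r_center**2) / 4.0
    outer_mm2 = math.pi * (grid.r_outer**2 - grid.r_inner**2) / 4.0
    for (q, ring), mask in masks.items():
        analytic = inner_mm2 if ring == "inner" else outer_mm2
        raster = mask.sum() * spec.mm_per_px**2
        assert abs(raster - analytic) / analytic < 0.01, (q, ring)


def test_macula_grid_is_four_inner_regions(macula_spec):
    masks = build_region_masks(macula_spec, center_grid(macula_spec))
    assert set(masks) == {(q, "inner") for q in QUADRANTS}
    assert region_labels("macula") == [(q, "inner") for q in QUADRANTS]


def test_laterality_flips_nasal_temporal(macula_spec):
    """OD: temporal on the image left; OS mirrors. Superior/inferior unaffected."""
    od = build_region_masks(macula_spec, center_grid(macula_spec))
    os_spec = ImageSpec(256, 256, 3.0, "macula", "OS")
    os_ = build_region_masks(os_spec, center_grid(os_spec))
    w = macula_spec.width_px
    xs = np.arange(w) + 0.5
    left = xs < w / 2
    od_temporal_cols = np.where(od[("temporal", "inner")].any(axis=0))[0]
    assert (od_temporal_cols + 0.5 < w / 2).all()  # OD temporal entirely on the left
    np.testing.assert_array_equal(od[("temporal", "inner")], os_[("nasal", "inner")])
    np.testing.assert_array_equal(od[("nasal", "inner")], os_[("temporal", "inner")])
    np.testing.assert_array_equal(od[("superior", "inner")], os_[("superior", "inner")])


def test_rotation_permutes_quadrant_densities(onh_spec, rng):
    """A 90-deg rotation about the grid center permutes quadrant densities:
    nasal -> superior -> temporal -> inferior -> nasal (OD map)."""
    skel = rng.random(onh_spec.shape) < 0.1
    grid = center_grid(onh_spec)
    d0 = extract_region_densities(skel, grid, onh_spec).set_index(["quadrant", "ring"])
    d1 = extract_region_densities(np.rot90(skel), grid, onh_spec).set_index(["quadrant", "ring"])
    permutation = {"nasal": "superior", "superior": "temporal",
                   "temporal": "inferior", "inferior": "nasal"}
    for src, dst in permutation.items():
        for ring in ("inner", "outer"):
            assert d1.loc[(dst, ring), "density"] == pytest.approx(
                d0.loc[(src, ring), "density"])


def test_center_grid_offsets(onh_spec):
    assert center_grid(onh_spec).center_px == (128.0, 128.0)
    g = center_grid(onh_spec, offset_px=(10.0, 0.0))
    assert g.center_px == (138.0, 128.0)
    g_back = center_grid(onh_spec, offset_px=(10.0 - 10.0, 0.0))
    assert g_back.center_px == center_grid(onh_spec).center_px
    with pytest.raises(ValueError):
        center_grid(onh_spec, offset_px=(200.0, 0.0))


def test_large_offset_clips_grid(onh_spec):
    with pytest.raises(GridClippedError):
        build_region_masks(onh_spec, center_grid(onh_spec, offset_px=(60.0, 0.0)))


def test_centering_jitter_robustness(onh_spec):
    """2-px centering jitter moves each regional density by < 5% relative."""
    img, truth = generate_angiogram(onh_spec, VesselSimConfig(seed=21, noise_sd=0.0))
    skel = skeletonize_mask(truth.vessel_mask).skeleton
    base = extract_region_densities(skel, center_grid(onh_spec), onh_spec)
    jit = extract_region_densities(skel, center_grid(onh_spec, offset_px=(2.0, -2.0)), onh_spec)
    merged = base.merge(jit, on=["quadrant", "ring"], suffixes=("_0", "_1"))
    rel = (merged["density_1"] - merged["density_0"]).abs() / merged["density_0"]
    assert (rel < 0.05).all()


def test_uniform_skeleton_yields_equal_densities(onh_spec, rng):
    """A spatially uniform random skeleton gives near-equal regional densities."""
    skel = rng.random(onh_spec.shape) < 0.1
    d = extract_region_densities(skel, center_grid(onh_spec), onh_spec)
    regional = d[d["quadrant"] != "all"]["density"]
    assert regional.max() - regional.min() < 0.02


def test_summary_record_is_mean_of_regions(onh_spec, rng):
    skel = rng.random(onh_spec.shape) < 0.1
    d = extract_region_densities(skel, center_grid(onh_spec), onh_spec, meta={"subject": "S1"})
    regional = d[d["quadrant"] != "all"]
    summary = d[d["quadrant"] == "all"]
    assert len(regional) == 8 and len(summary) == 1
    assert summary["density"].iloc[0] == pytest.approx(regional["density"].mean())
    assert (d["subject"] == "S1").all()


def test_planted_temporal_deficit_measured(onh_spec):
    """A temporal multiplier of 0.5 roughly halves measured temporal density."""
    img, truth = generate_angiogram(
        onh_spec, VesselSimConfig(seed=23, noise_sd=0.0,
                                  regional_multipliers={"temporal": 0.5}))
    skel = skeletonize_mask(truth.vessel_mask).skeleton
    d = extract_region_densities(skel, center_grid(onh_spec), onh_spec)
    regional = d[d["quadrant"] != "all"].set_index(["quadrant", "ring"])["density"]
    for ring in ("inner", "outer"):
        others = np.mean([regional[(q, ring)] for q in ("superior", "nasal", "inferior")])
        ratio = regional[("temporal", ring)] / others
        assert 0.3 < ratio < 0.7


def test_measured_density_tracks_ground_truth():
    """Across regions and images, skeleton densities correlate >= 0.95 with the
    planted mask-pixel fractions (at the default 512 px working resolution)."""
    spec = ImageSpec(512, 512, 6.0, "onh")
    measured, truth_vals = [], []
    for seed, mult in [(31, {}), (32, {"temporal": 0.4}),
                       (33, {"nasal": 0.6, "superior": 0.8}),
                       (34, {"temporal": 0.3, "inferior": 0.7})]:
        img, truth = generate_angiogram(
            spec, VesselSimConfig(seed=seed, noise_sd=0.0, regional_multipliers=mult))
        skel = skeletonize_mask(truth.vessel_mask).skeleton
        d = extract_region_densities(skel, center_grid(spec), spec)
        regional = d[d["quadrant"] != "all"].set_index(["quadrant", "ring"])["density"]
        for lab, true_d in truth.region_true_density.items():
            measured.append(regional[lab])
            truth_vals.append(true_d)
    assert np.corrcoef(measured, truth_vals)[0, 1] >= 0.95
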