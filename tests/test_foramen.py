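"""Apical foramen metrology: Feret diameters, classification rules, shapes."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from canalmorph.foramen import (
    classify_opening,
    classify_shape,
    cross_section_from_mask,
    ellipse_fit_residual,
    feret_diameters,
    measure_foramen,
)


def brute_force_feret(points: np.ndarray, step_deg: float = 1.0):
    """Independent oracle: projection extents over a dense rotation sweep."""
    angles = np.deg2rad(np.arange(0.0, 180.0, step_deg))
    dirs = np.stack([np.cos(angles), np.sin(angles)], axis=1)
    proj = points @ dirs.T
    widths = proj.max(axis=0) - proj.min(axis=0)
    return float(widths.max()), float(widths.min())


# -- Feret ------------------------------------------------------------------

@pytest.mark.parametrize("seed", range(8))
def test_feret_matches_rotation_oracle_on_random_polygons(seed):
    rng = np.random.default_rng(seed)
    pts = rng.normal(size=(30, 2)) * rng.uniform(0.5, 3.0, size=2)
    w, n = feret_diameters(pts)
    w_ref, n_ref = brute_force_feret(pts, step_deg=0.25)
    # the oracle's discrete angles undershoot the max and overshoot the min,
    # by at most ~ w * step/2 at a kink extremum
    slack = np.deg2rad(0.25) * w
    assert w_ref - 1e-9 <= w <= w_ref + slack
    assert n_ref - slack <= n <= n_ref + 1e-9
    assert n <= w


@settings(max_examples=60, derandomize=True, deadline=None)
@given(st.integers(min_value=0, max_value=10_000))
def test_feret_invariants_on_random_point_sets(seed):
    rng = np.random.default_rng(seed)
    pts = rng.uniform(-2, 2, size=(rng.integers(3, 25), 2))
    w, n = feret_diameters(pts)
    assert 0 <= n <= w
    # rotation invariance
    theta = rng.uniform(0, np.pi)
    rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    w2, n2 = feret_diameters(pts @ rot.T)
    assert w2 == pytest.approx(w, rel=1e-9)
    assert n2 == pytest.approx(n, rel=1e-9)


def test_feret_of_rotated_rectangle_is_exact():
    corners = np.array([[0, 0], [4.0, 0], [4.0, 1.5], [0, 1.5]])
    theta = np.deg2rad(33.0)
    rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    w, n = feret_diameters(corners @ rot.T)
    assert w == pytest.approx(np.hypot(4.0, 1.5), abs=1e-12)
    assert n == pytest.approx(1.5, abs=1e-12)


# -- sub-voxel measurement on rasterised shapes -----------------------------

def rasterize_ellipse(a_mm, b_mm, voxel, theta=0.0, lobe=0.0, n=160, antialias=True):
    """Coverage-shaded raster, mirroring the partial-volume shading of CT edges."""
    y, x = np.mgrid[:n, :n]
    cx = cy = (n - 1) / 2
    dx, dy = (x - cx) * voxel, (y - cy) * voxel
    xr = dx * np.cos(theta) + dy * np.sin(theta)
    yr = -dx * np.sin(theta) + dy * np.cos(theta)
    rho = np.sqrt((xr / a_mm) ** 2 + (yr / b_mm) ** 2)
    target = 1.0 + lobe * np.cos(3 * np.arctan2(yr, xr))
    if not antialias:
        return rho <= target
    return np.clip(0.5 - (rho - target) * b_mm / voxel, 0.0, 1.0)


@pytest.mark.parametrize("theta_deg", [0.0, 27.0, 90.0])
def test_elliptic_constriction_measured_within_one_voxel(theta_deg):
    voxel = 0.02
    mask = rasterize_ellipse(0.20, 0.14, voxel, np.deg2rad(theta_deg))
    section = cross_section_from_mask(mask, voxel)
    w, n, residual = measure_foramen(section)
    assert w == pytest.approx(0.40, abs=voxel)
    assert n == pytest.approx(0.28, abs=voxel)
    assert residual < 0.05


def test_binary_mask_measurement_stays_within_one_voxel():
    voxel = 0.02
    mask = rasterize_ellipse(0.20, 0.14, voxel, antialias=False)
    w, n, _ = measure_foramen(cross_section_from_mask(mask, voxel))
    assert w == pytest.approx(0.40, abs=voxel)
    assert n == pytest.approx(0.28, abs=voxel)


def test_circular_constriction_is_round_with_tiny_residual():
    voxel = 0.02
    mask = rasterize_ellipse(0.15, 0.15, voxel)
    section = cross_section_from_mask(mask, voxel)
    w, n, residual = measure_foramen(section)
    assert w == pytest.approx(0.30, abs=voxel)
    assert n == pytest.approx(0.30, abs=voxel)
    assert residual < 0.03
    assert classify_shape(w, n, residual) == "round"


def test_lobed_contour_is_irregular():
    voxel = 0.02
    mask = rasterize_ellipse(0.20, 0.14, voxel, lobe=0.18)
    section = cross_section_from_mask(mask, voxel)
    w, n, residual = measure_foramen(section)
    assert residual > 0.08
    assert classify_shape(w, n, residual) == "irregular"


def test_ellipse_residual_is_scale_free():
    t = np.linspace(0, 2 * np.pi, 80, endpoint=False)
    small = np.stack([0.2 * np.cos(t), 0.14 * np.sin(t)], axis=1)
    large = small * 50
    assert ellipse_fit_residual(small) == pytest.approx(ellipse_fit_residual(large), abs=1e-6)


# -- classification rules ---------------------------------------------------

def test_opening_rule_boundary_inclusive():
    assert classify_opening(0.21) == "physiological"
    assert classify_opening(0.20) == "physiological"
    assert classify_opening(0.19) == "accessory"


def test_opening_rule_sweep_smallest_physiological_is_020():
    diameters = [i / 100.0 for i in range(10, 31)]
    physio = [d for d in diameters if classify_opening(d) == "physiological"]
    assert min(physio) == 0.20


def test_shape_rule_boundary():
    assert classify_shape(0.40, 0.28, residual=0.01) == "oval"
    assert classify_shape(0.30, 0.29, residual=0.01) == "round"   # diff 0.01 < 0.02
    assert classify_shape(0.32, 0.30, residual=0.01) == "oval"    # diff exactly 0.02


def test_shape_rule_sweep_smallest_oval_difference_is_002():
    diffs = [i * 5 / 1000.0 for i in range(0, 11)]
    oval = [d for d in diffs if classify_shape(0.30 + d, 0.30, residual=0.01) == "oval"]
    assert min(oval) == pytest.approx(0.02)


def test_irregular_takes_precedence_over_oval():
    assert classify_shape(0.40, 0.28, residual=0.20) == "irregular"
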