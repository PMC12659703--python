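"""Linescans, FWHM, ratios, angles, bundle classes, summaries."""

import math

import numpy as np
import pytest
from hypothesis import assume, given, settings, strategies as st

from mtoc_atlas.morphometry import (LineScan, SpindleAngleRecord, angle_to_spindle,
                                    aspect_ratio, assign_centriole_one,
                                    classify_architecture, expansion_factor,
                                    extract_linescan, line_angle_deg,
                                    measure_extent, normalize_linescan,
                                    pair_relative_length, summarize)

from conftest import make_barrel_scene


def make_ls(samples, spacing=100.0):
    return LineScan(samples=np.asarray(samples, float), spacing=spacing, width_px=1,
                    endpoints=(np.zeros(3), np.array([0.0, 0.0, spacing])), z_plane=0)


# -- extract_linescan --------------------------------------------------------

def test_constant_volume_gives_constant_profile():
    vol = np.full((5, 20, 20), 7.0)
    for w in (1, 5):
        ls = extract_linescan(vol, 100.0, (200, 500, 200), (200, 500, 1700), width_px=w)
        assert np.allclose(ls.samples, 7.0)


def test_perpendicular_scan_is_symmetric_and_peaks_at_center():
    vol, truth, center, voxel, (hx, hy) = make_barrel_scene(
        length=1000.0, width=400.0, psf=60.0, voxel=50.0, noise="none")
    ls = extract_linescan(vol, voxel, center - np.array([0, hy, 0]),
                          center + np.array([0, hy, 0]), width_px=1)
    peak = int(np.argmax(ls.samples))
    assert abs(peak - (len(ls.samples) - 1) / 2) <= 1
    y = ls.samples
    assert np.allclose(y, y[::-1], atol=0.02 * y.max())


def test_wide_linescan_averages_down_noise():
    """5-px scans on a noisy volume are less variable than 1-px scans."""
    rng = np.random.default_rng(0)
    var1, var5 = [], []
    for seed in range(10):
        vol = rng.normal(size=(5, 40, 40))
        p0, p1 = (200.0, 2000.0, 200.0), (200.0, 2000.0, 3700.0)
        var1.append(extract_linescan(vol, 100.0, p0, p1, width_px=1).samples.var())
        var5.append(extract_linescan(vol, 100.0, p0, p1, width_px=5).samples.var())
    assert np.mean(var5) < np.mean(var1)


def test_cross_plane_linescan_rejected():
    vol = np.zeros((5, 10, 10))
    with pytest.raises(ValueError, match="different z-planes"):
        extract_linescan(vol, 100.0, (0, 500, 100), (400, 500, 900))


def test_endpoint_outside_volume_rejected():
    vol = np.zeros((5, 10, 10))
    with pytest.raises(ValueError, match="outside the volume"):
        extract_linescan(vol, 100.0, (200, 500, 100), (200, 500, 5000))


# -- normalize / FWHM --------------------------------------------------------

def test_normalize_formula():
    assert np.allclose(normalize_linescan(make_ls([10, 30, 20])), [0, 1, 0.5])


def test_normalize_identity_on_unit_range():
    x = [0.0, 0.25, 1.0, 0.5]
    assert np.allclose(normalize_linescan(make_ls(x)), x)


@settings(deadline=None, derandomize=True)
@given(a=st.floats(0.1, 100), b=st.floats(-50, 50))
def test_normalize_is_affine_invariant(a, b):
    base = np.array([3.0, 9.0, 5.0, 1.0, 4.0])
    out0 = normalize_linescan(make_ls(base))
    out1 = normalize_linescan(make_ls(a * base + b))
    assert np.allclose(out0, out1, atol=1e-9)
    assert out1.min() == 0.0 and out1.max() == 1.0


def test_normalize_flat_profile_is_error():
    with pytest.raises(ValueError, match="zero dynamic range"):
        normalize_linescan(make_ls([4.0, 4.0, 4.0]))


def test_fwhm_of_box_profile():
    samples = [0] * 5 + [1] * 10 + [0] * 5
    extent = measure_extent(make_ls(samples, spacing=100.0))
    assert extent == pytest.approx(1000.0, abs=100.0)


def test_fwhm_of_gaussian_profile_closed_form():
    sigma = 200.0
    x = np.arange(-1500, 1501, 25.0)
    ls = make_ls(np.exp(-x**2 / (2 * sigma**2)), spacing=25.0)
    expected = 2 * math.sqrt(2 * math.log(2)) * sigma      # ~470.96 nm
    assert measure_extent(ls) == pytest.approx(expected, rel=0.02)


def test_fwhm_without_flank_crossing_is_error():
    with pytest.raises(ValueError, match="crossing"):
        measure_extent(make_ls([1.0, 0.8, 0.6, 0.1]))      # never returns on the left


def test_rendered_barrel_length_recovered_after_expansion_division():
    vol, truth, center, voxel, (hx, hy) = make_barrel_scene(
        length=2000.0, width=200.0, expansion=5.5, psf=90.0, voxel=130.0,
        noise="gauss_poisson", read_sigma=0.1, seed=3)
    ls = extract_linescan(vol, voxel, center - np.array([0, 0, hx]),
                          center + np.array([0, 0, hx]), width_px=5)
    recovered = measure_extent(ls) / truth.expansion_factor
    assert recovered == pytest.approx(2000.0, rel=0.10)


# -- ratios ------------------------------------------------------------------

def test_aspect_ratio_examples():
    assert aspect_ratio(440.0, 200.0) == pytest.approx(2.2)
    assert aspect_ratio(5.0, 5.0) == 1.0
    assert aspect_ratio(4400.0, 2000.0) == aspect_ratio(440.0, 200.0)
    with pytest.raises(ValueError):
        aspect_ratio(0.0, 1.0)


def test_pair_relative_length_examples():
    assert pair_relative_length(900.0, 300.0) == pytest.approx(1 / 3)
    assert pair_relative_length(400.0, 400.0) == 1.0
    assert pair_relative_length(3.0, 7.0) == pair_relative_length(7.0, 3.0)
    with pytest.raises(ValueError):
        pair_relative_length(-1.0, 2.0)


def test_expansion_factor_point_estimate_and_identity():
    s = expansion_factor([1100.0, 1100.0], [200.0, 200.0])
    assert s.mean == pytest.approx(5.5) and s.std == 0.0
    same = expansion_factor([3.0, 4.0], [3.0, 4.0])
    assert same.mean == 1.0
    with pytest.raises(ValueError):
        expansion_factor([], [1.0])


# -- angles ------------------------------------------------------------------

def test_angle_subtraction_rule():
    # theta_c = 30 deg, theta_s = 45 deg -> 15 deg
    c = ((0.0, 0.0), (-math.tan(math.radians(30)) * 10, 10.0))
    s = ((0.0, 0.0), (-10.0, 10.0))
    assert angle_to_spindle(c, s) == pytest.approx(15.0, abs=1e-9)


def test_identical_lines_have_zero_angle():
    line = ((1.0, 2.0), (5.0, 9.0))
    assert angle_to_spindle(line, line) == 0.0


def test_angle_output_folded_into_0_90():
    c = ((0.0, 0.0), (0.0, 10.0))          # horizontal, 0 deg
    s = ((0.0, 0.0), (-1.0, -10.0))        # ~174 deg by Fiji convention
    a = angle_to_spindle(c, s)
    assert 0 <= a <= 90


def test_zero_length_line_rejected():
    with pytest.raises(ValueError, match="zero-length"):
        line_angle_deg((1.0, 1.0), (1.0, 1.0))


@settings(deadline=None, derandomize=True, max_examples=60)
@given(theta_s=st.floats(5, 60), delta=st.floats(2, 25), rot=st.floats(-20, 20))
def test_angle_invariant_under_joint_rotation(theta_s, delta, rot):
    """Rotating both lines together changes nothing while both angles keep one sign.

    The abs-subtraction rule assumes both lines read out in the same angular
    quadrant, so the invariance property holds away from the 0 and 180
    branch points (a rotation pushing one line across 0 legitimately changes
    the result of this convention).
    """
    assume((theta_s + rot) * (theta_s + delta + rot) > 0)
    assume(theta_s + delta + rot < 90)

    def line(theta):
        r = math.radians(theta)
        return ((0.0, 0.0), (-math.sin(r) * 50, math.cos(r) * 50))
    base = angle_to_spindle(line(theta_s + delta), line(theta_s))
    rotated = angle_to_spindle(line(theta_s + delta + rot), line(theta_s + rot))
    assert rotated == pytest.approx(base, abs=1e-6)


def test_assign_centriole_one_picks_smaller_angle():
    assert assign_centriole_one((12.0, 70.0)).centriole1_index == 0
    assert assign_centriole_one((70.0, 12.0)).centriole1_index == 1
    rec = assign_centriole_one((30.0, 30.0))
    assert rec.centriole1_index == 0 and rec.tie


def test_spindle_angle_record_validates():
    with pytest.raises(ValueError, match="smaller"):
        SpindleAngleRecord(theta_c1=50.0, theta_c2=10.0, centriole1_index=0)
    with pytest.raises(ValueError, match=r"\[0, 90\]"):
        SpindleAngleRecord(theta_c1=10.0, theta_c2=120.0, centriole1_index=0)


# -- architecture classification ---------------------------------------------

def radial_filament(direction, r0=600.0, r1=4000.0, n=30):
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    return np.linspace(r0, r1, n)[:, None] * d[None, :]


def test_no_bundles_at_metaphase_when_all_in_spindle_cone():
    spindle = (0.0, 0.0, 1.0)
    fils = [radial_filament((0, 0.1, 1.0)), radial_filament((0, -0.1, -1.0))]
    assert classify_architecture(fils, (0, 0, 0), "metaphase",
                                 spindle_axis=spindle) == "no_bundles"


def test_single_bundle_zoospore_scene():
    fils = [radial_filament((0, 1.0, 0.2))]
    assert classify_architecture(fils, (0, 0, 0), "nascent_zoospore") == "single_bundle"


def test_multiple_bundles_counted_outside_cone():
    spindle = (0.0, 0.0, 1.0)
    fils = [radial_filament((0, 1, 0)), radial_filament((0, -1, 0.3)),
            radial_filament((1, 0.5, 0)), radial_filament((0, 0.05, 1.0))]
    assert classify_architecture(fils, (0, 0, 0), "anaphase",
                                 spindle_axis=spindle) == "multiple_bundles"


def test_metaphase_without_spindle_axis_is_error():
    with pytest.raises(ValueError, match="spindle axis"):
        classify_architecture([], (0, 0, 0), "metaphase")


def test_filaments_outside_shell_ignored():
    fils = [radial_filament((0, 1, 0), r0=9000.0, r1=12000.0)]
    assert classify_architecture(fils, (0, 0, 0), "anaphase",
                                 shell=(500.0, 5000.0)) == "no_bundles"


# -- summaries ---------------------------------------------------------------

def test_summarize_closed_forms():
    s = summarize([2.0, 2.0, 2.0])
    assert (s.mean, s.std, s.sem) == (2.0, 0.0, 0.0)
    s2 = summarize([1.0, 3.0])
    assert s2.mean == 2.0
    assert s2.std == pytest.approx(math.sqrt(2))
    assert s2.sem == pytest.approx(1.0)
    with pytest.raises(ValueError):
        summarize([])


def test_grouped_summary_recovers_planted_group_means():
    """Basal-body vs centriole aspect ratios with planted means 2.8 vs 1.6."""
    rng = np.random.default_rng(21)
    bb = rng.normal(2.8, 0.3, size=40)
    ce = rng.normal(1.6, 0.3, size=40)
    s_bb, s_ce = summarize(bb), summarize(ce)
    assert abs(s_bb.mean - 2.8) <= 2 * s_bb.sem
    assert abs(s_ce.mean - 1.6) <= 2 * s_ce.sem
    assert s_bb.mean > s_ce.mean
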