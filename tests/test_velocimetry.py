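"""STI construction, wavelet velocimetry vs oracle, haemodynamic formulas."""

import math

import numpy as np
import pytest

from ocuflow import (STImage, SegmentHaemodynamics, VelocimetryConfig,
                     VesselSegment, VideoSimConfig, axial_velocity_oracle,
                     blood_flow, build_sti, cross_sectional_velocity,
                     estimate_axial_velocity_cwt, register_frames,
                     render_vessel_video, wall_shear_rate)
from ocuflow.geometry import edt_diameter, extract_centerlines, segment_vessels


def _gaussian_streak_sti(n_frames=40, length=160, disp_per_frame=8.333,
                         sigma=10.0, fps=60.0, ds_um=1.0):
    """Synthetic STI with one dark blob translating at a known slope."""
    t = np.arange(n_frames)[:, None]
    x = np.arange(length)[None, :]
    centre = 20.0 + disp_per_frame * t
    vals = -np.exp(-0.5 * ((x - centre) / sigma) ** 2)
    vals = vals - vals.mean(axis=1, keepdims=True)
    return STImage(vals, ds_um=ds_um, dt_s=1.0 / fps)


# ------------------------------------------------------------------- STI
def test_sti_shape_is_frames_by_samples(clean_video):
    stack, _ = clean_video
    vm = segment_vessels(stack.frames[0], stack.um_per_px)
    seg = extract_centerlines(vm)[0]
    sti = build_sti(stack, seg)
    assert sti.values.shape[0] == stack.n_frames
    assert sti.values.shape[1] >= 8


def test_stationary_scene_sti_columns_constant():
    cfg = VideoSimConfig(n_frames=10, axial_velocity_mm_s=0.0, noise_sd=0.0,
                         jitter_sd_px=0.0, blur_sigma_px=0.0, seed=2)
    stack, truth = render_vessel_video(cfg)
    seg = VesselSegment(points=truth.centerline_px[10:-10])
    sti = build_sti(stack, seg)
    assert np.allclose(sti.values.var(axis=0), 0.0, atol=1e-18)


def test_sti_streak_slope_matches_truth_by_minimum_tracking(clean_video):
    stack, truth = clean_video
    seg = VesselSegment(points=truth.centerline_px[5:-5])
    sti = build_sti(stack, seg)
    mins = np.argmin(sti.values, axis=1).astype(float)
    d = np.diff(mins)
    d = d[np.abs(d) < 30]  # drop plug hand-overs
    slope_um_per_s = np.median(d) * sti.ds_um / sti.dt_s
    assert slope_um_per_s == pytest.approx(
        truth.axial_velocity_mm_s * 1000, rel=0.05)


def test_centerline_outside_frame_rejected(clean_video):
    stack, _ = clean_video
    seg = VesselSegment(points=np.array([[-5.0, 10.0], [250.0, 10.0]]))
    with pytest.raises(ValueError, match="bounds"):
        build_sti(stack, seg)


# ------------------------------------------------------------------- CWT
def test_cwt_recovers_constructed_slope():
    # blob stays inside the field for the whole track
    sti = _gaussian_streak_sti(n_frames=15, disp_per_frame=8.333)  # 0.50 mm/s
    va = estimate_axial_velocity_cwt(sti)
    assert va == pytest.approx(0.50, rel=0.05)


def test_cwt_stationary_pattern_gives_zero():
    sti = _gaussian_streak_sti(disp_per_frame=0.0)
    assert estimate_axial_velocity_cwt(sti) == pytest.approx(0.0, abs=1e-6)


def test_cwt_pure_noise_is_indeterminate(rng):
    noise = rng.normal(0, 5, size=(60, 150))
    sti = STImage(noise - noise.mean(axis=1, keepdims=True), 1.0, 1 / 60)
    assert estimate_axial_velocity_cwt(sti) is None


def test_cwt_invariant_to_affine_intensity_rescale():
    sti = _gaussian_streak_sti()
    scaled = STImage(3.7 * sti.values, sti.ds_um, sti.dt_s)
    assert estimate_axial_velocity_cwt(scaled) == pytest.approx(
        estimate_axial_velocity_cwt(sti), rel=1e-6)


# ------------------------------------------------------------------ oracle
def test_oracle_exact_on_integer_lag():
    rng = np.random.default_rng(0)
    base = rng.normal(size=300)
    rows = [np.roll(base, 3 * t)[:200] for t in range(30)]
    sti = STImage(np.asarray(rows) - np.mean(rows, axis=1, keepdims=True),
                  ds_um=1.0, dt_s=1 / 60)
    assert axial_velocity_oracle(sti) == pytest.approx(0.18, abs=1e-12)


def test_oracle_constant_sti_gives_zero():
    vals = np.tile(np.sin(np.linspace(0, 6, 100)), (10, 1))
    sti = STImage(vals - vals.mean(axis=1, keepdims=True), 1.0, 1 / 60)
    assert axial_velocity_oracle(sti) == 0.0


def test_oracle_rejects_too_short_sti():
    sti = _gaussian_streak_sti(length=20)
    with pytest.raises(ValueError, match="max_lag"):
        axial_velocity_oracle(sti, max_lag=15)


@pytest.mark.parametrize("va_true", [0.3, 0.5, 0.7])
def test_cwt_agrees_with_oracle_on_simulator(va_true):
    cfg = VideoSimConfig(n_frames=80, axial_velocity_mm_s=va_true, seed=31)
    stack, truth = render_vessel_video(cfg)
    reg = register_frames(stack)
    vm = segment_vessels(reg.registered.frames[reg.reference_index],
                         stack.um_per_px)
    seg = extract_centerlines(vm)[0]
    sti = build_sti(reg.registered, seg)
    va_cwt = estimate_axial_velocity_cwt(sti)
    va_orc = axial_velocity_oracle(sti)
    assert va_cwt is not None
    assert abs(va_cwt - va_orc) / va_orc <= 0.10
    assert va_cwt == pytest.approx(va_true, rel=0.10)


# ----------------------------------------------------------------- formulas
def test_blood_flow_worked_example():
    # 0.35 mm/s in a 20 um vessel: 350*pi*400/4 um^3/s = 109.96 pl/s
    assert blood_flow(0.35, 20.0) == pytest.approx(109.9557, rel=1e-4)


def test_wall_shear_rate_worked_example():
    assert wall_shear_rate(0.35, 20.0) == pytest.approx(140.0, rel=1e-12)


def test_flow_and_wsr_scaling_laws():
    q1, q2 = blood_flow(0.4, 15.0), blood_flow(0.4, 30.0)
    assert q2 == pytest.approx(4 * q1, rel=1e-12)
    w1, w2 = wall_shear_rate(0.4, 30.0), wall_shear_rate(0.4, 15.0)
    assert w2 == pytest.approx(2 * w1, rel=1e-12)
    assert blood_flow(0.0, 20.0) == 0.0
    assert wall_shear_rate(0.0, 20.0) == 0.0


def test_cross_sectional_velocity_matches_published_pairs():
    cfg = VelocimetryConfig(k_axial_to_cross=1.42)
    assert cross_sectional_velocity(0.54, cfg) == pytest.approx(0.380, abs=5e-4)
    assert cross_sectional_velocity(0.50, cfg) == pytest.approx(0.352, abs=5e-4)
    assert cross_sectional_velocity(0.0, cfg) == 0.0
    with pytest.raises(ValueError):
        VelocimetryConfig(k_axial_to_cross=0.9)


def test_haemodynamics_identities_enforced():
    h = SegmentHaemodynamics.from_measurements(20.0, 0.497)
    assert h.flow_pl_s == pytest.approx(
        blood_flow(h.cross_velocity_mm_s, h.diameter_um), rel=1e-12)
    assert h.wsr_per_s == pytest.approx(
        wall_shear_rate(h.cross_velocity_mm_s, h.diameter_um), rel=1e-12)
    with pytest.raises(ValueError, match="Q inconsistent"):
        SegmentHaemodynamics(20.0, 0.5, 0.35, 1.0, 140.0)
    with pytest.raises(ValueError, match="Vs cannot exceed"):
        SegmentHaemodynamics(20.0, 0.3, 0.5,
                             blood_flow(0.5, 20.0), wall_shear_rate(0.5, 20.0))
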