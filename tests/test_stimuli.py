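"""Stimulus generators: geometry, durations, bounds and equivariance."""

import numpy as np
import pytest

from dmnet.hexlattice import enumerate_hex, hex_distance, hex_rotate
from dmnet.stimuli import (AugmentationConfig, augment, circular_flash,
                           moving_edge, ommatidium_flash, render_fly_eye)


@pytest.fixture(scope="module")
def lat():
    return enumerate_hex(6)


# ------------------------------------------------------------ fly-eye render


def test_render_constant_image(lat):
    video = np.full((2, 400, 400), 0.3)
    seq = render_fly_eye(video, lat, spacing=13)
    np.testing.assert_allclose(seq.frames, 0.3)


def test_render_half_plane_monotone_in_x(lat):
    img = np.zeros((1, 400, 400))
    img[:, :, 200:] = 1.0
    seq = render_fly_eye(img, lat, spacing=13)
    x, _ = lat.cartesian(13.0)
    order = np.argsort(x)
    vals = seq.frames[0][order]
    assert np.all(np.diff(vals) >= -1e-12)


def test_render_checkerboard_averages_to_half(lat):
    yy, xx = np.mgrid[0:401, 0:401]
    img = ((xx + yy) % 2).astype(float)[None]
    seq = render_fly_eye(img, lat, spacing=13)
    np.testing.assert_allclose(seq.frames, 0.5, atol=0.01)


def test_render_out_of_bounds(lat):
    with pytest.raises(ValueError):
        render_fly_eye(np.zeros((1, 50, 50)), lat, spacing=13)


# ------------------------------------------------------------------ flashes


def test_circular_flash_geometry_and_frames(lat):
    seq = circular_flash(lat, 1.0, radius=6, warmup=1000.0, flash=1000.0, dt=5.0)
    assert seq.frames.shape[0] == 400  # (1000 + 1000) / 5
    flashed = np.flatnonzero(seq.frames[-1] == 1.0)
    assert len(flashed) == 127  # 3*6*7 + 1
    assert np.all(hex_distance(lat.u[flashed], lat.v[flashed]) <= 6)
    np.testing.assert_allclose(seq.frames[:200], 0.5)


def test_grey_flash_is_constant(lat):
    seq = circular_flash(lat, 0.5, radius=6)
    np.testing.assert_allclose(seq.frames, 0.5)


def test_flash_radius_exceeding_lattice():
    with pytest.raises(ValueError):
        circular_flash(enumerate_hex(3), 1.0, radius=6)


# -------------------------------------------------------------- moving edge


def test_edge_duration_from_speed(lat):
    seq = moving_edge(lat, 0.0, 13.92, 1.0, dt=5.0)
    assert seq.duration / 1000.0 == pytest.approx(27.0 / 13.92, abs=0.005)


def test_edge_fully_crosses_swept_extent():
    """Within the +-13.5 deg sweep (a radius-2 lattice at 5.8 deg/column),
    every column has the edge intensity at the final frame."""
    small = enumerate_hex(2)
    for th in (0.0, 90.0, 210.0):
        seq = moving_edge(small, th, 56.26, 1.0, dt=5.0)
        np.testing.assert_allclose(seq.frames[-1], 1.0)


def test_edge_opposite_directions_reverse_onset_order(lat):
    """theta and theta+180 cross the columns in opposite order along the
    motion axis."""
    a = moving_edge(lat, 0.0, 27.84, 1.0, dt=5.0).frames
    b = moving_edge(lat, 180.0, 27.84, 1.0, dt=5.0).frames
    x, _ = lat.cartesian(1.0)
    swept = np.abs(x) * 5.8 <= 13.5

    def onset(frames):
        return np.array([np.argmax(frames[:, c] == 1.0) for c in range(frames.shape[1])])

    oa, ob = onset(a)[swept], onset(b)[swept]
    xs = x[swept]
    assert np.all(np.diff(oa[np.argsort(xs)]) >= 0)       # ON order follows +x
    assert np.all(np.diff(ob[np.argsort(xs)[::-1]]) >= 0)  # reversed for theta+180


def test_edge_values_binary_on_grey(lat):
    seq = moving_edge(lat, 30.0, 75.4, 0.0, dt=5.0)
    assert set(np.unique(seq.frames)) <= {0.0, 0.5}


# -------------------------------------------------------- ommatidium flashes


def test_ommatidium_flash_window_arithmetic(lat):
    seq = ommatidium_flash(lat, (2, -1), 1.0, duration=20.0, pre=2000.0,
                           post=5000.0, dt=5.0)
    dev = np.abs(seq.frames - 0.5).sum(axis=1)
    flashed = np.flatnonzero(dev > 0)
    assert len(flashed) == 4  # 20 ms / 5 ms
    assert flashed[0] == 400  # after 2 s of grey
    col = lat.position(2, -1)
    assert np.all(seq.frames[flashed, col] == 1.0)


def test_ommatidium_flash_rotation_equivariance(lat):
    """Rotating the whole stimulus equals flashing the rotated column."""
    tgt = (2, -1)
    a = ommatidium_flash(lat, tgt, 1.0, 20.0, pre=100.0, post=100.0, dt=5.0)
    rt = tuple(int(x) for x in hex_rotate(*tgt, 1))
    b = ommatidium_flash(lat, rt, 1.0, 20.0, pre=100.0, post=100.0, dt=5.0)
    # rotated[:, i] = original at R^{-1} c_i
    perm = lat.positions(*hex_rotate(lat.u, lat.v, 5))
    np.testing.assert_array_equal(a.frames[:, perm], b.frames)


def test_ommatidium_flash_outside_lattice(lat):
    with pytest.raises(ValueError):
        ommatidium_flash(lat, (99, 0), 1.0, 20.0)


# ------------------------------------------------------------- augmentation


def test_augment_identity_when_disabled(lat):
    seq = circular_flash(lat, 1.0, radius=3, warmup=50.0, flash=50.0, dt=5.0)
    cfg = AugmentationConfig(noise_std=0.0, contrast_var=0.0, brightness_var=0.0,
                             flip=False, rotate=False)
    out = augment(seq, cfg, seed=0)
    np.testing.assert_allclose(out.frames, seq.frames)


def test_augment_six_rotations_identity(lat):
    from dmnet.stimuli import _column_permutation

    perm = _column_permutation(lat, lambda u, v: hex_rotate(u, v, 1))
    p = np.arange(len(lat))
    for _ in range(6):
        p = p[perm]
    np.testing.assert_array_equal(p, np.arange(len(lat)))


def test_augment_noise_clamped_at_zero(lat):
    seq = circular_flash(lat, 0.0, radius=6, warmup=0.0, flash=200.0, dt=5.0)
    seq.frames[:] = 0.0
    cfg = AugmentationConfig(noise_std=0.08, contrast_var=0.0, brightness_var=0.0,
                             flip=False, rotate=False)
    out = augment(seq, cfg, seed=1)
    # X = 0 with noise: clamped at 0, then contrast transform with c=1, b=0
    assert out.frames.min() >= -0.5  # after X' = c(X-0.5)+0.5 with X >= 0
    pre_contrast = out.frames  # c=1, b=0 -> X' = X
    assert pre_contrast.min() >= 0.0


def test_augment_deterministic_and_flow_consistent(lat):
    rngf = np.random.default_rng(0)
    frames = rngf.random((4, len(lat)))
    from dmnet.stimuli import StimulusSequence

    seq = StimulusSequence(frames, 20.0, lat)
    flow = rngf.normal(size=(4, 2, len(lat)))
    cfg = AugmentationConfig(noise_std=0.0, contrast_var=0.0, brightness_var=0.0)
    o1, f1 = augment(seq, cfg, seed=5, flow=flow)
    o2, f2 = augment(seq, cfg, seed=5, flow=flow)
    np.testing.assert_array_equal(o1.frames, o2.frames)
    np.testing.assert_array_equal(f1, f2)
    # geometric transform preserves flow magnitudes
    np.testing.assert_allclose(np.linalg.norm(f1, axis=1).sum(),
                               np.linalg.norm(flow, axis=1).sum())


def test_augment_contrast_formula(lat):
    from dmnet.stimuli import StimulusSequence

    frames = np.full((2, len(lat)), 0.75)
    seq = StimulusSequence(frames, 20.0, lat)
    cfg = AugmentationConfig(noise_std=0.0, contrast_var=0.04, brightness_var=0.01,
                             flip=False, rotate=False)
    out = augment(seq, cfg, seed=3)
    rng = np.random.default_rng(3)
    c = np.exp(rng.normal(0, 0.2))
    b = rng.normal(0, 0.1)
    np.testing.assert_allclose(out.frames, c * (0.75 - 0.5) + 0.5 + c * b)
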