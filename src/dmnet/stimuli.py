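"""Stimulus generation on the hexagonal lattice.

Protocols follow the standard characterization battery: fly-eye rendering of
Cartesian video, circular flashes (contrast tuning), moving edges (direction
tuning), single-ommatidium flashes (receptive-field mapping) and the
training-time augmentation chain.  Luminance is in [0, 1] with grey = 0.5.

Angular calibration: one column subtends 5.8 degrees of visual angle (the
single-column receptive-field radius), which converts the printed edge
speeds in deg/s to lattice units.  Edges are hard (binary) luminance steps
sampled at column centres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hexlattice import HexArray, hex_distance, hex_flip, hex_rotate

__all__ = [
    "StimulusSequence",
    "AugmentationConfig",
    "DEG_PER_COLUMN",
    "EDGE_ANGLES",
    "EDGE_SPEEDS",
    "render_fly_eye",
    "circular_flash",
    "moving_edge",
    "ommatidium_flash",
    "grey_screen",
    "augment",
]

DEG_PER_COLUMN = 5.8
EDGE_ANGLES = tuple(range(0, 360, 30))  # 12 motion directions, deg
EDGE_SPEEDS = (13.92, 27.84, 56.26, 75.4, 110.2, 145.0)  # deg/s
EDGE_EXTENT_DEG = 13.5  # edge travels from -13.5 to +13.5 deg


@dataclass
class StimulusSequence:
    """Time x column luminance in [0, 1] on a hex lattice."""

    frames: np.ndarray   # (n_frames, n_columns)
    frame_dt: float      # ms
    lattice: HexArray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.frames.shape[1] != len(self.lattice):
            raise ValueError("column count does not match lattice")

    @property
    def duration(self) -> float:
        return self.frames.shape[0] * self.frame_dt

    def clamp(self) -> "StimulusSequence":
        return StimulusSequence(np.clip(self.frames, 0.0, 1.0), self.frame_dt,
                                self.lattice, dict(self.meta))


def grey_screen(lattice: HexArray, duration: float, dt: float,
                level: float = 0.5) -> StimulusSequence:
    n = int(round(duration / dt))
    return StimulusSequence(np.full((n, len(lattice)), level), dt, lattice,
                            meta=dict(kind="grey", level=level))


def render_fly_eye(video: np.ndarray, lattice: HexArray, spacing: int = 13,
                   frame_dt: float = 1000.0 / 24) -> StimulusSequence:
    """Sample Cartesian greyscale frames onto the lattice.

    Photoreceptors sit on the hex lattice in pixel space, `spacing` pixels
    apart; the transduced luminance of a column is the mean over the
    spacing x spacing pixel box around its centre.
    """
    video = np.asarray(video, dtype=float)
    if video.ndim == 2:
        video = video[None]
    n_frames, H, W = video.shape
    x, y = lattice.cartesian(spacing)
    cx, cy = W / 2.0, H / 2.0
    half = spacing // 2
    px = np.round(cx + x).astype(int)
    py = np.round(cy - y).astype(int)  # image rows grow downwards
    if (px - half < 0).any() or (px + half >= W).any() or (py - half < 0).any() or (py + half >= H).any():
        raise ValueError("hex array exceeds frame bounds at this spacing")
    frames = np.empty((n_frames, len(lattice)))
    for c in range(len(lattice)):
        patch = video[:, py[c] - half : py[c] + half + 1, px[c] - half : px[c] + half + 1]
        frames[:, c] = patch.mean(axis=(1, 2))
    return StimulusSequence(np.clip(frames, 0.0, 1.0), frame_dt, lattice,
                            meta=dict(kind="fly_eye", spacing=spacing))


def circular_flash(lattice: HexArray, intensity: float, radius: int = 6,
                   warmup: float = 1000.0, flash: float = 1000.0,
                   dt: float = 5.0, grey: float = 0.5) -> StimulusSequence:
    """Disc of `intensity` and hex radius `radius` on grey, after a grey lead-in."""
    if radius > lattice.radius:
        raise ValueError("flash radius exceeds lattice radius")
    n_warm = int(round(warmup / dt))
    n_flash = int(round(flash / dt))
    disc = hex_distance(lattice.u, lattice.v) <= radius
    frames = np.full((n_warm + n_flash, len(lattice)), grey)
    frames[n_warm:, disc] = intensity
    return StimulusSequence(frames, dt, lattice,
                            meta=dict(kind="flash", I=intensity, radius=radius,
                                      onset=warmup))


def moving_edge(lattice: HexArray, theta_deg: float, speed_deg_s: float,
                intensity: float, dt: float = 5.0, grey: float = 0.5,
                extent_deg: float = EDGE_EXTENT_DEG,
                deg_per_column: float = DEG_PER_COLUMN) -> StimulusSequence:
    """Half-plane edge of `intensity` advancing over grey along direction theta.

    The edge front starts at -extent and ends at +extent visual degrees
    (projected onto the motion axis), moving at the given angular speed; at
    the final frame the whole field has the edge intensity.
    """
    x, y = lattice.cartesian(1.0)
    th = np.deg2rad(theta_deg)
    proj_deg = (x * np.cos(th) + y * np.sin(th)) * deg_per_column
    duration_ms = 2 * extent_deg / speed_deg_s * 1000.0
    n = int(round(duration_ms / dt))
    t = (np.arange(1, n + 1)) * dt / 1000.0  # s
    front = -extent_deg + speed_deg_s * t    # deg along motion axis
    frames = np.where(proj_deg[None, :] <= front[:, None], intensity, grey)
    return StimulusSequence(frames, dt, lattice,
                            meta=dict(kind="edge", theta=theta_deg,
                                      speed=speed_deg_s, I=intensity))


def ommatidium_flash(lattice: HexArray, target: tuple[int, int], intensity: float,
                     duration: float, pre: float = 2000.0, post: float = 5000.0,
                     dt: float = 5.0, grey: float = 0.5) -> StimulusSequence:
    """Flash a single column for `duration` ms between grey lead-in/out."""
    if tuple(target) not in lattice:
        raise ValueError(f"target column {target} outside lattice")
    col = lattice.position(*target)
    n_pre = int(round(pre / dt))
    n_fl = int(round(duration / dt))
    n_post = int(round(post / dt))
    frames = np.full((n_pre + n_fl + n_post, len(lattice)), grey)
    frames[n_pre : n_pre + n_fl, col] = intensity
    return StimulusSequence(frames, dt, lattice,
                            meta=dict(kind="ommatidium", target=tuple(target),
                                      I=intensity, onset=pre, duration=duration))


@dataclass
class AugmentationConfig:
    """Training-time augmentation: hex flips/rotations, pixel noise, then a
    contrast/brightness transform X' = c (X - 0.5) + 0.5 + c b with
    log c ~ N(0, sigma_c^2) and b ~ N(0, sigma_b^2)."""

    noise_std: float = 0.08
    contrast_var: float = 0.04
    brightness_var: float = 0.01
    flip: bool = True
    rotate: bool = True

    def __post_init__(self):
        if min(self.noise_std, self.contrast_var, self.brightness_var) < 0:
            raise ValueError("augmentation variances must be non-negative")


def _column_permutation(lattice: HexArray, fn) -> np.ndarray:
    """Permutation p with stim_new[:, i] = stim_old[:, p[i]] for coord map fn."""
    u2, v2 = fn(lattice.u, lattice.v)
    return lattice.positions(u2, v2)


def _cartesian_matrix(lattice: HexArray, fn) -> np.ndarray:
    """2x2 matrix A with cartesian(fn(c)) = A @ cartesian(c) (exact: fn is linear)."""
    x, y = lattice.cartesian()
    u2, v2 = fn(lattice.u, lattice.v)
    from .hexlattice import hex_to_cartesian

    x2, y2 = hex_to_cartesian(u2, v2)
    A, *_ = np.linalg.lstsq(np.c_[x, y], np.c_[x2, y2], rcond=None)
    return A.T


def augment(seq: StimulusSequence, cfg: AugmentationConfig, seed: int,
            flow: np.ndarray | None = None):
    """Apply the augmentation chain; deterministic under `seed`.

    If per-column 2-D flow targets (n_frames, 2, n_columns) are supplied they
    receive the matching geometric transform (column permutation plus
    rotation/reflection of the flow vectors).  Returns the sequence, or
    (sequence, flow).
    """
    rng = np.random.default_rng(seed)
    frames = seq.frames.copy()
    perm = np.arange(len(seq.lattice))
    A = np.eye(2)
    if cfg.rotate:
        k = int(rng.integers(0, 6))
        p = _column_permutation(seq.lattice, lambda u, v: hex_rotate(u, v, k))
        perm = perm[p]
        A = _cartesian_matrix(seq.lattice, lambda u, v: hex_rotate(u, v, k)) @ A
    if cfg.flip and rng.random() < 0.5:
        axis = int(rng.integers(0, 3))
        p = _column_permutation(seq.lattice, lambda u, v: hex_flip(u, v, axis))
        perm = perm[p]
        A = _cartesian_matrix(seq.lattice, lambda u, v: hex_flip(u, v, axis)) @ A
    # new[:, i] = old[:, perm[i]], i.e. the stimulus is moved by the inverse
    # map; flow vectors transform with A^{-1} accordingly.
    frames = frames[:, perm]
    if cfg.noise_std > 0:
        frames = np.maximum(frames + rng.normal(0, cfg.noise_std, size=frames.shape), 0.0)
    c = float(np.exp(rng.normal(0, np.sqrt(cfg.contrast_var))))
    b = float(rng.normal(0, np.sqrt(cfg.brightness_var)))
    frames = c * (frames - 0.5) + 0.5 + c * b
    out = StimulusSequence(frames, seq.frame_dt, seq.lattice,
                           meta={**seq.meta, "augmented": True})
    if flow is None:
        return out
    Ainv = np.linalg.inv(A)
    flow2 = np.einsum("ij,njc->nic", Ainv, flow[:, :, perm])
    return out, flow2
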