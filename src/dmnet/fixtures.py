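"""Synthetic data generators: toy connectomes, optic-flow datasets, digits.

Everything downstream is testable offline from these three generators:

* :func:`make_motion_motif` — a four-type toy connectome implementing the
  classic delayed-flanking-inhibition motion detector (a photoreceptor
  drives a fast excitatory relay in the same column and a slow inhibitory
  relay one column over; a detector type sums the two).  The detector's
  designed preferred direction (from the excitatory centre towards the
  inhibitory flank) is recorded as ground-truth metadata.
* :func:`make_drifting_dataset` — rigidly drifting band patterns on the hex
  lattice with analytically exact per-column flow targets, split into train
  and validation sets with distinct base patterns (no leakage).
* :func:`make_digit_task` — a 10-class 28x28 template-plus-noise image set
  standing in for handwritten digits, class-balanced and easy enough that a
  dense baseline classifier exceeds 90% held-out accuracy.

All generators are pure functions of their seed.

Default lattice radius for fixtures is 6 (127 columns): large enough for
radius-6 disc flashes and multi-column filters, small enough for
seconds-scale tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .connectome import (CellTypeSpec, ConnectomeSpec, FilterEntry, ParamSet,
                         SignTable)
from .hexlattice import HexArray, enumerate_hex, hex_to_cartesian
from .stimuli import StimulusSequence

__all__ = [
    "MotionMotif",
    "make_motion_motif",
    "DetectorBank",
    "make_detector_bank",
    "DriftingDataset",
    "make_drifting_dataset",
    "make_digit_task",
]


@dataclass
class MotionMotif:
    spec: ConnectomeSpec
    params: ParamSet
    detector: str
    preferred_direction_deg: float  # designed ground truth
    inhib_offset: tuple[int, int]


def make_motion_motif(radius: int = 6, delay_ratio: float = 4.0, seed: int = 0,
                      mirror: bool = False,
                      include_inhibition: bool = True) -> MotionMotif:
    """Build the delayed-flanking-inhibition motion-detector toy connectome.

    `delay_ratio` = tau_slow / tau_fast must exceed 1 (the asymmetry of
    timing is what creates direction selectivity).  `mirror` flips the
    inhibitory flank to the opposite side, reversing the designed preferred
    direction by 180 degrees; `include_inhibition=False` ablates the slow
    arm, destroying selectivity.
    """
    if delay_ratio <= 1:
        raise ValueError("delay ratio must exceed 1")
    off = (-1, 0) if mirror else (1, 0)
    types = [
        CellTypeSpec("R"),        # photoreceptor
        CellTypeSpec("EF"),       # fast excitatory relay, same column
        CellTypeSpec("IS"),       # slow inhibitory relay
        CellTypeSpec("D"),        # detector
    ]
    signs = SignTable()
    signs[("R", "EF")] = 1
    signs[("R", "IS")] = 1
    signs[("EF", "D")] = 1
    signs[("IS", "D")] = -1
    filters = [
        FilterEntry("R", "EF", 0, 0, 10.0),
        FilterEntry("R", "IS", 0, 0, 10.0),
        FilterEntry("EF", "D", 0, 0, 10.0),
        # detector at c receives inhibition from the relay at c + off
        FilterEntry("IS", "D", -off[0], -off[1], 10.0),
    ]
    if not include_inhibition:
        filters = [f for f in filters if f.pre_type != "IS"]
    spec = ConnectomeSpec(types=types, filters=filters, signs=signs,
                          input_types=("R",), output_types=("EF", "D"))
    tau_fast = 20.0
    tau = np.array([tau_fast, tau_fast, tau_fast * delay_ratio, tau_fast])
    v_rest = np.array([0.0, 0.0, 0.0, -0.05])
    # unit gains per arm; inhibition slightly overweighted so the detector's
    # sustained (direction-independent) response rectifies away and the peak
    # is dominated by the directional transient
    gain = {("R", "EF"): 0.1, ("R", "IS"): 0.1, ("EF", "D"): 0.1, ("IS", "D"): 0.11}
    alpha = np.array([gain[p] for p in spec.pairs])
    params = ParamSet(tau=tau, v_rest=v_rest, alpha=alpha)
    # preferred direction: motion from the excitatory centre toward the flank
    x, y = hex_to_cartesian(np.array([off[0]]), np.array([off[1]]))
    pd = float(np.rad2deg(np.arctan2(y[0], x[0])) % 360.0)
    return MotionMotif(spec=spec, params=params, detector="D",
                       preferred_direction_deg=pd, inhib_offset=off)


@dataclass
class DetectorBank:
    """Four-direction variant of the motion motif (opponent channels)."""

    spec: ConnectomeSpec
    params: ParamSet
    detectors: tuple[str, ...]
    preferred_directions_deg: tuple[float, ...]


def make_detector_bank(delay_ratio: float = 4.0,
                       offsets=((1, 0), (-1, 0), (0, 1), (0, -1))) -> DetectorBank:
    """Motion-motif connectome with one detector type per flank offset.

    With the default four opponent flanks the bank spans the plane, so 2-D
    optic flow is decodable from the detector population -- the minimal
    connectome on which the flow task is well posed.
    """
    if delay_ratio <= 1:
        raise ValueError("delay ratio must exceed 1")
    det_names = tuple(f"D{i}" for i in range(len(offsets)))
    types = [CellTypeSpec("R"), CellTypeSpec("EF"), CellTypeSpec("IS")]
    types += [CellTypeSpec(n) for n in det_names]
    signs = SignTable()
    signs[("R", "EF")] = 1
    signs[("R", "IS")] = 1
    filters = [FilterEntry("R", "EF", 0, 0, 10.0), FilterEntry("R", "IS", 0, 0, 10.0)]
    for name, off in zip(det_names, offsets):
        signs[("EF", name)] = 1
        signs[("IS", name)] = -1
        filters.append(FilterEntry("EF", name, 0, 0, 10.0))
        filters.append(FilterEntry("IS", name, -off[0], -off[1], 10.0))
    spec = ConnectomeSpec(types=types, filters=filters, signs=signs,
                          input_types=("R",),
                          output_types=("EF",) + det_names)
    tau_fast = 20.0
    tau = np.array([tau_fast, tau_fast, tau_fast * delay_ratio]
                   + [tau_fast] * len(det_names))
    v_rest = np.array([0.0, 0.0, 0.0] + [-0.05] * len(det_names))
    alpha = np.array([0.1 if pre != "IS" else 0.11 for pre, _ in spec.pairs])
    pds = []
    for off in offsets:
        x, y = hex_to_cartesian(np.array([off[0]]), np.array([off[1]]))
        pds.append(float(np.rad2deg(np.arctan2(y[0], x[0])) % 360.0))
    return DetectorBank(spec=spec,
                        params=ParamSet(tau=tau, v_rest=v_rest, alpha=alpha),
                        detectors=det_names,
                        preferred_directions_deg=tuple(pds))


@dataclass
class DriftingDataset:
    train: list          # (StimulusSequence, flow (n_frames, 2, C))
    validation: list
    lattice: HexArray
    frame_dt: float


def _band_pattern(phase: np.ndarray, duty: float = 0.5) -> np.ndarray:
    """Binary band profile of a periodic pattern, values in {0.1, 0.9}."""
    return np.where((phase % 1.0) < duty, 0.9, 0.1)


def make_drifting_dataset(n_train: int = 16, n_val: int = 8, radius: int = 3,
                          n_frames: int = 19, frame_dt: float = 1000.0 / 24,
                          speeds=(4.0, 8.0), wavelength: float = 4.0,
                          seed: int = 0) -> DriftingDataset:
    """Rigidly drifting band patterns with exact analytic flow targets.

    Each sequence drifts a periodic band pattern at a constant velocity
    (columns/s) in a random direction; the flow target equals that velocity
    at every column and frame.  Train and validation sequences use disjoint
    random pattern phases and directions drawn from one seeded stream.
    """
    rng = np.random.default_rng(seed)
    lattice = enumerate_hex(radius)
    x, y = lattice.cartesian(1.0)
    C = len(lattice)

    def make_split(n):
        # balanced design: directions evenly spaced (with jitter), speeds
        # cycled, so neither split is biased toward a mean flow
        thetas = np.linspace(0, 2 * np.pi, n, endpoint=False)
        thetas = rng.permuted(thetas + rng.uniform(-0.1, 0.1, size=n))
        out = []
        for i in range(n):
            theta = float(thetas[i])
            speed = float(speeds[i % len(speeds)])     # columns / s
            phase0 = rng.uniform(0, 1)
            d = np.array([np.cos(theta), np.sin(theta)])
            proj = (x * d[0] + y * d[1]) / wavelength
            t = np.arange(n_frames) * frame_dt / 1000.0  # s
            phase = proj[None, :] - (speed / wavelength) * t[:, None] + phase0
            frames = _band_pattern(phase)
            flow = np.zeros((n_frames, 2, C))
            flow[:, 0, :] = speed * d[0]
            flow[:, 1, :] = speed * d[1]
            seq = StimulusSequence(frames, frame_dt, lattice,
                                   meta=dict(kind="drift", theta=float(np.rad2deg(theta)),
                                             speed=speed))
            out.append((seq, flow))
        return out

    return DriftingDataset(train=make_split(n_train), validation=make_split(n_val),
                           lattice=lattice, frame_dt=frame_dt)


def make_digit_task(n_train: int = 2000, n_test: int = 500, seed: int = 0,
                    noise: float = 0.5, size: int = 28):
    """10-class template-plus-noise images standing in for handwritten digits.

    Each class is a random smooth template on a size x size grid; samples
    are the class template plus i.i.d. Gaussian noise, clipped to [0, 1].
    Class balance is exact (n must be divisible by 10).  Returns
    (x_train, y_train, x_test, y_test) with images flattened.
    """
    if n_train % 10 or n_test % 10:
        raise ValueError("sample counts must be divisible by 10")
    rng = np.random.default_rng(seed)
    # smooth templates: low-frequency random fields, unit dynamic range
    k = 6
    templates = []
    for _ in range(10):
        coarse = rng.normal(0, 1, size=(k, k))
        fine = np.kron(coarse, np.ones((size // k + 1, size // k + 1)))[:size, :size]
        fine = (fine - fine.min()) / (fine.max() - fine.min())
        templates.append(fine.ravel())
    templates = np.stack(templates)

    def split(n):
        per = n // 10
        y = np.repeat(np.arange(10), per)
        xs = templates[y] + rng.normal(0, noise, size=(n, size * size))
        xs = np.clip(xs, 0.0, 1.0)
        order = rng.permutation(n)
        return xs[order], y[order]

    x_train, y_train = split(n_train)
    x_test, y_test = split(n_test)
    return x_train, y_train, x_test, y_test
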