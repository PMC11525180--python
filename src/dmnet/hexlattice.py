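"""Hexagonal retinotopic lattice: coordinates, symmetries, Cartesian embedding.

The visual-system model lives on a hexagonal lattice of ommatidial columns.
We use axial coordinates ``(u, v)`` with the implicit third cube coordinate
``-(u + v)``; a lattice of radius ``r`` contains every column with
``max(|u|, |v|, |u+v|) <= r``, i.e. ``3 r (r+1) + 1`` columns (radius 15 is
the "31 columns across" array of 721 columns).

Coordinates are enumerated ring by ring, sorted by Cartesian angle within a
ring, so buffer layouts are deterministic.  The Cartesian embedding is
pointy-top: the +u axis maps to +x, and angles are measured counterclockwise
from +x.  Direction-selectivity angles inherit this convention; comparisons
against external references should allow a global rotation/reflection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "HexArray",
    "enumerate_hex",
    "hex_rotate",
    "hex_flip",
    "hex_to_cartesian",
    "hex_distance",
    "hex_count",
]

_SQRT3_2 = np.sqrt(3.0) / 2.0


def hex_count(radius: int) -> int:
    """Number of columns in a hex lattice of the given radius: 3r(r+1)+1."""
    return 3 * radius * (radius + 1) + 1


def hex_distance(u, v) -> np.ndarray:
    """Hex (ring) distance from the origin."""
    u = np.asarray(u)
    v = np.asarray(v)
    return (np.abs(u) + np.abs(v) + np.abs(u + v)) // 2


def hex_to_cartesian(u, v, spacing: float = 1.0):
    """Pointy-top embedding; all nearest-neighbour pairs are `spacing` apart."""
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    return spacing * (u + 0.5 * v), spacing * (_SQRT3_2 * v)


def hex_rotate(u, v, k: int = 1):
    """Rotate axial coordinates by k*60 degrees counterclockwise."""
    u = np.asarray(u)
    v = np.asarray(v)
    for _ in range(k % 6):
        u, v = -v, u + v
    return u, v


def hex_flip(u, v, axis: int):
    """Reflect across one of the three principal axes (an involution).

    In cube coordinates (x, y, z) = (u, -u-v, v) the three reflections swap a
    pair of cube axes: axis 0 swaps x/z, axis 1 swaps x/y, axis 2 swaps y/z.
    """
    if axis not in (0, 1, 2):
        raise ValueError("axis must be 0, 1 or 2")
    u = np.asarray(u)
    v = np.asarray(v)
    if axis == 0:
        return v, u
    if axis == 1:
        return -u - v, v.copy() if hasattr(v, "copy") else v
    return u.copy() if hasattr(u, "copy") else u, -u - v


@dataclass(frozen=True)
class HexArray:
    """Ordered enumeration of a radius-r hex lattice with coord->index lookup."""

    radius: int
    u: np.ndarray
    v: np.ndarray
    index: dict = field(repr=False)

    def __len__(self) -> int:
        return len(self.u)

    def __contains__(self, coord) -> bool:
        return tuple(coord) in self.index

    def position(self, u: int, v: int) -> int:
        return self.index[(int(u), int(v))]

    def positions(self, u, v, missing: int = -1) -> np.ndarray:
        """Vectorized coord->index; `missing` for coords outside the lattice."""
        return np.array(
            [self.index.get((int(a), int(b)), missing) for a, b in zip(np.ravel(u), np.ravel(v))],
            dtype=np.int64,
        )

    def cartesian(self, spacing: float = 1.0):
        return hex_to_cartesian(self.u, self.v, spacing)


def enumerate_hex(radius: int) -> HexArray:
    """Enumerate the radius-r lattice ring by ring, angle-sorted within rings."""
    if radius < 0:
        raise ValueError("radius must be non-negative")
    us, vs = [0], [0]
    for r in range(1, radius + 1):
        ring_u, ring_v = [], []
        for u in range(-r, r + 1):
            for v in range(max(-r, -u - r), min(r, -u + r) + 1):
                if max(abs(u), abs(v), abs(u + v)) == r:
                    ring_u.append(u)
                    ring_v.append(v)
        x, y = hex_to_cartesian(np.array(ring_u), np.array(ring_v))
        order = np.argsort(np.mod(np.arctan2(y, x), 2 * np.pi), kind="stable")
        us.extend(np.array(ring_u)[order].tolist())
        vs.extend(np.array(ring_v)[order].tolist())
    u = np.array(us, dtype=np.int64)
    v = np.array(vs, dtype=np.int64)
    index = {(int(a), int(b)): i for i, (a, b) in enumerate(zip(u, v))}
    return HexArray(radius=radius, u=u, v=v, index=index)
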