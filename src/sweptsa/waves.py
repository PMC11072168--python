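"""Shared transmit-wave geometry used by both the simulator and the beamformer.

Keeping the delay and insonification conventions in one place guarantees the
forward model and the reconstruction agree on what t = 0 means:

* plane waves: t = 0 when the wavefront passes the array center, so a point
  at depth z on a 0° transmit echoes back at 2z/c;
* diverging waves: transmit delay is (‖p − vs‖ − d_vs)/c where d_vs is the
  virtual source's standoff behind the array plane, i.e. t = 0 when the
  spherical wavefront crosses the array plane.

Coordinates here are array-local (the caller subtracts the array pose).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "plane_delay",
    "plane_weight",
    "diverging_delay",
    "smoothstep_window",
]


def plane_delay(x, z, angle: float, c: float):
    """One-way arrival time of a steered plane wave at local (x, z)."""
    return (z * np.cos(angle) + x * np.sin(angle)) / c


def smoothstep_window(u, half_width: float, roll: float):
    """1 inside ±half_width, smooth cubic rolloff to 0 over ``roll`` outside."""
    if roll <= 0:
        return (np.abs(u) <= half_width).astype(float)
    s = np.clip((half_width + roll - np.abs(u)) / roll, 0.0, 1.0)
    return s * s * (3.0 - 2.0 * s)


def plane_weight(x, z, angle: float, footprint: float, roll: float = 2e-3):
    """Insonification weight of an aperture-limited steered plane wave.

    A finite aperture only launches the plane wave over its own footprint:
    a field point is insonified when its back-projection along the steering
    direction lands on the aperture.  The hard edge is softened by a
    ``roll``-wide smoothstep as a first-order stand-in for edge diffraction.
    """
    u = x - z * np.tan(angle)
    return smoothstep_window(u, footprint / 2.0, roll)


def diverging_delay(x, y, z, virtual_source, c: float):
    """Transmit delay of a diverging wave from a local virtual source."""
    vx, vy, vz = virtual_source
    dist = np.sqrt((x - vx) ** 2 + (y - vy) ** 2 + (z - vz) ** 2)
    return (dist - abs(vz)) / c
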