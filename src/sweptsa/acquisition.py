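"""Transducer geometry, transmit events, sweep trajectories and pulse sequencing.

Coordinate convention (used throughout the package): right-handed Cartesian
with lateral ``x`` along the element row (positive in the sweep direction),
elevation ``y``, and axial ``z`` positive into the medium.  The center of the
array at the first frame is the world origin.  All quantities are SI (meters,
seconds, Hz); the CLI and config layer accept the usual clinical units
(mm, µs, degrees) and convert at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "ArraySpec",
    "P4_2V",
    "TransmitEvent",
    "PulseSequence",
    "SweepTrajectory",
    "element_positions",
    "virtual_source_position",
    "make_sequence",
    "make_trajectory",
]


@dataclass(frozen=True)
class ArraySpec:
    """Physical description of a 1-D phased array.

    Defaults model a P4-2v-style small phased array: 64 elements, 0.3 mm
    pitch, 3 MHz center frequency, 80% fractional bandwidth.
    """

    n_elements: int = 64
    pitch: float = 0.3e-3
    center_frequency: float = 3.0e6
    fractional_bandwidth: float = 0.8
    sound_speed: float = 1540.0

    def __post_init__(self) -> None:
        if self.n_elements < 2:
            raise ValueError("n_elements must be >= 2")
        if self.pitch <= 0:
            raise ValueError("pitch must be positive")
        if not 0 < self.fractional_bandwidth < 2:
            raise ValueError("fractional_bandwidth must lie in (0, 2)")
        if self.center_frequency <= 0 or self.sound_speed <= 0:
            raise ValueError("center_frequency and sound_speed must be positive")

    @property
    def wavelength(self) -> float:
        return self.sound_speed / self.center_frequency

    @property
    def aperture(self) -> float:
        """Element-center extent, (n − 1) · pitch."""
        return (self.n_elements - 1) * self.pitch

    @property
    def footprint(self) -> float:
        """Physical footprint including the outer element half-widths, n · pitch."""
        return self.n_elements * self.pitch


#: The default small phased array used across the study.
P4_2V = ArraySpec()


def element_positions(spec: ArraySpec) -> np.ndarray:
    """Element-center positions, shape (n_elements, 3), centered on the origin.

    Elements are spaced by ``pitch`` along x with zero elevation and axial
    coordinates, symmetric about the array center.
    """
    x = (np.arange(spec.n_elements) - (spec.n_elements - 1) / 2.0) * spec.pitch
    pos = np.zeros((spec.n_elements, 3))
    pos[:, 0] = x
    return pos


@dataclass(frozen=True)
class TransmitEvent:
    """A single transmission within a frame.

    kind
        ``"plane"`` (optionally steered by ``angle``, radians) or
        ``"diverging"`` (requires ``virtual_source``).
    virtual_source
        Array-local (x, y, z) of the virtual point source; a negative z means
        the source sits behind the array plane and the wave diverges.
    subaperture
        ``(start, stop)`` element index range used to synthesize the virtual
        source (informational; the field model treats the source as a point).
    t_offset
        Transmit time within the frame, seconds from the frame timestamp.
    """

    kind: str
    angle: float = 0.0
    virtual_source: tuple[float, float, float] | None = None
    subaperture: tuple[int, int] | None = None
    t_offset: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("plane", "diverging"):
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.kind == "diverging" and self.virtual_source is None:
            raise ValueError("diverging events require a virtual_source")
        if self.kind == "plane" and self.virtual_source is not None:
            raise ValueError("plane events carry no virtual_source")


def virtual_source_position(
    spec: ArraySpec, subaperture: tuple[int, int], f_number: float
) -> np.ndarray:
    """Virtual-source position for a subaperture and transmit f-number.

    The source sits at the lateral center of the subaperture with axial
    coordinate ``f_number × subaperture width``; a negative f-number places it
    behind the array, producing a diverging wave.
    """
    start, stop = subaperture
    if not (0 <= start < stop <= spec.n_elements):
        raise ValueError(
            f"subaperture {subaperture} outside array of {spec.n_elements} elements"
        )
    if f_number == 0:
        raise ValueError("f_number must be nonzero")
    centers = element_positions(spec)[start:stop, 0]
    width = (stop - start) * spec.pitch
    return np.array([centers.mean(), 0.0, f_number * width])


@dataclass(frozen=True)
class PulseSequence:
    """Ordered transmit events repeated at ``frame_rate``.

    Event ``t_offset`` values are offsets from the frame timestamp (the time
    of the frame's first event); the whole pattern must fit within one frame
    period.
    """

    events: tuple[TransmitEvent, ...]
    frame_rate: float
    intra_frame_spacing: float

    def __post_init__(self) -> None:
        if not self.events:
            raise ValueError("sequence needs at least one event")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        period = 1.0 / self.frame_rate
        if len(self.events) * self.intra_frame_spacing >= period:
            raise ValueError(
                f"{len(self.events)} events at {self.intra_frame_spacing * 1e6:.0f} µs "
                f"spacing exceed the {period * 1e6:.0f} µs frame period"
            )
        offsets = [e.t_offset for e in self.events]
        if any(b <= a for a, b in zip(offsets, offsets[1:])):
            raise ValueError("event offsets must strictly increase")

    @property
    def frame_period(self) -> float:
        return 1.0 / self.frame_rate


def make_sequence(
    mode: str,
    spec: ArraySpec = P4_2V,
    frame_rate: float = 500.0,
    spacing: float = 260e-6,
    subaperture_size: int = 11,
    f_number: float = -0.75,
) -> PulseSequence:
    """Build the interleaved tracking/imaging pulse sequence.

    ``alternating_center`` interleaves a 0° plane wave with a single diverging
    wave from the array center.  ``left_right`` follows the plane wave with
    diverging waves from the left and then the right edge subapertures, which
    extends the synthesized transmit aperture by roughly a transducer length.
    """
    n = spec.n_elements
    if subaperture_size > n:
        raise ValueError("subaperture larger than array")

    def diverging(start: int, stop: int, t_offset: float) -> TransmitEvent:
        vs = virtual_source_position(spec, (start, stop), f_number)
        return TransmitEvent(
            "diverging",
            virtual_source=tuple(vs),
            subaperture=(start, stop),
            t_offset=t_offset,
        )

    plane = TransmitEvent("plane", t_offset=0.0)
    if mode == "alternating_center":
        lo = (n - subaperture_size) // 2
        events = (plane, diverging(lo, lo + subaperture_size, spacing))
    elif mode == "left_right":
        events = (
            plane,
            diverging(0, subaperture_size, spacing),
            diverging(n - subaperture_size, n, 2 * spacing),
        )
    else:
        raise ValueError(f"unknown sequence mode {mode!r}")
    return PulseSequence(events=events, frame_rate=frame_rate, intra_frame_spacing=spacing)


@dataclass(frozen=True)
class SweepTrajectory:
    """True lateral positions of the array center at each frame timestamp."""

    frame_times: np.ndarray
    lateral_positions: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.frame_times, dtype=float)
        x = np.asarray(self.lateral_positions, dtype=float)
        if t.shape != x.shape or t.ndim != 1:
            raise ValueError("frame_times and lateral_positions must be matching 1-D arrays")
        if t.size > 1 and np.any(np.diff(t) <= 0):
            raise ValueError("frame_times must strictly increase")
        if not np.all(np.isfinite(x)):
            raise ValueError("positions must be finite")
        object.__setattr__(self, "frame_times", t)
        object.__setattr__(self, "lateral_positions", x)

    @property
    def n_frames(self) -> int:
        return self.frame_times.size

    @property
    def extent(self) -> float:
        return float(self.lateral_positions.max() - self.lateral_positions.min())

    def position_at(self, t: np.ndarray | float) -> np.ndarray | float:
        """Linear interpolation of position at time(s) ``t``, clamped at the ends."""
        return np.interp(t, self.frame_times, self.lateral_positions)


def make_trajectory(
    extent: float,
    duration: float,
    frame_rate: float,
    profile: str = "constant",
    label: str | None = None,
) -> SweepTrajectory:
    """Sweep trajectory covering ``extent`` meters in ``duration`` seconds.

    ``constant`` moves at uniform velocity; ``smoothstep`` uses the cubic
    3s² − 2s³ ease, emulating the acceleration/deceleration of a manual sweep
    (zero velocity at both ends, peak velocity 1.5× the mean).
    """
    if extent < 0:
        raise ValueError("extent must be >= 0")
    if duration <= 0 or frame_rate <= 0:
        raise ValueError("duration and frame_rate must be positive")
    n = max(int(round(duration * frame_rate)), 1)
    times = np.arange(n) / frame_rate
    s = times / times[-1] if n > 1 else np.zeros(1)
    if profile == "constant":
        shape = s
    elif profile == "smoothstep":
        shape = s * s * (3.0 - 2.0 * s)
    else:
        raise ValueError(f"unknown trajectory profile {profile!r}")
    return SweepTrajectory(
        frame_times=times,
        lateral_positions=extent * shape,
        label=label if label is not None else f"{profile} {extent * 1e3:.1f} mm",
    )
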