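"""Delay-and-sum image formation.

All beamforming runs on the analytic (axially Hilbert-transformed) channel
signal so that frames can be combined coherently and the envelope is simply
the pixel magnitude.  Plane-wave images are formed in array-local
coordinates; diverging-wave frames acquired along a sweep are focused in
world coordinates using each frame's (true or estimated) pose.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import hilbert

from .acquisition import ArraySpec, element_positions
from .simulate import ChannelFrame
from . import waves

#: Tukey ratio of the dynamic receive aperture window (0 = rectangular).
DYNAMIC_APERTURE_TAPER = 0.5

__all__ = [
    "ImageGrid",
    "BeamformedImage",
    "das_plane_wave",
    "compound_reference",
    "das_diverging",
    "resample_sweep",
    "ssa_reconstruct",
    "envelope_log",
    "effective_aperture",
]


@dataclass(frozen=True)
class ImageGrid:
    """Uniform Cartesian pixel grid: lateral axis ``x``, axial axis ``z``."""

    x: np.ndarray
    z: np.ndarray

    def __post_init__(self) -> None:
        for name, ax in (("x", self.x), ("z", self.z)):
            ax = np.asarray(ax, dtype=float)
            if ax.ndim != 1 or ax.size < 2:
                raise ValueError(f"{name} axis must be 1-D with >= 2 samples")
            d = np.diff(ax)
            if np.any(d <= 0) or not np.allclose(d, d[0], rtol=1e-6):
                raise ValueError(f"{name} axis must be strictly increasing and uniform")
            object.__setattr__(self, name, ax)

    @classmethod
    def from_bounds(cls, xlim, zlim, dx: float, dz: float) -> "ImageGrid":
        return cls(
            x=np.arange(xlim[0], xlim[1] + dx / 2, dx),
            z=np.arange(zlim[0], zlim[1] + dz / 2, dz),
        )

    @property
    def dx(self) -> float:
        return float(self.x[1] - self.x[0])

    @property
    def dz(self) -> float:
        return float(self.z[1] - self.z[0])

    @property
    def shape(self) -> tuple[int, int]:
        return (self.z.size, self.x.size)


@dataclass(frozen=True)
class BeamformedImage:
    """Complex (analytic) pixel values on an ImageGrid, shape (nz, nx)."""

    grid: ImageGrid
    pixels: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pixels.shape != self.grid.shape:
            raise ValueError("pixels must match grid shape (nz, nx)")

    @property
    def envelope(self) -> np.ndarray:
        return np.abs(self.pixels)


def _analytic_baseband(frame: ChannelFrame) -> tuple[np.ndarray, float]:
    """Analytic channel signal demodulated to baseband.

    Interpolating the slowly-varying complex baseband and re-applying the
    carrier phase at the exact delay avoids the amplitude/phase ripple that
    linear interpolation of a carrier-frequency signal would introduce.
    """
    omega = 2.0 * math.pi * frame.spec.center_frequency
    analytic = hilbert(frame.rf.astype(np.float64), axis=0)
    t = frame.sample_times
    return analytic * np.exp(-1j * omega * t)[:, None], omega


def _gather(baseband: np.ndarray, e: int, idx: np.ndarray) -> np.ndarray:
    """Linear interpolation of baseband channel ``e`` at fractional sample indices."""
    n = baseband.shape[0]
    i0 = np.floor(idx).astype(np.int64)
    valid = (i0 >= 0) & (i0 < n - 1)
    i0c = np.clip(i0, 0, n - 2)
    frac = idx - i0
    col = baseband[:, e]
    out = col[i0c] * (1.0 - frac) + col[i0c + 1] * frac
    out[~valid] = 0.0
    return out


def _das(
    frame: ChannelFrame,
    grid: ImageGrid,
    tau_tx: np.ndarray,
    tx_weight,
    elem_x: np.ndarray,
    px: np.ndarray,
    pz: np.ndarray,
    f_number_rx: float | None,
    sound_speed: float,
    rx_taper: float = 0.0,
) -> np.ndarray:
    baseband, omega = _analytic_baseband(frame)
    static_apod = _tukey_weight(np.linspace(0.0, 1.0, elem_x.size), rx_taper)
    out = np.zeros(px.shape, dtype=np.complex128)
    for e, xe in enumerate(elem_x):
        r = np.hypot(px - xe, pz)
        tau = tau_tx + r / sound_speed
        contrib = _gather(baseband, e, (tau - frame.t0) * frame.fs)
        contrib *= static_apod[e] * np.exp(1j * omega * tau)
        if f_number_rx is not None:
            # dynamic aperture of the stated f-number, tapered so neither a
            # moving hard edge nor the static array edge textures the image
            u = (px - xe) * (f_number_rx / pz) + 0.5
            inside = (u >= 0.0) & (u <= 1.0)
            contrib = contrib * np.where(
                inside, _tukey_weight(np.clip(u, 0.0, 1.0), DYNAMIC_APERTURE_TAPER), 0.0
            )
        out += contrib
    if tx_weight is not None:
        out *= tx_weight
    return out


def das_plane_wave(
    frame: ChannelFrame,
    grid: ImageGrid,
    f_number_rx: float | None = 1.5,
    sound_speed: float | None = None,
    rx_taper: float = 0.0,
) -> BeamformedImage:
    """Delay-and-sum a (possibly steered) plane-wave frame in local coordinates.

    Receive channels are dynamically apodized to a rectangular aperture of
    the stated f-number (None = full aperture); pixels are weighted by the
    transmit insonification window of the steered wave.  ``sound_speed``
    overrides the array's true speed, for sound-speed-error studies.
    """
    if frame.event.kind != "plane":
        raise ValueError("das_plane_wave requires a plane transmit")
    spec = frame.spec
    c = sound_speed if sound_speed is not None else spec.sound_speed
    px, pz = np.meshgrid(grid.x, grid.z)
    tau_tx = waves.plane_delay(px, pz, frame.event.angle, c)
    tx_w = waves.plane_weight(px, pz, frame.event.angle, spec.footprint)
    elem_x = element_positions(spec)[:, 0]
    pixels = _das(frame, grid, tau_tx, tx_w, elem_x, px, pz, f_number_rx, c, rx_taper)
    return BeamformedImage(
        grid, pixels,
        provenance={"kind": "plane", "frame_index": frame.frame_index,
                    "angle": frame.event.angle},
    )


def compound_reference(
    frames,
    grid: ImageGrid,
    f_number_rx: float | None = None,
    sound_speed: float | None = None,
    rx_taper: float = 0.0,
) -> BeamformedImage:
    """Coherent plane-wave compounding over a set of steered transmits."""
    frames = list(frames)
    if not frames:
        raise ValueError("need at least one frame to compound")
    pixels = np.zeros(grid.shape, dtype=np.complex128)
    angles = []
    for frame in frames:
        img = das_plane_wave(frame, grid, f_number_rx=f_number_rx,
                             sound_speed=sound_speed, rx_taper=rx_taper)
        pixels += img.pixels
        angles.append(frame.event.angle)
    return BeamformedImage(grid, pixels, provenance={"kind": "compound", "angles": angles})


def das_diverging(
    frame: ChannelFrame,
    grid: ImageGrid,
    pose: float,
    f_number_rx: float | None = None,
    sound_speed: float | None = None,
) -> BeamformedImage:
    """Delay-and-sum a diverging-wave frame on a world-coordinate grid.

    The virtual source and receive elements are translated by ``pose``; the
    transmit delay uses the same virtual-source convention as the simulator
    (see :mod:`sweptsa.waves`).
    """
    if frame.event.kind != "diverging":
        raise ValueError("das_diverging requires a diverging transmit")
    if not math.isfinite(pose):
        raise ValueError("pose must be finite")
    spec = frame.spec
    c = sound_speed if sound_speed is not None else spec.sound_speed
    px, pz = np.meshgrid(grid.x, grid.z)
    tau_tx = waves.diverging_delay(px - pose, 0.0, pz, frame.event.virtual_source, c)
    elem_x = element_positions(spec)[:, 0] + pose
    pixels = _das(frame, grid, tau_tx, None, elem_x, px, pz, f_number_rx, c)
    return BeamformedImage(
        grid, pixels,
        provenance={"kind": "diverging", "frame_index": frame.frame_index, "pose": pose},
    )


def resample_sweep(positions, spacing: float = 0.5e-3) -> np.ndarray:
    """Greedy spatial resampling of sweep positions.

    Keeps the first frame, then every frame whose position differs from the
    last kept one by at least ``spacing``; stationary segments collapse to a
    single frame.  Returns the kept indices.
    """
    positions = np.asarray(positions, dtype=float)
    if positions.size == 0:
        return np.array([], dtype=int)
    if not np.all(np.isfinite(positions)):
        raise ValueError("positions must be finite")
    kept = [0]
    last = positions[0]
    for i in range(1, positions.size):
        if abs(positions[i] - last) >= spacing:
            kept.append(i)
            last = positions[i]
    return np.array(kept, dtype=int)


def _tukey_weight(u: np.ndarray, alpha: float) -> np.ndarray:
    """Tukey (tapered cosine) window evaluated at positions u ∈ [0, 1]."""
    u = np.asarray(u, dtype=float)
    if alpha <= 0:
        return np.ones_like(u)
    w = np.ones_like(u)
    edge = np.minimum(u, 1.0 - u)
    lo = edge < alpha / 2.0
    w[lo] = 0.5 * (1.0 + np.cos(math.pi * (2.0 * edge[lo] / alpha - 1.0)))
    return w


def ssa_reconstruct(
    frames,
    positions,
    grid: ImageGrid,
    taper: float = 0.25,
    spacing: float = 0.5e-3,
    f_number_rx: float | None = None,
) -> BeamformedImage:
    """Swept-synthetic-aperture reconstruction from diverging-wave frames.

    ``positions`` gives the (true or estimated) array pose of every frame,
    aligned 1:1 with ``frames``.  Repetitions are spatially resampled to
    ``spacing``, each retained diverging frame is beamformed at its own pose,
    left/right transmits are coherently combined, and frames are weighted by
    a Tukey window (ratio ``taper``) across the sweep's position axis.
    """
    frames = list(frames)
    positions = np.asarray(positions, dtype=float)
    if len(frames) == 0:
        raise ValueError("no diverging frames to reconstruct from")
    if positions.shape != (len(frames),):
        raise ValueError("positions must align 1:1 with frames")
    if any(f.event.kind != "diverging" for f in frames):
        raise ValueError("ssa_reconstruct expects diverging-wave frames only")

    # group frames by repetition (frame_index); resample on repetition centers
    rep_ids: list[int] = []
    rep_members: dict[int, list[int]] = {}
    for i, f in enumerate(frames):
        if f.frame_index not in rep_members:
            rep_ids.append(f.frame_index)
            rep_members[f.frame_index] = []
        rep_members[f.frame_index].append(i)
    rep_pos = np.array([np.mean(positions[rep_members[r]]) for r in rep_ids])
    sel = resample_sweep(rep_pos, spacing)
    sel_pos = rep_pos[sel]
    span = sel_pos.max() - sel_pos.min()
    if span > 0:
        # pad by half a frame spacing so end frames keep a nonzero weight
        h = span / (2.0 * max(sel.size - 1, 1))
        u = (sel_pos - sel_pos.min() + h) / (span + 2.0 * h)
    else:
        u = np.full(sel_pos.shape, 0.5)
    weights = _tukey_weight(u, taper)

    pixels = np.zeros(grid.shape, dtype=np.complex128)
    used = []
    for k, w in zip(sel, weights):
        for i in rep_members[rep_ids[k]]:
            img = das_diverging(
                frames[i], grid, pose=float(positions[i]),
                f_number_rx=f_number_rx,
            )
            pixels += w * img.pixels
            used.append((frames[i].frame_index, float(w)))
    return BeamformedImage(
        grid, pixels,
        provenance={"kind": "ssa", "frames": used, "taper": taper, "spacing": spacing},
    )


def envelope_log(image: BeamformedImage, dynamic_range: float = 50.0) -> np.ndarray:
    """Log-compressed envelope, normalized to a 0 dB peak, floored at −dynamic_range."""
    env = image.envelope
    peak = env.max()
    if peak == 0:
        raise ValueError("all-zero image cannot be log-compressed")
    with np.errstate(divide="ignore"):
        db = 20.0 * np.log10(env / peak)
    return np.maximum(db, -dynamic_range)


def effective_aperture(sweep_extent: float, spec: ArraySpec, sequence=None) -> dict:
    """Effective aperture diagnostic: the average of the swept transmit and
    receive aperture spans.

    The receive span is the sweep extent plus the array footprint.  The
    transmit span depends on where the virtual sources sit: diverging waves
    from the edge subapertures extend it by the distance between the two
    source centers (roughly a transducer length), center sources add nothing.
    """
    rx_span = sweep_extent + spec.footprint
    tx_extra = 0.0
    if sequence is not None:
        vs_x = [e.virtual_source[0] for e in sequence.events if e.kind == "diverging"]
        if vs_x:
            tx_extra = max(vs_x) - min(vs_x)
    tx_span = sweep_extent + tx_extra
    return {
        "receive_span": rx_span,
        "transmit_span": tx_span,
        "effective_aperture": 0.5 * (rx_span + tx_span),
    }
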