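"""Point-scatterer RF channel-data simulator.

A linear far-field model: every scatterer returns a Gaussian-modulated echo
pulse into every receive element, delayed by the transmit path plus the
element-to-scatterer distance and scaled by the scatterer amplitude, 1/r
receive spreading and (optionally) the element directivity.  The full
spatial-impulse-response integration of aperture simulators is deliberately
not reproduced; lateral resolution and inter-frame correlation — the
quantities this package studies — are governed by array geometry and pulse
bandwidth, which this model preserves.

The echo pulse is a closed-form function of (t − τ), evaluated through a
dense lookup table at the continuous arrival time of each scatterer, so
channel data sampled at the 20 MHz output rate carry no delay quantization.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .acquisition import ArraySpec, PulseSequence, SweepTrajectory, TransmitEvent, element_positions
from . import waves

__all__ = [
    "ScattererField",
    "ChannelFrame",
    "ssa_resolution_cell",
    "make_phantom",
    "simulate_frame",
    "simulate_sweep",
    "add_band_noise",
    "depth_time_window",
]

#: Echo pulse support, in envelope standard deviations, on each side of the peak.
PULSE_SUPPORT_SIGMAS = 5.0


def pulse_sigma(spec: ArraySpec) -> float:
    """Envelope std dev giving the array's −6 dB (two-way) fractional bandwidth."""
    return math.sqrt(2.0 * math.log(2.0)) / (
        math.pi * spec.fractional_bandwidth * spec.center_frequency
    )


def echo_pulse(t: np.ndarray, spec: ArraySpec) -> np.ndarray:
    """Gaussian-windowed sinusoid modeling the round-trip echo pulse."""
    s = pulse_sigma(spec)
    return np.exp(-(t**2) / (2.0 * s**2)) * np.cos(2.0 * math.pi * spec.center_frequency * t)


_LUT_CACHE: dict[tuple[float, float], tuple[np.ndarray, float, float]] = {}


def _pulse_lut(spec: ArraySpec) -> tuple[np.ndarray, float, float]:
    """Dense pulse table (values, t0, dt); linear interp error < −80 dB."""
    key = (spec.center_frequency, spec.fractional_bandwidth)
    if key not in _LUT_CACHE:
        half = PULSE_SUPPORT_SIGMAS * pulse_sigma(spec)
        dt = 1.0 / (256.0 * spec.center_frequency)
        t = np.arange(-half, half + dt, dt)
        _LUT_CACHE[key] = (echo_pulse(t, spec), float(t[0]), dt)
    return _LUT_CACHE[key]


try:  # accelerated deposit kernel; a vectorized numpy path backs it up
    from numba import njit

    @njit(cache=True, fastmath=True)
    def _deposit(rf, tau, amp, t0, fs, lut, lut_t0, lut_dt, half_support):  # pragma: no cover
        n_samples, _ = rf.shape
        n_scat, n_elem = tau.shape
        n_lut = lut.shape[0]
        for s in range(n_scat):
            for e in range(n_elem):
                a = amp[s, e]
                if a == 0.0:
                    continue
                tc = tau[s, e]
                i0 = int(math.ceil((tc - half_support - t0) * fs))
                i1 = int(math.floor((tc + half_support - t0) * fs))
                if i1 < 0 or i0 >= n_samples:
                    continue
                if i0 < 0:
                    i0 = 0
                if i1 >= n_samples:
                    i1 = n_samples - 1
                for i in range(i0, i1 + 1):
                    u = (t0 + i / fs - tc - lut_t0) / lut_dt
                    k = int(u)
                    if k < 0 or k >= n_lut - 1:
                        continue
                    f = u - k
                    rf[i, e] += a * (lut[k] * (1.0 - f) + lut[k + 1] * f)

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def _deposit(rf, tau, amp, t0, fs, lut, lut_t0, lut_dt, half_support):
        n_samples, n_elem = rf.shape
        n_win = int(math.ceil(2 * half_support * fs)) + 2
        offs = np.arange(n_win)
        for e in range(n_elem):
            i0 = np.ceil((tau[:, e] - half_support - t0) * fs).astype(np.int64)
            idx = i0[:, None] + offs[None, :]
            dt = t0 + idx / fs - tau[:, e][:, None]
            u = (dt - lut_t0) / lut_dt
            k = np.clip(u.astype(np.int64), 0, lut.size - 2)
            frac = u - k
            vals = amp[:, e][:, None] * (lut[k] * (1.0 - frac) + lut[k + 1] * frac)
            ok = (idx >= 0) & (idx < n_samples) & (u >= 0) & (u < lut.size - 1)
            np.add.at(rf[:, e], idx[ok], vals[ok])


@dataclass(frozen=True)
class ScattererField:
    """Point scatterers constituting a phantom.

    positions : (N, 3) meters; amplitudes : (N,) reflectivities;
    extents : (3, 2) bounding box, one (lo, hi) row per axis.
    """

    positions: np.ndarray
    amplitudes: np.ndarray
    extents: np.ndarray

    def __post_init__(self) -> None:
        pos = np.atleast_2d(np.asarray(self.positions, dtype=float))
        amp = np.atleast_1d(np.asarray(self.amplitudes, dtype=float))
        ext = np.asarray(self.extents, dtype=float)
        if pos.shape != (amp.size, 3) or ext.shape != (3, 2):
            raise ValueError("positions (N,3), amplitudes (N,), extents (3,2) required")
        if not np.all(np.isfinite(amp)) or not np.all(np.isfinite(pos)):
            raise ValueError("positions and amplitudes must be finite")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "amplitudes", amp)
        object.__setattr__(self, "extents", ext)

    @property
    def n_scatterers(self) -> int:
        return self.amplitudes.size

    def __add__(self, other: "ScattererField") -> "ScattererField":
        ext = np.column_stack(
            [
                np.minimum(self.extents[:, 0], other.extents[:, 0]),
                np.maximum(self.extents[:, 1], other.extents[:, 1]),
            ]
        )
        return ScattererField(
            np.vstack([self.positions, other.positions]),
            np.concatenate([self.amplitudes, other.amplitudes]),
            ext,
        )


@dataclass(frozen=True)
class ChannelFrame:
    """RF channel data for one transmit event.

    rf : (samples, elements), fs : sampling rate, t0 : time of the first
    sample after the transmit reference (see :mod:`sweptsa.waves`),
    pose : true lateral position of the array center at acquisition.
    """

    rf: np.ndarray
    fs: float
    t0: float
    event: TransmitEvent
    pose: float
    frame_index: int
    spec: ArraySpec

    @property
    def n_samples(self) -> int:
        return self.rf.shape[0]

    @property
    def sample_times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs


def ssa_resolution_cell(
    spec: ArraySpec = ArraySpec(),
    depth: float = 60e-3,
    effective_aperture: float = 70e-3,
    elevation: float | None = None,
) -> tuple[float, float | None, float]:
    """Resolution cell (x, y, z dimensions) at the expected swept-aperture scale.

    Lateral size λ·depth/effective aperture, axial λ/2, elevation the slab
    thickness (None for 2-D slabs).
    """
    lam = spec.wavelength
    return (lam * depth / effective_aperture, elevation, lam / 2.0)


def make_phantom(
    extents,
    density: float = 15.0,
    resolution_cell: tuple[float, float | None, float] | None = None,
    lesions: tuple[tuple[tuple[float, float, float], float], ...] = (),
    points: tuple[tuple[float, float, float], ...] = (),
    seed: int = 0,
    point_amplitude_db: float = 40.0,
    spec: ArraySpec = ArraySpec(),
) -> ScattererField:
    """Random speckle phantom with optional anechoic lesions and point targets.

    Scatterer count is Poisson with mean ``density`` per resolution cell over
    the box volume (axes of zero width are skipped, so a 2-D slab works).
    Positions are uniform, amplitudes i.i.d. standard normal.  Scatterers
    inside lesion spheres are removed; point targets are appended with
    amplitude ``point_amplitude_db`` above the speckle RMS.
    """
    if density <= 0:
        raise ValueError("density must be positive")
    ext = np.asarray(extents, dtype=float).reshape(3, 2)
    if resolution_cell is None:
        resolution_cell = ssa_resolution_cell(spec)
    widths = ext[:, 1] - ext[:, 0]
    expected = density
    for w, cell in zip(widths, resolution_cell):
        if w > 0:
            if cell is None or cell <= 0:
                raise ValueError("finite resolution_cell needed for every extended axis")
            expected *= w / cell
    rng = np.random.default_rng(seed)
    n = int(rng.poisson(expected))
    pos = ext[:, 0] + rng.uniform(size=(n, 3)) * widths
    amp = rng.standard_normal(n)

    for center, radius in lesions:
        c = np.asarray(center, dtype=float)
        keep = np.linalg.norm(pos - c, axis=1) >= radius
        pos, amp = pos[keep], amp[keep]

    if points:
        speckle_rms = 1.0  # standard-normal speckle amplitudes
        p_amp = speckle_rms * 10.0 ** (point_amplitude_db / 20.0)
        for p in points:
            p = np.asarray(p, dtype=float)
            for center, radius in lesions:
                if np.linalg.norm(p - np.asarray(center)) < radius:
                    warnings.warn("point target lies inside an anechoic lesion; placing anyway")
            pos = np.vstack([pos, p])
            amp = np.append(amp, p_amp)
    return ScattererField(pos, amp, ext)


def _transmit(field: ScattererField, event: TransmitEvent, pose: float, spec: ArraySpec):
    """Per-scatterer transmit delay and insonification weight (array-local)."""
    x = field.positions[:, 0] - pose
    y = field.positions[:, 1]
    z = field.positions[:, 2]
    if event.kind == "plane":
        tau = waves.plane_delay(x, z, event.angle, spec.sound_speed)
        w = waves.plane_weight(x, z, event.angle, spec.footprint)
    else:
        tau = waves.diverging_delay(x, y, z, event.virtual_source, spec.sound_speed)
        w = np.ones_like(tau)
    return tau, w


def simulate_frame(
    field: ScattererField,
    spec: ArraySpec,
    event: TransmitEvent,
    pose: float = 0.0,
    fs: float = 20e6,
    t0: float | None = None,
    n_samples: int | None = None,
    directivity: str = "rect",
    frame_index: int = 0,
) -> ChannelFrame:
    """Simulate the RF channel data of a single transmit event.

    ``directivity`` selects the receive element sensitivity pattern:
    ``"rect"`` (hard-baffle strip of width = pitch: sinc × cosine, the
    default), ``"cos"`` or ``"none"``.
    """
    if not math.isfinite(pose):
        raise ValueError("pose must be finite")
    lut, lut_t0, lut_dt = _pulse_lut(spec)
    half_support = PULSE_SUPPORT_SIGMAS * pulse_sigma(spec)

    if field.n_scatterers == 0:
        if t0 is None:
            t0 = 0.0
        if n_samples is None:
            n_samples = 16
        rf = np.zeros((n_samples, spec.n_elements), dtype=np.float32)
        return ChannelFrame(rf, fs, t0, event, pose, frame_index, spec)

    tau_tx, tx_w = _transmit(field, event, pose, spec)
    elem = element_positions(spec)
    dx = field.positions[:, 0, None] - (elem[None, :, 0] + pose)
    dy = field.positions[:, 1, None]
    dz = field.positions[:, 2, None]
    lateral = np.hypot(dx, dy)
    dist = np.hypot(lateral, dz)
    np.maximum(dist, spec.wavelength / 4.0, out=dist)  # guard 1/r at the face

    if directivity == "none":
        d = 1.0
    else:
        cos_t = dz / dist
        if directivity == "cos":
            d = cos_t
        elif directivity == "rect":
            sin_t = lateral / dist
            d = np.sinc(spec.pitch * sin_t / spec.wavelength) * cos_t
        else:
            raise ValueError(f"unknown directivity {directivity!r}")

    amp = (field.amplitudes * tx_w)[:, None] * d / dist
    tau = tau_tx[:, None] + dist / spec.sound_speed

    if t0 is None:
        t0 = float(tau.min()) - 1.5 * half_support
    if n_samples is None:
        n_samples = int(math.ceil((float(tau.max()) + 1.5 * half_support - t0) * fs)) + 1

    rf = np.zeros((n_samples, spec.n_elements), dtype=np.float64)
    _deposit(
        rf,
        np.ascontiguousarray(tau),
        np.ascontiguousarray(amp, dtype=np.float64),
        float(t0),
        float(fs),
        lut,
        lut_t0,
        lut_dt,
        half_support,
    )
    return ChannelFrame(rf.astype(np.float32), fs, float(t0), event, pose, frame_index, spec)


def depth_time_window(
    depth_range: tuple[float, float], spec: ArraySpec, fs: float = 20e6
) -> tuple[float, int]:
    """(t0, n_samples) covering two-way echoes from a depth band.

    Allows for off-axis receive paths out to the array footprint and for the
    pulse support on both ends.
    """
    zmin, zmax = depth_range
    c = spec.sound_speed
    half = PULSE_SUPPORT_SIGMAS * pulse_sigma(spec)
    t_lo = 2.0 * zmin / c - 3.0 * half
    t_hi = (zmax + math.hypot(zmax, spec.footprint)) / c + 3.0 * half
    return t_lo, int(math.ceil((t_hi - t_lo) * fs)) + 1


def simulate_sweep(
    field: ScattererField,
    spec: ArraySpec,
    sequence: PulseSequence,
    trajectory: SweepTrajectory,
    fs: float = 20e6,
    depth_window: tuple[float, float] | None = None,
    directivity: str = "rect",
) -> list[ChannelFrame]:
    """One ChannelFrame per event per repetition along a sweep.

    The pose of each event is interpolated from the trajectory at the event's
    absolute time (frame timestamp + intra-frame offset).  When
    ``depth_window`` is given all frames share the same record window, which
    downstream raw-channel correlation requires; otherwise each frame gets a
    window fitted to its own echoes.
    """
    t0 = n_samples = None
    if depth_window is not None:
        t0, n_samples = depth_time_window(depth_window, spec, fs)
    frames = []
    for i, frame_time in enumerate(trajectory.frame_times):
        for event in sequence.events:
            pose = float(trajectory.position_at(frame_time + event.t_offset))
            frames.append(
                simulate_frame(
                    field, spec, event, pose=pose, fs=fs, t0=t0,
                    n_samples=n_samples, directivity=directivity, frame_index=i,
                )
            )
    return frames


def add_band_noise(
    frame: ChannelFrame,
    snr_db: float,
    reference_depth: float,
    band: tuple[float, float] | None = None,
    seed: int = 0,
    window_extent: float = 10e-3,
    signal_power: float | None = None,
) -> ChannelFrame:
    """Add band-limited Gaussian channel noise at a prescribed in-window SNR.

    White Gaussian noise is band-pass filtered to ``band`` (default: the
    pulse's −6 dB band) and scaled so that, within the axial window of
    ``window_extent`` centered on ``reference_depth``, signal power over
    noise power equals ``snr_db``.  Each channel gets independent noise.
    ``signal_power`` overrides the measured in-window power, for applying a
    common noise floor across frames with differing signal content.
    """
    if math.isinf(snr_db) and snr_db > 0:
        return replace(frame)
    spec = frame.spec
    if band is None:
        h = spec.fractional_bandwidth / 2.0
        band = (spec.center_frequency * (1 - h), spec.center_frequency * (1 + h))
    f_lo, f_hi = band
    if not 0 < f_lo < f_hi < frame.fs / 2.0:
        raise ValueError("band must satisfy 0 < f_lo < f_hi < fs/2")

    c = spec.sound_speed
    t = frame.sample_times
    sel = np.abs(t - 2.0 * reference_depth / c) <= window_extent / c  # two-way window
    if not np.any(sel):
        raise ValueError("reference window outside recorded samples")
    if signal_power is not None:
        sig_power = float(signal_power)
    else:
        sig_power = float(np.mean(frame.rf[sel].astype(np.float64) ** 2))
    if sig_power == 0.0:
        raise ValueError("zero signal power in reference window; SNR undefined")

    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(frame.rf.shape)
    sos = signal.butter(4, band, btype="bandpass", fs=frame.fs, output="sos")
    noise = signal.sosfiltfilt(sos, noise, axis=0)
    noise_power = float(np.mean(noise[sel] ** 2))
    scale = math.sqrt(sig_power / noise_power * 10.0 ** (-snr_db / 10.0))
    rf = frame.rf + (scale * noise).astype(np.float32)
    return replace(frame, rf=rf)
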