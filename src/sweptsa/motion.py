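"""Lateral transducer motion estimation from plane-wave frames.

Two estimators are provided.  Speckle tracking correlates an
envelope-detected image kernel laterally between beamformed plane-wave
images; channel correlation correlates axially-windowed raw RF from
spatially overlapping element subsets, without any beamforming.  Both
produce a displacement quantized to their native lateral sampling (image
pixel / element pitch) which is refined by band-limited subsample peak
interpolation, then fused over many frame pairs by weighted least squares.

Sign convention: displacements are transducer motion (position of the later
frame minus the earlier one).  The apparent motion of the scene in image or
channel space is the opposite of the transducer motion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .beamform import BeamformedImage
from .simulate import ChannelFrame

__all__ = [
    "CorrelationCurve",
    "PairEstimate",
    "TrajectoryEstimate",
    "BoundaryPeakError",
    "subsample_peak",
    "speckle_track_pair",
    "channel_correlate_pair",
    "build_multilag_system",
    "solve_wls",
    "estimate_trajectory",
    "interpolate_event_positions",
]


class BoundaryPeakError(RuntimeError):
    """The correlation maximum sits at the edge of the searched lag range."""


@dataclass(frozen=True)
class CorrelationCurve:
    """Normalized correlation versus lag (strictly increasing, uniform lags)."""

    lags: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        lags = np.asarray(self.lags, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if lags.shape != values.shape or lags.ndim != 1:
            raise ValueError("lags and values must be matching 1-D arrays")
        if np.any(np.diff(lags) <= 0):
            raise ValueError("lags must strictly increase")
        object.__setattr__(self, "lags", lags)
        object.__setattr__(self, "values", values)


@dataclass(frozen=True)
class PairEstimate:
    """Estimated transducer displacement between frames i < j (meters)."""

    i: int
    j: int
    displacement: float
    peak_corr: float


@dataclass(frozen=True)
class TrajectoryEstimate:
    """Per-frame lateral positions with the weighted least-squares system
    (H, W, Y) that produced them; position of ``anchor`` is fixed at 0."""

    H: np.ndarray
    Y: np.ndarray
    W: np.ndarray
    positions: np.ndarray
    anchor: int = 0


def subsample_peak(curve: CorrelationCurve, method: str = "iterative") -> tuple[float, float]:
    """Continuous-lag location and value of the correlation peak.

    ``iterative`` reconstructs the sampled curve with a band-limited (sinc)
    basis and refines the maximum by bounded scalar optimization to 1e-4
    sample; ``polynomial`` fits a parabola through the three samples around
    the discrete maximum.  Raises :class:`BoundaryPeakError` when the
    discrete maximum is not interior.
    """
    v = curve.values
    if v.size < 3:
        raise ValueError("need at least 3 correlation samples")
    k = int(np.argmax(v))
    if k == 0 or k == v.size - 1:
        raise BoundaryPeakError("correlation peak at search boundary; widen the search")
    step = curve.lags[1] - curve.lags[0]

    if method == "polynomial":
        denom = v[k - 1] - 2.0 * v[k] + v[k + 1]
        delta = 0.0 if denom == 0 else 0.5 * (v[k - 1] - v[k + 1]) / denom
        peak = v[k] - 0.25 * (v[k - 1] - v[k + 1]) * delta
        return float(curve.lags[k] + delta * step), float(peak)
    if method != "iterative":
        raise ValueError(f"unknown subsample method {method!r}")

    idx = np.arange(v.size, dtype=float)

    def recon(u: float) -> float:
        return float(np.dot(v, np.sinc(u - idx)))

    res = minimize_scalar(
        lambda u: -recon(u),
        bounds=(k - 1.0, k + 1.0),
        method="bounded",
        options={"xatol": 1e-4},
    )
    u = float(res.x)
    return float(curve.lags[0] + u * step), recon(u)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = math.sqrt(float(np.dot(a, a)) * float(np.dot(b, b)))
    return float(np.dot(a, b)) / denom if denom > 0 else 0.0


def speckle_track_pair(
    img_ref: BeamformedImage,
    img_tgt: BeamformedImage,
    kernel: tuple[float, float, float] = (20e-3, 10e-3, 10e-3),
    search: float = 2.5e-3,
    kernel_center_x: float = 0.0,
    subsample: str = "iterative",
) -> tuple[PairEstimate, CorrelationCurve]:
    """Lateral speckle tracking between two envelope-detected plane-wave images.

    ``kernel`` is (center depth, axial extent, lateral extent).  The kernel
    from the reference image is correlated laterally against the target over
    ±``search``; the subsample-refined peak lag, negated, is the transducer
    displacement.
    """
    grid = img_ref.grid
    if not (np.array_equal(grid.x, img_tgt.grid.x) and np.array_equal(grid.z, img_tgt.grid.z)):
        raise ValueError("both images must share one Cartesian grid")
    depth, ax_extent, lat_extent = kernel

    rows = np.flatnonzero(np.abs(grid.z - depth) <= ax_extent / 2.0)
    cols = np.flatnonzero(np.abs(grid.x - kernel_center_x) <= lat_extent / 2.0)
    if rows.size < 2 or cols.size < 2:
        raise ValueError("kernel does not fit inside the image grid")
    n_search = int(math.ceil(search / grid.dx))
    if cols[0] - n_search < 0 or cols[-1] + n_search >= grid.x.size:
        raise ValueError("kernel + search region extends beyond the image extent")

    env_ref = img_ref.envelope
    env_tgt = img_tgt.envelope
    k0 = env_ref[np.ix_(rows, cols)]
    k0 = k0 - k0.mean()
    k_norm = float(np.sum(k0 * k0))

    strip = env_tgt[np.ix_(rows, np.arange(cols[0] - n_search, cols[-1] + n_search + 1))]
    windows = np.lib.stride_tricks.sliding_window_view(strip, cols.size, axis=1)
    # windows: (n_rows, 2 n_search + 1, kernel_cols)
    n = k0.size
    s_w = windows.sum(axis=(0, 2))
    s_w2 = np.einsum("rlk,rlk->l", windows, windows)
    cov = np.einsum("rlk,rk->l", windows, k0)
    var_w = s_w2 - s_w**2 / n
    denom = np.sqrt(np.maximum(var_w * k_norm, 0.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(denom > 0, cov / denom, 0.0)

    lags = (np.arange(-n_search, n_search + 1)) * grid.dx
    curve = CorrelationCurve(lags=lags, values=corr)
    lag, peak = subsample_peak(curve, method=subsample)
    i = int(img_ref.provenance.get("frame_index", 0))
    j = int(img_tgt.provenance.get("frame_index", 1))
    return (
        PairEstimate(i=i, j=j, displacement=-lag, peak_corr=min(peak, 1.0)),
        curve,
    )


def channel_correlate_pair(
    frame_ref: ChannelFrame,
    frame_tgt: ChannelFrame,
    depth: float = 20e-3,
    axial_extent: float = 10e-3,
    max_shift: int = 10,
    sound_speed: float | None = None,
    subsample: str = "iterative",
    element_taper: float = 0.5,
) -> tuple[PairEstimate, CorrelationCurve]:
    """Displacement from raw channel correlation of overlapping subapertures.

    For each integer element shift k the axially-windowed RF of elements
    [k:] of the reference frame is correlated against elements [:E−k] of the
    target (mirrored for negative k), forming a curve on the lag grid
    k × pitch whose refined peak is the transducer displacement — no
    beamforming involved.  ``sound_speed`` only selects the depth window.

    ``element_taper`` applies a Tukey window across the overlapped elements
    before correlating; the hard subaperture edge otherwise aliases the
    pitch-sampled coherence function and inflates the cyclic subsample error.
    """
    for f in (frame_ref, frame_tgt):
        if f.event.kind != "plane":
            raise ValueError("channel correlation uses plane-wave frames")
    spec = frame_ref.spec
    if not 0 < max_shift < spec.n_elements:
        raise ValueError("max_shift must lie in (0, n_elements)")
    c = sound_speed if sound_speed is not None else spec.sound_speed

    t = frame_ref.sample_times
    t_lo = 2.0 * (depth - axial_extent / 2.0) / c
    t_hi = 2.0 * (depth + axial_extent / 2.0) / c
    if t_lo < t[0] or t_hi > t[-1]:
        raise ValueError("axial window outside recorded samples")
    rows = (t >= t_lo) & (t <= t_hi)
    a = frame_ref.rf[rows].astype(np.float64)
    b = frame_tgt.rf[rows].astype(np.float64)

    from .beamform import _tukey_weight

    shifts = np.arange(-max_shift, max_shift + 1)
    corr = np.empty(shifts.size)
    n_elem = spec.n_elements
    for idx, k in enumerate(shifts):
        if k >= 0:
            aa, bb = a[:, k:], b[:, : n_elem - k]
        else:
            aa, bb = a[:, : n_elem + k], b[:, -k:]
        w = _tukey_weight(np.linspace(0.0, 1.0, aa.shape[1]), element_taper)[None, :]
        corr[idx] = _pearson((aa * w).ravel(), (bb * w).ravel())

    curve = CorrelationCurve(lags=shifts * spec.pitch, values=corr)
    lag, peak = subsample_peak(curve, method=subsample)
    return (
        PairEstimate(
            i=frame_ref.frame_index,
            j=frame_tgt.frame_index,
            displacement=lag,
            peak_corr=min(peak, 1.0),
        ),
        curve,
    )


def build_multilag_system(items, pair_fn, max_lag: int = 10):
    """Pairwise displacement observations for every pair up to ``max_lag`` apart.

    ``pair_fn(ref, tgt)`` returns ``(PairEstimate, CorrelationCurve)`` (a
    bare PairEstimate also works).  Returns ``(H, Y, W)``: the difference
    matrix with one row per ordered pair (−1 at i, +1 at j), the observed
    displacements and the diagonal weights (peak correlation clipped to
    [0, 1]).
    """
    items = list(items)
    n = len(items)
    if n < 2:
        raise ValueError("need at least two frames")
    if max_lag < 1:
        raise ValueError("max_lag must be >= 1")
    rows, ys, ws = [], [], []
    for i in range(n - 1):
        for j in range(i + 1, min(i + max_lag, n - 1) + 1):
            est = pair_fn(items[i], items[j])
            if isinstance(est, tuple):
                est = est[0]
            row = np.zeros(n)
            row[i], row[j] = -1.0, 1.0
            rows.append(row)
            ys.append(est.displacement)
            ws.append(min(max(est.peak_corr, 0.0), 1.0))
    return np.array(rows), np.array(ys), np.array(ws)


def solve_wls(H: np.ndarray, Y: np.ndarray, W: np.ndarray, anchor: int = 0) -> TrajectoryEstimate:
    """Weighted least-squares fusion of pairwise displacements.

    Minimizes Σ w_r (H_r X − Y_r)² with the gauge fixed by X[anchor] = 0
    (the difference operator annihilates constants, so the unconstrained
    normal equations are singular).  Raises if the weighted pair graph does
    not connect all frames, naming the disconnected components.
    """
    H = np.asarray(H, dtype=float)
    Y = np.asarray(Y, dtype=float)
    W = np.asarray(W, dtype=float)
    if np.any(W < 0):
        raise ValueError("weights must be nonnegative")
    n_obs, n_frames = H.shape

    active = W > 0
    ii, jj = [], []
    for r in np.flatnonzero(active):
        nz = np.flatnonzero(H[r])
        if nz.size == 2:
            ii.append(nz[0])
            jj.append(nz[1])
    adj = coo_matrix((np.ones(len(ii)), (ii, jj)), shape=(n_frames, n_frames))
    n_comp, labels = connected_components(adj, directed=False)
    if n_comp > 1:
        groups = [[int(k) for k in np.flatnonzero(labels == c)] for c in range(n_comp)]
        raise ValueError(f"pair graph is disconnected; components: {groups}")

    keep = [k for k in range(n_frames) if k != anchor]
    sw = np.sqrt(W)
    x_red, *_ = np.linalg.lstsq(sw[:, None] * H[:, keep], sw * Y, rcond=None)
    positions = np.zeros(n_frames)
    positions[keep] = x_red
    return TrajectoryEstimate(H=H, Y=Y, W=W, positions=positions, anchor=anchor)


def estimate_trajectory(items, pair_fn, max_lag: int = 10, anchor: int = 0) -> TrajectoryEstimate:
    """Convenience: build the multi-lag system and solve it in one call."""
    H, Y, W = build_multilag_system(items, pair_fn, max_lag=max_lag)
    return solve_wls(H, Y, W, anchor=anchor)


def interpolate_event_positions(positions, plane_times, event_times) -> np.ndarray:
    """Linearly interpolate plane-frame position estimates to other event times.

    Queries outside the plane-wave time span are clamped to the end values.
    """
    positions = np.asarray(positions, dtype=float)
    plane_times = np.asarray(plane_times, dtype=float)
    if positions.shape != plane_times.shape:
        raise ValueError("positions and plane_times must align")
    return np.interp(event_times, plane_times, positions)
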