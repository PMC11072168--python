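"""Image-quality and trajectory-accuracy metrics: lateral PSF / FWHM,
generalized contrast-to-noise ratio (gCNR), and position-error summaries."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .beamform import BeamformedImage

__all__ = ["PSFMeasurement", "ErrorSummary", "lateral_psf", "gcnr", "error_summary"]


@dataclass(frozen=True)
class PSFMeasurement:
    """Lateral point-spread-function slice through the target peak.

    ``profile_db`` is peak-normalized to 0 dB; ``fwhm`` is measured on the
    linear envelope amplitude (−6.02 dB crossings, linearly interpolated).
    """

    lateral: np.ndarray
    profile_db: np.ndarray
    fwhm: float
    peak_position: float


@dataclass(frozen=True)
class ErrorSummary:
    """Summary statistics of per-frame position errors (estimated − truth)."""

    errors: np.ndarray
    bias: float
    sd: float
    rmse: float
    max_abs: float


def lateral_psf(
    image: BeamformedImage,
    approx_point: tuple[float, float],
    search_radius: float = 3e-3,
) -> PSFMeasurement:
    """Measure the lateral PSF of a point target near ``approx_point`` (x, z).

    Locates the envelope peak within ``search_radius``, slices the lateral
    line at the peak depth, normalizes it to 0 dB and computes the FWHM from
    the half-amplitude crossings on either side of the peak.
    """
    grid = image.grid
    env = image.envelope
    x0, z0 = approx_point
    cols = np.flatnonzero(np.abs(grid.x - x0) <= search_radius)
    rows = np.flatnonzero(np.abs(grid.z - z0) <= search_radius)
    if cols.size == 0 or rows.size == 0:
        raise ValueError("approx_point outside the image grid")
    sub = env[np.ix_(rows, cols)]
    r, c = np.unravel_index(np.argmax(sub), sub.shape)
    iz, ix = rows[r], cols[c]

    profile = env[iz, :].astype(float)
    peak = profile[ix]
    if peak <= 0:
        raise ValueError("zero peak amplitude; no point target found")
    half = peak / 2.0

    def crossing(direction: int) -> float:
        k = ix
        while 0 <= k + direction < profile.size and profile[k + direction] >= half:
            k += direction
        nxt = k + direction
        if nxt < 0 or nxt >= profile.size:
            raise ValueError("half-maximum not bracketed within the image")
        frac = (profile[k] - half) / (profile[k] - profile[nxt])
        return grid.x[k] + frac * (grid.x[nxt] - grid.x[k])

    fwhm = crossing(+1) - crossing(-1)
    with np.errstate(divide="ignore"):
        profile_db = 20.0 * np.log10(profile / peak)
    return PSFMeasurement(
        lateral=grid.x.copy(),
        profile_db=profile_db,
        fwhm=float(fwhm),
        peak_position=float(grid.x[ix]),
    )


def gcnr(image, region_in: np.ndarray, region_out: np.ndarray, n_bins: int = 256) -> float:
    """Generalized contrast-to-noise ratio of two image regions.

    gCNR = 1 − Σ_k min(f_k, g_k) where f and g are the histograms of the two
    regions' envelope values, normalized to unit sum, computed on ``n_bins``
    equal-width bins spanning the pooled min–max of both regions.  Bounded in
    [0, 1]: 0 for identical distributions, 1 for disjoint value supports.
    """
    values = image.envelope if isinstance(image, BeamformedImage) else np.asarray(image)
    region_in = np.asarray(region_in, dtype=bool)
    region_out = np.asarray(region_out, dtype=bool)
    if region_in.shape != values.shape or region_out.shape != values.shape:
        raise ValueError("region masks must match the image shape")
    if np.any(region_in & region_out):
        raise ValueError("regions must be disjoint")
    a = values[region_in].ravel()
    b = values[region_out].ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("both regions must be non-empty")
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    if lo == hi:
        return 0.0
    edges = np.linspace(lo, hi, n_bins + 1)
    f, _ = np.histogram(a, bins=edges)
    g, _ = np.histogram(b, bins=edges)
    f = f / f.sum()
    g = g / g.sum()
    return float(1.0 - np.minimum(f, g).sum())


def error_summary(estimated, truth) -> ErrorSummary:
    """Per-frame position errors and their bias / sd / rmse / max statistics.

    Both trajectories must share an anchor (the rmse decomposition
    rmse² = bias² + sd² uses the population standard deviation).
    """
    estimated = np.asarray(estimated, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if estimated.shape != truth.shape:
        raise ValueError("estimated and truth must have equal length")
    errors = estimated - truth
    bias = float(errors.mean())
    sd = float(errors.std(ddof=0))
    rmse = float(math.sqrt(np.mean(errors**2)))
    return ErrorSummary(
        errors=errors, bias=bias, sd=sd, rmse=rmse, max_abs=float(np.abs(errors).max())
    )
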