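"""Spectral pre-treatment: rubber-band baseline, smoothing, segmentation.

The chain applied before deconvolution is, in order: rubber-band baseline
correction (lower convex hull of the spectrum, removing fluorescence and
zero offset), second-order Savitzky-Golay smoothing over 9 points, and
segmentation to the 1495-1535 cm^-1 window containing the C=C stretching
band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .errors import EmptySegmentError, ValidationError
from .io import Spectrum

__all__ = [
    "Baseline",
    "rubberband_baseline",
    "subtract_baseline",
    "savgol_smooth",
    "segment_band",
    "preprocess_spectrum",
]

_CLIP_TOL = 1e-9


@dataclass(frozen=True)
class Baseline:
    """Piecewise-linear baseline through the lower convex hull vertices."""

    values: np.ndarray
    anchor_indices: np.ndarray


def _lower_hull_indices(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Andrew's monotone chain restricted to the lower hull.

    ``x`` must be strictly increasing; the first and last point are always
    vertices.
    """
    hull: list[int] = []
    for i in range(x.size):
        while len(hull) >= 2:
            a, b = hull[-2], hull[-1]
            # drop b if it lies on or above the chord a->i
            cross = (x[b] - x[a]) * (y[i] - y[a]) - (y[b] - y[a]) * (x[i] - x[a])
            if cross <= 0:
                hull.pop()
            else:
                break
        hull.append(i)
    return np.asarray(hull, dtype=int)


def rubberband_baseline(spectrum: Spectrum) -> Baseline:
    """Rubber-band baseline: the lower convex hull of (wavenumber, intensity).

    The hull is linearly interpolated between its vertices; subtracting it
    leaves a non-negative signal that touches zero at every anchor.
    """
    if len(spectrum) < 3:
        raise ValidationError("rubber-band baseline needs at least 3 points")
    x, y = spectrum.wavenumbers, spectrum.intensities
    anchors = _lower_hull_indices(x, y)
    values = np.interp(x, x[anchors], y[anchors])
    return Baseline(values=values, anchor_indices=anchors)


def subtract_baseline(spectrum: Spectrum, baseline: Baseline) -> Spectrum:
    """Subtract a baseline; residuals within -1e-9 of zero are clipped to 0."""
    if baseline.values.size != len(spectrum):
        raise ValidationError("baseline length does not match spectrum length")
    corrected = spectrum.intensities - baseline.values
    corrected = np.where((corrected < 0) & (corrected >= -_CLIP_TOL), 0.0, corrected)
    return spectrum.with_intensities(corrected)


def savgol_smooth(spectrum: Spectrum, window: int = 9, order: int = 2) -> Spectrum:
    """Savitzky-Golay smoothing (default: 9-point window, quadratic).

    Each interior point is replaced by the centered least-squares polynomial
    value; the terminal half-windows use polynomial extrapolation of the
    edge fits (scipy's ``mode="interp"``), keeping the filter deterministic.
    """
    if window % 2 == 0 or window <= order:
        raise ValidationError("window must be odd and greater than the polynomial order")
    if len(spectrum) < window:
        raise ValidationError("spectrum shorter than the filter window")
    smoothed = savgol_filter(spectrum.intensities, window_length=window, polyorder=order, mode="interp")
    return spectrum.with_intensities(smoothed)


def segment_band(spectrum: Spectrum, low: float = 1495.0, high: float = 1535.0) -> Spectrum:
    """Restrict a spectrum to ``low <= wavenumber <= high`` (closed interval)."""
    if low >= high:
        raise ValidationError("segment bounds must satisfy low < high")
    mask = (spectrum.wavenumbers >= low) & (spectrum.wavenumbers <= high)
    if not np.any(mask):
        raise EmptySegmentError(f"no points in [{low}, {high}] cm^-1")
    return Spectrum(
        wavenumbers=spectrum.wavenumbers[mask],
        intensities=spectrum.intensities[mask],
        sample_id=spectrum.sample_id,
        region=spectrum.region,
        label=spectrum.label,
    )


def preprocess_spectrum(
    spectrum: Spectrum,
    window: int = 9,
    order: int = 2,
    seg_low: float | None = 1495.0,
    seg_high: float | None = 1535.0,
) -> Spectrum:
    """Full pre-treatment chain: baseline -> smooth -> (optional) segment.

    Pass ``seg_low=None`` (or ``seg_high=None``) to skip segmentation, e.g.
    before full-spectrum major-peak detection.
    """
    corrected = subtract_baseline(spectrum, rubberband_baseline(spectrum))
    smoothed = savgol_smooth(corrected, window=window, order=order)
    if seg_low is None or seg_high is None:
        return smoothed
    return segment_band(smoothed, low=seg_low, high=seg_high)
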