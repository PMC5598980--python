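"""Shared preprocessing: RIP compensation, smoothing, noise estimation.

The reactant ion peak (RIP) is a high-intensity vertical band caused by
the ionised carrier gas; it sits at a fixed drift position across all
retention times and must be removed before peak analysis.  Smoothing uses
a separable 2-D Savitzky-Golay filter; the noise level is a robust
median + k·MAD estimate of the background.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .core_data import Measurement

__all__ = [
    "NoiseModel",
    "estimate_noise",
    "find_rip_band",
    "compensate_rip",
    "smooth_savgol",
    "threshold_denoise",
]

# MAD -> sigma for Gaussian noise
_MAD_SCALE = 1.4826


@dataclass(frozen=True)
class NoiseModel:
    """Robust background model: location + k·scale threshold."""

    center: float
    spread: float
    threshold_factor: float = 3.0

    def noise_level(self) -> float:
        return self.center + self.threshold_factor * self.spread


def estimate_noise(values: Measurement | np.ndarray, k: float = 3.0) -> NoiseModel:
    """Estimate the noise floor of a measurement (or raw array).

    Center is the median over all cells, spread the median absolute
    deviation scaled by 1.4826 (consistent for Gaussian noise).  Peaks
    occupy few cells, so both statistics are dominated by background.
    """
    x = values.intensity if isinstance(values, Measurement) else np.asarray(values, float)
    center = float(np.median(x))
    spread = float(_MAD_SCALE * np.median(np.abs(x - center)))
    return NoiseModel(center=center, spread=spread, threshold_factor=k)


def find_rip_band(m: Measurement, band_fraction: float = 0.5) -> tuple[int, int] | None:
    """Locate the RIP band as a contiguous column range (inclusive), or None.

    The RIP column is the argmax of column-wise median intensity; the band
    extends over contiguous neighbours whose median exceeds
    ``band_fraction`` of that maximum.  A flat measurement (no column
    rising above the global background) has no band.
    """
    col_med = np.median(m.intensity, axis=0)
    peak_col = int(np.argmax(col_med))
    overall = float(np.median(col_med))
    if col_med[peak_col] <= overall or col_med[peak_col] <= 0:
        return None
    cutoff = band_fraction * col_med[peak_col]
    lo = peak_col
    while lo > 0 and col_med[lo - 1] > cutoff:
        lo -= 1
    hi = peak_col
    while hi < col_med.size - 1 and col_med[hi + 1] > cutoff:
        hi += 1
    return lo, hi


def compensate_rip(m: Measurement, band_fraction: float = 0.5) -> Measurement:
    """Subtract the reactant-ion-peak band from a measurement.

    Within the detected band each column's 25th percentile across
    retention times is taken as the RIP profile — a robust baseline that
    captures the retention-invariant artifact while ignoring analyte
    peaks riding on it — subtracted, and the result clamped at zero.
    Columns outside the band are returned unchanged.
    """
    band = find_rip_band(m, band_fraction)
    if band is None:
        return m.with_intensity(m.intensity.copy())
    lo, hi = band
    out = m.intensity.copy()
    profile = np.percentile(out[:, lo : hi + 1], 25, axis=0)
    out[:, lo : hi + 1] = np.clip(out[:, lo : hi + 1] - profile, 0.0, None)
    return m.with_intensity(out)


def _check_sg(window: int, order: int) -> None:
    if window < 3 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 3, got {window}")
    if order >= window:
        raise ValueError(f"polynomial order {order} must be < window {window}")


def smooth_savgol(m: Measurement, window: int = 5, order: int = 2) -> Measurement:
    """Separable 2-D Savitzky-Golay smoothing along both axes.

    Local polynomial regression of the given order in each direction;
    reproduces polynomial surfaces up to that order exactly on interior
    cells.  Edges are handled by nearest-value extension.
    """
    _check_sg(window, order)
    out = savgol_filter(m.intensity, window, order, axis=0, mode="nearest")
    out = savgol_filter(out, window, order, axis=1, mode="nearest")
    return m.with_intensity(out)


def threshold_denoise(m: Measurement, level: float) -> Measurement:
    """Zero out every cell below ``level``; cells at or above it pass through."""
    if level < 0:
        raise ValueError("threshold level must be >= 0")
    out = np.where(m.intensity < level, 0.0, m.intensity)
    return m.with_intensity(out)
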