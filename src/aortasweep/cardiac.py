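"""Cardiac timing from the lumen area-time signal.

During a freehand sweep the segmented lumen area oscillates with the
cardiac cycle.  The dominant peak of the power-density spectrum inside the
physiological range gives the heart frequency; a +/- 0.2 Hz band around it
(a +/- 12 beats/min allowance for rate drift during breath-hold) constrains
the subsequent search for the area minima that mark the end-diastolic
frames.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks, periodogram

__all__ = [
    "AreaTimeSignal",
    "HeartFrequencyRange",
    "CardiacSignalError",
    "lumen_area_series",
    "detect_heart_frequency",
    "detect_ed_frames",
    "ellipse_mask_area",
]

#: Default physiological heart-rate search range, Hz (40-120 beats/min).
PHYSIO_RANGE_HZ = (0.67, 2.0)

#: Half-width of the detected heart-frequency band, Hz.
FREQUENCY_HALF_BAND_HZ = 0.2


class CardiacSignalError(ValueError):
    """The area-time signal carries no usable cardiac information."""


@dataclass(frozen=True)
class AreaTimeSignal:
    """Per-frame lumen area over (possibly non-equidistant) time."""

    areas: np.ndarray          # mm^2
    times: np.ndarray          # s, strictly increasing
    frame_indices: np.ndarray

    def __post_init__(self):
        a = np.asarray(self.areas, dtype=float)
        t = np.asarray(self.times, dtype=float)
        idx = np.asarray(self.frame_indices, dtype=int)
        if np.any(a <= 0):
            raise CardiacSignalError("areas must be positive")
        if len(t) > 1 and np.any(np.diff(t) <= 0):
            raise CardiacSignalError("timestamps must be strictly increasing")
        object.__setattr__(self, "areas", a)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "frame_indices", idx)

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    def resampled(self) -> tuple[np.ndarray, np.ndarray]:
        """Equidistant resampling at the median sampling interval."""
        t = self.times
        if len(t) < 2:
            return t.copy(), self.areas.copy()
        dt = float(np.median(np.diff(t)))
        n = int(np.floor((t[-1] - t[0]) / dt + 1e-9)) + 1
        tu = t[0] + np.arange(n) * dt
        au = np.interp(tu, t, self.areas)
        return tu, au


@dataclass(frozen=True)
class HeartFrequencyRange:
    """Detected heart frequency with its +/- 0.2 Hz uncertainty band."""

    f_peak: float

    def __post_init__(self):
        if self.f_peak - FREQUENCY_HALF_BAND_HZ <= 0:
            raise CardiacSignalError("heart frequency too low: f_low must be positive")

    @property
    def f_low(self) -> float:
        return self.f_peak - FREQUENCY_HALF_BAND_HZ

    @property
    def f_high(self) -> float:
        return self.f_peak + FREQUENCY_HALF_BAND_HZ

    @property
    def period_range(self) -> tuple[float, float]:
        """(shortest, longest) admissible cardiac period in seconds."""
        return (1.0 / self.f_high, 1.0 / self.f_low)


def ellipse_mask_area(ellipse, pixel_spacing: float = 0.1) -> float:
    """Area of an ellipse from a rasterized binary mask (pixel count x spacing^2).

    Falls back to the analytic pi*a*b with a warning when the ellipse is too
    small for the grid (semi-minor axis under 2 pixels).
    """
    a, b = ellipse.a, ellipse.b
    if b / pixel_spacing < 2.0:
        warnings.warn(
            "ellipse radius below 2 pixels at this spacing; using analytic area",
            stacklevel=2,
        )
        return float(np.pi * a * b)
    pad = 2 * pixel_spacing
    nx = int(np.ceil(2 * (a + pad) / pixel_spacing))
    if nx % 2 == 0:  # centre the ellipse on a pixel centre
        nx += 1
    x = ellipse.cx + (np.arange(nx) - (nx - 1) / 2.0) * pixel_spacing
    y = ellipse.cy + (np.arange(nx) - (nx - 1) / 2.0) * pixel_spacing
    X, Y = np.meshgrid(x, y)
    c, s = np.cos(ellipse.phi), np.sin(ellipse.phi)
    u = (X - ellipse.cx) * c + (Y - ellipse.cy) * s
    v = -(X - ellipse.cx) * s + (Y - ellipse.cy) * c
    q = np.sqrt((u / a) ** 2 + (v / b) ** 2)
    band = 1.5 * pixel_spacing / b
    inside = q <= 1.0 - band
    area = float(inside.sum()) * pixel_spacing**2
    # boundary pixels contribute their sub-sampled coverage fraction
    bi, bj = np.nonzero((q > 1.0 - band) & (q <= 1.0 + band))
    if bi.size:
        k = 4
        offs = (np.arange(k) + 0.5) / k - 0.5
        ox, oy = np.meshgrid(offs * pixel_spacing, offs * pixel_spacing)
        xs = X[bi, bj][:, None] + ox.ravel()[None, :]
        ys = Y[bi, bj][:, None] + oy.ravel()[None, :]
        us = (xs - ellipse.cx) * c + (ys - ellipse.cy) * s
        vs = -(xs - ellipse.cx) * s + (ys - ellipse.cy) * c
        frac = ((us / a) ** 2 + (vs / b) ** 2 <= 1.0 + 1e-12).mean(axis=1)
        area += float(frac.sum()) * pixel_spacing**2
    return area


def lumen_area_series(
    contours,
    times,
    pixel_spacing: float = 0.1,
    frame_indices=None,
) -> AreaTimeSignal:
    """Binary-mask lumen area per segmented ellipse, as a time signal."""
    contours = list(contours)
    if not contours:
        raise CardiacSignalError("need at least one contour")
    areas = np.array([ellipse_mask_area(e, pixel_spacing) for e in contours])
    if frame_indices is None:
        frame_indices = np.arange(len(contours))
    return AreaTimeSignal(areas, np.asarray(times, dtype=float), frame_indices)


def detect_heart_frequency(
    signal: AreaTimeSignal,
    physio_range: tuple[float, float] = PHYSIO_RANGE_HZ,
) -> HeartFrequencyRange:
    """Highest power-density peak inside the physiological range, +/- 0.2 Hz.

    The signal is resampled to equidistant steps, mean-removed and analysed
    with a Hann-windowed periodogram.  A peak that does not clearly rise
    above the in-range noise floor raises "no cardiac signal".
    """
    f_lo, f_hi = physio_range
    if signal.duration < 2.0 / f_lo:
        raise CardiacSignalError(
            "sweep too short: need at least two cardiac cycles observable"
        )
    tu, au = signal.resampled()
    dt = float(np.median(np.diff(tu)))
    x = au - au.mean()
    if np.ptp(x) <= 1e-12 * max(abs(au.mean()), 1.0):
        raise CardiacSignalError("no cardiac signal: constant area")
    freqs, power = periodogram(x, fs=1.0 / dt, window="hann", detrend=False)
    in_range = (freqs >= f_lo) & (freqs <= f_hi)
    if not np.any(in_range):
        raise CardiacSignalError("no cardiac signal: spectrum does not cover range")
    p_in = power[in_range]
    k = int(np.argmax(p_in))
    floor = float(np.median(p_in))
    if p_in[k] <= 5.0 * max(floor, 1e-300):
        raise CardiacSignalError("no cardiac signal: no peak above the noise floor")
    return HeartFrequencyRange(float(freqs[in_range][k]))


def detect_ed_frames(signal: AreaTimeSignal, hf: HeartFrequencyRange) -> np.ndarray:
    """Frames nearest the area minima, one per cardiac cycle.

    Minima of the equidistantly resampled signal are accepted only when
    separated by at least the minimal cardiac period 1/f_high and prominent
    against noise (>= 10% of the signal peak-to-peak).  Each minimum time is
    mapped back to the nearest original frame index.
    """
    tu, au = signal.resampled()
    dt = float(np.median(np.diff(tu)))
    distance = max(1, int(np.ceil((1.0 / hf.f_high) / dt)))
    prominence = 0.1 * np.ptp(au)
    minima, _ = find_peaks(-au, distance=distance, prominence=prominence)
    if len(minima) < 2:
        raise CardiacSignalError("sweep too short: fewer than 2 end-diastolic minima")
    idx = []
    for m in minima:
        k = int(np.argmin(np.abs(signal.times - tu[m])))
        idx.append(int(signal.frame_indices[k]))
    idx = np.array(sorted(set(idx)), dtype=int)
    return idx
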