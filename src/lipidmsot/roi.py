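"""ROI time-course extraction and profile-line analysis at 930 nm.

The core measurement of the pipeline: the arithmetic mean of the raw pixel
intensities inside a manually-segmented region of interest (vessel lumen,
muscle, subcutaneous fat) on 930-nm frames — no filtering or denoising —
tracked over the acquisition schedule. Peak time and relative increase are
read off the measured (not normalized) series; normalization against the
series maximum is applied only for display. Profile-line analysis reports
the contiguous half-maximum band around the brightest pixel on a line,
which localises a structure against its surroundings.

Conventions: pixel coordinates are 0-based (row, col) with the origin at
the top-left; index intervals are inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from skimage.draw import line as _bresenham_line

from .simulate import MultispectralStudy, _wavelength_index

__all__ = [
    "ROIMask",
    "TimeCourse",
    "ProfileBand",
    "MaskError",
    "mean_roi_intensity",
    "extract_timecourse",
    "normalize_timecourse",
    "relative_increase",
    "peak_time",
    "profile_band",
    "line_coordinates",
]


class MaskError(ValueError):
    """ROI mask is empty or incompatible with the image geometry."""


@dataclass(frozen=True)
class ROIMask:
    """Binary pixel membership for one compartment, by one rater."""

    mask: np.ndarray
    compartment: str = "unknown"
    rater: str = "unknown"

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        if m.ndim != 2:
            raise MaskError("mask must be a 2-D array")
        if not m.any():
            raise MaskError("mask has no member pixels")
        object.__setattr__(self, "mask", m)

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class TimeCourse:
    """Mean ROI signal per scheduled time point, baseline at t=0."""

    times: np.ndarray
    values: np.ndarray
    normalized_values: np.ndarray | None = None
    compartment: str = "unknown"
    rater: str = "unknown"

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.size != v.size or t.size < 2:
            raise ValueError("need matching times/values with at least 2 points")
        if t[0] != 0:
            raise ValueError("first time point must be 0 (fasting baseline)")
        if not np.all(np.diff(t) > 0):
            raise ValueError("times must be ascending")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class ProfileBand:
    """Half-maximum band along an image profile line.

    band is the inclusive (start, stop) index interval of the maximal
    contiguous run containing the argmax with intensity >= threshold * max.
    """

    coords: np.ndarray          # (N, 2) ordered (row, col) pixels
    intensities: np.ndarray
    band: tuple[int, int]
    threshold_frac: float
    pixel_pitch: float | None = None

    @property
    def width_px(self) -> int:
        return self.band[1] - self.band[0] + 1

    @property
    def width_mm(self) -> float | None:
        return None if self.pixel_pitch is None else self.width_px * self.pixel_pitch


def mean_roi_intensity(frame: np.ndarray, mask: ROIMask | np.ndarray) -> float:
    """Arithmetic mean of the raw frame values over the mask's member pixels."""
    m = mask.mask if isinstance(mask, ROIMask) else np.asarray(mask, dtype=bool)
    frame = np.asarray(frame)
    if frame.shape != m.shape:
        raise MaskError(f"frame shape {frame.shape} != mask shape {m.shape}")
    if not m.any():
        raise MaskError("mask has no member pixels")
    return float(frame[m].mean())


def extract_timecourse(
    study: MultispectralStudy, mask: ROIMask | np.ndarray, wavelength: float = 930.0
) -> TimeCourse:
    """Mean ROI signal at one wavelength for every scheduled time point."""
    wl_idx = _wavelength_index(study.schedule.wavelengths, wavelength)
    roi = mask if isinstance(mask, ROIMask) else ROIMask(np.asarray(mask, dtype=bool))
    values = [
        mean_roi_intensity(study.frames[ti, wl_idx], roi)
        for ti in range(study.schedule.time_points.size)
    ]
    return TimeCourse(
        times=study.schedule.time_points.copy(),
        values=np.asarray(values),
        compartment=roi.compartment,
        rater=roi.rater,
    )


def normalize_timecourse(tc: TimeCourse) -> TimeCourse:
    """Divide by the series maximum (display convention); keeps raw values."""
    peak = tc.values.max()
    if peak <= 0:
        raise ValueError("cannot normalize a series with non-positive maximum")
    return replace(tc, normalized_values=tc.values / peak)


def relative_increase(tc: TimeCourse) -> float:
    """Percent increase of the series maximum over the fasting baseline.

    Computed on the measured values: 100 * (max - v[0]) / v[0]. The search
    includes every time point, baseline included (a flat or decaying series
    yields 0%).
    """
    baseline = tc.values[0]
    if baseline <= 0:
        raise ValueError("baseline (t=0) value must be > 0")
    return float(100.0 * (tc.values.max() - baseline) / baseline)


def peak_time(tc: TimeCourse) -> float:
    """Scheduled time (min) of the global maximum; earliest point wins ties."""
    return float(tc.times[int(np.argmax(tc.values))])


def line_coordinates(start: tuple[int, int], end: tuple[int, int]) -> np.ndarray:
    """Ordered (row, col) pixels of the straight line start -> end (inclusive)."""
    rr, cc = _bresenham_line(int(start[0]), int(start[1]), int(end[0]), int(end[1]))
    return np.column_stack([rr, cc])


def profile_band(
    frame: np.ndarray,
    line: np.ndarray | Sequence[tuple[int, int]],
    threshold_frac: float = 0.5,
    pixel_pitch: float | None = None,
) -> ProfileBand:
    """Half-max band along a profile line (nearest-pixel sampling).

    Finds the global intensity maximum along the line and returns the
    maximal contiguous index interval containing it on which the intensity
    stays >= threshold_frac * max.
    """
    if not (0.0 < threshold_frac < 1.0):
        raise ValueError("threshold_frac must lie in (0, 1)")
    coords = np.asarray(line)
    if coords.ndim != 2 or coords.shape[1] != 2 or coords.shape[0] < 3:
        raise ValueError("line must be an (N, 2) array of pixels with N >= 3")
    frame = np.asarray(frame)
    rows, cols = coords[:, 0].astype(int), coords[:, 1].astype(int)
    if (rows.min() < 0 or cols.min() < 0
            or rows.max() >= frame.shape[0] or cols.max() >= frame.shape[1]):
        raise IndexError("profile line exits the image bounds")
    intensities = frame[rows, cols].astype(float)
    peak_idx = int(np.argmax(intensities))
    cutoff = threshold_frac * intensities[peak_idx]
    above = intensities >= cutoff
    start = peak_idx
    while start > 0 and above[start - 1]:
        start -= 1
    stop = peak_idx
    while stop < len(intensities) - 1 and above[stop + 1]:
        stop += 1
    return ProfileBand(
        coords=coords,
        intensities=intensities,
        band=(start, stop),
        threshold_frac=threshold_frac,
        pixel_pitch=pixel_pitch,
    )
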