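"""Quantitative scores for A-line and B-line artifacts.

The reverberation between transducer face and pleura shows up as an echo
train with period 2 L / c (L = muscle thickness), i.e. horizontal image
bands at depth multiples of L; the fluid-infiltrated LDZ shows up as a
bright vertical stripe below the pleural line.  Both are quantified here
so qualitative image features become testable numbers.

The B-line score compares mean linear image intensity below the pleural
line in columns under the LDZ versus columns away from it.  Because the
horizontal reverberation bands are common to every column and carry most
of the linear-scale energy, the rows belonging to detected bands are
excluded from the comparison: the score then isolates the *inter-band*
fill that makes a B-line a continuous vertical structure rather than
re-measuring the A-lines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .imaging import BScanImage

__all__ = [
    "EchoTrain",
    "BLineScore",
    "detect_echoes",
    "reverberation_bands",
    "pleural_depth",
    "bline_score",
    "bline_width",
    "aline_peak_depths",
]


@dataclass(frozen=True)
class EchoTrain:
    """Detected echo arrivals, strictly increasing in time."""

    arrival_times: np.ndarray
    amplitudes: np.ndarray

    @property
    def spacings(self) -> np.ndarray:
        return np.diff(self.arrival_times)


def detect_echoes(
    trace: np.ndarray,
    times: np.ndarray,
    threshold: float = 0.1,
    min_separation: float = 2.0e-6,
    t_min: float = 0.0,
) -> EchoTrain:
    """Local maxima of an envelope trace above ``threshold`` x max.

    ``t_min`` excludes an initial dead time (e.g. the transmit pulse)
    from both the search and the normalization.  May return an empty
    train.
    """
    trace = np.asarray(trace, dtype=float)
    times = np.asarray(times, dtype=float)
    sel = times >= t_min
    seg = trace[sel]
    t_seg = times[sel]
    if len(seg) == 0 or seg.max() <= 0:
        return EchoTrain(np.empty(0), np.empty(0))
    dt = times[1] - times[0]
    distance = max(1, int(round(min_separation / dt)))
    peaks, _ = find_peaks(seg, height=threshold * seg.max(), distance=distance)
    return EchoTrain(arrival_times=t_seg[peaks], amplitudes=seg[peaks])


def _reference_columns(
    lateral: np.ndarray, extent: tuple[float, float] | None, guard: float
) -> np.ndarray:
    if extent is None:
        return np.ones(len(lateral), dtype=bool)
    x_lo, x_hi = extent
    return (lateral < x_lo - guard) | (lateral > x_hi + guard)


def reverberation_bands(
    image: BScanImage,
    exclude_extent: tuple[float, float] | None = None,
    guard: float = 0.002,
    min_depth: float = 0.004,
    min_spacing: float = 0.004,
    prominence_fraction: float = 0.2,
) -> np.ndarray:
    """Depths of the horizontal reverberation bands (pleural line first).

    The laterally averaged linear intensity is computed over columns
    outside ``exclude_extent`` (so a B-line stripe cannot mask or mimic
    the bands), and prominent maxima beyond ``min_depth`` — which skips
    the transmit-pulse band near zero depth — are returned in depth
    order.
    """
    cols = _reference_columns(image.lateral_axis, exclude_extent, guard)
    if not cols.any():
        raise ValueError("excluded extent covers all columns")
    profile = image.linear[:, cols].mean(axis=1)
    sel = image.depth_axis >= min_depth
    prof = profile[sel]
    depths = image.depth_axis[sel]
    if len(prof) < 3:
        return np.empty(0)
    dz = float(np.mean(np.diff(image.depth_axis)))
    distance = max(1, int(round(min_spacing / dz)))
    peaks, _ = find_peaks(
        prof, distance=distance,
        prominence=prominence_fraction * (prof.max() - prof.min()),
    )
    return depths[peaks]


def pleural_depth(image: BScanImage, **kwargs) -> float:
    """Depth of the pleural line: the shallowest reverberation band."""
    bands = reverberation_bands(image, **kwargs)
    if len(bands) == 0:
        raise ValueError("no horizontal band found beyond the minimum depth")
    return float(bands[0])


# alias kept for symmetry with the echo-train view of the same physics
aline_peak_depths = reverberation_bands


@dataclass(frozen=True)
class BLineScore:
    """Inter-band mean linear intensity below the pleura, inside vs
    outside the LDZ lateral extent."""

    inside_mean: float
    outside_mean: float
    ratio: float
    pleural_depth: float
    band_depths: np.ndarray


def _scored_region(
    image: BScanImage,
    ldz_extent: tuple[float, float],
    guard: float,
    band_halfwidth: float,
    min_depth: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    lat = image.lateral_axis
    x_lo, x_hi = ldz_extent
    inside = (lat >= x_lo) & (lat <= x_hi)
    outside = _reference_columns(lat, ldz_extent, guard)
    if not outside.any():
        raise ValueError("LDZ extent covers all columns: no reference region")
    if not inside.any():
        raise ValueError("LDZ extent contains no columns")
    bands = reverberation_bands(image, exclude_extent=ldz_extent, guard=guard,
                                min_depth=min_depth)
    first = bands[0] if len(bands) else min_depth
    rows = image.depth_axis > first + band_halfwidth
    for b in bands:
        rows &= np.abs(image.depth_axis - b) > band_halfwidth
    if not rows.any():
        raise ValueError("no inter-band image content below the pleural line")
    return inside, outside, rows, bands


def bline_score(
    image: BScanImage,
    ldz_extent: tuple[float, float],
    guard: float = 0.002,
    band_halfwidth: float = 0.002,
    min_depth: float = 0.004,
) -> BLineScore:
    """Vertical-artifact contrast: inside/outside mean linear intensity.

    Scored over the sub-pleural region with the horizontal reverberation
    bands masked out (half-width ``band_halfwidth`` around each detected
    band).  Columns within ``ldz_extent`` are "inside"; columns further
    than ``guard`` beyond the extent are "outside".  A continuous bright
    stripe under the LDZ drives the ratio above 1; without an LDZ the
    inter-band region is uniformly dim and the ratio stays near 1.
    """
    inside, outside, rows, bands = _scored_region(
        image, ldz_extent, guard, band_halfwidth, min_depth
    )
    col = image.linear[rows, :].mean(axis=0)
    inside_mean = float(col[inside].mean())
    outside_mean = float(col[outside].mean())
    return BLineScore(
        inside_mean=inside_mean,
        outside_mean=outside_mean,
        ratio=inside_mean / outside_mean,
        pleural_depth=float(bands[0]) if len(bands) else np.nan,
        band_depths=bands,
    )


def bline_width(
    image: BScanImage,
    ldz_extent: tuple[float, float],
    guard: float = 0.002,
    band_halfwidth: float = 0.002,
    min_depth: float = 0.004,
) -> float:
    """Lateral width (m) of the high-intensity vertical region: columns
    whose inter-band sub-pleural mean exceeds the midpoint between the
    inside and outside means."""
    inside, outside, rows, _ = _scored_region(
        image, ldz_extent, guard, band_halfwidth, min_depth
    )
    col = image.linear[rows, :].mean(axis=0)
    thr = 0.5 * (col[inside].mean() + col[outside].mean())
    dlat = float(np.mean(np.diff(image.lateral_axis)))
    return float((col > thr).sum() * dlat)
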