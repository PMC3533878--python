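"""Noise smoothing and baseline correction for ion chromatograms.

High-frequency detector noise is suppressed with Savitzky-Golay
least-squares polynomial smoothing or with moving mean/median windows.
Low-frequency baseline drift (chemical noise, column bleed) is removed with
the top-hat transform of mathematical morphology: the trace minus its
opening under a flat structuring element, which deletes every feature
broader than the element while leaving narrower chromatographic peaks
intact.

Edge handling for the window filters is truncation with re-fit: points
within half a window of a trace end are fitted/averaged over the clipped
window rather than over padded, fabricated samples. The morphological
filters use clipped windows for the same reason (``mode='nearest'`` is
equivalent for flat-element min/max).

Defaults (SG window 7 points / degree 2, moving window 5, top-hat element
90 s) suit a 0.375 s scan period and are freely configurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.ndimage import grey_opening
from scipy.signal import savgol_filter

from .core import IonChromatogram
from .binning import IntensityMatrix

__all__ = [
    "SmoothingParams",
    "TophatParams",
    "savitzky_golay",
    "window_smooth",
    "tophat",
    "map_columns",
    "map_rows",
    "DEFAULT_SG_WINDOW",
    "DEFAULT_SG_DEGREE",
    "DEFAULT_MOVING_WINDOW",
    "DEFAULT_TOPHAT_SECONDS",
]

DEFAULT_SG_WINDOW = 7
DEFAULT_SG_DEGREE = 2
DEFAULT_MOVING_WINDOW = 5
DEFAULT_TOPHAT_SECONDS = 90.0


@dataclass(frozen=True)
class SmoothingParams:
    """Window smoothing settings: odd ``window``; ``degree`` is SG-only."""

    window: int = DEFAULT_SG_WINDOW
    degree: int = DEFAULT_SG_DEGREE
    statistic: str = "mean"

    def __post_init__(self) -> None:
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be an odd count >= 3")
        if self.degree < 0 or self.degree >= self.window:
            raise ValueError("degree must satisfy 0 <= degree < window")
        if self.statistic not in ("mean", "median"):
            raise ValueError("statistic must be 'mean' or 'median'")


@dataclass(frozen=True)
class TophatParams:
    """Structuring-element extent, as seconds (float/"90s"/"1.5m") or points (int)."""

    element_width: float | int | str = DEFAULT_TOPHAT_SECONDS


def _check_window(window: int, n: int) -> None:
    if window % 2 == 0:
        raise ValueError(f"window must be odd, got {window}")
    if window > n:
        raise ValueError(f"window ({window}) exceeds trace length ({n})")


def savitzky_golay(
    ic: IonChromatogram, params: SmoothingParams | None = None
) -> IonChromatogram:
    """Least-squares polynomial smoothing at the stated window and degree.

    Each point is replaced by the center value of the degree-``d``
    polynomial fitted over its window; a degree-``d`` filter therefore
    reproduces any polynomial trace of degree <= d exactly on interior
    points. Edge points are re-fitted over their truncated windows (degree
    capped at window size - 1 there).
    """
    params = params or SmoothingParams()
    x = ic.intensities
    n = x.size
    _check_window(params.window, n)
    out = savgol_filter(x, params.window, params.degree)
    half = params.window // 2
    for i in list(range(half)) + list(range(n - half, n)):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        t = np.arange(lo, hi, dtype=float) - i
        deg = min(params.degree, hi - lo - 1)
        coeffs = np.polynomial.polynomial.polyfit(t, x[lo:hi], deg)
        out[i] = coeffs[0]  # value of the local fit at the point itself
    # intensities are physical counts: clip the filter's negative ringing
    if np.any(x < 0):
        return ic.replace(out)
    return ic.replace(np.maximum(out, 0.0))


def window_smooth(
    ic: IonChromatogram, params: SmoothingParams | None = None
) -> IonChromatogram:
    """Centered moving mean or median with truncated edge windows."""
    params = params or SmoothingParams(window=DEFAULT_MOVING_WINDOW)
    x = ic.intensities
    n = x.size
    _check_window(params.window, n)
    half = params.window // 2
    out = np.empty_like(x)
    stat = np.mean if params.statistic == "mean" else np.median
    if n >= params.window:
        windows = np.lib.stride_tricks.sliding_window_view(x, params.window)
        out[half : n - half] = stat(windows, axis=1)
    for i in list(range(half)) + list(range(n - half, n)):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        out[i] = stat(x[lo:hi])
    return ic.replace(out)


def _element_points(width: float | int | str, ic: IonChromatogram) -> int:
    """Resolve a structuring-element width to an odd point count."""
    if isinstance(width, str):
        s = width.strip()
        if s.endswith("m"):
            seconds = float(s[:-1]) * 60.0
        elif s.endswith("s"):
            seconds = float(s[:-1])
        else:
            raise ValueError(f"element width {width!r} needs an 's' or 'm' suffix")
    elif isinstance(width, int):
        points = width
        if points % 2 == 0:
            points += 1
        return points
    else:
        seconds = float(width)
    if seconds <= 0:
        raise ValueError("element width must be positive")
    points = int(round(seconds / ic.time_step()))
    if points % 2 == 0:
        points += 1
    return max(points, 3)


def tophat(ic: IonChromatogram, params: TophatParams | None = None) -> IonChromatogram:
    """Baseline correction: the trace minus its morphological opening.

    The opening (erosion then dilation by a flat element) reconstructs every
    structure broader than the element — i.e. the baseline — so the
    difference retains only the narrow peaks. Output is non-negative and
    pointwise <= the input; the transform is idempotent.
    """
    params = params or TophatParams()
    x = ic.intensities
    points = _element_points(params.element_width, ic)
    if points > x.size:
        raise ValueError(
            f"structuring element ({points} points) is wider than the trace ({x.size})"
        )
    opening = grey_opening(x, size=points, mode="nearest")
    return ic.replace(np.maximum(x - opening, 0.0))


TraceOp = Callable[[IonChromatogram], IonChromatogram]


def _apply_traces(
    matrix: np.ndarray, axis_rt: np.ndarray, op: TraceOp, what: str
) -> np.ndarray:
    out = np.empty_like(matrix)
    for j in range(matrix.shape[1]):
        trace = IonChromatogram(matrix[:, j], axis_rt)
        result = op(trace)
        if len(result) != matrix.shape[0]:
            raise ValueError(
                f"{what} operation changed trace length "
                f"({matrix.shape[0]} -> {len(result)})"
            )
        out[:, j] = result.intensities
    return out


def map_columns(im: IntensityMatrix, op: TraceOp) -> IntensityMatrix:
    """Apply ``op`` independently to every ion chromatogram (column).

    Columns are independent, so this is the library's sequential embodiment
    of the by-column parallel-processing contract; results do not depend on
    the order in which columns are visited.
    """
    values = _apply_traces(im.values, im.rt, op, "column")
    return IntensityMatrix(
        values, im.rt, im.bin_centers, im.bin_size, im.lower_offset, im.upper_offset
    )


def map_rows(im: IntensityMatrix, op: TraceOp) -> IntensityMatrix:
    """Apply ``op`` independently to every mass spectrum (row).

    Each row is presented to ``op`` as a trace over the m/z axis (the
    "retention" vector is the ascending bin-center vector).
    """
    values = _apply_traces(im.values.T, im.bin_centers, op, "row").T
    return IntensityMatrix(
        values.copy(),
        im.rt,
        im.bin_centers,
        im.bin_size,
        im.lower_offset,
        im.upper_offset,
    )
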