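"""Peak detection, deconvolution and integration (Biller-Biemann style).

Electron-impact GC-MS peaks are multi-ion objects: one eluting compound
produces co-apexing maxima on many m/z channels. Detection therefore works
per ion chromatogram — find local maxima within a sliding window — and
deconvolution combines maxima whose apex scans lie within ``scans`` of each
other (single-linkage chaining) into one composite peak carrying the apex
intensity of every member ion.

Peak lists are then cleaned with two filters: ``filter_num_ions`` keeps
peaks with at least ``ions`` member intensities at or above ``threshold``,
and ``filter_rel_intensity`` drops ions weaker than ``r``% of the peak's
base ion. Per-ion areas use outward accumulation from the apex: intensities
are added moving away from the apex until a candidate contributes less than
``stop_fraction`` of the accumulated area (default 0.5%) or the trace
starts rising again (the shoulder of a neighbouring peak).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .binning import IntensityMatrix, get_ic_at_index, _mass_to_column
from .core import IonChromatogram, MassSpectrum

__all__ = [
    "DetectionParams",
    "Peak",
    "PRESETS",
    "find_ion_maxima",
    "deconvolute",
    "filter_num_ions",
    "filter_rel_intensity",
    "integrate_ion",
    "quantify_peak",
    "make_uid",
    "detect_peaks",
    "write_peaks_json",
    "read_peaks_json",
    "write_peaks_csv",
]

DEFAULT_STOP_FRACTION = 0.005


@dataclass(frozen=True)
class DetectionParams:
    """Peak detection settings.

    window: odd point count over which per-ion local maxima are detected.
    scans: maximum apex-scan separation for ions to join one peak.
    ions: minimum number of qualifying ions a peak must keep.
    threshold: minimum apex intensity for an ion to qualify (counts).
    r: percentage of the base-ion intensity below which ions are dropped.
    """

    window: int = 5
    scans: int = 2
    ions: int = 3
    threshold: float = 2000.0
    r: float = 2.0

    def __post_init__(self) -> None:
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be an odd count >= 3")
        if self.scans < 1:
            raise ValueError("scans must be >= 1")
        if self.ions < 1:
            raise ValueError("ions must be >= 1")
        if self.threshold < 0:
            raise ValueError("threshold must be >= 0")
        if not 0 <= self.r < 100:
            raise ValueError("r must lie in [0, 100)")


#: Parameter sets used for the two benchmark sample types: a low-complexity
#: metabolite mix, and metabolite-spiked serum (complex biological matrix).
PRESETS: dict[str, DetectionParams] = {
    "mix": DetectionParams(window=5, ions=3, scans=2, threshold=2000.0, r=2.0),
    "serum": DetectionParams(window=13, ions=3, scans=2, threshold=6000.0, r=2.0),
}


@dataclass(frozen=True)
class Peak:
    """A deconvoluted multi-ion peak.

    ``spectrum`` holds the composite apex spectrum (one intensity per member
    ion, zeros elsewhere). ``ion_bounds`` maps each member ion's mass to its
    (left, apex, right) integration scan triplet; before integration the
    bounds collapse onto the ion's own apex scan. ``area`` is the total
    (all-ions) area once quantified.
    """

    uid: str
    rt: float
    spectrum: MassSpectrum
    ion_bounds: Mapping[float, tuple[int, int, int]] = field(default_factory=dict)
    ion_areas: Mapping[float, float] = field(default_factory=dict)
    area: float = 0.0

    def __post_init__(self) -> None:
        for mass, (l, a, r) in self.ion_bounds.items():
            if not l <= a <= r:
                raise ValueError(f"ion {mass}: bounds must satisfy left <= apex <= right")

    def member_ions(self) -> dict[float, float]:
        """Mass -> apex intensity of every member ion."""
        return self.spectrum.nonzero()

    def top_ions(self, n: int) -> list[float]:
        """The n most intense member masses, strongest first, ties to lower m/z."""
        members = self.member_ions()
        ranked = sorted(members, key=lambda m: (-members[m], m))
        return ranked[:n]


def make_uid(spectrum: MassSpectrum, rt: float) -> str:
    """Unique peak ID: ``<top ion>-<second ion>-<second/top % .1f>-<rt s .1f>``.

    A single-ion peak falls back to ``<ion>-<rt>``. Intensity ties rank the
    lower m/z first.
    """
    members = spectrum.nonzero()
    if not members:
        raise ValueError("cannot build a UID for an empty spectrum")
    ranked = sorted(members, key=lambda m: (-members[m], m))
    if len(ranked) == 1:
        return f"{ranked[0]:g}-{rt:.1f}"
    top, second = ranked[0], ranked[1]
    ratio = 100.0 * members[second] / members[top]
    return f"{top:g}-{second:g}-{ratio:.1f}-{rt:.1f}"


def find_ion_maxima(ic: IonChromatogram, window: int) -> list[int]:
    """Indices of local maxima within a centered window of ``window`` points.

    A point qualifies if it is strictly greater than every earlier point in
    its window, at least as large as every later one, and strictly greater
    than at least one window point: plateaus report their leftmost point and
    flat traces report nothing.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be an odd count >= 3")
    x = ic.intensities
    n = x.size
    if window > n:
        raise ValueError(f"window ({window}) exceeds trace length ({n})")
    half = window // 2
    # Sliding max/min over the half-windows either side of each point;
    # +-inf padding makes clipped edge windows fall out of the comparisons.
    pad_max = np.concatenate((np.full(half, -np.inf), x, np.full(half, -np.inf)))
    pad_min = np.concatenate((np.full(half, np.inf), x, np.full(half, np.inf)))
    wmax = np.lib.stride_tricks.sliding_window_view(pad_max, half)
    wmin = np.lib.stride_tricks.sliding_window_view(pad_min, half)
    left_max = wmax[:n].max(axis=1)  # max over x[i-half : i]
    left_min = wmin[:n].min(axis=1)
    right_max = wmax[half + 1 : half + 1 + n].max(axis=1)  # over x[i+1 : i+half+1]
    right_min = wmin[half + 1 : half + 1 + n].min(axis=1)
    is_apex = (
        (x > left_max)
        & (x >= right_max)
        & ((left_min < x) | (right_min < x))
    )
    return [int(i) for i in np.nonzero(is_apex)[0]]


def _build_peak(
    im: IntensityMatrix, members: Sequence[tuple[int, int, float]]
) -> Peak:
    """Assemble a composite peak from (apex_scan, column, intensity) members."""
    best: dict[int, tuple[int, float]] = {}
    for scan, col, inten in members:
        if col not in best or inten > best[col][1]:
            best[col] = (scan, inten)
    # apex rt = scan with the greatest summed member-ion intensity (tie: earliest)
    scan_sums: dict[int, float] = {}
    for scan, inten in best.values():
        scan_sums[scan] = scan_sums.get(scan, 0.0) + inten
    apex_scan = min(scan_sums, key=lambda s: (-scan_sums[s], s))
    spectrum = np.zeros(im.n_bins)
    bounds: dict[float, tuple[int, int, int]] = {}
    for col, (scan, inten) in best.items():
        spectrum[col] = inten
        bounds[float(im.bin_centers[col])] = (scan, scan, scan)
    ms = MassSpectrum(im.bin_centers.copy(), spectrum)
    rt = float(im.rt[apex_scan])
    return Peak(uid=make_uid(ms, rt), rt=rt, spectrum=ms, ion_bounds=bounds)


def deconvolute(
    im: IntensityMatrix, params: DetectionParams, noise_floor: float = 0.0
) -> list[Peak]:
    """Combine co-apexing per-ion maxima into composite peaks.

    Maxima whose apex scans differ by at most ``params.scans`` chain into
    the same peak (transitive single-linkage grouping). ``noise_floor``
    optionally discards per-ion maxima at or below that intensity before
    grouping; peak-list intensity filtering proper is done afterwards by
    :func:`filter_num_ions`.
    """
    events: list[tuple[int, int, float]] = []
    for col in range(im.n_bins):
        x = im.values[:, col]
        ic = IonChromatogram(x, im.rt)
        for i in find_ion_maxima(ic, params.window):
            if x[i] > noise_floor:
                events.append((i, col, float(x[i])))
    events.sort(key=lambda e: e[0])
    peaks: list[Peak] = []
    group: list[tuple[int, int, float]] = []
    for event in events:
        if group and event[0] - group[-1][0] > params.scans:
            peaks.append(_build_peak(im, group))
            group = []
        group.append(event)
    if group:
        peaks.append(_build_peak(im, group))
    peaks.sort(key=lambda p: p.rt)
    return peaks


def filter_num_ions(
    peaks: Iterable[Peak], ions: int, threshold: float
) -> list[Peak]:
    """Keep peaks with at least ``ions`` member intensities >= ``threshold``."""
    kept = []
    for peak in peaks:
        qualifying = sum(
            1 for inten in peak.member_ions().values() if inten >= threshold
        )
        if qualifying >= ions:
            kept.append(peak)
    return kept


def filter_rel_intensity(peak: Peak, r: float) -> Peak:
    """Drop ions with apex intensity below ``r``% of the base ion.

    The base ion always survives, so the spectrum never empties; ``r = 0``
    is the identity.
    """
    members = peak.member_ions()
    if not members:
        raise ValueError("peak has no member ions")
    cutoff = (r / 100.0) * max(members.values())
    keep = {m for m, inten in members.items() if inten >= cutoff}
    intensities = np.where(
        np.isin(peak.spectrum.masses, sorted(keep)), peak.spectrum.intensities, 0.0
    )
    spectrum = MassSpectrum(peak.spectrum.masses, intensities)
    bounds = {m: b for m, b in peak.ion_bounds.items() if m in keep}
    areas = {m: a for m, a in peak.ion_areas.items() if m in keep}
    return Peak(
        uid=make_uid(spectrum, peak.rt),
        rt=peak.rt,
        spectrum=spectrum,
        ion_bounds=bounds,
        ion_areas=areas,
        area=sum(areas.values()) if areas else peak.area,
    )


def integrate_ion(
    ic: IonChromatogram, apex: int, stop_fraction: float = DEFAULT_STOP_FRACTION
) -> tuple[int, int, float]:
    """Outward area accumulation for one ion trace.

    Starting from the apex, points are added moving left and right
    (independently, each direction seeded with the apex intensity) until the
    candidate point contributes less than ``stop_fraction`` of the area
    accumulated so far, or its intensity exceeds the previously included
    point (the rising edge of a neighbouring signal). Returns
    ``(left, right, area)`` with the rectangle (sum x scan period) area
    convention; bounds are the last included scans.
    """
    x = ic.intensities
    n = x.size
    if not 0 <= apex < n:
        raise IndexError(f"apex {apex} out of range")
    if (apex > 0 and x[apex] < x[apex - 1]) or (apex < n - 1 and x[apex] < x[apex + 1]):
        raise ValueError(f"scan {apex} is not a local maximum of the trace")
    dt = ic.time_step() if n > 1 else 1.0

    def walk(step: int) -> tuple[int, float]:
        acc = float(x[apex])
        bound = apex
        i = apex + step
        while 0 <= i < n:
            cand = float(x[i])
            if cand > x[i - step]:  # rising edge of a neighbour
                break
            if cand < stop_fraction * acc:
                break
            acc += cand
            bound = i
            i += step
        return bound, acc - float(x[apex])

    left, left_sum = walk(-1)
    right, right_sum = walk(+1)
    area = (float(x[apex]) + left_sum + right_sum) * dt
    return left, right, area


def quantify_peak(
    peak: Peak,
    im: IntensityMatrix,
    mode: str | float = "all-ions",
    stop_fraction: float = DEFAULT_STOP_FRACTION,
) -> Peak:
    """Integrate the peak's member ions and set its area.

    ``mode="all-ions"`` sums every member ion's area into ``peak.area``;
    passing a mass uses that single ion's area alone. Per-ion bounds and
    areas are stored on the returned peak either way.
    """
    members = peak.member_ions()
    if not members:
        raise ValueError("peak has no member ions")
    if mode != "all-ions":
        ion = float(mode)
        if ion not in members:
            raise ValueError(f"ion {ion} is not a member of peak {peak.uid}")
    bounds: dict[float, tuple[int, int, int]] = {}
    areas: dict[float, float] = {}
    for mass in sorted(members):
        col = _mass_to_column(im, mass)
        ic = get_ic_at_index(im, col)
        apex = peak.ion_bounds.get(mass, (None, None, None))[1]
        if apex is None:
            raise ValueError(f"peak {peak.uid} carries no apex scan for ion {mass}")
        left, right, area = integrate_ion(ic, apex, stop_fraction)
        bounds[mass] = (left, apex, right)
        areas[mass] = area
    total = sum(areas.values()) if mode == "all-ions" else areas[float(mode)]
    return replace(peak, ion_bounds=bounds, ion_areas=areas, area=total)


def detect_peaks(
    im: IntensityMatrix,
    params: DetectionParams,
    stop_fraction: float = DEFAULT_STOP_FRACTION,
    noise_floor: float = 0.0,
) -> list[Peak]:
    """Full detection pipeline: deconvolute, filter, integrate (all ions).

    On noisy data set ``noise_floor`` to roughly 5-10x the detector-noise
    standard deviation: surviving noise maxima otherwise chain unrelated
    apexes together during grouping.
    """
    candidates = deconvolute(im, params, noise_floor)
    trimmed = [filter_rel_intensity(p, params.r) for p in candidates]
    kept = filter_num_ions(trimmed, params.ions, params.threshold)
    return [quantify_peak(p, im, "all-ions", stop_fraction) for p in kept]


def _peak_to_dict(peak: Peak) -> dict:
    members = peak.member_ions()
    masses = sorted(members)
    return {
        "uid": peak.uid,
        "rt": peak.rt,
        "masses": masses,
        "intensities": [members[m] for m in masses],
        "ion_bounds": {repr(m): list(b) for m, b in sorted(peak.ion_bounds.items())},
        "ion_areas": {repr(m): a for m, a in sorted(peak.ion_areas.items())},
        "area": peak.area,
    }


def _peak_from_dict(doc: dict) -> Peak:
    spectrum = MassSpectrum(doc["masses"], doc["intensities"])
    return Peak(
        uid=doc["uid"],
        rt=doc["rt"],
        spectrum=spectrum,
        ion_bounds={float(m): tuple(b) for m, b in doc["ion_bounds"].items()},
        ion_areas={float(m): a for m, a in doc["ion_areas"].items()},
        area=doc["area"],
    )


def write_peaks_json(peaks: Sequence[Peak], path: str | Path) -> None:
    """Serialize a peak list (sparse spectra) to a JSON document."""
    doc = {"peaks": [_peak_to_dict(p) for p in peaks]}
    Path(path).write_text(json.dumps(doc, indent=1))


def read_peaks_json(path: str | Path) -> list[Peak]:
    """Load a peak list written by :func:`write_peaks_json`."""
    doc = json.loads(Path(path).read_text())
    return [_peak_from_dict(d) for d in doc["peaks"]]


def write_peaks_csv(peaks: Sequence[Peak], path: str | Path) -> None:
    """Peak-list CSV: uid, rt_s, area, then ``mass:intensity`` pairs."""
    with Path(path).open("w", newline="") as fh:
        fh.write("uid,rt_s,area,spectrum\n")
        for peak in peaks:
            members = peak.member_ions()
            pairs = ";".join(f"{m:g}:{members[m]:g}" for m in sorted(members))
            fh.write(f"{peak.uid},{peak.rt!r},{peak.area!r},{pairs}\n")
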