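"""m/z binning of raw runs into a rectangular intensity matrix.

Centroided scans have variable length and non-uniform m/z sampling; binning
maps every (m/z, intensity) point onto a fixed m/z grid, producing a
scans x bins table whose cells hold sums of intensities. Bin intervals are
half-open, ``[center - lower_offset, center + upper_offset)``, so the bins
tile the m/z axis and every point lands in exactly one bin — total intensity
is conserved exactly.

The default grid is nominal-mass binning with boundaries at -0.3/+0.7
around integer centers: accurate masses of most (CHN-rich) metabolite
fragments sit slightly above the integer, so the asymmetric bin keeps a
fragment's centroid in its nominal bin. Grid centers sit at integer
multiples of ``bin_size``.

All matrix-returning operations return new values rather than mutating
their input, so processing pipelines are referentially transparent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .core import FormatError, IonChromatogram, MassSpectrum, RawRun, TIC_LABEL

__all__ = [
    "IntensityMatrix",
    "build_intensity_matrix",
    "build_intensity_matrix_i",
    "get_ic_at_index",
    "get_ic_at_mass",
    "get_ms_at_index",
    "get_scan_at_index",
    "null_mass",
    "crop_mass",
    "export_matrix",
    "import_matrix_csv",
    "EXPORT_DIALECTS",
]

EXPORT_DIALECTS = ("space", "csv", "leco-csv")


@dataclass(frozen=True)
class IntensityMatrix:
    """Binned GC-MS data: rows are scans (time), columns are m/z bins."""

    values: np.ndarray
    rt: np.ndarray
    bin_centers: np.ndarray
    bin_size: float
    lower_offset: float
    upper_offset: float

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        rt = np.asarray(self.rt, dtype=float)
        centers = np.asarray(self.bin_centers, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "rt", rt)
        object.__setattr__(self, "bin_centers", centers)
        if values.ndim != 2:
            raise ValueError("values must be 2-D (scans x bins)")
        if values.shape != (rt.size, centers.size):
            raise ValueError("values shape must be (len(rt), len(bin_centers))")
        if np.any(values < 0):
            raise ValueError("intensities must be non-negative")
        if rt.size > 1 and not np.all(np.diff(rt) > 0):
            raise ValueError("rt must be strictly increasing")
        if centers.size > 1 and not np.allclose(
            np.diff(centers), self.bin_size, rtol=0, atol=1e-9
        ):
            raise ValueError("bin_centers must step by bin_size")
        if not math.isclose(self.lower_offset + self.upper_offset, self.bin_size):
            raise ValueError("lower_offset + upper_offset must equal bin_size")

    @property
    def n_scans(self) -> int:
        return int(self.rt.size)

    @property
    def n_bins(self) -> int:
        return int(self.bin_centers.size)

    def get_size(self) -> tuple[int, int]:
        return self.n_scans, self.n_bins

    def time_step(self) -> float:
        if self.n_scans < 2:
            raise ValueError("time step undefined for a single-scan matrix")
        return float(np.mean(np.diff(self.rt)))

    def total_intensity(self) -> float:
        return float(self.values.sum())

    # thin method aliases mirroring the functional API
    def get_ic_at_index(self, index: int) -> IonChromatogram:
        return get_ic_at_index(self, index)

    def get_ic_at_mass(self, mass: float) -> IonChromatogram:
        return get_ic_at_mass(self, mass)

    def get_ms_at_index(self, index: int) -> MassSpectrum:
        return get_ms_at_index(self, index)

    def get_scan_at_index(self, index: int) -> MassSpectrum:
        return get_scan_at_index(self, index)


def build_intensity_matrix(
    run: RawRun,
    bin_size: float = 1.0,
    lower_offset: float = 0.3,
    upper_offset: float = 0.7,
) -> IntensityMatrix:
    """Bin a raw run onto a fixed m/z grid.

    A point with m/z ``x`` contributes its intensity to the unique bin with
    center ``k * bin_size`` satisfying
    ``center - lower_offset <= x < center + upper_offset``; the contiguous
    grid spans from the bin of the smallest observed m/z to the bin of the
    largest. Cells receiving no points are zero.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    if not math.isclose(lower_offset + upper_offset, bin_size):
        raise ValueError("lower_offset + upper_offset must equal bin_size")
    indices_per_scan = []
    kmin, kmax = None, None
    for scan in run.scans:
        if len(scan) == 0:
            indices_per_scan.append(np.empty(0, dtype=int))
            continue
        k = np.floor((scan.mz + lower_offset) / bin_size).astype(int)
        indices_per_scan.append(k)
        lo, hi = int(k.min()), int(k.max())
        kmin = lo if kmin is None else min(kmin, lo)
        kmax = hi if kmax is None else max(kmax, hi)
    if kmin is None:
        raise ValueError("run contains no mass-spectral points to bin")
    centers = np.arange(kmin, kmax + 1, dtype=float) * bin_size
    values = np.zeros((run.n_scans, centers.size))
    for row, (scan, k) in enumerate(zip(run.scans, indices_per_scan)):
        if k.size:
            np.add.at(values[row], k - kmin, scan.intensity)
    return IntensityMatrix(values, run.rt, centers, bin_size, lower_offset, upper_offset)


def build_intensity_matrix_i(run: RawRun) -> IntensityMatrix:
    """Default nominal-mass binning: 1 Th bins with -0.3/+0.7 boundaries."""
    return build_intensity_matrix(run, 1.0, 0.3, 0.7)


def get_ic_at_index(im: IntensityMatrix, index: int) -> IonChromatogram:
    """The ion chromatogram of bin column ``index``."""
    if not 0 <= index < im.n_bins:
        raise IndexError(f"bin index {index} out of range [0, {im.n_bins - 1}]")
    return IonChromatogram(
        im.values[:, index].copy(), im.rt, label=float(im.bin_centers[index])
    )


def get_ic_at_mass(im: IntensityMatrix, mass: float) -> IonChromatogram:
    """The IC of the bin whose center is nearest ``mass`` (ties: lower center)."""
    lo = im.bin_centers[0] - im.lower_offset
    hi = im.bin_centers[-1] + im.upper_offset
    if not lo <= mass < hi:
        raise IndexError(f"mass {mass} outside binned range [{lo}, {hi})")
    # argmin returns the first minimum, i.e. the lower center on a tie
    index = int(np.argmin(np.abs(im.bin_centers - mass)))
    return get_ic_at_index(im, index)


def get_ms_at_index(im: IntensityMatrix, index: int) -> MassSpectrum:
    """The mass spectrum of scan row ``index`` over all bin centers."""
    if not 0 <= index < im.n_scans:
        raise IndexError(f"scan index {index} out of range [0, {im.n_scans - 1}]")
    return MassSpectrum(im.bin_centers.copy(), im.values[index].copy())


def get_scan_at_index(im: IntensityMatrix, index: int) -> MassSpectrum:
    """Alias of :func:`get_ms_at_index` (row access while looping over scans)."""
    return get_ms_at_index(im, index)


def _mass_to_column(im: IntensityMatrix, mass: float) -> int:
    diffs = np.abs(im.bin_centers - mass)
    index = int(np.argmin(diffs))
    if diffs[index] > im.bin_size / 2 + 1e-9:
        raise IndexError(f"mass {mass} does not map to an existing bin")
    return index


def null_mass(im: IntensityMatrix, masses: Iterable[float]) -> IntensityMatrix:
    """Zero the named mass columns (e.g. TMS artifact ions 73 and 147).

    Returns a new matrix; the input is untouched.
    """
    values = im.values.copy()
    for mass in masses:
        values[:, _mass_to_column(im, mass)] = 0.0
    return IntensityMatrix(
        values, im.rt, im.bin_centers, im.bin_size, im.lower_offset, im.upper_offset
    )


def crop_mass(im: IntensityMatrix, mz_lo: float, mz_hi: float) -> IntensityMatrix:
    """Keep only columns whose bin center lies in ``[mz_lo, mz_hi]``."""
    if mz_lo >= mz_hi:
        raise ValueError("mz_lo must be less than mz_hi")
    keep = (im.bin_centers >= mz_lo) & (im.bin_centers <= mz_hi)
    if not np.any(keep):
        raise ValueError(f"no bin centers inside [{mz_lo}, {mz_hi}]")
    return IntensityMatrix(
        im.values[:, keep],
        im.rt,
        im.bin_centers[keep],
        im.bin_size,
        im.lower_offset,
        im.upper_offset,
    )


def export_matrix(im: IntensityMatrix, path: str | Path, dialect: str = "csv") -> None:
    """Write the binned table in one of three ASCII dialects.

    - ``space``: bare numeric matrix, one scan per line, space-separated.
    - ``csv``: header ``rt`` + bin centers; each row starts with rt seconds.
    - ``leco-csv``: header ``"Scan","Time",<masses...>``; rows carry the scan
      number, rt in seconds, then intensities (comma-separated).
    """
    path = Path(path)
    if dialect not in EXPORT_DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {EXPORT_DIALECTS}")
    with path.open("w", newline="") as fh:
        if dialect == "space":
            for row in im.values:
                fh.write(" ".join(repr(float(v)) for v in row) + "\n")
        elif dialect == "csv":
            fh.write("rt," + ",".join(repr(float(m)) for m in im.bin_centers) + "\n")
            for rt, row in zip(im.rt, im.values):
                fh.write(
                    repr(float(rt)) + "," + ",".join(repr(float(v)) for v in row) + "\n"
                )
        else:  # leco-csv
            fh.write(
                '"Scan","Time",' + ",".join(f"{float(m):g}" for m in im.bin_centers) + "\n"
            )
            for i, (rt, row) in enumerate(zip(im.rt, im.values)):
                fh.write(
                    f"{i},{float(rt)!r}," + ",".join(repr(float(v)) for v in row) + "\n"
                )


def import_matrix_csv(path: str | Path) -> IntensityMatrix:
    """Round-trip partner of the ``csv`` export dialect.

    Bin offsets are not stored in the file; the default -0.3/+0.7 split is
    assumed for 1-unit grids, symmetric offsets otherwise.
    """
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().strip().split(",")
        if not header or header[0] != "rt":
            raise FormatError(f"{path}: not a gcmskit csv matrix (header {header[:2]!r})")
        centers = np.array([float(x) for x in header[1:]])
        rts: list[float] = []
        rows: list[list[float]] = []
        for line in fh:
            cells = line.strip().split(",")
            if len(cells) != centers.size + 1:
                raise FormatError(f"{path}: ragged row with {len(cells)} cells")
            rts.append(float(cells[0]))
            rows.append([float(x) for x in cells[1:]])
    bin_size = float(centers[1] - centers[0]) if centers.size > 1 else 1.0
    if math.isclose(bin_size, 1.0):
        lower, upper = 0.3, 0.7
    else:
        lower = upper = bin_size / 2.0
    return IntensityMatrix(
        np.asarray(rows), np.asarray(rts), centers, bin_size, lower, upper
    )
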