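"""Reading and summarizing raw GC-MS runs (ANDI-MS/NetCDF and JCAMP-DX).

ANDI-MS (AIA) files are classic NetCDF with the mass-spectrometry variable
set ``scan_acquisition_time``, ``point_count`` (or ``scan_index``),
``mass_values`` and ``intensity_values``. JCAMP-DX is the flat ASCII
chromatography/MS dialect; the accepted grammar is the one produced by
:func:`gcmskit.simulate.write_jcamp` (``##PAGE=``/``##DATA TABLE=`` scan
blocks or per-scan ``##RETENTION_TIME=``/``##XYDATA=`` blocks). Compressed
JCAMP numeric forms (SQZ/DIF/PAC letter codes) are rejected with a clear
error.

Zero-intensity centroid points are retained on read: dropping them would be
a lossy transformation nothing downstream requires.
"""

from __future__ import annotations

import csv
import math
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.io import netcdf_file

from .core import FormatError, IonChromatogram, MassSpectrum, RawRun, ScanRecord, TIC_LABEL

__all__ = [
    "RunSummary",
    "read_andi",
    "read_jcamp",
    "summarize",
    "trim",
    "parse_time_literal",
    "total_ion_chromatogram",
    "write_raw_csv",
    "read_raw_csv",
]

_ANDI_TIME = "scan_acquisition_time"
_ANDI_MASS = "mass_values"
_ANDI_INTENSITY = "intensity_values"


@dataclass(frozen=True)
class RunSummary:
    """Compact description of a raw run (the ``info()`` block)."""

    rt_min: float
    rt_max: float
    time_step_mean: float
    time_step_std: float
    n_scans: int
    mz_min: float
    mz_max: float
    mz_per_scan_mean: float
    mz_per_scan_median: float
    single_scan_warning: bool = False

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"Data retention time range: {self.rt_min / 60.0:.3f} min -- "
            f"{self.rt_max / 60.0:.3f} min\n"
            f"Time step: {self.time_step_mean:.3f} s "
            f"(std = {self.time_step_std:.3f} s)\n"
            f"Number of scans: {self.n_scans}\n"
            f"Minimum m/z measured: {self.mz_min:.3f}\n"
            f"Maximum m/z measured: {self.mz_max:.3f}\n"
            f"Mean number of m/z values per scan: {self.mz_per_scan_mean:.0f}\n"
            f"Median number of m/z values per scan: {self.mz_per_scan_median:.0f}"
        )


def _require_variable(nc, name: str, path) -> np.ndarray:
    if name not in nc.variables:
        raise FormatError(f"{path}: missing mandatory NetCDF variable '{name}'")
    return np.array(nc.variables[name][:])


def read_andi(path: str | Path) -> RawRun:
    """Read an ANDI-MS (AIA NetCDF) file into a :class:`RawRun`.

    Raises :class:`FileNotFoundError` for a missing file and
    :class:`gcmskit.core.FormatError` for missing variables, non-monotone
    scan times, or an inconsistent/overlapping scan index.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with netcdf_file(str(path), "r", mmap=False) as nc:
        times = _require_variable(nc, _ANDI_TIME, path).astype(float)
        masses = _require_variable(nc, _ANDI_MASS, path).astype(float)
        intens = _require_variable(nc, _ANDI_INTENSITY, path).astype(float)
        if "point_count" in nc.variables:
            counts = np.array(nc.variables["point_count"][:]).astype(int)
            if counts.size != times.size:
                raise FormatError(f"{path}: point_count length mismatch")
            if np.any(counts < 0) or counts.sum() != masses.size:
                raise FormatError(f"{path}: point_count inconsistent with mass_values")
            starts = np.concatenate(([0], np.cumsum(counts)[:-1]))
            ends = np.cumsum(counts)
        elif "scan_index" in nc.variables:
            starts = np.array(nc.variables["scan_index"][:]).astype(int)
            if starts.size != times.size:
                raise FormatError(f"{path}: scan_index length mismatch")
            ends = np.concatenate((starts[1:], [masses.size]))
            if np.any(starts < 0) or np.any(ends < starts) or np.any(ends > masses.size):
                raise FormatError(
                    f"{path}: scan_index implies overlapping or out-of-range point ranges"
                )
        else:
            raise FormatError(
                f"{path}: missing mandatory NetCDF variable 'point_count' or 'scan_index'"
            )
    if times.size > 1 and not np.all(np.diff(times) > 0):
        raise FormatError(f"{path}: scan times are not strictly increasing")
    scans = [
        ScanRecord(masses[a:b], intens[a:b]) for a, b in zip(starts, ends)
    ]
    return RawRun(tuple(scans), times, source=f"{path}#andi")


# JCAMP data lines hold bare numbers only; any alphabetic character (besides
# an exponent marker inside a number) indicates SQZ/DIF/PAC compression.
_NUMBER_RE = re.compile(r"^[+-]?(\d+\.?\d*|\.\d+)([eE][+-]?\d+)?$")


def _parse_pairs(line: str, lineno: int, path) -> tuple[list[float], list[float]]:
    mzs: list[float] = []
    ints: list[float] = []
    for token in line.replace(";", " ").split():
        parts = token.split(",") if "," in token else [token]
        for p in parts:
            if not _NUMBER_RE.match(p):
                raise FormatError(
                    f"{path}:{lineno}: unparseable data token {p!r} "
                    "(compressed SQZ/DIF numeric forms are not supported)"
                )
        if len(parts) == 2:
            mzs.append(float(parts[0]))
            ints.append(float(parts[1]))
        else:
            # space-separated alternating x y tokens
            if len(mzs) == len(ints):
                mzs.append(float(parts[0]))
            else:
                ints.append(float(parts[0]))
    if len(mzs) != len(ints):
        raise FormatError(f"{path}:{lineno}: odd number of values in data line")
    return mzs, ints


def read_jcamp(path: str | Path) -> RawRun:
    """Read a JCAMP-DX chromatography/MS file into a :class:`RawRun`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    scans: list[ScanRecord] = []
    rts: list[float] = []
    cur_rt: float | None = None
    cur_mz: list[float] = []
    cur_int: list[float] = []
    in_data = False

    def flush() -> None:
        nonlocal cur_rt, cur_mz, cur_int, in_data
        if cur_rt is not None:
            order = np.argsort(cur_mz, kind="stable")
            scans.append(
                ScanRecord(np.asarray(cur_mz)[order], np.asarray(cur_int)[order])
            )
            rts.append(cur_rt)
        cur_rt, cur_mz, cur_int, in_data = None, [], [], False

    for lineno, raw_line in enumerate(text.splitlines(), start=1):
        line = raw_line.strip()
        if not line:
            continue
        if line.startswith("##"):
            key, _, value = line[2:].partition("=")
            key = key.strip().upper().replace(" ", "")
            value = value.strip()
            if key == "PAGE":
                flush()
                m = re.match(r"T\s*=\s*([0-9.eE+-]+)", value)
                if not m:
                    raise FormatError(f"{path}:{lineno}: unparseable ##PAGE= value")
                cur_rt = float(m.group(1))
            elif key in ("RETENTION_TIME", "RETENTIONTIME"):
                flush()
                cur_rt = float(value)
            elif key in ("DATATABLE", "XYDATA"):
                if cur_rt is None:
                    raise FormatError(
                        f"{path}:{lineno}: data block before any retention time"
                    )
                in_data = True
            elif key == "END":
                flush()
            # all other ## records are descriptive headers; ignored
        else:
            if not in_data or cur_rt is None:
                raise FormatError(f"{path}:{lineno}: data line outside a scan block")
            mzs, ints = _parse_pairs(line, lineno, path)
            cur_mz.extend(mzs)
            cur_int.extend(ints)
    flush()
    if not scans:
        raise FormatError(f"{path}: no scans found")
    rt = np.asarray(rts, dtype=float)
    if rt.size > 1 and not np.all(np.diff(rt) > 0):
        raise FormatError(f"{path}: scan times are not strictly increasing")
    return RawRun(tuple(scans), rt, source=f"{path}#jcamp")


def summarize(run: RawRun) -> RunSummary:
    """Compute the ``info()``-style summary of a run.

    The per-scan point-count median uses the lower of the two middle values
    for even counts. A single-scan run reports zero time-step statistics and
    sets ``single_scan_warning``.
    """
    counts = sorted(len(s) for s in run.scans)
    nonempty = [s for s in run.scans if len(s) > 0]
    if not nonempty:
        raise ValueError("run has no mass-spectral points")
    mz_min = min(float(s.mz[0]) for s in nonempty)
    mz_max = max(float(s.mz[-1]) for s in nonempty)
    if run.n_scans > 1:
        steps = np.diff(run.rt)
        step_mean, step_std, warn = float(steps.mean()), float(steps.std()), False
    else:
        step_mean = step_std = 0.0
        warn = True
    return RunSummary(
        rt_min=float(run.rt[0]),
        rt_max=float(run.rt[-1]),
        time_step_mean=step_mean,
        time_step_std=step_std,
        n_scans=run.n_scans,
        mz_min=mz_min,
        mz_max=mz_max,
        mz_per_scan_mean=float(np.mean(counts)),
        mz_per_scan_median=float(counts[(len(counts) - 1) // 2]),
        single_scan_warning=warn,
    )


def parse_time_literal(value: int | float | str, run: RawRun, *, is_begin: bool) -> int:
    """Convert a trim bound to a scan index.

    A bare integer (or digit string) is a scan index. Strings with a unit
    suffix are retention times: ``"390s"`` = 390 seconds, ``"6.5m"`` = 6.5
    minutes. Time bounds map to the nearest enclosed scan: the first scan
    with rt >= begin, or the last scan with rt <= end.
    """
    if isinstance(value, str):
        s = value.strip()
        if s.endswith("m"):
            seconds = float(s[:-1]) * 60.0
        elif s.endswith("s"):
            seconds = float(s[:-1])
        elif s.isdigit() or (s.startswith("-") and s[1:].isdigit()):
            return int(s)
        else:
            raise ValueError(
                f"time literal {value!r} needs an 's' (seconds) or 'm' (minutes) suffix"
            )
        if is_begin:
            idx = int(np.searchsorted(run.rt, seconds, side="left"))
            if idx >= run.n_scans:
                raise IndexError(f"begin time {value!r} is past the end of the run")
        else:
            idx = int(np.searchsorted(run.rt, seconds, side="right")) - 1
            if idx < 0:
                raise IndexError(f"end time {value!r} is before the start of the run")
        return idx
    if isinstance(value, float) and not value.is_integer():
        raise ValueError("fractional scan index; use an 's'/'m' time literal")
    return int(value)


def trim(run: RawRun, begin: int | float | str, end: int | float | str) -> RawRun:
    """Return the scans with index in ``[begin, end]`` (both endpoints kept).

    Bounds may be scan indices or time literals (``"6.5m"``, ``"390s"``).
    Retention times are preserved, not re-zeroed.
    """
    b = parse_time_literal(begin, run, is_begin=True)
    e = parse_time_literal(end, run, is_begin=False)
    if b >= e:
        raise ValueError(f"begin ({b}) must be less than end ({e}) after conversion")
    if b < 0 or e >= run.n_scans:
        raise IndexError(
            f"trim bounds [{b}, {e}] outside data range [0, {run.n_scans - 1}]"
        )
    return RawRun(run.scans[b : e + 1], run.rt[b : e + 1], source=run.source)


def total_ion_chromatogram(run: RawRun) -> IonChromatogram:
    """The TIC: per-scan sum of all ion intensities, sharing the run's rt."""
    tic = np.array([s.intensity.sum() for s in run.scans], dtype=float)
    return IonChromatogram(tic, run.rt, label=TIC_LABEL)


def write_raw_csv(run: RawRun, path: str | Path) -> None:
    """Export raw points, one ``rt_s,mz,intensity`` record per (scan, point).

    Scans with no points contribute no lines and are therefore not
    reconstructable from the CSV.
    """
    path = Path(path)
    with path.open("w", newline="") as fh:
        fh.write("rt_s,mz,intensity\n")
        for rt, scan in zip(run.rt, run.scans):
            for mz, inten in zip(scan.mz, scan.intensity):
                fh.write(f"{float(rt)!r},{float(mz)!r},{float(inten)!r}\n")


def read_raw_csv(path: str | Path) -> RawRun:
    """Re-assemble a run from :func:`write_raw_csv` output (round-trip partner)."""
    path = Path(path)
    rts: list[float] = []
    scans_mz: list[list[float]] = []
    scans_int: list[list[float]] = []
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != ["rt_s", "mz", "intensity"]:
            raise FormatError(f"{path}: unexpected header {header!r}")
        for row in reader:
            rt, mz, inten = (float(x) for x in row)
            if not rts or rt != rts[-1]:
                rts.append(rt)
                scans_mz.append([])
                scans_int.append([])
            scans_mz[-1].append(mz)
            scans_int[-1].append(inten)
    if not rts:
        raise FormatError(f"{path}: no data rows")
    scans = tuple(
        ScanRecord(np.asarray(m), np.asarray(i)) for m, i in zip(scans_mz, scans_int)
    )
    return RawRun(scans, np.asarray(rts), source=f"{path}#csv")
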