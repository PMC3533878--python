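"""Core containers shared across the GC-MS processing pipeline.

A raw GC-MS run is a time-ordered list of centroided mass-spectral scans;
each scan is a variable-length vector of (m/z, intensity) pairs. Retention
times are stored in seconds everywhere inside the library; minutes appear
only at I/O boundaries (e.g. the ``"6.5m"`` trim literals).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "FormatError",
    "ScanRecord",
    "RawRun",
    "IonChromatogram",
    "MassSpectrum",
    "TIC_LABEL",
]

#: Label marking an IonChromatogram as the total ion chromatogram.
TIC_LABEL = "TIC"


class FormatError(ValueError):
    """Raised when an input file violates the expected on-disk format."""


def _as_float_array(values: Sequence[float] | np.ndarray) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError("expected a 1-D sequence")
    return arr


@dataclass(frozen=True)
class ScanRecord:
    """One centroided mass-spectral scan: ascending m/z with intensities."""

    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "mz", _as_float_array(self.mz))
        object.__setattr__(self, "intensity", _as_float_array(self.intensity))
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity must have equal length")
        if self.mz.size > 1 and not np.all(np.diff(self.mz) > 0):
            raise ValueError("m/z values must be strictly ascending")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")

    def __len__(self) -> int:
        return int(self.mz.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ScanRecord):
            return NotImplemented
        return np.array_equal(self.mz, other.mz) and np.array_equal(
            self.intensity, other.intensity
        )


@dataclass(frozen=True)
class RawRun:
    """A raw GC-MS run: scans plus a strictly increasing rt vector (seconds)."""

    scans: tuple[ScanRecord, ...]
    rt: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "scans", tuple(self.scans))
        object.__setattr__(self, "rt", _as_float_array(self.rt))
        if len(self.scans) < 1:
            raise ValueError("a run must contain at least one scan")
        if len(self.scans) != self.rt.size:
            raise ValueError("rt vector length must equal the number of scans")
        if self.rt.size > 1 and not np.all(np.diff(self.rt) > 0):
            raise ValueError("retention times must be strictly increasing")

    @property
    def n_scans(self) -> int:
        return len(self.scans)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RawRun):
            return NotImplemented
        return (
            np.array_equal(self.rt, other.rt)
            and len(self.scans) == len(other.scans)
            and all(a == b for a, b in zip(self.scans, other.scans))
        )

    def total_intensity(self) -> float:
        """Sum of every recorded intensity in the run."""
        return float(sum(s.intensity.sum() for s in self.scans))


@dataclass(frozen=True)
class IonChromatogram:
    """One intensity-vs-time trace: a single m/z bin or the TIC.

    ``label`` is the bin-center mass (Th) for an extracted ion
    chromatogram, or :data:`TIC_LABEL` for the total ion chromatogram.
    """

    intensities: np.ndarray
    rt: np.ndarray
    label: float | str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "intensities", _as_float_array(self.intensities))
        object.__setattr__(self, "rt", _as_float_array(self.rt))
        if self.intensities.shape != self.rt.shape:
            raise ValueError("intensities and rt must have equal length")

    def __len__(self) -> int:
        return int(self.rt.size)

    @property
    def is_tic(self) -> bool:
        return self.label == TIC_LABEL

    def time_step(self) -> float:
        """Mean sampling period in seconds."""
        if len(self) < 2:
            raise ValueError("time step undefined for a single-point trace")
        return float(np.mean(np.diff(self.rt)))

    def replace(self, intensities: np.ndarray) -> "IonChromatogram":
        """Same trace with new intensity values (rt and label preserved)."""
        return IonChromatogram(intensities, self.rt, self.label)


@dataclass(frozen=True)
class MassSpectrum:
    """A spectrum over ascending masses; zeros are meaningful (empty bins)."""

    masses: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "masses", _as_float_array(self.masses))
        object.__setattr__(self, "intensities", _as_float_array(self.intensities))
        if self.masses.shape != self.intensities.shape:
            raise ValueError("masses and intensities must have equal length")
        if self.masses.size > 1 and not np.all(np.diff(self.masses) > 0):
            raise ValueError("masses must be strictly ascending")

    def __len__(self) -> int:
        return int(self.masses.size)

    def nonzero(self) -> dict[float, float]:
        """Mapping of mass -> intensity for the non-empty channels."""
        idx = np.nonzero(self.intensities)[0]
        return {float(self.masses[i]): float(self.intensities[i]) for i in idx}

    def base_ion(self) -> float:
        """Mass of the most intense channel; ties go to the lower mass."""
        if self.masses.size == 0 or not np.any(self.intensities > 0):
            raise ValueError("spectrum has no non-zero channel")
        return float(self.masses[int(np.argmax(self.intensities))])
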