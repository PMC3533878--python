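"""Synthetic EI-GC-MS runs with embedded ground truth.

Every component elutes as a Gaussian of width ``sigma`` seconds centered at
``rt_center`` (plus a per-replicate drift), and deposits its EI fragment
spectrum — a list of (m/z, relative intensity) pairs with the base ion at
1.0 — scaled by ``amplitude`` and the replicate's dilution factor. On top
of the signal the generator emulates the noise structure of real
quadrupole data: zero-mean high-frequency detector noise, an optional
low-frequency baseline (linear drift or a broad "hump") carried on
column-bleed channels, and a detector threshold that suppresses weak points
into blocks of zeros. Centroid m/z values are jittered within +-0.2 Th of
nominal to exercise binning boundaries.

Ground truth accompanies every run: the drifted apex rt and the analytic
per-ion areas ``amplitude * rel * dilution * sigma * sqrt(2*pi)`` of each
component, which detection and quantitation results can be scored against.

What this emulates and what it does not: Gaussian elution (no tailing/EMG),
nominal-mass fragments with bounded centroid error, stationary Gaussian
detector noise. Real data adds peak asymmetry, saturation, and
spectral skew across a peak; passing against these fixtures validates the
algorithms' contracts, not instrument-specific robustness.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.io import netcdf_file

from .core import MassSpectrum, RawRun, ScanRecord

__all__ = [
    "SyntheticComponent",
    "NoiseModel",
    "RunDesign",
    "GroundTruthPeak",
    "simulate_run",
    "write_andi",
    "write_andi_raw",
    "write_jcamp",
    "benchmark_detection",
    "mix_like_design",
    "overlap_design",
    "serum_like_design",
    "dilution_series_design",
    "random_spectrum",
    "DESIGNS",
]

#: m/z channels that carry baseline (column bleed / derivatization residue).
BLEED_IONS = (73.0, 147.0, 207.0, 281.0)

MZ_JITTER = 0.2  # Th, uniform centroid jitter around the nominal mass


@dataclass(frozen=True)
class SyntheticComponent:
    """One eluting compound: Gaussian profile times an EI fragment spectrum."""

    rt_center: float
    sigma: float
    spectrum: tuple[tuple[float, float], ...]  # (m/z, relative intensity)
    amplitude: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        rels = [rel for _, rel in self.spectrum]
        if not rels or not math.isclose(max(rels), 1.0):
            raise ValueError("relative intensities must lie in (0, 1] with max == 1")
        if min(rels) <= 0:
            raise ValueError("relative intensities must be positive")


@dataclass(frozen=True)
class NoiseModel:
    """hf_sd: detector-noise s.d. (counts); baseline: none|linear|hump with
    an amplitude; detector_threshold: counts below which points vanish."""

    hf_sd: float = 0.0
    baseline: str = "none"
    baseline_amplitude: float = 0.0
    detector_threshold: float = 0.0

    def __post_init__(self) -> None:
        if self.hf_sd < 0 or self.detector_threshold < 0:
            raise ValueError("noise parameters must be non-negative")
        if self.baseline not in ("none", "linear", "hump"):
            raise ValueError("baseline must be one of none|linear|hump")


@dataclass(frozen=True)
class RunDesign:
    """The full recipe for a set of replicate runs; ``seed`` fixes everything."""

    components: tuple[SyntheticComponent, ...]
    rt_start: float
    rt_end: float
    scan_period: float
    noise: NoiseModel = NoiseModel()
    drift_mean: float = 0.0
    drift_sd: float = 0.0
    dilutions: tuple[float, ...] = (1.0,)
    n_noise_channels: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scan_period <= 0:
            raise ValueError("scan period must be positive")
        if self.rt_start >= self.rt_end:
            raise ValueError("rt_start must be before rt_end")


@dataclass(frozen=True)
class GroundTruthPeak:
    """True apex rt, component spectrum, and analytic per-ion areas."""

    rt: float
    spectrum: MassSpectrum
    ion_areas: dict[float, float]

    @property
    def area(self) -> float:
        return float(sum(self.ion_areas.values()))


def _baseline_trace(noise: NoiseModel, t: np.ndarray) -> np.ndarray:
    span = t[-1] - t[0]
    if noise.baseline == "linear":
        return noise.baseline_amplitude * (t - t[0]) / span
    if noise.baseline == "hump":
        mid, width = t[0] + span / 2.0, span / 4.0
        return noise.baseline_amplitude * np.exp(-((t - mid) ** 2) / (2 * width**2))
    return np.zeros_like(t)


def simulate_run(
    design: RunDesign, replicate: int = 0
) -> tuple[RawRun, list[GroundTruthPeak]]:
    """Generate one replicate run and its ground truth.

    All randomness derives from ``(design.seed, replicate)``, so the same
    inputs always reproduce the same run. The replicate index selects the
    dilution factor (cycling if more replicates than factors are requested)
    and draws the replicate's rt drift.
    """
    rng = np.random.default_rng([design.seed % (2**31), replicate])
    t = np.arange(design.rt_start, design.rt_end, design.scan_period)
    drift = rng.normal(design.drift_mean, design.drift_sd) if design.drift_sd > 0 else design.drift_mean
    dilution = design.dilutions[replicate % len(design.dilutions)]

    channels: dict[float, np.ndarray] = {}

    def channel(mz: float) -> np.ndarray:
        if mz not in channels:
            channels[mz] = np.zeros_like(t)
        return channels[mz]

    truth: list[GroundTruthPeak] = []
    for comp in design.components:
        center = comp.rt_center + drift
        if not design.rt_start <= comp.rt_center <= design.rt_end:
            raise ValueError(
                f"component at rt {comp.rt_center} lies outside the rt range"
            )
        profile = np.exp(-((t - center) ** 2) / (2.0 * comp.sigma**2))
        ion_areas: dict[float, float] = {}
        masses, intensities = [], []
        for mz, rel in sorted(comp.spectrum):
            height = comp.amplitude * rel * dilution
            channel(float(mz))
            channels[float(mz)] = channels[float(mz)] + height * profile
            ion_areas[float(mz)] = height * comp.sigma * math.sqrt(2.0 * math.pi)
            masses.append(float(mz))
            intensities.append(height)
        truth.append(
            GroundTruthPeak(
                rt=float(center),
                spectrum=MassSpectrum(masses, intensities),
                ion_areas=ion_areas,
            )
        )

    noise = design.noise
    if noise.baseline != "none":
        base = _baseline_trace(noise, t)
        for mz in BLEED_IONS:
            channel(mz)
            channels[mz] = channels[mz] + base
    if noise.hf_sd > 0:
        lo = min(channels) if channels else 50.0
        hi = max(channels) if channels else 300.0
        extra = rng.integers(int(lo), int(hi) + 1, size=design.n_noise_channels)
        for mz in extra:
            channel(float(mz))
        for mz in sorted(channels):
            channels[mz] = channels[mz] + rng.normal(0.0, noise.hf_sd, size=t.size)

    order = sorted(channels)
    scans: list[ScanRecord] = []
    for i in range(t.size):
        mzs, ints = [], []
        for mz in order:
            value = channels[mz][i]
            if value <= 0 or value < noise.detector_threshold:
                continue  # detector threshold: weak points vanish (zero blocks)
            jitter = rng.uniform(-MZ_JITTER, MZ_JITTER)
            mzs.append(mz + jitter)
            ints.append(value)
        scans.append(ScanRecord(np.asarray(mzs), np.asarray(ints)))
    run = RawRun(tuple(scans), t, source=f"synthetic:{design.seed}/{replicate}")
    truth.sort(key=lambda g: g.rt)
    return run, truth


# ---------------------------------------------------------------------------
# serialization: round-trip partners of the raw_io readers


def write_andi(run: RawRun, path: str | Path) -> None:
    """Serialize a run as an ANDI-MS (AIA) classic NetCDF file."""
    counts = np.array([len(s) for s in run.scans], dtype=np.int32)
    total = int(counts.sum())
    if total == 0:
        raise ValueError("cannot serialize a run with no mass-spectral points")
    starts = np.concatenate(([0], np.cumsum(counts)[:-1])).astype(np.int32)
    masses = np.concatenate([s.mz for s in run.scans if len(s)])
    intens = np.concatenate([s.intensity for s in run.scans if len(s)])
    write_andi_raw(path, run.rt, starts, masses, intens, point_count=counts)


def write_andi_raw(
    path: str | Path,
    scan_times: np.ndarray,
    scan_index: np.ndarray,
    mass_values: np.ndarray,
    intensity_values: np.ndarray,
    point_count: np.ndarray | None = None,
) -> None:
    """Low-level ANDI writer taking the NetCDF variables verbatim.

    No consistency checks are applied, so deliberately corrupt files (e.g.
    an overlapping ``scan_index``) can be produced for reader error tests.
    """
    path = Path(path)
    with netcdf_file(str(path), "w") as nc:
        nc.createDimension("scan_number", len(scan_times))
        nc.createDimension("point_number", len(mass_values))
        v = nc.createVariable("scan_acquisition_time", "d", ("scan_number",))
        v[:] = np.asarray(scan_times, dtype=float)
        v = nc.createVariable("scan_index", "i", ("scan_number",))
        v[:] = np.asarray(scan_index, dtype=np.int32)
        if point_count is not None:
            v = nc.createVariable("point_count", "i", ("scan_number",))
            v[:] = np.asarray(point_count, dtype=np.int32)
        v = nc.createVariable("mass_values", "d", ("point_number",))
        v[:] = np.asarray(mass_values, dtype=float)
        v = nc.createVariable("intensity_values", "d", ("point_number",))
        v[:] = np.asarray(intensity_values, dtype=float)


def write_jcamp(run: RawRun, path: str | Path) -> None:
    """Serialize a run in the JCAMP-DX chromatography/MS dialect."""
    path = Path(path)
    lines = [
        "##TITLE=gcmskit synthetic run",
        "##JCAMP-DX=4.24",
        "##DATA TYPE=GC-MS DATA",
        f"##NPOINTS={sum(len(s) for s in run.scans)}",
    ]
    for rt, scan in zip(run.rt, run.scans):
        lines.append(f"##PAGE=T={float(rt)!r}")
        lines.append(f"##NPOINTS={len(scan)}")
        lines.append("##DATA TABLE=(XY..XY), PEAKS")
        for mz, inten in zip(scan.mz, scan.intensity):
            lines.append(f"{float(mz)!r},{float(inten)!r}")
    lines.append("##END=")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# scoring detection output against ground truth


def benchmark_detection(
    detected: Sequence, truth: Sequence[GroundTruthPeak], rt_tol: float
) -> tuple[float, float]:
    """Greedy one-to-one rt matching; returns (precision, recall).

    Candidate pairs are taken nearest-first within ``rt_tol``. With nothing
    detected, precision is reported as 0.0 (flagging convention) rather
    than undefined.
    """
    if rt_tol <= 0:
        raise ValueError("rt_tol must be positive")
    pairs = sorted(
        (
            (abs(d.rt - g.rt), i, j)
            for i, d in enumerate(detected)
            for j, g in enumerate(truth)
            if abs(d.rt - g.rt) <= rt_tol
        ),
    )
    used_d: set[int] = set()
    used_g: set[int] = set()
    matched = 0
    for _, i, j in pairs:
        if i in used_d or j in used_g:
            continue
        used_d.add(i)
        used_g.add(j)
        matched += 1
    precision = matched / len(detected) if detected else 0.0
    recall = matched / len(truth) if truth else 0.0
    return precision, recall


# ---------------------------------------------------------------------------
# the default fixture library


def random_spectrum(
    rng: np.random.Generator,
    n_ions_range: tuple[int, int] = (8, 14),
    mz_range: tuple[int, int] = (50, 300),
    strong_ions: int = 3,
) -> tuple[tuple[float, float], ...]:
    """Draw a pseudo-EI fragment spectrum.

    ``strong_ions`` fragments (including the base ion at 1.0) get relative
    intensities >= 0.3 so that peaks always carry a few quantifiable ions;
    the remainder fall anywhere in (0.05, 0.9).
    """
    n_ions = int(rng.integers(*n_ions_range))
    masses = rng.choice(
        np.arange(mz_range[0], mz_range[1]), size=n_ions, replace=False
    ).astype(float)
    rels = rng.uniform(0.05, 0.9, size=n_ions)
    rels[: max(strong_ions - 1, 0)] = rng.uniform(0.3, 0.9, size=max(strong_ions - 1, 0))
    rels[strong_ions - 1] = 1.0
    rng.shuffle(masses)
    return tuple(zip(masses.tolist(), rels.tolist()))


def _spread_components(
    rng: np.random.Generator,
    n: int,
    rt_start: float,
    rt_end: float,
    amplitude_range: tuple[float, float],
    sigma_range: tuple[float, float] = (2.0, 3.5),
) -> tuple[SyntheticComponent, ...]:
    margin = 30.0
    centers = np.linspace(rt_start + margin, rt_end - margin, n)
    centers = centers + rng.uniform(-5.0, 5.0, size=n)
    comps = []
    log_lo, log_hi = math.log10(amplitude_range[0]), math.log10(amplitude_range[1])
    for c in centers:
        comps.append(
            SyntheticComponent(
                rt_center=float(c),
                sigma=float(rng.uniform(*sigma_range)),
                spectrum=random_spectrum(rng),
                amplitude=float(10 ** rng.uniform(log_lo, log_hi)),
            )
        )
    return tuple(comps)


def mix_like_design(seed: int = 0) -> RunDesign:
    """15 well-separated components on a clean background (metabolite mix).

    Amplitudes are log-uniform over 1e4..5e5 counts — metabolite panels span
    orders of magnitude in abundance — with low detector noise and no
    baseline, mirroring a low-complexity standard mix.
    """
    rng = np.random.default_rng([seed % (2**31), 101])
    return RunDesign(
        components=_spread_components(rng, 15, 60.0, 660.0, (1e4, 5e5)),
        rt_start=60.0,
        rt_end=660.0,
        scan_period=0.375,
        noise=NoiseModel(hf_sd=20.0, detector_threshold=50.0),
        seed=seed,
    )


def overlap_design(seed: int = 0) -> RunDesign:
    """A co-eluting triplet: three distinct compounds under two TIC humps."""
    rng = np.random.default_rng([seed % (2**31), 202])
    comps = tuple(
        SyntheticComponent(
            rt_center=center,
            sigma=2.0,
            spectrum=random_spectrum(rng),
            amplitude=float(rng.uniform(4e4, 8e4)),
        )
        for center in (600.0, 605.0, 610.0)
    )
    return RunDesign(
        components=comps,
        rt_start=540.0,
        rt_end=670.0,
        scan_period=0.375,
        noise=NoiseModel(hf_sd=20.0, detector_threshold=50.0),
        seed=seed,
    )


def serum_like_design(seed: int = 0) -> RunDesign:
    """30 components over a hump baseline with strong noise (serum matrix)."""
    rng = np.random.default_rng([seed % (2**31), 303])
    return RunDesign(
        components=_spread_components(
            rng, 30, 60.0, 740.0, (4e4, 8e5), sigma_range=(1.5, 3.0)
        ),
        rt_start=60.0,
        rt_end=740.0,
        scan_period=0.375,
        noise=NoiseModel(
            hf_sd=150.0,
            baseline="hump",
            baseline_amplitude=2000.0,
            detector_threshold=100.0,
        ),
        seed=seed,
    )


def dilution_series_design(seed: int = 0) -> RunDesign:
    """Four replicates spiked with 2-fold decreasing amounts (10 components).

    Replicate k carries dilution ``2**-k``; rt drift s.d. is 0.8 s. Noise is
    kept light so that quantitation reflects the algorithms rather than the
    detector floor at the weakest dilution.
    """
    rng = np.random.default_rng([seed % (2**31), 404])
    return RunDesign(
        components=_spread_components(rng, 10, 60.0, 500.0, (8e4, 4e5)),
        rt_start=60.0,
        rt_end=500.0,
        scan_period=0.375,
        noise=NoiseModel(hf_sd=10.0, detector_threshold=20.0),
        drift_sd=0.8,
        dilutions=(1.0, 0.5, 0.25, 0.125),
        seed=seed,
    )


def jittered_peak_lists(
    n_components: int,
    n_replicates: int,
    jitter_sd: float,
    seed: int = 0,
    spacing: float = 30.0,
) -> tuple[list[list], list[list[int]]]:
    """Replicate peak lists for alignment-recovery studies.

    Each component keeps an identical spectrum across replicates; its
    retention time in each replicate is the true center plus N(0, jitter_sd)
    noise. Returns (peak_lists, labels): ``labels[rep][i]`` is the true
    component index of ``peak_lists[rep][i]`` after rt sorting.
    """
    from .peaks import Peak, make_uid  # local import avoids a cycle

    rng = np.random.default_rng([seed % (2**31), 505])
    centers = spacing * (1 + np.arange(n_components))
    spectra = [
        MassSpectrum(*zip(*sorted(random_spectrum(rng)))) for _ in range(n_components)
    ]
    amplitudes = rng.uniform(1e4, 1e5, size=n_components)
    lists: list[list] = []
    labels: list[list[int]] = []
    for rep in range(n_replicates):
        entries = []
        for c in range(n_components):
            rt = float(centers[c] + rng.normal(0.0, jitter_sd))
            spec = MassSpectrum(
                spectra[c].masses, spectra[c].intensities * amplitudes[c]
            )
            # nominal per-ion areas: proportional to apex intensities
            ion_areas = {m: i * 2.5 for m, i in spec.nonzero().items()}
            entries.append(
                (
                    rt,
                    c,
                    Peak(
                        uid=make_uid(spec, rt),
                        rt=rt,
                        spectrum=spec,
                        ion_areas=ion_areas,
                        area=sum(ion_areas.values()),
                    ),
                )
            )
        entries.sort(key=lambda e: e[0])
        lists.append([p for _, _, p in entries])
        labels.append([c for _, c, _ in entries])
    return lists, labels


DESIGNS = {
    "mix": mix_like_design,
    "overlap": overlap_design,
    "serum": serum_like_design,
    "dilution": dilution_series_design,
}


def write_truth_json(truth: Sequence[GroundTruthPeak], path: str | Path) -> None:
    """Persist ground truth next to serialized synthetic runs."""
    doc = [
        {
            "rt": g.rt,
            "masses": g.spectrum.masses.tolist(),
            "intensities": g.spectrum.intensities.tolist(),
            "ion_areas": {repr(m): a for m, a in sorted(g.ion_areas.items())},
        }
        for g in truth
    ]
    Path(path).write_text(json.dumps(doc, indent=1))
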