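"""Declarative processing pipelines: a validated stage list run in order.

A pipeline config (YAML or an in-memory dict) chains the library's stages —
``simulate``, ``detect``, ``align``, ``quantify`` — over a set of runs,
writing every intermediate artifact with a stable name and recording a
manifest of outputs with SHA-256 checksums. Under a fixed seed the whole
pipeline is deterministic, manifest checksums included.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import yaml

from . import align as align_mod
from . import binning, peaks, raw_io, simulate

log = logging.getLogger("gcmskit.pipeline")

__all__ = ["PipelineConfig", "PipelineError", "ValidationError", "run_pipeline", "load_config"]

KNOWN_STAGES = ("simulate", "detect", "align", "quantify")


class ValidationError(ValueError):
    """Config rejected before any stage ran."""


class PipelineError(RuntimeError):
    """A stage failed during execution; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage


@dataclass(frozen=True)
class PipelineConfig:
    """Ordered stages with parameter blocks, output directory and seed."""

    stages: tuple[dict, ...]
    out_dir: Path
    seed: int = 0
    inputs: tuple[Path, ...] = ()

    @staticmethod
    def from_dict(doc: Mapping[str, Any]) -> "PipelineConfig":
        stages = doc.get("stages")
        if not stages:
            raise ValidationError("config must list at least one stage")
        for stage in stages:
            name = stage.get("stage")
            if name not in KNOWN_STAGES:
                raise ValidationError(
                    f"unknown stage {name!r}; expected one of {KNOWN_STAGES}"
                )
        if "out_dir" not in doc:
            raise ValidationError("config must set out_dir")
        _validate_params(stages)
        return PipelineConfig(
            stages=tuple(dict(s) for s in stages),
            out_dir=Path(doc["out_dir"]),
            seed=int(doc.get("seed", 0)),
            inputs=tuple(Path(p) for p in doc.get("inputs", [])),
        )

    def to_dict(self) -> dict:
        """Canonical form; ``from_dict`` of this dict round-trips."""
        return {
            "stages": [dict(s) for s in self.stages],
            "out_dir": str(self.out_dir),
            "seed": self.seed,
            "inputs": [str(p) for p in self.inputs],
        }


def _validate_params(stages: Sequence[Mapping[str, Any]]) -> None:
    """Validate stage parameters against the owning module's invariants."""
    for stage in stages:
        name = stage["stage"]
        if name == "simulate":
            design = stage.get("design", "mix")
            if design not in simulate.DESIGNS and not Path(str(design)).suffix == ".json":
                raise ValidationError(
                    f"simulate: unknown design {design!r}; expected one of "
                    f"{tuple(simulate.DESIGNS)} or a design.json path"
                )
            if int(stage.get("replicates", 1)) < 1:
                raise ValidationError("simulate: replicates must be >= 1")
        elif name == "detect":
            preset = stage.get("preset")
            if preset is not None and preset not in peaks.PRESETS:
                raise ValidationError(f"detect: unknown preset {preset!r}")
            _detect_params(stage)  # raises ValueError on bad invariants
        elif name == "align":
            try:
                align_mod.AlignmentParams(
                    D=float(stage.get("D", align_mod.DEFAULT_D)),
                    gap=float(stage.get("gap", align_mod.DEFAULT_GAP)),
                    min_peaks=int(stage.get("min_peaks", 1)),
                )
            except ValueError as exc:
                raise ValidationError(f"align: {exc}") from exc
        elif name == "quantify":
            if int(stage.get("n", align_mod.DEFAULT_COMMON_ION_N)) < 1:
                raise ValidationError("quantify: n must be >= 1")


def _detect_params(stage: Mapping[str, Any]) -> peaks.DetectionParams:
    base = peaks.PRESETS.get(stage.get("preset", ""), peaks.DetectionParams())
    try:
        return peaks.DetectionParams(
            window=int(stage.get("window", base.window)),
            scans=int(stage.get("scans", base.scans)),
            ions=int(stage.get("ions", base.ions)),
            threshold=float(stage.get("threshold", base.threshold)),
            r=float(stage.get("r", base.r)),
        )
    except ValueError as exc:
        raise ValidationError(f"detect: {exc}") from exc


def load_config(path: str | Path) -> PipelineConfig:
    """Parse a YAML pipeline config file."""
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, Mapping):
        raise ValidationError(f"{path}: config must be a mapping")
    return PipelineConfig.from_dict(doc)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the stages in order and return the artifact manifest.

    The manifest maps every written artifact to its SHA-256 checksum and is
    also written to ``<out_dir>/manifest.json``. Stage failures raise
    :class:`PipelineError` naming the stage.
    """
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []
    runs: list = [raw_io.read_andi(p) if p.suffix in (".cdf", ".nc") else raw_io.read_jcamp(p) for p in config.inputs]
    peak_lists: list[list[peaks.Peak]] = []
    table = None
    for stage in config.stages:
        name = stage["stage"]
        log.info("stage %s: %s", name, {k: v for k, v in stage.items() if k != "stage"})
        try:
            if name == "simulate":
                design = simulate.DESIGNS[stage.get("design", "mix")](config.seed)
                n_rep = int(stage.get("replicates", len(design.dilutions)))
                runs = []
                for rep in range(n_rep):
                    run, truth = simulate.simulate_run(design, rep)
                    cdf = out / f"run_{rep:02d}.cdf"
                    simulate.write_andi(run, cdf)
                    simulate.write_truth_json(truth, out / f"run_{rep:02d}_truth.json")
                    artifacts += [cdf, out / f"run_{rep:02d}_truth.json"]
                    runs.append(run)
            elif name == "detect":
                if not runs:
                    raise PipelineError(name, "no runs to detect on (simulate first or list inputs)")
                params = _detect_params(stage)
                floor = float(stage.get("noise_floor", 0.0))
                peak_lists = []
                for rep, run in enumerate(runs):
                    im = binning.build_intensity_matrix_i(run)
                    plist = peaks.detect_peaks(im, params, noise_floor=floor)
                    path = out / f"peaks_{rep:02d}.json"
                    peaks.write_peaks_json(plist, path)
                    artifacts.append(path)
                    peak_lists.append(plist)
            elif name == "align":
                if len(peak_lists) < 2:
                    raise PipelineError(name, "need at least two detected peak lists")
                params = align_mod.AlignmentParams(
                    D=float(stage.get("D", align_mod.DEFAULT_D)),
                    gap=float(stage.get("gap", align_mod.DEFAULT_GAP)),
                    min_peaks=int(stage.get("min_peaks", 1)),
                )
                table = align_mod.align_all(peak_lists, params)
            elif name == "quantify":
                if table is None:
                    raise PipelineError(name, "no alignment table (run align first)")
                result = align_mod.common_ion_quantify(
                    table, int(stage.get("n", align_mod.DEFAULT_COMMON_ION_N))
                )
                a_path, m_path = align_mod.write_alignment_csv(
                    table, result, out / "alignment"
                )
                artifacts += [a_path, m_path]
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(name, str(exc)) from exc
    manifest = {
        "seed": config.seed,
        "artifacts": {str(p.relative_to(out)): _sha256(p) for p in artifacts},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
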