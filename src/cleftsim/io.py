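"""Configuration, persistence and the umbrella pipeline.

Configs are flat YAML mappings mirroring the dataclass field names exactly;
unknown keys are rejected so typos never silently fall back to defaults.
States persist as NPZ archives (dense cells/ecm arrays with dx, dt and step
as attributes). A pipeline run writes a JSON manifest recording the seed,
package version and SHA-256 hashes of every input and output, and skips a
stage on rerun when its inputs are unchanged.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .metrics import summarize_invasion
from .model import SimulationState, run
from .params import ModelParams
from .quant import (
    correction_factor,
    max_migration_distance,
    sampling_correction,
    shell_counts,
    write_nucleus_table,
)
from .params import high_density_params
from .scanfit import fit_interface_conditions
from .synth import PatternSpec, generate_pattern

logger = logging.getLogger("cleftsim")

__all__ = [
    "load_config",
    "save_config",
    "save_state",
    "load_state",
    "RunManifest",
    "run_pipeline",
]


def _coerce(value, pytype):
    if pytype is int:
        if isinstance(value, bool) or int(value) != value:
            raise ValueError(f"expected an integer, got {value!r}")
        return int(value)
    if pytype is float:
        return float(value)
    if pytype is bool:
        if not isinstance(value, bool):
            raise ValueError(f"expected a boolean, got {value!r}")
        return value
    return value


def load_config(path, kind: str = "model"):
    """Load and validate a flat YAML config.

    ``kind`` selects the schema: "model" -> ModelParams, "pattern" ->
    PatternSpec. Missing keys take the documented defaults (logged); unknown
    keys raise with a field-level message.
    """
    cls = {"model": ModelParams, "pattern": PatternSpec}[kind]
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a flat mapping")
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = sorted(set(raw) - set(fields))
    if unknown:
        raise ValueError(f"{path}: unknown config keys {unknown}")
    kwargs = {}
    for name, value in raw.items():
        ftype = fields[name].type
        pytype = {"int": int, "float": float, "bool": bool}.get(str(ftype), None)
        try:
            kwargs[name] = _coerce(value, pytype)
        except (TypeError, ValueError) as err:
            raise ValueError(f"{path}: field {name!r}: {err}") from err
    for name in set(fields) - set(raw):
        logger.info("config %s: %s defaulted to %r", path, name,
                    fields[name].default)
    try:
        return cls(**kwargs)
    except ValueError as err:
        raise ValueError(f"{path}: {err}") from err


def save_config(obj, path) -> None:
    Path(path).write_text(yaml.safe_dump(obj.to_dict(), sort_keys=False))


def save_state(state: SimulationState, params: ModelParams, path) -> None:
    """Persist cells/ecm arrays with dx, dt and step as NPZ attributes."""
    np.savez_compressed(
        path,
        cells=state.cells,
        ecm=state.ecm,
        step=np.asarray(state.step),
        dx=np.asarray(params.dx),
        dt=np.asarray(params.dt),
    )


def load_state(path) -> tuple[SimulationState, dict]:
    with np.load(path) as npz:
        state = SimulationState(
            cells=npz["cells"], ecm=npz["ecm"], step=int(npz["step"])
        )
        attrs = {"dx": float(npz["dx"]), "dt": float(npz["dt"])}
    return state, attrs


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


@dataclasses.dataclass
class RunManifest:
    """Traceability record of a pipeline run."""

    config_hash: str
    seed: int
    version: str
    stages: dict = dataclasses.field(default_factory=dict)
    created: str = ""

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_file(cls, path):
        data = json.loads(Path(path).read_text())
        return cls(**data)


def _stage_seed(seed: int, index: int) -> int:
    """Derive a per-stage seed below 2**31 from the global seed."""
    return int(np.random.SeedSequence([seed, index]).generate_state(1)[0] % (2**31))


def run_pipeline(
    out_dir,
    seed: int = 0,
    model_config=None,
    pattern_config=None,
    stages=("simulate", "summarize", "scan", "fit", "synth", "quantify"),
    force: bool = False,
) -> RunManifest:
    """Execute the pipeline stages in dependency order.

    simulate -> summarize reduce the high-density condition run; scan -> fit
    produce the two-condition degradation-rate fit; synth -> quantify
    generate and quantify the synthetic invasion pattern. Stages whose
    inputs are unchanged since the recorded manifest are skipped unless
    ``force``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = (
        load_config(model_config, "model") if model_config else high_density_params()
    )
    spec = (
        load_config(pattern_config, "pattern")
        if pattern_config
        else PatternSpec(seed=_stage_seed(seed, 4))
    )
    config_blob = json.dumps(
        {"model": params.to_dict(), "pattern": spec.to_dict()}, sort_keys=True
    )
    config_hash = hashlib.sha256(config_blob.encode()).hexdigest()

    manifest_path = out / "manifest.json"
    previous = None
    if manifest_path.exists() and not force:
        try:
            previous = RunManifest.from_file(manifest_path)
        except (json.JSONDecodeError, TypeError):
            previous = None
        if previous is not None and previous.config_hash != config_hash:
            previous = None
    manifest = RunManifest(
        config_hash=config_hash,
        seed=seed,
        version=__version__,
        created=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )

    def unchanged(name: str, inputs: dict) -> bool:
        if previous is None or name not in previous.stages:
            return False
        prev = previous.stages[name]
        if prev.get("inputs") != inputs:
            return False
        for f, digest in prev.get("outputs", {}).items():
            p = out / f
            if not p.exists():
                return False
            if _sha256(p) != digest:
                raise RuntimeError(
                    f"stage {name}: output {f} does not match its recorded "
                    "hash (corrupted intermediate)"
                )
        return True

    def record(name: str, inputs: dict, outputs: list[str]) -> None:
        manifest.stages[name] = {
            "inputs": inputs,
            "outputs": {f: _sha256(out / f) for f in outputs},
        }
        manifest_path.write_text(manifest.to_json())

    def wrap(name, fn, inputs, outputs):
        if name not in stages:
            if previous is not None and name in previous.stages:
                manifest.stages[name] = previous.stages[name]
            return
        if unchanged(name, inputs):
            logger.info("stage %s: inputs unchanged, skipping", name)
            manifest.stages[name] = previous.stages[name]
            manifest_path.write_text(manifest.to_json())
            return
        logger.info("stage %s: running", name)
        try:
            fn()
        except Exception as err:
            raise RuntimeError(f"stage {name} failed: {err}") from err
        record(name, inputs, outputs)

    # simulate / summarize: the configured (default: high-density) condition
    def _simulate():
        result = run(params, log=lambda s, c, m: logger.info(
            "step %d: cell mass %.2f, ecm mass %.2f", s, c, m))
        save_state(result.final, params, out / "state.npz")

    wrap("simulate", _simulate, {"config": config_hash}, ["state.npz"])

    def _summarize():
        state, _ = load_state(out / "state.npz")
        s = summarize_invasion(state, params)
        s.radial_profile.to_csv(out / "radial_profile.csv", index=False)
        (out / "summary.json").write_text(json.dumps(
            {
                "interface_mass": s.interface_mass,
                "bulk_mass": s.bulk_mass,
                "interface_fraction": s.interface_fraction,
            },
            indent=2,
        ))

    wrap(
        "summarize",
        _summarize,
        {"state": _sha256(out / "state.npz") if (out / "state.npz").exists() else ""},
        ["summary.json", "radial_profile.csv"],
    )

    # scan / fit: both assay conditions over the delta grid
    fit_holder = {}

    def _scan_fit():
        fit = fit_interface_conditions()
        fit_holder["fit"] = fit
        pd.concat([fit.scan_high, fit.scan_low], ignore_index=True).to_csv(
            out / "scan.csv", index=False
        )
        (out / "fit.json").write_text(json.dumps(
            {
                "delta_high": fit.high.delta,
                "delta_low": fit.low.delta,
                "ratio": fit.ratio,
                "objective_high": fit.high.objective,
                "objective_low": fit.low.objective,
            },
            indent=2,
        ))

    if "scan" in stages or "fit" in stages:
        wrap("scan", _scan_fit, {"config": config_hash}, ["scan.csv", "fit.json"])
        manifest.stages.setdefault("fit", manifest.stages.get("scan", {}))
        manifest_path.write_text(manifest.to_json())

    # synth / quantify: synthetic pattern and its quantification
    def _synth():
        table, truth = generate_pattern(spec)
        write_nucleus_table(table, out / "points.csv")
        (out / "truth.json").write_text(json.dumps(truth.to_jsonable(), indent=2))

    wrap("synth", _synth, {"spec": config_hash, "seed": seed},
         ["points.csv", "truth.json"])

    def _quantify():
        from .quant import read_nucleus_table

        table = read_nucleus_table(out / "points.csv")
        rim = spec.spheroid_radius
        iface = shell_counts(table, rim, spec.interface_bin, ("interface",))
        bulk = shell_counts(table, rim, spec.bulk_bin, ("bulk_top", "bulk_bottom"))
        factor = correction_factor(0.5, spec.depth_imaged, spec.depth_total)
        raw_bulk = bulk["bulk_top"].total + bulk["bulk_bottom"].total
        report = {
            "interface_count": iface["interface"].total,
            "bulk_raw_count": raw_bulk,
            "bulk_corrected_count": sampling_correction(
                raw_bulk, 0.5, spec.depth_imaged, spec.depth_total
            ),
            "correction_factor": factor,
            "max_distance_interface_um": max_migration_distance(
                table, rim, ("interface",)
            ),
            "max_distance_bulk_top_um": max_migration_distance(
                table, rim, ("bulk_top",)
            ),
            "max_distance_bulk_bottom_um": max_migration_distance(
                table, rim, ("bulk_bottom",)
            ),
        }
        (out / "quant_report.json").write_text(json.dumps(report, indent=2))

    wrap(
        "quantify",
        _quantify,
        {"points": _sha256(out / "points.csv") if (out / "points.csv").exists() else ""},
        ["quant_report.json"],
    )

    manifest_path.write_text(manifest.to_json())
    return manifest
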