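"""Configuration and time-series I/O plus run provenance.

Model configurations are YAML (or JSON) documents with 1-based region
and input indices, converted to the package's 0-based internals here and
nowhere else.  Unknown keys are rejected so typos never pass silently.
BOLD series travel as wide CSV (``time`` column plus one column per
region) written at full float precision so write -> read round-trips
bit-exactly.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .inversion import InversionConfig
from .model import (ModelSpec, PhysioParams, RegionGraphSpec, StimulusSet,
                    validate_model)

__all__ = [
    "ConfigError",
    "load_config",
    "load_model_config",
    "save_model_config",
    "load_inversion_config",
    "read_bold_csv",
    "write_bold_csv",
    "write_manifest",
]


class ConfigError(ValueError):
    pass


_MODEL_KEYS = {"regions", "edges", "modulatory_edges", "driving", "self_mod",
               "mu_mod", "lambda_mod", "params", "stimuli"}
_EDGE_KEYS = {"from", "to", "a0"}
_MOD_KEYS = {"from", "to", "input", "b", "modulation_only"}
_DRIVE_KEYS = {"region", "input", "c"}
_SELF_KEYS = {"region", "input", "b"}
_STIM_KEYS = {"dt", "duration", "n_driving", "n_modulatory", "n_mu", "n_lambda"}
_INV_KEYS = {"max_iterations", "tolerance", "learning_rate", "free_parameters",
             "gradient_method", "max_backtracks", "seed"}
_PARAM_FIELDS = set(PhysioParams.__dataclass_fields__)


def _reject_unknown(d: dict, allowed: set, where: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in {where}; "
                          f"allowed: {sorted(allowed)}")


def _load_doc(path) -> dict:
    path = Path(path)
    try:
        with open(path) as fh:
            doc = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(doc, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    return doc


def _params_from(doc: dict, n: int) -> tuple[PhysioParams, ...]:
    spec = doc.get("params", {}) or {}
    _reject_unknown(spec, {"defaults", "per_region"}, "params")
    defaults = spec.get("defaults", {}) or {}
    _reject_unknown(defaults, _PARAM_FIELDS, "params.defaults")
    base = PhysioParams(**{k: float(v) for k, v in defaults.items()})
    out = [base] * n
    for key, over in (spec.get("per_region", {}) or {}).items():
        r = int(key) - 1
        if not 0 <= r < n:
            raise ConfigError(f"params.per_region: region {key} out of range")
        _reject_unknown(over, _PARAM_FIELDS, f"params.per_region.{key}")
        out[r] = base.with_overrides(**{k: float(v) for k, v in over.items()})
    return tuple(out)


def load_model_config(path, stimuli: StimulusSet | None = None) -> ModelSpec:
    """Load and validate a model document (1-based indices in the file)."""
    doc = _load_doc(path)
    _reject_unknown(doc, _MODEL_KEYS, str(path))
    if "regions" not in doc:
        raise ConfigError(f"{path}: missing required key 'regions'")
    n = int(doc["regions"])

    edges = {}
    for e in doc.get("edges", []) or []:
        _reject_unknown(e, _EDGE_KEYS, "edges entry")
        edges[(int(e["from"]) - 1, int(e["to"]) - 1)] = float(e.get("a0", 0.0))
    mod = {}
    mod_only = set()
    for e in doc.get("modulatory_edges", []) or []:
        _reject_unknown(e, _MOD_KEYS, "modulatory_edges entry")
        key = (int(e["from"]) - 1, int(e["to"]) - 1, int(e["input"]) - 1)
        mod[key] = float(e["b"])
        if e.get("modulation_only", False):
            mod_only.add(key[:2])
    driving = {}
    for d in doc.get("driving", []) or []:
        _reject_unknown(d, _DRIVE_KEYS, "driving entry")
        driving[(int(d["region"]) - 1, int(d["input"]) - 1)] = float(d["c"])
    self_mod = {}
    for d in doc.get("self_mod", []) or []:
        _reject_unknown(d, _SELF_KEYS, "self_mod entry")
        self_mod[(int(d["region"]) - 1, int(d["input"]) - 1)] = float(d["b"])
    mu_mod = {}
    for d in doc.get("mu_mod", []) or []:
        _reject_unknown(d, _SELF_KEYS, "mu_mod entry")
        mu_mod[(int(d["region"]) - 1, int(d["input"]) - 1)] = float(d["b"])
    lam_mod = {}
    for d in doc.get("lambda_mod", []) or []:
        _reject_unknown(d, _SELF_KEYS, "lambda_mod entry")
        lam_mod[(int(d["region"]) - 1, int(d["input"]) - 1)] = float(d["b"])

    if stimuli is None:
        sdoc = doc.get("stimuli")
        if sdoc is None:
            raise ConfigError(f"{path}: no 'stimuli' section and no StimulusSet given")
        _reject_unknown(sdoc, _STIM_KEYS, "stimuli")
        stimuli = StimulusSet.zeros(
            dt=float(sdoc["dt"]), duration=float(sdoc["duration"]),
            n_driving=int(sdoc.get("n_driving", 1)),
            n_modulatory=int(sdoc.get("n_modulatory", 0)),
            n_mu=int(sdoc.get("n_mu", 0)),
            n_lambda=int(sdoc.get("n_lambda", 0)))

    graph = RegionGraphSpec(
        n_regions=n, edges=edges, modulatory_edges=mod, driving_map=driving,
        self_mod=self_mod, inhibitory_mu_mod=mu_mod, inhibitory_lambda_mod=lam_mod,
        modulation_only=frozenset(mod_only))
    return validate_model(graph, _params_from(doc, n), stimuli)


def save_model_config(model: ModelSpec, path) -> None:
    """Write a model back to YAML (1-based indices; round-trips exactly)."""
    g = model.graph
    doc: dict = {"regions": g.n_regions}
    doc["edges"] = [{"from": s + 1, "to": t + 1, "a0": a}
                    for (s, t), a in g.edges.items()]
    doc["modulatory_edges"] = [
        {"from": s + 1, "to": t + 1, "input": m + 1, "b": b,
         "modulation_only": (s, t) in g.modulation_only}
        for (s, t, m), b in g.modulatory_edges.items()]
    doc["driving"] = [{"region": r + 1, "input": j + 1, "c": c}
                      for (r, j), c in g.driving_map.items()]
    if g.self_mod:
        doc["self_mod"] = [{"region": r + 1, "input": j + 1, "b": b}
                           for (r, j), b in g.self_mod.items()]
    base = model.params[0]
    doc["params"] = {"defaults": asdict(base)}
    per = {str(i + 1): {k: v for k, v in asdict(p).items()
                        if v != getattr(base, k)}
           for i, p in enumerate(model.params) if p != base}
    if per:
        doc["params"]["per_region"] = per
    stim = model.stimuli
    doc["stimuli"] = {"dt": stim.dt, "duration": stim.duration,
                      "n_driving": int(stim.driving.shape[0]),
                      "n_modulatory": int(stim.modulatory.shape[0]),
                      "n_mu": int(stim.mu_context.shape[0]),
                      "n_lambda": int(stim.lambda_context.shape[0])}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_inversion_config(path) -> InversionConfig:
    doc = _load_doc(path)
    _reject_unknown(doc, _INV_KEYS, str(path))
    if "free_parameters" in doc:
        doc["free_parameters"] = tuple(doc["free_parameters"])
    cfg = InversionConfig(**doc)
    cfg.check()
    return cfg


def load_config(path):
    """Dispatch on document shape: model configs carry 'regions'."""
    doc = _load_doc(path)
    if "regions" in doc:
        return load_model_config(path)
    return load_inversion_config(path)


def read_bold_csv(path) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Read a wide BOLD CSV; returns (time, y (samples x regions), columns).

    The time column must form a uniform grid (validated) with no missing
    values.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if df.columns[0] != "time":
        raise ConfigError(f"{path}: first column must be 'time'")
    if df.isna().any().any():
        raise ConfigError(f"{path}: missing values")
    t = df["time"].to_numpy(dtype=float)
    if len(t) > 1:
        steps = np.diff(t)
        if not np.allclose(steps, steps[0], rtol=1e-9, atol=1e-12):
            raise ConfigError(f"{path}: time column is not a uniform grid")
    cols = [c for c in df.columns if c != "time"]
    return t, df[cols].to_numpy(dtype=float), cols


def write_bold_csv(time: np.ndarray, y: np.ndarray, path,
                   columns: list[str] | None = None) -> None:
    """Write a wide BOLD CSV at full float precision (lossless round-trip)."""
    y = np.atleast_2d(np.asarray(y).T).T
    columns = columns or [f"R{i + 1}" for i in range(y.shape[1])]
    df = pd.DataFrame({"time": np.asarray(time)})
    for j, c in enumerate(columns):
        df[c] = y[:, j]
    df.to_csv(path, index=False, float_format="%.17g")


def write_manifest(out_dir, command: str, seed: int | None = None,
                   config: dict | None = None, extra: dict | None = None) -> Path:
    """Append-only JSON run manifest with a config hash for provenance."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    from . import __version__

    cfg_json = json.dumps(config or {}, sort_keys=True, default=str)
    manifest = {
        "command": command,
        "seed": seed,
        "config": config or {},
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "package_version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    manifest.update(extra or {})
    path = out_dir / "manifest.json"
    entries = []
    if path.exists():
        entries = json.loads(path.read_text())
    entries.append(manifest)
    path.write_text(json.dumps(entries, indent=2, default=str))
    return path
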