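"""Configuration loading and trace/report persistence.

Configs are YAML or JSON (JSON parses as YAML).  Trace files are plain CSV
with a leading ``time_ms`` column and canonical neuron columns, accompanied
by a ``<path>.meta.json`` side-car holding the full provenance (model,
stimulus label, dt, seed, parameters) so any artifact can be regenerated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .dynamics import SimulationResult
from .params import ModelParams, NoiseParams, Weights, params_from_dict, params_to_dict
from .stimuli import CONDITIONS

__all__ = [
    "RunConfig",
    "ConfigError",
    "SchemaError",
    "load_config",
    "config_to_dict",
    "write_config",
    "write_traces",
    "read_traces",
]


class ConfigError(ValueError):
    """A configuration file failed validation; message names the field."""


class SchemaError(ValueError):
    """A trace or report file does not match the expected schema."""


@dataclass
class RunConfig:
    """A validated simulation run description."""

    model: str = "opponency"
    condition: str = "dichoptic_gratings"
    contrast: float = 0.5
    duration_s: float = 160.0
    dt_ms: float = 2.0
    seed: int = 0
    params: ModelParams = field(default_factory=ModelParams)
    out: str | None = None
    workers: int = 1
    log_level: str = "INFO"


_TOP_KEYS = {
    "model",
    "condition",
    "contrast",
    "duration_s",
    "dt_ms",
    "seed",
    "out",
    "workers",
    "log_level",
    "params",
}
_PARAM_KEYS = {
    "sigma",
    "sigma_opp",
    "tau_ms",
    "tau_adapt_s",
    "adapt_scale",
    "adapt_enabled",
    "noise_on_opponency",
    "noise_on_summation",
    "sigma_exponent",
    "noise",
    "weights",
}


def _check_keys(given: dict, allowed: set[str], where: str) -> None:
    unknown = set(given) - allowed
    if unknown:
        raise ConfigError(
            f"unknown key(s) {sorted(unknown)} in {where}; "
            f"allowed: {sorted(allowed)}"
        )


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML/JSON run config.

    Unset fields take the model defaults (sigma 0.5, sigma_opp 0.9, noise
    amplitude 0.05, smoothness 800 ms, tau 50 ms); unknown keys are
    rejected with a field-level message.
    """
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    _check_keys(raw, _TOP_KEYS, "config")

    params_raw = dict(raw.get("params") or {})
    _check_keys(params_raw, _PARAM_KEYS, "config.params")
    noise_raw = dict(params_raw.pop("noise", {}) or {})
    _check_keys(noise_raw, {"amplitude", "smoothness_ms", "seed"}, "config.params.noise")
    weights_raw = dict(params_raw.pop("weights", {}) or {})
    _check_keys(
        weights_raw,
        {f.name for f in Weights.__dataclass_fields__.values()},
        "config.params.weights",
    )
    try:
        params = ModelParams(
            noise=NoiseParams(**noise_raw),
            weights=Weights(**weights_raw),
            **params_raw,
        )
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"invalid params in {path}: {exc}") from exc

    cfg = RunConfig(params=params, **{k: v for k, v in raw.items() if k != "params"})
    if cfg.model not in ("conventional", "opponency"):
        raise ConfigError(f"model must be 'conventional' or 'opponency', got {cfg.model!r}")
    if cfg.condition not in CONDITIONS:
        raise ConfigError(f"condition must be one of {CONDITIONS}, got {cfg.condition!r}")
    if not 0.0 <= cfg.contrast <= 1.0:
        raise ConfigError(f"contrast must be in [0, 1], got {cfg.contrast}")
    if cfg.duration_s <= 0:
        raise ConfigError(f"duration_s must be > 0, got {cfg.duration_s}")
    if cfg.dt_ms <= 0:
        raise ConfigError(f"dt_ms must be > 0, got {cfg.dt_ms}")
    return cfg


def config_to_dict(cfg: RunConfig) -> dict[str, Any]:
    d: dict[str, Any] = {
        "model": cfg.model,
        "condition": cfg.condition,
        "contrast": cfg.contrast,
        "duration_s": cfg.duration_s,
        "dt_ms": cfg.dt_ms,
        "seed": cfg.seed,
        "out": cfg.out,
        "workers": cfg.workers,
        "log_level": cfg.log_level,
        "params": params_to_dict(cfg.params),
    }
    return d


def write_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(cfg), sort_keys=False))


def write_traces(result: SimulationResult, path: str | Path) -> None:
    """Write a trace CSV plus its ``.meta.json`` provenance side-car."""
    path = Path(path)
    frame = result.to_frame()
    frame.to_csv(path, index=False, float_format="%.17g")
    meta = {
        "model": result.model,
        "stimulus_label": result.stimulus_label,
        "dt_ms": result.dt_ms,
        "seed": result.seed,
        "params": params_to_dict(result.params),
    }
    Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=2))


def read_traces(path: str | Path) -> SimulationResult:
    """Read a trace CSV (and side-car, if present) back to a SimulationResult."""
    path = Path(path)
    frame = pd.read_csv(path)
    if "time_ms" not in frame.columns:
        raise SchemaError(f"{path} is missing the required 'time_ms' column")
    meta_path = Path(str(path) + ".meta.json")
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        params = params_from_dict(meta["params"])
        model = meta["model"]
        label = meta["stimulus_label"]
        dt_ms = float(meta["dt_ms"])
        seed = int(meta["seed"])
    else:
        params = ModelParams()
        model = "opponency" if "opp_RL_A" in frame.columns else "conventional"
        label = "unknown"
        t = frame["time_ms"].to_numpy()
        dt_ms = float(t[1] - t[0]) if len(t) > 1 else float(t[0])
        seed = 0
    traces = {
        c: frame[c].to_numpy(dtype=float) for c in frame.columns if c != "time_ms"
    }
    return SimulationResult(
        t_ms=frame["time_ms"].to_numpy(dtype=float),
        traces=traces,
        params=params,
        model=model,
        stimulus_label=label,
        dt_ms=dt_ms,
        seed=seed,
    )


def write_json(obj: dict, path: str | Path) -> None:
    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(f"not JSON-serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=_default))
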