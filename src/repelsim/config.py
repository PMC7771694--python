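"""YAML scenario configuration: loading, validation, manifests.

A config file mirrors :class:`~repelsim.engine.ScenarioConfig` field names.
Every omitted field falls back to the model's documented defaults (0.03 s
steps, unit response rates, ``alpha = beta = 0.5``, ``D = mu = 1``,
concentration cap 5); sources required by the scenario but not configured are
created at the cage release corner with those defaults.  Unknown keys are an
error naming the key.

A run manifest echoes the fully resolved configuration plus the package
version, base seed and a timestamp, and is sufficient to re-run the experiment
bit-identically.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import __version__
from .engine import CageGeometry, ScenarioConfig
from .field import SourceSpec
from .flight import FlightParams, Phenotype

__all__ = ["ConfigError", "load_config", "config_to_dict", "config_from_dict", "write_manifest", "load_manifest"]


class ConfigError(ValueError):
    """A scenario configuration file is invalid."""


_SOURCE_KEYS = {"location", "release_rate", "diffusivity", "release_scale", "cap", "threshold"}
_CAGE_KEYS = {"lx", "ly", "lz", "release_corner"}
_PHEN_KEYS = {"susceptibility", "tolerance_factor", "mode"}
_FLIGHT_KEYS = {f.name for f in dataclasses.fields(FlightParams)}
_TOP_KEYS = {
    "scenario",
    "cage",
    "attractant",
    "repellent",
    "phenotype",
    "flight",
    "n_mosquitoes",
    "max_duration",
    "n_replicates",
    "base_seed",
    "landing_radius",
    "repelled_radius",
}


def _check_keys(doc: dict, allowed: set, where: str) -> None:
    unknown = set(doc) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) in {where}: {', '.join(sorted(unknown))}")


def _numeric(value, key: str):
    """Coerce YAML scalars to float ('1.5e6' parses as a string under YAML 1.1)."""
    if value is None or isinstance(value, (int, float)):
        return value
    if isinstance(value, str):
        try:
            return float(value)
        except ValueError:
            pass
    if isinstance(value, (list, tuple)):
        return [_numeric(v, key) for v in value]
    raise ConfigError(f"{key}: expected a number, got {value!r}")


def _build_source(doc: Optional[dict], kind: str, cage: CageGeometry) -> Optional[SourceSpec]:
    if doc is None:
        return None
    _check_keys(doc, _SOURCE_KEYS, kind)
    kw = {k: _numeric(v, f"{kind}.{k}") for k, v in doc.items()}
    kw.setdefault("location", cage.release_corner)
    try:
        return SourceSpec(kind=kind, **kw)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{kind}: {exc}") from exc


def config_from_dict(doc: dict) -> ScenarioConfig:
    """Build a fully resolved ScenarioConfig from a plain dict."""
    if not isinstance(doc, dict):
        raise ConfigError("config document must be a mapping")
    _check_keys(doc, _TOP_KEYS, "config")
    if "scenario" not in doc:
        raise ConfigError("config must name a scenario")
    scenario = doc["scenario"]

    cage_doc = doc.get("cage") or {}
    _check_keys(cage_doc, _CAGE_KEYS, "cage")
    cage_doc = {k: _numeric(v, f"cage.{k}") for k, v in cage_doc.items()}
    try:
        cage = CageGeometry(**cage_doc)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"cage: {exc}") from exc

    attract = _build_source(doc.get("attractant"), "attractant", cage)
    repel = _build_source(doc.get("repellent"), "repellent", cage)
    # scenarios that need a source get a default one at the release corner
    if scenario in ("attractant_only", "both") and attract is None:
        attract = SourceSpec(location=cage.release_corner, kind="attractant")
    if scenario in ("repellent_only", "both") and repel is None:
        repel = SourceSpec(location=cage.release_corner, kind="repellent")

    phen_doc = doc.get("phenotype") or {}
    _check_keys(phen_doc, _PHEN_KEYS, "phenotype")
    if "tolerance_factor" in phen_doc:
        phen_doc = {**phen_doc, "tolerance_factor": _numeric(phen_doc["tolerance_factor"], "phenotype.tolerance_factor")}
    try:
        phen = Phenotype(**phen_doc)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"phenotype: {exc}") from exc

    flight_doc = doc.get("flight") or {}
    _check_keys(flight_doc, _FLIGHT_KEYS, "flight")
    flight_doc = {k: _numeric(v, f"flight.{k}") for k, v in flight_doc.items()}
    try:
        flight = FlightParams(**flight_doc)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"flight: {exc}") from exc

    simple = {
        k: _numeric(doc[k], k)
        for k in ("n_mosquitoes", "max_duration", "n_replicates", "base_seed", "landing_radius", "repelled_radius")
        if k in doc
    }
    try:
        return ScenarioConfig(
            scenario=scenario, cage=cage, attractant=attract, repellent=repel, phenotype=phen, flight=flight, **simple
        )
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc


def load_config(path) -> ScenarioConfig:
    """Load and validate a YAML scenario configuration file."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        doc = yaml.safe_load(path.read_text(encoding="utf-8"))
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: not valid YAML: {exc}") from exc
    return config_from_dict(doc or {})


def _as_plain(value):
    if isinstance(value, np.ndarray):
        return [float(v) for v in value]
    if isinstance(value, (np.floating, np.integer)):
        return value.item()
    return value


def config_to_dict(cfg: ScenarioConfig) -> dict:
    """Fully resolved config as a plain dict (round-trips through config_from_dict)."""
    doc: dict = {"scenario": cfg.scenario}
    doc["cage"] = {k: _as_plain(getattr(cfg.cage, k)) for k in ("lx", "ly", "lz", "release_corner")}
    for name, src in (("attractant", cfg.attractant), ("repellent", cfg.repellent)):
        if src is not None:
            doc[name] = {k: _as_plain(getattr(src, k)) for k in sorted(_SOURCE_KEYS)}
    doc["phenotype"] = {k: _as_plain(getattr(cfg.phenotype, k)) for k in sorted(_PHEN_KEYS)}
    doc["flight"] = {k: _as_plain(getattr(cfg.flight, k)) for k in sorted(_FLIGHT_KEYS)}
    for k in ("n_mosquitoes", "max_duration", "n_replicates", "base_seed", "landing_radius", "repelled_radius"):
        doc[k] = _as_plain(getattr(cfg, k))
    return doc


def write_manifest(cfg: ScenarioConfig, path, base_seed: Optional[int] = None) -> Path:
    """Write a run manifest (resolved config + version + seed + timestamp)."""
    path = Path(path)
    doc = {
        "artifact_version": __version__,
        "base_seed": int(cfg.base_seed if base_seed is None else base_seed),
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "config": config_to_dict(cfg),
    }
    path.write_text(json.dumps(doc, indent=2) + "\n", encoding="utf-8")
    return path


def load_manifest(path) -> ScenarioConfig:
    """Rebuild the exact ScenarioConfig recorded in a manifest."""
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    return config_from_dict(doc["config"])
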