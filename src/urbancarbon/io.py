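"""Configuration loading, CSV round-tripping and run manifests.

A run configuration is a YAML document with optional ``inventory``,
``mortality``, ``lca``, ``scenario`` and ``tables`` sections mirroring the
corresponding dataclasses.  Every simulation output can be accompanied by a
JSON manifest (config snapshot, seed, package version, SHA-256 digests of
the input files, timestamp) sufficient to re-run it bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

import yaml

from . import __version__
from .allometry import AllometryTable, load_default_allometry
from .growth import SpeciesRegistry, load_default_registry
from .inventory import InventoryConfig
from .lca import LCAConfig
from .mortality import MortalityModel, PlantingScenario

__all__ = ["load_run_config", "RunConfig", "write_manifest", "file_digest"]


@dataclasses.dataclass
class RunConfig:
    inventory: InventoryConfig
    mortality: MortalityModel
    lca: LCAConfig
    scenario: PlantingScenario
    registry: SpeciesRegistry
    allometry: AllometryTable
    raw: dict


def _build(cls, section: dict, what: str):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - valid
    if unknown:
        raise ValueError(f"{what}: unknown field(s) {sorted(unknown)}")
    # tuple-ify age distributions loaded from YAML lists
    if cls is InventoryConfig and "age_distributions" in section:
        section = dict(section)
        section["age_distributions"] = {
            k: tuple(v) for k, v in section["age_distributions"].items()
        }
    try:
        return cls(**section)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{what}: {exc}") from exc


def load_run_config(path: str | Path | None = None,
                    seed: int | None = None) -> RunConfig:
    """Load a YAML run configuration; missing sections take package defaults.

    A ``seed`` override is threaded into every seeded sub-config.
    """
    raw: dict = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: configuration must be a mapping")

    tables = raw.get("tables", {})
    registry = (SpeciesRegistry.from_csv(tables["species"])
                if "species" in tables else load_default_registry())
    allometry = (AllometryTable.from_csv(tables["allometry"])
                 if "allometry" in tables else load_default_allometry())

    cfg = RunConfig(
        inventory=_build(InventoryConfig, raw.get("inventory", {}), "inventory"),
        mortality=_build(MortalityModel, raw.get("mortality", {}), "mortality"),
        lca=_build(LCAConfig, raw.get("lca", {}), "lca"),
        scenario=_build(PlantingScenario, raw.get("scenario", {}), "scenario"),
        registry=registry,
        allometry=allometry,
        raw=raw,
    )
    if seed is not None:
        # one user seed, deterministic per-module substreams
        cfg.inventory.seed = seed
        cfg.mortality.seed = seed + 1
        cfg.lca.seed = seed + 2
        cfg.scenario.seed = seed + 3
    return cfg


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(output_path: str | Path, *, seed: int | None,
                   config: dict, inputs: list[str | Path] = ()) -> Path:
    """Write ``<output>.manifest.json`` beside a simulation output."""
    manifest = {
        "package": "urbancarbon",
        "version": __version__,
        "seed": seed,
        "config": config,
        "input_digests": {str(p): file_digest(p) for p in inputs},
        "written_at": datetime.now(timezone.utc).isoformat(),
        "output": str(output_path),
    }
    path = Path(str(output_path) + ".manifest.json")
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path
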