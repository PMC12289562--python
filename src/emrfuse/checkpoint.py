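"""Checkpointing: one parameter archive plus a JSON manifest for exact reload."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np

from .config import ModelConfig
from .crossval import _build_model
from .fusion import FusionModel
from .objectives import ProjectionHead, Temperature
from .schema import FeatureSchema

__all__ = ["save_checkpoint", "load_checkpoint", "schema_fingerprint"]


def schema_fingerprint(schema: FeatureSchema) -> str:
    desc = {
        "categorical": [(f.name, list(f.categories)) for f in schema.categorical_fields],
        "numeric": [(f.name, f.units, list(f.valid_range)) for f in schema.numeric_fields],
        "text_units": list(schema.text_units),
    }
    return hashlib.sha256(json.dumps(desc, sort_keys=True).encode()).hexdigest()[:16]


def save_checkpoint(path, model: FusionModel, head: ProjectionHead, temp: Temperature,
                    model_cfg: ModelConfig, schema: FeatureSchema, seed: int) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    arrays = {}
    for prefix, module in (("model", model), ("head", head), ("temp", temp)):
        for name, value in module.state_dict().items():
            arrays[f"{prefix}.{name}"] = value
    np.savez(path / "params.npz", **arrays)
    manifest = {
        "model_config": model_cfg.model_dump(),
        "schema_fingerprint": schema_fingerprint(schema),
        "seed": seed,
        "format_version": 1,
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_checkpoint(path, schema: FeatureSchema):
    """Rebuild (model, head, temp, manifest); refuses a mismatched schema."""
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    if manifest["schema_fingerprint"] != schema_fingerprint(schema):
        raise ValueError("checkpoint was trained against a different schema")
    model_cfg = ModelConfig.model_validate(manifest["model_config"])
    model = _build_model(schema, model_cfg, seed=manifest["seed"])
    rng = np.random.default_rng(manifest["seed"] + 104729)
    head = ProjectionHead(model_cfg.dim, model_cfg.d_z, rng)
    temp = Temperature(model_cfg.tau_init)
    with np.load(path / "params.npz") as archive:
        states: dict[str, dict] = {"model": {}, "head": {}, "temp": {}}
        for key in archive.files:
            prefix, name = key.split(".", 1)
            states[prefix][name] = archive[key]
    model.load_state_dict(states["model"])
    head.load_state_dict(states["head"])
    temp.load_state_dict(states["temp"])
    return model, head, temp, manifest
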