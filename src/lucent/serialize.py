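"""Checkpoint I/O: parameter arrays as .npz plus a JSON config sidecar."""

from __future__ import annotations

import json
from dataclasses import asdict, is_dataclass
from pathlib import Path

import numpy as np

from lucent.nn import Module


def _jsonable(obj):
    if is_dataclass(obj):
        return {k: _jsonable(v) for k, v in asdict(obj).items()}
    if isinstance(obj, (tuple, list)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, Path):
        return str(obj)
    return obj


def save_model(model: Module, meta: dict, path: str | Path) -> Path:
    """Write weights to ``path`` (.npz) and ``meta`` to a .json sidecar."""
    path = Path(path).with_suffix(".npz")
    arrays = {f"a{i:04d}": a for i, a in enumerate(model.state())}
    np.savez_compressed(path, **arrays)
    path.with_suffix(".json").write_text(json.dumps(_jsonable(meta), indent=2))
    return path


def load_model_state(model: Module, path: str | Path) -> dict:
    """Load weights saved by :func:`save_model` into ``model``; returns meta."""
    path = Path(path).with_suffix(".npz")
    with np.load(path) as z:
        arrays = [z[k] for k in sorted(z.files)]
    model.load_state(arrays)
    sidecar = path.with_suffix(".json")
    return json.loads(sidecar.read_text()) if sidecar.exists() else {}
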