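"""Checkpoints and run artifacts.

Networks are saved as ``.npz`` weight archives with a JSON sidecar holding
the architecture and activation mode; accuracy tables go to CSV and run
manifests to JSON, so a run is reproducible from its output directory.
"""

from __future__ import annotations

import json
from dataclasses import asdict, is_dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .network import DenseNet

__all__ = ["save_checkpoint", "load_checkpoint", "write_run_outputs"]


def save_checkpoint(net: DenseNet, path) -> None:
    """Write weights to ``<path>.npz`` and metadata to ``<path>.json``."""
    path = Path(path)
    np.savez(path.with_suffix(".npz"),
             **{f"w{l}": w for l, w in enumerate(net.weights)})
    meta = {"layer_sizes": net.layer_sizes, "activation_mode": net.activation_mode}
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_checkpoint(path) -> DenseNet:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    with np.load(path.with_suffix(".npz")) as arch:
        weights = [arch[f"w{l}"] for l in range(len(meta["layer_sizes"]) - 1)]
    net = DenseNet(meta["layer_sizes"], weights)
    net.activation_mode = meta.get("activation_mode", "wake")
    return net


def _jsonable(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def write_run_outputs(out_dir, table: pd.DataFrame, manifest: dict) -> None:
    """Write the per-phase accuracy table (CSV) and run manifest (JSON)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table.to_csv(out / "accuracy.csv", index=False)
    (out / "manifest.json").write_text(json.dumps(_jsonable(manifest), indent=2))
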