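"""Deterministic run records: JSON summaries, CSV tables, manifests."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__

__all__ = ["to_jsonable", "write_json", "write_csv", "write_manifest"]


def to_jsonable(obj):
    """Recursively convert results (dataclasses, arrays, enums) to plain
    JSON-serializable structures.  Floats keep full round-trip precision."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: to_jsonable(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {str(k): to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [to_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [to_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if hasattr(obj, "value") and obj.__class__.__module__.startswith("qsnoise"):
        return obj.value  # enums
    return obj


def write_json(obj, path: str | Path) -> Path:
    """Write a JSON summary; floats use Python's shortest round-trip repr,
    so reloading reproduces every value bit-exactly."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(to_jsonable(obj), fh, indent=2, allow_nan=True)
        fh.write("\n")
    return path


def write_csv(df: pd.DataFrame, path: str | Path) -> Path:
    """RFC-4180 CSV, '.' decimal, UTF-8, floats at 17 significant digits."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.17g", lineterminator="\r\n")
    return path


def write_manifest(
    command: str, params: dict, seeds: list[int], outputs: list[Path]
) -> Path:
    """Write a reproducibility manifest next to the first output file."""
    outputs = [Path(p) for p in outputs]
    digests = {}
    for p in outputs:
        h = hashlib.sha256()
        h.update(p.read_bytes())
        digests[p.name] = h.hexdigest()
    manifest = {
        "command": command,
        "params": to_jsonable(params),
        "seeds": seeds,
        "rng": "numpy legacy MT19937 inside compiled kernels; PCG64 for initial states",
        "version": __version__,
        "written_at": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
        "outputs": digests,
    }
    path = outputs[0].with_suffix(outputs[0].suffix + ".manifest.json")
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
        fh.write("\n")
    return path
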