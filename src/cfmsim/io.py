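"""Import/export helpers: YAML parameter blocks and raw-array map exports.

Masks and field maps are written as flat binary arrays (C order) with a JSON
sidecar describing shape, dtype, voxel geometry and provenance, so they can
be reloaded or inspected with any external tool.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import yaml

from .field import FieldMap
from .geometry import CFMParams, SusceptibilityMap

__all__ = [
    "params_from_yaml",
    "params_to_yaml",
    "export_mask",
    "export_field",
    "load_array",
]


def params_from_yaml(path: str | Path) -> CFMParams:
    """Read a CFMParams block from a YAML file (keys mirror the field names)."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    valid = {f.name for f in dataclasses.fields(CFMParams)}
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"unknown parameter keys in {path}: {sorted(unknown)}")
    return CFMParams(**data)


def params_to_yaml(params: CFMParams, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(params), fh, sort_keys=False)


def _export(array: np.ndarray, path: Path, sidecar: dict) -> None:
    array.tofile(path)
    sidecar = dict(sidecar, shape=list(array.shape), dtype=str(array.dtype),
                   order="C")
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump(sidecar, fh, indent=2)


def export_mask(smap: SusceptibilityMap, path: str | Path,
                params: CFMParams | None = None) -> None:
    """Write the intravascular mask as flat uint8 plus a JSON sidecar."""
    meta = {
        "content": "intravascular mask (1 = inside vessel)",
        "voxel_size_um": smap.voxel_size_um,
        "volume_fraction": smap.volume_fraction,
    }
    if params is not None:
        meta["params"] = dataclasses.asdict(params)
    _export(smap.inside_mask.astype(np.uint8), Path(path), meta)


def export_field(fmap: FieldMap, path: str | Path) -> None:
    """Write the field perturbation (tesla) as flat float64 plus sidecar."""
    _export(
        np.ascontiguousarray(fmap.delta_b),
        Path(path),
        {
            "content": "field perturbation along B0",
            "units": "tesla",
            "b0_magnitude": fmap.b0_magnitude,
            "b0_direction": fmap.b0_direction.tolist(),
            "voxel_size_um": fmap.voxel_size_um,
        },
    )


def load_array(path: str | Path) -> tuple[np.ndarray, dict]:
    """Reload an exported array and its sidecar metadata."""
    path = Path(path)
    with open(path.with_suffix(path.suffix + ".json")) as fh:
        meta = json.load(fh)
    arr = np.fromfile(path, dtype=np.dtype(meta["dtype"])).reshape(meta["shape"])
    return arr, meta
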