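"""File I/O: multi-page TIFF stacks, label volumes, tables and configs.

Voxel spacing travels with every stack as a JSON sidecar
(``<stack>.meta.json``); an explicit spacing argument always wins, the
sidecar is second, and a missing spacing is an error rather than a guess.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .containers import ImageStack, LabelVolume

__all__ = [
    "read_stack",
    "write_stack",
    "read_labels",
    "write_labels",
    "read_config",
    "write_config",
]

log = logging.getLogger("prophase3d")


def _sidecar(path: Path) -> Path:
    return path.with_name(path.name + ".meta.json")


def _load_spacing(path: Path, voxel_nm) -> tuple[float, float, float]:
    if voxel_nm is not None:
        sidecar = _sidecar(path)
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            stored = tuple(float(v) for v in meta.get("voxel_nm", ()))
            given = tuple(float(v) for v in voxel_nm)
            if stored and any(
                abs(a - b) > 1e-6 for a, b in zip(stored, given)
            ):
                raise ValueError(
                    f"voxel spacing mismatch for {path}: "
                    f"config says {given}, sidecar says {stored}"
                )
        return tuple(float(v) for v in voxel_nm)
    sidecar = _sidecar(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        if "voxel_nm" in meta:
            return tuple(float(v) for v in meta["voxel_nm"])
    raise ValueError(
        f"voxel spacing unknown for {path}: pass voxel_nm or provide "
        f"{sidecar.name} with a 'voxel_nm' field"
    )


def _read_grid(path: str | Path, voxel_nm) -> tuple[np.ndarray, tuple[float, float, float]]:
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise ValueError(
            f"{path}: expected a multi-page grayscale TIFF, got shape {data.shape} "
            "(RGB or higher-dimensional data is not supported)"
        )
    return data, _load_spacing(path, voxel_nm)


def read_stack(path: str | Path, voxel_nm=None) -> ImageStack:
    """Read a multi-page grayscale TIFF as a 16-bit intensity stack.

    Integer inputs narrower than 16 bits are widened with a warning
    (values preserved); wider or floating data are an error.
    """
    data, spacing = _read_grid(path, voxel_nm)
    if data.dtype != np.uint16:
        if np.issubdtype(data.dtype, np.integer) and np.iinfo(data.dtype).bits < 16:
            warnings.warn(
                f"{path}: {data.dtype.name} input widened to 16-bit", stacklevel=2
            )
            data = data.astype(np.uint16)
        else:
            raise ValueError(
                f"{path}: expected 16-bit grayscale data, got {data.dtype.name}"
            )
    return ImageStack(data, spacing)


def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write a stack as multi-page 16-bit TIFF plus a spacing sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, stack.data.astype(np.uint16), photometric="minisblack")
    _sidecar(path).write_text(json.dumps({"voxel_nm": list(stack.voxel_nm)}))


def read_labels(path: str | Path, voxel_nm=None) -> LabelVolume:
    data, spacing = _read_grid(path, voxel_nm)
    if not np.issubdtype(data.dtype, np.integer):
        raise ValueError(f"{path}: label volume must be integer-valued")
    return LabelVolume(data.astype(np.int32), spacing)


def write_labels(labels: LabelVolume, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if labels.data.max() > 65535:
        raise ValueError("more than 65535 labels cannot be stored as 16-bit TIFF")
    tifffile.imwrite(path, labels.data.astype(np.uint16), photometric="minisblack")
    _sidecar(path).write_text(json.dumps({"voxel_nm": list(labels.voxel_nm)}))


def read_config(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(text) or {}
    return json.loads(text)


def write_config(config: dict, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(config, sort_keys=False))
    else:
        path.write_text(json.dumps(config, indent=2, default=str))
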