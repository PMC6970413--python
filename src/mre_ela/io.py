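"""NIfTI / YAML / CSV interchange with provenance sidecars.

Every image written by the package gets a YAML sidecar recording the kind of
stack, its axis layout, geometry, and provenance (seed, config hash, applied
stages), so a rerun can be reproduced and a reader can refuse silently
mis-ordered axes.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any, Dict, Optional, Union

import nibabel as nib
import numpy as np
import yaml

from .containers import ComplexWaveField, ElastogramMaps, PhaseImageSeries, T1Series

__all__ = [
    "write_phase_series",
    "write_t1_series",
    "write_complex_field",
    "write_elastogram",
    "read_image_stack",
    "config_hash",
]

PHASE_LAYOUT = "row,col,dynamic"
T1_LAYOUT = "slice,row,col,tr"


def config_hash(obj: Any) -> str:
    """Stable short hash of a JSON-serialisable configuration mapping."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suf in (".nii.gz", ".nii"):
        if name.endswith(suf):
            return path.with_name(name[: -len(suf)] + ".yaml")
    return path.with_suffix(".yaml")


def _write_nifti(path: Path, data: np.ndarray, pixel_spacing_mm: float) -> None:
    affine = np.diag([pixel_spacing_mm, pixel_spacing_mm, 1.0, 1.0])
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine), str(path))


def write_phase_series(
    path: Union[str, Path],
    series: PhaseImageSeries,
    extra_meta: Optional[Dict[str, Any]] = None,
) -> Path:
    """Write one MSG-sign phase series (3rd axis = temporal offset) + sidecar."""
    path = Path(path)
    _write_nifti(path, series.data, series.pixel_spacing * 1e3)
    meta = {
        "kind": "phase_series",
        "layout": PHASE_LAYOUT,
        "shape": list(series.data.shape),
        "msg_sign": int(series.msg_sign),
        "drive_frequency_hz": float(series.drive_frequency),
        "pixel_spacing_m": float(series.pixel_spacing),
        "wrapped": bool(series.wrapped),
    }
    if extra_meta:
        meta.update(extra_meta)
    _sidecar_path(path).write_text(yaml.safe_dump(meta, sort_keys=False))
    return path


def write_t1_series(
    path: Union[str, Path],
    series: T1Series,
    pixel_spacing_m: float = 1.5e-4,
    extra_meta: Optional[Dict[str, Any]] = None,
) -> Path:
    path = Path(path)
    _write_nifti(path, series.data, pixel_spacing_m * 1e3)
    meta = {
        "kind": "t1_series",
        "layout": T1_LAYOUT,
        "shape": list(series.data.shape),
        "tr_list_ms": [float(t) for t in series.tr_list],
        "pixel_spacing_m": float(pixel_spacing_m),
    }
    if extra_meta:
        meta.update(extra_meta)
    _sidecar_path(path).write_text(yaml.safe_dump(meta, sort_keys=False))
    return path


def write_complex_field(path_prefix: Union[str, Path], field: ComplexWaveField) -> Dict[str, Path]:
    """Dump an intermediate complex field as real/imag NIfTI pair + sidecar."""
    prefix = Path(path_prefix)
    paths = {}
    for part, data in (("real", field.data.real), ("imag", field.data.imag)):
        p = prefix.with_name(prefix.name + f"_{part}.nii.gz")
        _write_nifti(p, data, field.pixel_spacing * 1e3)
        paths[part] = p
    meta = {
        "kind": "complex_field",
        "layout": "row,col",
        "drive_frequency_hz": float(field.drive_frequency),
        "pixel_spacing_m": float(field.pixel_spacing),
        "provenance": list(field.provenance),
    }
    prefix.with_name(prefix.name + ".yaml").write_text(yaml.safe_dump(meta, sort_keys=False))
    return paths


def write_elastogram(
    path_prefix: Union[str, Path],
    maps: ElastogramMaps,
    pixel_spacing_m: float,
    extra_meta: Optional[Dict[str, Any]] = None,
) -> Dict[str, Path]:
    """Write storage/loss/magnitude/phi maps plus the validity mask."""
    prefix = Path(path_prefix)
    volumes = {
        "g_prime": maps.g_prime,
        "g_doubleprime": maps.g_doubleprime,
        "g_abs": maps.g_abs,
        "phi": maps.phi,
        "valid_mask": maps.valid_mask.astype(float),
    }
    paths = {}
    for name, data in volumes.items():
        p = prefix.with_name(prefix.name + f"_{name}.nii.gz")
        _write_nifti(p, data, pixel_spacing_m * 1e3)
        paths[name] = p
    meta = {
        "kind": "elastogram",
        "layout": "row,col",
        "density_kg_m3": float(maps.density),
        "drive_frequency_hz": float(maps.drive_frequency),
        "pixel_spacing_m": float(pixel_spacing_m),
    }
    if extra_meta:
        meta.update(extra_meta)
    prefix.with_name(prefix.name + ".yaml").write_text(yaml.safe_dump(meta, sort_keys=False))
    return paths


def read_image_stack(
    path: Union[str, Path], layout: str
) -> Union[PhaseImageSeries, T1Series]:
    """Read a NIfTI stack written by this package back into its container.

    ``layout`` must name the axis order and match the sidecar exactly; a
    transposed descriptor raises instead of silently permuting axes.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar}")
    meta = yaml.safe_load(sidecar.read_text())
    if layout != meta["layout"]:
        raise ValueError(
            f"layout mismatch: descriptor {layout!r} but file was written as {meta['layout']!r}"
        )
    data = np.asarray(nib.load(str(path)).dataobj)
    expected = tuple(meta.get("shape", data.shape))
    if tuple(data.shape) != expected:
        raise ValueError(f"dimension mismatch: expected shape {expected}, found {tuple(data.shape)}")
    if meta["kind"] == "phase_series":
        return PhaseImageSeries(
            data=data,
            msg_sign=int(meta["msg_sign"]),
            drive_frequency=float(meta["drive_frequency_hz"]),
            pixel_spacing=float(meta["pixel_spacing_m"]),
            wrapped=bool(meta["wrapped"]),
        )
    if meta["kind"] == "t1_series":
        return T1Series(data=data, tr_list=np.asarray(meta["tr_list_ms"], dtype=float))
    raise ValueError(f"unsupported stack kind {meta['kind']!r}")
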