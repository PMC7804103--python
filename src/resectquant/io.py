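"""NIfTI, CSV and JSON input/output.

Coordinate convention: arrays are indexed ``(i, j, k)``; the NIfTI affine is
built as a diagonal spacing matrix plus origin translation. Volumes written
here round-trip exactly through :func:`read_volume`/:func:`write_volume`.
"""
from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .core import DscSeries, Volume3D

__all__ = [
    "read_volume",
    "write_volume",
    "read_dsc",
    "write_dsc",
    "read_json",
    "write_json",
]


def write_volume(vol: Volume3D, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(np.asarray(vol.values, dtype=np.float32), vol.affine())
    img.header.set_zooms(vol.spacing_mm)
    nib.save(img, str(path))
    return path


def read_volume(path: str | Path) -> Volume3D:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(np.float64)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D NIfTI volume, shape={data.shape}")
    zooms = img.header.get_zooms()[:3]
    origin = tuple(float(x) for x in img.affine[:3, 3])
    return Volume3D(values=data, spacing_mm=tuple(float(z) for z in zooms), origin_mm=origin)


def write_dsc(series: DscSeries, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    aff = np.eye(4)
    aff[:3, :3] = np.diag(series.spacing_mm)
    aff[:3, 3] = series.origin_mm
    img = nib.Nifti1Image(np.asarray(series.values, dtype=np.float32), aff)
    img.header.set_zooms(series.spacing_mm + (series.dt_s,))
    # stash acquisition parameters in the header description
    img.header["descrip"] = f"TE={series.te_ms}ms;NB={series.n_baseline};DT={series.dt_s}s".encode()
    nib.save(img, str(path))
    return path


def read_dsc(path: str | Path, te_ms: float | None = None,
             n_baseline: int | None = None, dt_s: float | None = None) -> DscSeries:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(np.float64)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4D NIfTI series, shape={data.shape}")
    zooms = img.header.get_zooms()
    descrip = bytes(img.header["descrip"]).decode(errors="ignore").rstrip("\x00")
    meta: dict[str, float] = {}
    for part in descrip.split(";"):
        if "=" in part:
            key, _, val = part.partition("=")
            try:
                meta[key] = float(val.rstrip("ms").rstrip("s"))
            except ValueError:
                pass
    return DscSeries(
        values=data,
        spacing_mm=tuple(float(z) for z in zooms[:3]),
        origin_mm=tuple(float(x) for x in img.affine[:3, 3]),
        te_ms=te_ms if te_ms is not None else meta.get("TE", 40.0),
        n_baseline=int(n_baseline if n_baseline is not None else meta.get("NB", 10)),
        dt_s=dt_s if dt_s is not None else meta.get("DT", 1.5),
    )


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default) + "\n")
    return path


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
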