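"""File formats: HDF5 / TIFF stacks, g2 stores, parameter maps, manifests.

The canonical stack container is HDF5 (dataset ``frames``, T x H x W, with
``frame_rate``, ``exposure`` and ``black_level`` attributes) because the
workload is dominated by per-pixel time-series access; multi-page TIFF with
a JSON metadata sidecar is accepted for input. Parameter maps are written
as one float32 TIFF per quantity (categorical maps as int16), ROI summaries
as CSV, and every run records a JSON manifest with the configuration,
package version and input checksums.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .correlation import AcquisitionMeta, FrameStack
from .fitting import ParameterMaps
from .models import Regime

__all__ = [
    "read_stack",
    "write_stack",
    "write_g2_store",
    "read_g2_store",
    "write_maps",
    "read_roi_mask",
    "roi_summary",
    "write_manifest",
    "sha256_of",
]

_META_ATTRS = ("frame_rate", "exposure", "black_level")


def _meta_from_attrs(attrs, n_frames: int) -> AcquisitionMeta:
    missing = [a for a in _META_ATTRS if a not in attrs]
    if missing:
        raise ValueError(f"stack metadata is missing attribute(s): {', '.join(missing)}")
    frame_rate = float(attrs["frame_rate"])
    return AcquisitionMeta(
        frame_rate=frame_rate,
        exposure=float(attrs["exposure"]),
        black_level=float(attrs["black_level"]),
        total_duration=n_frames / frame_rate,
    )


def read_stack(path: str | Path) -> FrameStack:
    """Read a frame stack from HDF5 (.h5/.hdf5) or TIFF (+ JSON sidecar)."""
    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            if "frames" not in f:
                raise ValueError(f"{path}: no 'frames' dataset")
            frames = f["frames"][...]
            meta = _meta_from_attrs(f["frames"].attrs, frames.shape[0])
        return FrameStack(frames=frames, meta=meta)
    if path.suffix.lower() in (".tif", ".tiff"):
        frames = tifffile.imread(path)
        sidecar = path.with_suffix(".json")
        if not sidecar.exists():
            raise ValueError(f"TIFF stack requires a metadata sidecar at {sidecar}")
        attrs = json.loads(sidecar.read_text())
        return FrameStack(frames=frames, meta=_meta_from_attrs(attrs, frames.shape[0]))
    raise ValueError(f"unsupported stack format: {path.suffix}")


def write_stack(path: str | Path, stack: FrameStack) -> None:
    """Write a stack to HDF5 with metadata attributes."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        ds = f.create_dataset("frames", data=stack.frames)
        ds.attrs["frame_rate"] = stack.meta.frame_rate
        ds.attrs["exposure"] = stack.meta.exposure
        ds.attrs["black_level"] = stack.meta.black_level


def write_g2_store(
    path: str | Path, lags: np.ndarray, g2: np.ndarray, flags: np.ndarray,
    meta: AcquisitionMeta,
) -> None:
    """Write per-pixel g2 curves (H x W x L) with lag grid and flags."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.create_dataset("lags", data=np.asarray(lags))
        ds = f.create_dataset("g2", data=np.asarray(g2))
        f.create_dataset("flags", data=np.asarray(flags, dtype=bool))
        ds.attrs["frame_rate"] = meta.frame_rate
        ds.attrs["exposure"] = meta.exposure
        ds.attrs["black_level"] = meta.black_level
        ds.attrs["total_duration"] = meta.total_duration


def read_g2_store(path: str | Path):
    """Read a g2 store written by :func:`write_g2_store`.

    Returns ``(lags, g2, flags, meta)``.
    """
    with h5py.File(path, "r") as f:
        lags = f["lags"][...]
        g2 = f["g2"][...]
        flags = f["flags"][...]
        a = f["g2"].attrs
        meta = AcquisitionMeta(
            frame_rate=float(a["frame_rate"]), exposure=float(a["exposure"]),
            black_level=float(a["black_level"]),
            total_duration=float(a["total_duration"]),
        )
    return lags, g2, flags, meta


def write_maps(out_dir: str | Path, maps: ParameterMaps, prefix: str = "") -> list[Path]:
    """Write parameter maps as float32 TIFFs (categoricals as int16)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, arr in maps.as_dict().items():
        p = out_dir / f"{prefix}{name}.tif"
        if arr.dtype.kind in "iub":
            tifffile.imwrite(p, arr.astype(np.int16))
        else:
            tifffile.imwrite(p, arr.astype(np.float32))
        written.append(p)
    return written


def read_roi_mask(path: str | Path) -> np.ndarray:
    """Read an unsigned-integer label image; 0 is background."""
    mask = tifffile.imread(path)
    if mask.dtype.kind not in "iu":
        raise ValueError("ROI mask must be an integer label image")
    return mask.astype(int)


def roi_summary(maps: ParameterMaps, roi_mask: np.ndarray | None = None) -> pd.DataFrame:
    """Mean and SD of each parameter map per ROI label (NaNs excluded).

    Without a mask, one row summarizes the whole image. An empty mask (no
    nonzero labels) yields an empty frame.
    """
    data = maps.as_dict()
    if roi_mask is None:
        roi_mask = np.ones(maps.tau_c.shape, dtype=int)
    rows = []
    for label in sorted(np.unique(roi_mask)):
        if label == 0:
            continue
        sel = roi_mask == label
        row = {"roi": int(label), "n_pixels": int(sel.sum())}
        for name, arr in data.items():
            vals = arr[sel].astype(float)
            vals = vals[np.isfinite(vals)]
            row[f"{name}_mean"] = vals.mean() if len(vals) else np.nan
            row[f"{name}_sd"] = vals.std() if len(vals) else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path: str | Path, config: dict, inputs: list[str | Path],
                   extra: dict | None = None) -> None:
    """Record run provenance: config, package version, input checksums."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "config": config,
        "inputs": {str(p): sha256_of(p) for p in inputs if Path(p).exists()},
    }
    if extra:
        manifest.update(extra)
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
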