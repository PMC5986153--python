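"""Reading and writing volumes, boundary sets and feature tables."""

from __future__ import annotations

import hashlib
import json
import re
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .core import FEATURE_NAMES, BoundarySet, FeatureVector, OCTVolume, RetoctError

VoxelDims = Tuple[float, float, float]


def volume_hash(volume: OCTVolume) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(volume.intensities).tobytes())
    h.update(json.dumps(volume.voxel_dims).encode())
    return h.hexdigest()[:16]


def sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_volume(path, volume: OCTVolume, extra: Optional[Dict] = None) -> Path:
    """Write a volume as multi-page 8-bit TIFF plus a JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, volume.intensities.astype(np.uint8))
    meta = {"voxel_dims": list(volume.voxel_dims)}
    if extra:
        meta.update(extra)
    sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def _natural_key(name: str):
    return [int(t) if t.isdigit() else t for t in re.split(r"(\d+)", name)]


def read_volume(path, voxel_dims: Optional[VoxelDims] = None) -> OCTVolume:
    """Load a multi-page TIFF or a directory of PNG B-scans.

    Voxel dimensions come from the sidecar JSON unless given explicitly.
    """
    path = Path(path)
    if path.is_dir():
        pages = sorted(path.glob("*.png"), key=lambda p: _natural_key(p.name))
        if not pages:
            raise RetoctError(f"no PNG B-scans found in {path}")
        frames = [np.asarray(iio.imread(p)) for p in pages]
    else:
        arr = tifffile.imread(path)
        frames = [arr] if arr.ndim == 2 else list(arr)
    shapes = {f.shape for f in frames}
    if len(shapes) != 1:
        raise RetoctError(f"inconsistent B-scan shapes: {sorted(shapes)}")
    if voxel_dims is None:
        sc = sidecar_path(path)
        if not sc.exists():
            raise RetoctError(
                f"voxel dimensions required: pass them explicitly or provide {sc}")
        voxel_dims = tuple(json.loads(sc.read_text())["voxel_dims"])
    return OCTVolume(np.stack(frames), tuple(float(v) for v in voxel_dims))


def write_mask(path, mask) -> Path:
    """Write a pathology mask as a multi-page 8-bit TIFF (0/255)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, (mask.mask.astype(np.uint8) * 255))
    sidecar_path(path).write_text(json.dumps(
        {"kind": mask.kind, "voxel_dims": list(mask.voxel_dims),
         "count": mask.count}))
    return path


def write_boundaries(path, boundaries: BoundarySet,
                     meta: Optional[Dict] = None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    doc = {"boundaries": boundaries.to_dict(), "meta": meta or {}}
    path.write_text(json.dumps(doc))
    return path


def read_boundaries(path) -> BoundarySet:
    doc = json.loads(Path(path).read_text())
    return BoundarySet.from_dict(doc["boundaries"])


def features_to_frame(rows: Sequence[Tuple[str, FeatureVector, Optional[str]]]) -> pd.DataFrame:
    recs = []
    for vid, fv, label in rows:
        rec = {"id": vid, **fv.to_dict()}
        if label is not None:
            rec["label"] = label
        recs.append(rec)
    return pd.DataFrame(recs)


def write_features_csv(path, rows) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    features_to_frame(rows).to_csv(path, index=False)
    return path


def read_features_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in FEATURE_NAMES if c not in df.columns]
    if missing:
        raise RetoctError(f"feature table missing columns: {missing}")
    return df
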