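"""File formats: PLY point clouds, CSV fallback, TIFF volumes.

Point clouds are written as binary-little-endian PLY with per-vertex
properties ``x, y, z`` (float32, micrometres or unit-sphere units) and
``refractive_index`` (float32); training point sets add a ``provenance``
uchar (0 = FPS, 1 = RIIES).  Cloud metadata (normalized flag, label) rides
in PLY comments.  The CSV fallback uses the header ``x,y,z,n``.

Volumes are single-channel 32-bit float multi-page TIFF (pages along z) with
a JSON sidecar holding spacing, label, seed and a spec hash; masks are 8-bit
TIFF.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import InvalidConfigError
from .phantom import LabeledVolume, PhantomSpec
from .ripcs import TrainingPointSet
from .voxelcloud import RIPointCloud, VoxelVolume

__all__ = [
    "write_ply",
    "read_ply",
    "write_csv",
    "read_csv",
    "write_volume",
    "read_volume",
    "spec_hash",
]

_PLY_MAGIC = b"ply"


def _cloud_fields(obj) -> tuple[np.ndarray, np.ndarray, np.ndarray | None, int | None, bool]:
    if isinstance(obj, TrainingPointSet):
        return obj.xyz, obj.ri, obj.provenance, obj.label, True
    return obj.xyz, obj.ri, None, obj.label, obj.normalized


def write_ply(path: str | Path, cloud: RIPointCloud | TrainingPointSet) -> None:
    xyz, ri, prov, label, normalized = _cloud_fields(cloud)
    n = len(ri)
    header = [
        "ply",
        "format binary_little_endian 1.0",
        f"comment ripc normalized={int(bool(normalized))}",
    ]
    if label is not None:
        header.append(f"comment ripc label={int(label)}")
    header += [
        f"element vertex {n}",
        "property float x",
        "property float y",
        "property float z",
        "property float refractive_index",
    ]
    fields = [("x", "<f4"), ("y", "<f4"), ("z", "<f4"), ("refractive_index", "<f4")]
    if prov is not None:
        header.append("property uchar provenance")
        fields.append(("provenance", "u1"))
    header.append("end_header")
    rec = np.empty(n, dtype=np.dtype(fields))
    rec["x"], rec["y"], rec["z"] = xyz[:, 0], xyz[:, 1], xyz[:, 2]
    rec["refractive_index"] = ri
    if prov is not None:
        rec["provenance"] = prov
    with open(path, "wb") as fh:
        fh.write(("\n".join(header) + "\n").encode("ascii"))
        fh.write(rec.tobytes())


def read_ply(path: str | Path) -> RIPointCloud | TrainingPointSet:
    """Read a cloud written by :func:`write_ply` (binary little-endian PLY
    with x/y/z/refractive_index and optional provenance)."""
    raw = Path(path).read_bytes()
    if not raw.startswith(_PLY_MAGIC):
        raise InvalidConfigError(f"{path} is not a PLY file")
    end = raw.index(b"end_header\n") + len(b"end_header\n")
    lines = raw[:end].decode("ascii").splitlines()
    n = None
    fields: list[tuple[str, str]] = []
    normalized, label = False, None
    fmt_map = {"float": "<f4", "double": "<f8", "uchar": "u1", "int": "<i4"}
    for line in lines:
        parts = line.split()
        if parts[:2] == ["element", "vertex"]:
            n = int(parts[2])
        elif parts[0] == "property" and n is not None:
            fields.append((parts[2], fmt_map[parts[1]]))
        elif parts[0] == "comment" and len(parts) >= 3 and parts[1] == "ripc":
            key, val = parts[2].split("=")
            if key == "normalized":
                normalized = bool(int(val))
            elif key == "label":
                label = int(val)
        elif parts[0] == "format" and parts[1] != "binary_little_endian":
            raise InvalidConfigError(f"unsupported PLY format {parts[1]}")
    if n is None:
        raise InvalidConfigError(f"{path}: missing vertex element")
    rec = np.frombuffer(raw[end:], dtype=np.dtype(fields), count=n)
    xyz = np.stack(
        [rec["x"], rec["y"], rec["z"]], axis=1
    ).astype(np.float64)
    ri = rec["refractive_index"].astype(np.float64)
    if "provenance" in rec.dtype.names:
        return TrainingPointSet(xyz, ri, rec["provenance"].copy(), label)
    return RIPointCloud(xyz, ri, normalized=normalized, label=label)


def write_csv(path: str | Path, cloud: RIPointCloud) -> None:
    pd.DataFrame(
        {"x": cloud.xyz[:, 0], "y": cloud.xyz[:, 1], "z": cloud.xyz[:, 2], "n": cloud.ri}
    ).to_csv(path, index=False)


def read_csv(path: str | Path) -> RIPointCloud:
    df = pd.read_csv(path)
    return RIPointCloud(df[["x", "y", "z"]].to_numpy(), df["n"].to_numpy())


def spec_hash(spec: PhantomSpec) -> str:
    return hashlib.sha256(
        json.dumps(dataclasses.asdict(spec), sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def write_volume(
    out_dir: str | Path,
    stem: str,
    lv: LabeledVolume,
    spec: PhantomSpec | None = None,
    seed: int | None = None,
) -> dict:
    """Write ``<stem>.tif`` (float32 RI, pages along z), ``<stem>_mask.tif``
    (uint8) and ``<stem>.json`` (spacing, label, seed, spec hash).  Returns
    the sidecar dict."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    # grid is (x, y, z); TIFF pages are (z, y, x)
    tifffile.imwrite(out_dir / f"{stem}.tif", lv.volume.ri.T.astype(np.float32))
    tifffile.imwrite(out_dir / f"{stem}_mask.tif", lv.mask.T.astype(np.uint8))
    sidecar = {
        "spacing_um": float(lv.volume.spacing),
        "label": int(lv.label),
        "seed": None if seed is None else int(seed),
        "spec_hash": None if spec is None else spec_hash(spec),
    }
    (out_dir / f"{stem}.json").write_text(json.dumps(sidecar, indent=2))
    return sidecar


def read_volume(path: str | Path, spacing: float | None = None) -> VoxelVolume:
    """Read a multi-page float TIFF volume; spacing comes from the JSON
    sidecar if present, else from the argument (default 1.0)."""
    path = Path(path)
    arr = tifffile.imread(path)
    if arr.ndim != 3:
        raise InvalidConfigError(f"{path}: expected a 3D volume, got shape {arr.shape}")
    sidecar = path.with_suffix(".json")
    if spacing is None and sidecar.exists():
        spacing = json.loads(sidecar.read_text()).get("spacing_um")
    return VoxelVolume(arr.T.astype(np.float32), float(spacing or 1.0))


def read_mask(path: str | Path) -> np.ndarray:
    arr = tifffile.imread(path)
    return arr.T.astype(bool)
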