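"""In-memory image containers and NIfTI-1 + JSON sidecar I/O.

Voxel-order convention (fixed throughout the package): axis 0 runs
left-to-right with the anatomical midline at the grid centre (between
indices N/2-1 and N/2 for an even grid), axis 1 runs ventral-to-dorsal,
and an optional axis 2 indexes slices.  Indices are 0-based.  Image
series carry their frame axis last; on disk they are stored as 4-D
NIfTI volumes (singleton slice axis inserted for 2-D data) with all
acquisition metadata in a JSON sidecar next to the image file.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "ImageVolume",
    "ImageSeries",
    "mirror",
    "read_series",
    "write_series",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
]


@dataclass
class ImageVolume:
    """A single voxel grid with spacing and a modality tag."""

    data: np.ndarray
    voxel_size_mm: tuple
    modality: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)
        if self.data.ndim not in (2, 3):
            raise ValueError(f"expected 2-D or 3-D volume, got shape {self.data.shape}")


@dataclass
class ImageSeries:
    """A stack of co-registered frames (trailing axis) plus per-frame metadata.

    ``frame_meta`` holds per-frame lists such as ``b_value`` (s/mm^2),
    ``direction``, ``te_ms`` or ``time_min``; any list-valued entry must
    have one element per frame.
    """

    frames: np.ndarray
    voxel_size_mm: tuple
    modality: str
    frame_meta: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=np.float64)
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)
        if self.frames.ndim not in (3, 4):
            raise ValueError(
                f"expected spatial axes + frame axis, got shape {self.frames.shape}"
            )
        for key, val in self.frame_meta.items():
            if isinstance(val, (list, tuple)) and len(val) != self.n_frames:
                raise ValueError(
                    f"frame_meta[{key!r}] has {len(val)} entries for "
                    f"{self.n_frames} frames"
                )

    @property
    def n_frames(self) -> int:
        return self.frames.shape[-1]

    @property
    def spatial_shape(self) -> tuple:
        return self.frames.shape[:-1]

    def frame(self, k: int) -> ImageVolume:
        meta = dict(self.meta)
        for key, val in self.frame_meta.items():
            if isinstance(val, (list, tuple)):
                meta[key] = val[k]
        return ImageVolume(self.frames[..., k], self.voxel_size_mm, self.modality, meta)


def mirror(arr: np.ndarray, axis: int = 0) -> np.ndarray:
    """Reflect across the midline plane (index i -> N-1-i along ``axis``)."""
    return np.flip(arr, axis=axis)


# ---------------------------------------------------------------------------
# NIfTI + sidecar I/O


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def _affine(voxel_size_mm: tuple) -> np.ndarray:
    sizes = list(voxel_size_mm) + [1.0] * (3 - len(voxel_size_mm))
    return np.diag(sizes[:3] + [1.0])


def _save_nifti(data: np.ndarray, voxel_size_mm: tuple, path: Path) -> None:
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), _affine(voxel_size_mm))
    img.header.set_data_dtype(np.float64)
    nib.save(img, str(path))


def _load_sidecar(path: Path) -> dict:
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"missing JSON sidecar for {path}: expected {sidecar}")
    with open(sidecar) as fh:
        return json.load(fh)


def write_series(series: ImageSeries, path) -> Path:
    path = Path(path)
    spatial_ndim = series.frames.ndim - 1
    data = series.frames
    if spatial_ndim == 2:  # NIfTI wants (x, y, z, t)
        data = data[:, :, np.newaxis, :]
    _save_nifti(data, series.voxel_size_mm, path)
    sidecar = {
        "kind": "series",
        "modality": series.modality,
        "voxel_size_mm": list(series.voxel_size_mm),
        "spatial_ndim": spatial_ndim,
        "n_frames": series.n_frames,
        "frame_meta": _jsonable(series.frame_meta),
        "meta": _jsonable(series.meta),
    }
    with open(_sidecar_path(path), "w") as fh:
        json.dump(sidecar, fh, indent=1, sort_keys=True)
    return path


def read_series(path) -> ImageSeries:
    path = Path(path)
    side = _load_sidecar(path)
    data = np.asanyarray(nib.load(str(path)).dataobj, dtype=np.float64)
    if side.get("spatial_ndim") == 2 and data.ndim == 4:
        data = data[:, :, 0, :]
    if data.shape[-1] != side["n_frames"]:
        raise ValueError(
            f"{path}: sidecar declares {side['n_frames']} frames, "
            f"image has {data.shape[-1]}"
        )
    return ImageSeries(
        frames=data,
        voxel_size_mm=tuple(side["voxel_size_mm"]),
        modality=side["modality"],
        frame_meta=side.get("frame_meta", {}),
        meta=side.get("meta", {}),
    )


def write_volume(vol: ImageVolume, path) -> Path:
    path = Path(path)
    _save_nifti(vol.data, vol.voxel_size_mm, path)
    sidecar = {
        "kind": "volume",
        "modality": vol.modality,
        "voxel_size_mm": list(vol.voxel_size_mm),
        "spatial_ndim": vol.data.ndim,
        "meta": _jsonable(vol.meta),
    }
    with open(_sidecar_path(path), "w") as fh:
        json.dump(sidecar, fh, indent=1, sort_keys=True)
    return path


def read_volume(path) -> ImageVolume:
    path = Path(path)
    side = _load_sidecar(path)
    data = np.asanyarray(nib.load(str(path)).dataobj, dtype=np.float64)
    data = np.squeeze(data) if data.ndim > side.get("spatial_ndim", data.ndim) else data
    return ImageVolume(
        data=data,
        voxel_size_mm=tuple(side["voxel_size_mm"]),
        modality=side["modality"],
        meta=side.get("meta", {}),
    )


def write_mask(mask: np.ndarray, label: str, voxel_size_mm: tuple, path, meta=None):
    path = Path(path)
    data = np.asarray(mask).astype(np.uint8)
    img = nib.Nifti1Image(
        data[:, :, np.newaxis] if data.ndim == 2 else data, _affine(voxel_size_mm)
    )
    img.header.set_data_dtype(np.uint8)
    nib.save(img, str(path))
    sidecar = {
        "kind": "mask",
        "label": label,
        "voxel_size_mm": list(voxel_size_mm),
        "spatial_ndim": data.ndim,
        "meta": _jsonable(meta or {}),
    }
    with open(_sidecar_path(path), "w") as fh:
        json.dump(sidecar, fh, indent=1, sort_keys=True)
    return path


def read_mask(path):
    path = Path(path)
    side = _load_sidecar(path)
    data = np.asanyarray(nib.load(str(path)).dataobj)
    if side.get("spatial_ndim") == 2 and data.ndim == 3:
        data = data[:, :, 0]
    return data.astype(bool), side["label"], side.get("meta", {})


def _jsonable(obj):
    """Recursively convert numpy scalars/arrays to plain JSON types."""
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    return obj
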