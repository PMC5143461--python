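"""Core / penumbra / hypoperfused segmentation and mirror ROIs.

Rules follow the perfusion-diffusion-mismatch workflow for transient
focal ischemia:

* acute core: perfusion strictly below 57 % of contralateral;
* subacute core (24 h): T2 hyperintensity exceeding the contralateral
  mean by k standard deviations (default k=2, the rule "significantly
  above healthy-tissue variation" made explicit);
* hypoperfused territory: perfusion below a configurable outer cutoff
  (default 90 %, since no outer boundary is standardized);
* penumbra: the mismatch, hypoperfused minus core.

Each thresholded mask keeps only its largest connected component — a
reproducible stand-in for manual ROI drawing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .images import mirror
from .mapfit import ParamMap

__all__ = [
    "RoiMask",
    "largest_component",
    "segment_core_acute",
    "segment_core_subacute",
    "segment_hypoperfused",
    "segment_penumbra",
    "mirror_roi",
    "dice",
]


@dataclass
class RoiMask:
    """A binary voxel mask with a tissue label and optional timepoint tag."""

    mask: np.ndarray
    label: str
    timepoint: str | None = None

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def largest_component(mask: np.ndarray) -> np.ndarray:
    """Largest 4-connected (2-D; face-connected in 3-D) component of a mask."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return mask.copy()
    labels, n = ndimage.label(mask)
    if n == 1:
        return mask.copy()
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return labels == int(np.argmax(counts))


def _threshold_mask(values, fit_mask, ipsi_mask, keep, label, timepoint) -> RoiMask:
    ipsi = np.asarray(ipsi_mask, dtype=bool)
    if not ipsi.any():
        raise ValueError("empty ipsilateral brain mask")
    with np.errstate(invalid="ignore"):
        sel = ipsi & fit_mask & keep(values)
    out = largest_component(sel)
    if not out.any():
        warnings.warn(f"{label} segmentation produced an empty mask", stacklevel=3)
    return RoiMask(out, label, timepoint)


def segment_core_acute(
    perf_ratio: ParamMap,
    ipsi_mask: np.ndarray,
    threshold_pct: float = 57.0,
    timepoint: str | None = None,
) -> RoiMask:
    """Acute core: perfusion ratio strictly below ``threshold_pct``.

    The inequality is strict, so exact-boundary voxels are excluded.
    """
    return _threshold_mask(
        perf_ratio.values,
        perf_ratio.fit_mask,
        ipsi_mask,
        lambda v: v < threshold_pct,
        "core",
        timepoint,
    )


def segment_core_subacute(
    t2_map: ParamMap,
    contra_mask: np.ndarray,
    ipsi_mask: np.ndarray,
    k: float = 2.0,
    timepoint: str | None = None,
) -> RoiMask:
    """Subacute core: T2 above contralateral mean + k * contralateral SD."""
    contra = np.asarray(contra_mask, dtype=bool) & t2_map.fit_mask
    if not contra.any():
        raise ValueError("empty contralateral reference region")
    vals = t2_map.values[contra]
    thr = float(vals.mean() + k * vals.std(ddof=1))
    roi = _threshold_mask(
        t2_map.values,
        t2_map.fit_mask,
        ipsi_mask,
        lambda v: v > thr,
        "core",
        timepoint,
    )
    return roi


def segment_hypoperfused(
    perf_ratio: ParamMap,
    ipsi_mask: np.ndarray,
    cutoff_pct: float = 90.0,
    timepoint: str | None = None,
) -> RoiMask:
    """Hypoperfused territory: perfusion ratio below ``cutoff_pct``."""
    return _threshold_mask(
        perf_ratio.values,
        perf_ratio.fit_mask,
        ipsi_mask,
        lambda v: v < cutoff_pct,
        "hypoperfused",
        timepoint,
    )


def segment_penumbra(hypo: RoiMask, core: RoiMask) -> RoiMask:
    """Penumbra = mismatch area, hypoperfused minus core."""
    if hypo.mask.shape != core.mask.shape:
        raise ValueError("mask shapes differ")
    return RoiMask(hypo.mask & ~core.mask, "penumbra", hypo.timepoint)


def mirror_roi(roi: RoiMask, midline_axis: int = 0) -> RoiMask:
    """Reflect a mask across the midline plane (an involution)."""
    label = roi.label
    prefix = "contralateral_mirror("
    if label.startswith(prefix) and label.endswith(")"):
        label = label[len(prefix) : -1]  # mirror of a mirror is the original
    else:
        label = f"contralateral_mirror({label})"
    return RoiMask(mirror(roi.mask, midline_axis), label, roi.timepoint)


def dice(a, b) -> float:
    """Dice overlap 2|A&B| / (|A|+|B|); 1.0 for two empty masks."""
    a = np.asarray(a.mask if isinstance(a, RoiMask) else a, dtype=bool)
    b = np.asarray(b.mask if isinstance(b, RoiMask) else b, dtype=bool)
    total = int(a.sum()) + int(b.sum())
    if total == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / total
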