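"""Contralateral-normalized ROI ratios, sodium slope maps, group statistics.

Ratio orientation: every value is ipsilateral / contralateral x 100
("% contralateral"), so reduced quantities read below 100.  Group cells
are mean +/- SEM over subjects with a paired two-sided t-test between
the ipsilateral and mirrored-contralateral ROI means; p <= 0.05 flags
significance, with no multiple-testing correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .images import ImageSeries, ImageVolume
from .lesion import RoiMask
from .mapfit import ParamMap

__all__ = [
    "SlopeMap",
    "roi_mean",
    "roi_ratio",
    "sodium_slope_map",
    "paired_t_test",
    "summarize_group",
]


@dataclass
class SlopeMap:
    """Voxelwise temporal slope of the reference-normalized signal, %/h."""

    values: np.ndarray
    reference_label: str
    time_window_min: tuple
    fit_mask: np.ndarray
    meta: dict = field(default_factory=dict)


def _values_and_validity(image):
    if isinstance(image, ParamMap):
        return image.values, image.fit_mask
    if isinstance(image, ImageVolume):
        data = image.data
    elif isinstance(image, np.ndarray):
        data = image
    else:
        raise TypeError(f"unsupported image type {type(image)!r}")
    return data, np.isfinite(data)


def roi_mean(image, roi: RoiMask) -> float:
    """Mean of the image over the ROI, restricted to valid (fitted) voxels."""
    values, valid = _values_and_validity(image)
    sel = roi.mask & valid
    if not sel.any():
        raise ValueError(f"ROI '{roi.label}' contains no valid voxels")
    return float(values[sel].mean())


def roi_ratio(image, roi: RoiMask, mirror: RoiMask) -> float:
    """100 x mean(image in roi) / mean(image in mirror).

    ``roi`` and ``mirror`` must be non-empty and disjoint (they live in
    opposite hemispheres); a zero contralateral mean is an error.
    """
    if (roi.mask & mirror.mask).any():
        raise ValueError("roi and its mirror overlap")
    ipsi = roi_mean(image, roi)
    contra = roi_mean(image, mirror)
    if contra == 0:
        raise ValueError("contralateral mean is zero; ratio undefined")
    return 100.0 * ipsi / contra


def sodium_slope_map(
    series: ImageSeries,
    reference: RoiMask,
    mask: np.ndarray | None = None,
) -> SlopeMap:
    """Per-voxel OLS slope of the reference-normalized sodium signal, %/h.

    Each frame is divided by the mean of that frame over the (contralateral)
    reference ROI and multiplied by 100; the per-voxel slope of that
    normalized signal against acquisition time (hours) is the map value.
    By construction the mean slope over the reference ROI itself is zero.
    """
    t_min = np.asarray(series.frame_meta["time_min"], dtype=float)
    if t_min.size < 3:
        raise ValueError("slope fitting needs at least three time frames")
    if np.any(np.diff(t_min) <= 0):
        raise ValueError("timestamps must be strictly increasing")
    if not reference.mask.any():
        raise ValueError("empty reference ROI")
    ref_means = series.frames[reference.mask].mean(axis=0)
    if np.any(ref_means <= 0):
        raise ValueError("non-positive reference-ROI mean; cannot normalize")
    norm = 100.0 * series.frames / ref_means
    t_h = t_min / 60.0
    tc = t_h - t_h.mean()
    slope = norm @ tc / float((tc**2).sum())
    finite = np.all(np.isfinite(norm), axis=-1)
    fit_mask = finite if mask is None else (finite & np.asarray(mask, dtype=bool))
    values = np.where(fit_mask, slope, np.nan)
    return SlopeMap(
        values=values,
        reference_label=reference.label,
        time_window_min=(float(t_min[0]), float(t_min[-1])),
        fit_mask=fit_mask,
        meta={"n_frames": int(t_min.size)},
    )


def paired_t_test(ipsi, contra):
    """Two-sided paired Student t-test; returns ``(t, p)``.

    Degenerate cases: identically-zero differences give ``(0.0, 1.0)``
    with a warning; identical nonzero differences give ``(+/-inf, 0.0)``.
    """
    a = np.asarray(ipsi, dtype=float)
    b = np.asarray(contra, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be 1-D and equal length")
    if a.size < 2:
        raise ValueError("paired t-test needs n >= 2")
    d = a - b
    if np.ptp(d) == 0:  # all differences identical -> zero variance
        if d[0] == 0:
            warnings.warn("all paired differences are zero; reporting p = 1")
            return 0.0, 1.0
        warnings.warn("paired differences are identical and nonzero; p -> 0")
        return float(np.sign(d[0]) * np.inf), 0.0
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)


def summarize_group(
    per_subject: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Group-level table of contralateral-normalized ratios.

    ``per_subject`` needs columns ``subject, timepoint, quantity, region,
    ipsi_mean, contra_mean`` (one row per subject x cell).  Returns one
    row per (quantity, region, timepoint) with n, mean ratio, SEM
    (SD/sqrt(n), sample SD), the paired ipsi-vs-contra t and p, and the
    significance flag at ``p <= alpha``.  Unbalanced n across timepoints
    (scan dropout) is supported; n = 1 cells report SEM 0 with a warning.
    """
    required = {"subject", "timepoint", "quantity", "region", "ipsi_mean", "contra_mean"}
    missing = required - set(per_subject.columns)
    if missing:
        raise ValueError(f"per_subject is missing columns: {sorted(missing)}")
    df = per_subject.copy()
    df["ratio_pct"] = 100.0 * df["ipsi_mean"] / df["contra_mean"]
    rows = []
    for (quantity, region, timepoint), grp in df.groupby(
        ["quantity", "region", "timepoint"], sort=False
    ):
        ratios = grp["ratio_pct"].to_numpy()
        n = ratios.size
        if n == 1:
            warnings.warn(
                f"{quantity}/{region}/{timepoint}: single subject, SEM set to 0"
            )
            sem = 0.0
            t_stat, p_val = np.nan, np.nan
        else:
            sem = float(ratios.std(ddof=1) / np.sqrt(n))
            t_stat, p_val = paired_t_test(
                grp["ipsi_mean"].to_numpy(), grp["contra_mean"].to_numpy()
            )
        rows.append(
            {
                "quantity": quantity,
                "region": region,
                "timepoint": timepoint,
                "n": n,
                "mean_ratio_pct": float(ratios.mean()),
                "sem_pct": sem,
                "t": t_stat,
                "p": p_val,
                "significant": bool(p_val <= alpha) if np.isfinite(p_val) else False,
            }
        )
    return pd.DataFrame(rows)
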