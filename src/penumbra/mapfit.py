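"""Voxelwise parameter-map fitting: ADC, T2 and perfusion ratio.

Both exponential fits use log-linear ordinary least squares
(``ln S = ln S0 - x * k``), which is exact on noiseless data, fully
deterministic, and adequate at the simulated SNR; the test suite
quantifies the difference against nonlinear and brute-force oracles.
Voxels where the fit cannot be attempted (non-positive signal) or where
it produces a non-physical value (ADC or T2 <= 0) are excluded from the
fit mask and set to NaN — never silently zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .images import ImageSeries, ImageVolume, mirror

__all__ = ["ParamMap", "fit_adc", "fit_t2", "perfusion_ratio_map"]


@dataclass
class ParamMap:
    """A voxelwise fitted quantity with its fit mask and per-voxel QC."""

    values: np.ndarray  # NaN outside fit_mask
    quantity: str  # "adc" | "t2" | "perfusion_ratio" | ...
    units: str
    fit_mask: np.ndarray
    qc: np.ndarray | None = None  # residual 2-norm of the log-domain fit
    meta: dict = field(default_factory=dict)


def _ols_loglinear(x: np.ndarray, logy: np.ndarray, weights: np.ndarray | None = None):
    """(Weighted) OLS of ``logy`` (n_voxels, k) on ``x`` (k,).

    ``weights`` may carry per-voxel rows.  Returns slope, intercept and
    the (weighted) residual 2-norm.
    """
    x = np.asarray(x, dtype=float)
    if weights is None:
        weights = np.ones_like(x)
    w = np.broadcast_to(weights, logy.shape)
    wsum = w.sum(axis=-1)
    xbar = (w * x).sum(axis=-1) / wsum
    ybar = (w * logy).sum(axis=-1) / wsum
    xc = x - xbar[..., None]
    yc = logy - ybar[..., None]
    slope = (w * xc * yc).sum(axis=-1) / (w * xc**2).sum(axis=-1)
    intercept = ybar - slope * xbar
    fitted = intercept[..., None] + slope[..., None] * x
    resid = np.sqrt((w * (logy - fitted) ** 2).sum(axis=-1))
    return slope, intercept, resid


def _exp_decay_map(
    series, x_per_frame, mask, quantity, units, rate_to_value, meta, weighting="uniform"
):
    x = np.asarray(x_per_frame, dtype=float)
    levels = np.unique(x)
    # average repeated frames (b=0 repeats, diffusion directions) per level
    means = np.stack([series.frames[..., x == lev].mean(axis=-1) for lev in levels], -1)
    if mask is None:
        mask = np.ones(series.spatial_shape, dtype=bool)
    attempt = mask & np.all(means > 0, axis=-1)
    values = np.full(series.spatial_shape, np.nan)
    qc = np.full(series.spatial_shape, np.nan)
    fit_mask = np.zeros(series.spatial_shape, dtype=bool)
    if attempt.any():
        sel = means[attempt]
        weights = sel**2 if weighting == "signal" else None
        slope, _, resid = _ols_loglinear(levels, np.log(sel), weights)
        fitted = rate_to_value(slope)
        ok = np.isfinite(fitted) & (fitted > 0)
        values[attempt] = np.where(ok, fitted, np.nan)
        qc[attempt] = resid
        fit_mask[attempt] = ok
    return ParamMap(values, quantity, units, fit_mask, qc, meta)


def fit_adc(dwi: ImageSeries, mask: np.ndarray | None = None) -> ParamMap:
    """Fit an ADC map (mm^2/s) from a multi-b-value diffusion series.

    Per voxel: the b=0 repeats are averaged, the diffusion directions at
    each b are averaged (the readout is a direction-mean, scalar ADC),
    and ``ln S(b)`` is regressed on b over all b levels.

    Raises ``ValueError`` with fewer than two distinct b-values.
    """
    b = np.asarray(dwi.frame_meta["b_value"], dtype=float)
    if np.unique(b).size < 2:
        raise ValueError("fit_adc needs at least two distinct b-values")
    return _exp_decay_map(
        dwi,
        b,
        mask,
        "adc",
        "mm^2/s",
        rate_to_value=lambda slope: -slope,
        meta={"b_values": sorted(float(v) for v in set(b))},
    )


def fit_t2(
    msme: ImageSeries, mask: np.ndarray | None = None, weighting: str = "signal"
) -> ParamMap:
    """Fit a T2 map (ms) from a multi-echo spin-echo series (>=3 echoes).

    The log-linear regression is signal-squared weighted by default —
    the standard linearization of the exponential least-squares problem,
    which keeps late echoes near the magnitude-noise floor from
    dominating the log-domain fit.  ``weighting="uniform"`` gives plain
    OLS.  Both are exact on noiseless data.
    """
    te = np.asarray(msme.frame_meta["te_ms"], dtype=float)
    if np.unique(te).size < 3:
        raise ValueError("fit_t2 needs at least three distinct echo times")
    if weighting not in ("signal", "uniform"):
        raise ValueError("weighting must be 'signal' or 'uniform'")
    with np.errstate(divide="ignore"):
        return _exp_decay_map(
            msme,
            te,
            mask,
            "t2",
            "ms",
            rate_to_value=lambda slope: np.where(slope < 0, -1.0 / slope, np.nan),
            meta={"te_ms": [float(v) for v in te], "weighting": weighting},
            weighting=weighting,
        )


def perfusion_ratio_map(
    perf: ImageVolume,
    brain_mask: np.ndarray,
    midline_axis: int = 0,
    neighborhood: int = 3,
) -> ParamMap:
    """Perfusion as percent of the homologous contralateral neighbourhood.

    Each voxel is divided by the brain-restricted mean of the
    ``neighborhood x neighborhood`` in-plane window centred on its mirror
    across the midline, x100.  A mirror-symmetric coil profile cancels
    (to the smoothing window's accuracy).  Voxels whose mirrored
    neighbourhood contains no brain are excluded from the fit mask.
    """
    if neighborhood < 1 or neighborhood % 2 == 0:
        raise ValueError("neighborhood must be a positive odd integer")
    data = perf.data
    bm = np.asarray(brain_mask, dtype=bool)
    if bm.shape != data.shape:
        raise ValueError("brain_mask shape does not match the image")
    if not bm.any():
        raise ValueError("empty brain mask")
    flipped = mirror(data, midline_axis)
    fbm = mirror(bm, midline_axis).astype(float)
    size = [1] * data.ndim
    size[0] = size[1] = neighborhood  # in-plane window only
    num = ndimage.uniform_filter(flipped * fbm, size=size, mode="constant")
    den = ndimage.uniform_filter(fbm, size=size, mode="constant")
    with np.errstate(divide="ignore", invalid="ignore"):
        mirror_mean = np.where(den > 0, num / den, np.nan)
        ratio = 100.0 * data / mirror_mean
    fit_mask = bm & (den > 0) & np.isfinite(mirror_mean) & (mirror_mean > 0)
    values = np.where(fit_mask, ratio, np.nan)
    return ParamMap(
        values,
        "perfusion_ratio",
        "% contralateral",
        fit_mask,
        meta={"neighborhood": neighborhood, "midline_axis": midline_axis},
    )
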