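"""End-to-end orchestration: simulate -> fit -> segment -> quantify -> report.

The per-subject analysis mirrors the study workflow: the acute
(before-reperfusion) perfusion ratio map defines the hypoperfused
territory and the <57 % core; the penumbra is the mismatch.  Those
acute masks are reused at the after-reperfusion timepoint (the series
are born co-registered).  At 24 h the core is re-segmented from the
fitted T2 map (hyperintensity rule) and the penumbra is the acute
hypoperfused territory minus that subacute core.  Sodium ratios are
measured on the first sodium frame of each timepoint, ADC ratios on the
fitted ADC map, always against the mirrored contralateral ROI.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .images import write_mask, write_series, write_volume
from .lesion import (
    RoiMask,
    mirror_roi,
    segment_core_acute,
    segment_core_subacute,
    segment_hypoperfused,
    segment_penumbra,
)
from .mapfit import fit_adc, fit_t2, perfusion_ratio_map
from .phantom import (
    TIMEPOINT_LABELS,
    TIMEPOINTS,
    PhantomSpec,
    generate_cohort,
)
from .quant import roi_mean, sodium_slope_map, summarize_group

logger = logging.getLogger("penumbra")

__all__ = ["PipelineConfig", "PipelineResult", "analyze_subject", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Thresholds, cohort size and options for a full phantom study run."""

    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    n_subjects: int = 10
    core_perfusion_threshold_pct: float = 57.0
    hypoperfusion_cutoff_pct: float = 90.0
    t2_hyperintensity_k: float = 2.0
    mirror_neighborhood: int = 3
    seed: int | None = None  # overrides phantom.seed when set
    out_dir: str | None = None

    def resolved_spec(self) -> PhantomSpec:
        spec = self.phantom
        if self.seed is not None:
            spec = PhantomSpec.from_dict({**spec.to_dict(), "seed": int(self.seed)})
        return spec

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "phantom"}
        d["phantom"] = self.phantom.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        kwargs = dict(d)
        phantom = kwargs.pop("phantom", None)
        spec = PhantomSpec.from_dict(phantom) if phantom else PhantomSpec()
        return cls(phantom=spec, **kwargs)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class PipelineResult:
    per_subject: pd.DataFrame  # subject x cell ROI means and ratios
    summary: pd.DataFrame  # group table (the Table-1 analogue)
    slope_per_subject: pd.DataFrame  # pre-reperfusion sodium slopes
    masks: dict  # subject -> {name: RoiMask}
    manifest: dict


def _first_sodium_frame(series):
    return series.frame(0)


def analyze_subject(data: dict, brain_mask, ipsi_mask, contra_mask, cfg: PipelineConfig):
    """Run fitting + segmentation + ROI quantification for one subject.

    ``data`` maps timepoint -> modality -> image, as produced by
    :func:`penumbra.phantom.generate_subject` (or read back from disk).
    Returns ``(rows, slope_rows, masks)``.
    """
    if "pre" not in data:
        raise ValueError("the before-reperfusion timepoint is required for segmentation")
    rows, slope_rows = [], []

    perf_map = perfusion_ratio_map(
        data["pre"]["perfusion"],
        brain_mask,
        midline_axis=cfg.phantom.midline_axis,
        neighborhood=cfg.mirror_neighborhood,
    )
    ipsi_brain = np.asarray(ipsi_mask, bool) & np.asarray(brain_mask, bool)
    contra_brain = np.asarray(contra_mask, bool) & np.asarray(brain_mask, bool)
    hypo = segment_hypoperfused(
        perf_map, ipsi_brain, cfg.hypoperfusion_cutoff_pct, timepoint="pre"
    )
    core_acute = segment_core_acute(
        perf_map, ipsi_brain, cfg.core_perfusion_threshold_pct, timepoint="pre"
    )
    # the <57% set is nested in the <cutoff set; component selection keeps
    # the same lesion blob, but intersect defensively so the mask algebra
    # (core | penumbra == hypoperfused) holds on every subject
    core_acute = RoiMask(core_acute.mask & hypo.mask, "core", "pre")
    penumbra_acute = segment_penumbra(hypo, core_acute)
    masks = {"hypoperfused": hypo, "core_acute": core_acute, "penumbra_acute": penumbra_acute}

    region_masks = {
        "pre": {"core": core_acute, "penumbra": penumbra_acute},
        "post": {"core": core_acute, "penumbra": penumbra_acute},
    }
    if "h24" in data:
        t2_map = fit_t2(data["h24"]["msme"], brain_mask)
        core_sub = segment_core_subacute(
            t2_map, contra_brain, ipsi_brain, cfg.t2_hyperintensity_k, timepoint="h24"
        )
        penumbra_sub = RoiMask(hypo.mask & ~core_sub.mask, "penumbra", "h24")
        masks["core_subacute"] = core_sub
        masks["penumbra_subacute"] = penumbra_sub
        region_masks["h24"] = {"core": core_sub, "penumbra": penumbra_sub}

    for tp, regions in region_masks.items():
        if tp not in data:
            continue
        adc_map = fit_adc(data[tp]["dwi"], brain_mask)
        sodium_img = _first_sodium_frame(data[tp]["sodium"])
        for region, roi in regions.items():
            if not roi.mask.any():
                logger.warning("empty %s mask at %s; cell skipped", region, tp)
                continue
            mroi = mirror_roi(roi, cfg.phantom.midline_axis)
            for quantity, image in (("adc", adc_map), ("sodium", sodium_img)):
                rows.append(
                    {
                        "timepoint": tp,
                        "quantity": quantity,
                        "region": region,
                        "ipsi_mean": roi_mean(image, roi),
                        "contra_mean": roi_mean(image, mroi),
                    }
                )

    # Pre-reperfusion sodium slope map, normalized to the mirrored acute
    # core (the contralateral caudate-putamen territory).
    if core_acute.mask.any():
        reference = mirror_roi(core_acute, cfg.phantom.midline_axis)
        slope_map = sodium_slope_map(data["pre"]["sodium"], reference, brain_mask)
        for region, roi in (("core", core_acute), ("penumbra", penumbra_acute)):
            if roi.mask.any():
                sel = roi.mask & slope_map.fit_mask
                slope_rows.append(
                    {
                        "region": region,
                        "mean_slope_pct_per_h": float(slope_map.values[sel].mean()),
                        "n_voxels": int(sel.sum()),
                    }
                )
    return rows, slope_rows, masks


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Simulate the cohort and run the full analysis; optionally write outputs."""
    spec = config.resolved_spec()
    logger.info(
        "pipeline thresholds: core <%s%% perfusion, hypoperfusion cutoff %s%%, "
        "T2 hyperintensity k=%s, mirror neighbourhood %s, seed=%s",
        config.core_perfusion_threshold_pct,
        config.hypoperfusion_cutoff_pct,
        config.t2_hyperintensity_k,
        config.mirror_neighborhood,
        spec.seed,
    )
    all_rows, all_slopes, all_masks = [], [], {}
    out_dir = Path(config.out_dir) if config.out_dir else None
    for idx, data, gt in generate_cohort(spec, config.n_subjects):
        rows, slope_rows, masks = analyze_subject(
            data,
            gt.masks["brain"],
            gt.masks["ipsi_hemisphere"],
            gt.masks["contra_hemisphere"],
            config,
        )
        for r in rows:
            r["subject"] = idx + 1
        for r in slope_rows:
            r["subject"] = idx + 1
        all_rows.extend(rows)
        all_slopes.extend(slope_rows)
        all_masks[idx + 1] = masks
        if out_dir is not None:
            _write_subject(out_dir, idx + 1, data, gt, masks, spec)

    per_subject = pd.DataFrame(all_rows)
    summary = summarize_group(per_subject)
    slope_df = pd.DataFrame(all_slopes)
    slope_summary = (
        slope_df.groupby("region", sort=False)["mean_slope_pct_per_h"]
        .agg(["mean", "std", "count"])
        .reset_index()
        if len(slope_df)
        else pd.DataFrame()
    )
    manifest = _manifest(config, spec, per_subject, summary)
    result = PipelineResult(per_subject, summary, slope_df, all_masks, manifest)
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        per_subject.to_csv(out_dir / "per_subject.csv", index=False)
        summary.to_csv(out_dir / "summary.csv", index=False)
        slope_df.to_csv(out_dir / "slopes_per_subject.csv", index=False)
        if len(slope_summary):
            slope_summary.to_csv(out_dir / "slopes_summary.csv", index=False)
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
    return result


def _manifest(config, spec, per_subject, summary) -> dict:
    payload = (
        per_subject.to_csv(index=False) + summary.to_csv(index=False)
    ).encode()
    return {
        "package_version": __version__,
        "config": _drop_out_dir(config.to_dict()),
        "seed": int(spec.seed),
        "n_subjects": int(config.n_subjects),
        "thresholds": {
            "core_perfusion_threshold_pct": config.core_perfusion_threshold_pct,
            "hypoperfusion_cutoff_pct": config.hypoperfusion_cutoff_pct,
            "t2_hyperintensity_k": config.t2_hyperintensity_k,
        },
        "results_sha256": hashlib.sha256(payload).hexdigest(),
    }


def _drop_out_dir(d: dict) -> dict:
    d = dict(d)
    d.pop("out_dir", None)
    return d


def _write_subject(out_dir: Path, subject: int, data, gt, masks, spec) -> None:
    sdir = out_dir / f"sub-{subject:02d}"
    for tp, modalities in data.items():
        tdir = sdir / tp
        tdir.mkdir(parents=True, exist_ok=True)
        for name, img in modalities.items():
            if hasattr(img, "frames"):
                write_series(img, tdir / f"{name}.nii")
            else:
                write_volume(img, tdir / f"{name}.nii")
    mdir = sdir / "masks"
    mdir.mkdir(parents=True, exist_ok=True)
    for name, roi in masks.items():
        write_mask(
            roi.mask, roi.label, spec.voxel_size_mm, mdir / f"{name}.nii",
            meta={"timepoint": roi.timepoint},
        )
    for name in ("core", "penumbra", "hypoperfused", "brain"):
        write_mask(gt.masks[name], name, spec.voxel_size_mm, mdir / f"truth_{name}.nii")
    with open(sdir / "ground_truth.json", "w") as fh:
        json.dump({"ratios": gt.ratios, "scale": gt.scale}, fh, indent=1, sort_keys=True)


def table1_report(summary: pd.DataFrame) -> pd.DataFrame:
    """Reshape the group summary into the study's wide table layout."""
    rows = []
    for quantity in ("sodium", "adc"):
        for region in ("penumbra", "core"):
            row = {"measure": f"{quantity.upper() if quantity=='adc' else quantity.capitalize()} {region} (%contr.)"}
            for tp in TIMEPOINTS:
                cell = summary[
                    (summary.quantity == quantity)
                    & (summary.region == region)
                    & (summary.timepoint == tp)
                ]
                if len(cell):
                    c = cell.iloc[0]
                    star = "*" if c.significant else ""
                    row[TIMEPOINT_LABELS[tp] + f" (N={int(c.n)})"] = (
                        f"{c.mean_ratio_pct:.0f} ± {c.sem_pct:.0f}{star}"
                    )
            rows.append(row)
    return pd.DataFrame(rows)
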