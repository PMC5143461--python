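"""Synthetic multinuclear stroke phantom.

Generates co-registered diffusion-, T2-, perfusion- and sodium-weighted
image series for virtual subjects at three timepoints around transient
middle-cerebral-artery occlusion (before reperfusion, shortly after
reperfusion, 24 h after reperfusion), together with ground-truth masks
and realized tissue parameters, so the downstream fitting, segmentation
and quantification stages can be tested without any acquired data.

The anatomy is a stylized 2-D coronal slice: an elliptical brain with a
vertical midline, a dorsal cortical band and one caudate-putamen disc
per hemisphere.  The lesion occupies the right hemisphere: the
hypoperfused territory spans the right cortex plus the right caudate
putamen, and the core is confined to the caudate putamen — matching the
histological pattern of a 90-min filament occlusion in rat, where the
final infarct sits in the caudate putamen while the overlying cortex is
salvaged penumbra.

Signal models are the standard closed forms for each contrast:

* diffusion:   S(b)  = S0 * exp(-b * ADC)
* spin echo:   S(TE) = S0 * exp(-TE / T2)
* sodium:      S(t)  = (C + r * (t - t_ref)/60) * exp(-TE / T2*)

where C is the tissue sodium level in percent of the contralateral
caudate putamen and r the pre-reperfusion drift in percent of the
contralateral level per hour (so r is, by construction, the value a
contralaterally-normalized slope map reads out).  Every signal is
multiplied by a smooth coil-sensitivity field that is exactly
mirror-symmetric about the midline — contralateral normalization then
cancels it — and corrupted with Rician (magnitude-MRI) noise.

Between-subject biology is emulated by drawing each compartment's
ipsilateral/contralateral ratio per subject from a normal law whose
mean and spread default to the group dynamics of the tMCAO study the
phantom is parameterized from.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import yaml

from .images import ImageSeries, ImageVolume, mirror

__all__ = [
    "TIMEPOINTS",
    "TIMEPOINT_LABELS",
    "QUANTITIES",
    "REGIONS",
    "PhantomSpec",
    "GroundTruth",
    "default_lesion_ratios",
    "default_baseline",
    "compartment_masks",
    "coil_profile",
    "signal_dwi",
    "signal_msme",
    "signal_sodium",
    "add_rician_noise",
    "generate_subject",
    "generate_cohort",
]

#: Study timepoints: before reperfusion (90-min occlusion), shortly after
#: reperfusion, and 24 h after reperfusion.
TIMEPOINTS = ("pre", "post", "h24")
TIMEPOINT_LABELS = {
    "pre": "before reperfusion",
    "post": "after reperfusion",
    "h24": "24 h after reperfusion",
}
QUANTITIES = ("sodium", "adc", "t2", "perfusion")
REGIONS = ("core", "penumbra")


def default_lesion_ratios() -> dict:
    """Per-compartment ipsi/contra ratio dynamics (% contralateral).

    ``mean`` entries are ordered (pre, post, 24h).  Sodium and ADC means
    are the group values of the tMCAO study; their ``sd`` entries are the
    printed between-animal spreads (the study's printed p-values are only
    consistent with reading its "±" numbers as per-subject SDs, see
    docs/methods.md).  T2 and perfusion dynamics are not tabulated in the
    study and carry literature-typical values: perfusion in the core sits
    well below the 57 % viability line before reperfusion and the
    penumbra between that line and the hypoperfusion cutoff; T2 rises in
    the core only at 24 h (vasogenic edema).
    """
    return {
        "sodium": {
            "core": {"mean": [101.0, 123.0, 168.0], "sd": [8.0, 14.0, 27.0]},
            "penumbra": {"mean": [88.0, 98.0, 105.0], "sd": [14.0, 11.0, 16.0]},
        },
        "adc": {
            "core": {"mean": [68.0, 67.0, 80.0], "sd": [7.0, 15.0, 10.0]},
            "penumbra": {"mean": [91.0, 95.0, 96.0], "sd": [7.0, 5.0, 3.0]},
        },
        "t2": {
            "core": {"mean": [100.0, 108.0, 135.0], "sd": [2.0, 4.0, 8.0]},
            "penumbra": {"mean": [100.0, 100.0, 102.0], "sd": [2.0, 2.0, 3.0]},
        },
        "perfusion": {
            "core": {"mean": [40.0, 75.0, 90.0], "sd": [5.0, 5.0, 4.0]},
            "penumbra": {"mean": [70.0, 85.0, 95.0], "sd": [5.0, 5.0, 3.0]},
        },
    }


def default_baseline() -> dict:
    """Absolute contralateral tissue values (the study reports only ratios)."""
    return {
        "adc_mm2_s": 0.75e-3,  # healthy rat brain water diffusivity
        "t2_ms": 50.0,  # at 9.4 T
        "t2star_ms": 7.0,  # sodium effective T2*, mid-range of 5-9 ms
        "sodium_au": 100.0,
        "perfusion_au": 100.0,
        "s0_dwi": 1000.0,
        "s0_msme": 1000.0,
    }


def default_noise_sigma() -> dict:
    """Rician sigma per modality, relative to the contralateral mean signal.

    0.05 puts the contralateral ROI-mean SNR near 20 for every contrast.
    """
    return {"dwi": 0.05, "msme": 0.05, "sodium": 0.05, "perfusion": 0.05}


@dataclass
class PhantomSpec:
    """Full parameterization of the synthetic stroke brain."""

    grid_shape: tuple = (64, 64)
    voxel_size_mm: tuple = (0.5, 0.5)
    midline_axis: int = 0
    lesion_side: str = "right"  # high-index half of the midline axis
    brain_semiaxes_vox: tuple = (27.0, 23.0)
    cortex_min_index: int = 40  # dorsal band: axis-1 index >= this
    cpu_center_vox: tuple = (44.0, 32.0)  # ipsilateral caudate putamen
    cpu_radius_vox: float = 8.5
    baseline: dict = field(default_factory=default_baseline)
    lesion_ratios: dict = field(default_factory=default_lesion_ratios)
    # Pre-reperfusion sodium drift in % of the contralateral caudate-putamen
    # level per hour: +20 in the subcortical core territory, -10 in the
    # ipsilateral upper cortex, 0 elsewhere.
    drift_core_pct_per_h: float = 20.0
    drift_cortex_pct_per_h: float = -10.0
    # Acquisition protocol
    b_values: tuple = (530.0, 1079.0)  # s/mm^2
    n_b0: int = 5
    n_directions: int = 3
    echo_times_ms: tuple = tuple(11.0 * (k + 1) for k in range(16))  # 11-176 ms
    sodium_te_ms: float = 2.9
    sodium_times_min: tuple = tuple(float(t) for t in np.linspace(15.0, 80.0, 9))
    noise_sigma: dict = field(default_factory=default_noise_sigma)
    coil_amplitude: float = 0.15
    coil_sigma_vox: tuple = (30.0, 35.0)
    coil_center_index: float = 45.0  # axis-1 position of peak sensitivity
    subject_scale_sd: float = 0.03  # global amplitude jitter (coil loading)
    timepoints: tuple = TIMEPOINTS
    survivors: tuple = (1, 2, 3, 7, 9, 10)  # 1-based subjects with 24 h data
    seed: int = 0

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        if len(self.grid_shape) not in (2, 3) or any(
            int(n) < 16 for n in self.grid_shape[:2]
        ):
            raise ValueError(f"grid_shape must be >=16 per axis, got {self.grid_shape}")
        if self.lesion_side not in ("left", "right"):
            raise ValueError("lesion_side must be 'left' or 'right'")
        for mod, sig in self.noise_sigma.items():
            if sig < 0:
                raise ValueError(f"noise_sigma[{mod!r}] must be >= 0, got {sig}")
        if self.cpu_radius_vox <= 0:
            raise ValueError("cpu_radius_vox must be positive")
        if not (0 < self.cortex_min_index < self.grid_shape[1]):
            raise ValueError("cortex_min_index outside the grid")
        masks = compartment_masks(self)
        if not masks["core"].any():
            raise ValueError("core compartment is empty (caudate putamen outside brain?)")
        if not (masks["core"] <= masks["hypoperfused"]).all():
            raise ValueError("core must be a subset of the hypoperfused territory")
        if (masks["core"] & ~masks["ipsi_hemisphere"]).any():
            raise ValueError("core crosses the midline; move cpu_center_vox")
        for q in QUANTITIES:
            for r in REGIONS:
                entry = self.lesion_ratios[q][r]
                if len(entry["mean"]) != len(TIMEPOINTS) or len(entry["sd"]) != len(
                    TIMEPOINTS
                ):
                    raise ValueError(f"lesion_ratios[{q}][{r}] needs one value per timepoint")

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        def conv(v):
            if isinstance(v, tuple):
                return [conv(x) for x in v]
            if isinstance(v, dict):
                return {k: conv(x) for k, x in v.items()}
            if isinstance(v, (np.floating, np.integer)):
                return v.item()
            return v

        return {k: conv(v) for k, v in self.__dict__.items()}

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        kwargs = dict(d)
        for key in (
            "grid_shape",
            "voxel_size_mm",
            "brain_semiaxes_vox",
            "cpu_center_vox",
            "b_values",
            "echo_times_ms",
            "sodium_times_min",
            "coil_sigma_vox",
            "timepoints",
            "survivors",
        ):
            if key in kwargs and isinstance(kwargs[key], list):
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PhantomSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def sham(self) -> "PhantomSpec":
        """A no-lesion copy: all ratios 100 %, no drift, no spread."""
        out = copy.deepcopy(self)
        for q in QUANTITIES:
            for r in REGIONS:
                out.lesion_ratios[q][r]["mean"] = [100.0] * len(TIMEPOINTS)
                out.lesion_ratios[q][r]["sd"] = [0.0] * len(TIMEPOINTS)
        out.drift_core_pct_per_h = 0.0
        out.drift_cortex_pct_per_h = 0.0
        return out


# ---------------------------------------------------------------------------
# Geometry


def _grids(spec: PhantomSpec):
    nx, ny = int(spec.grid_shape[0]), int(spec.grid_shape[1])
    i = np.arange(nx, dtype=float)[:, None]
    j = np.arange(ny, dtype=float)[None, :]
    return nx, ny, i, j


def _expand_slices(mask2d: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    if len(spec.grid_shape) == 3:
        return np.repeat(mask2d[:, :, None], int(spec.grid_shape[2]), axis=2)
    return mask2d


def compartment_masks(spec: PhantomSpec) -> dict:
    """Boolean masks for every anatomical/lesion compartment.

    The lesion masks partition: ``core | penumbra == hypoperfused`` and
    ``core & penumbra`` is empty, with everything confined to the
    ipsilateral hemisphere.  Mirror masks are exact reflections.
    """
    nx, ny, i, j = _grids(spec)
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    ax, ay = spec.brain_semiaxes_vox
    full = np.ones((nx, ny), dtype=bool)
    brain = ((i - cx) / ax) ** 2 + ((j - cy) / ay) ** 2 <= 1.0
    ipsi = ((i > cx) if spec.lesion_side == "right" else (i < cx)) & full
    # centre column (odd grids only) belongs to neither hemisphere
    contra = ((i < cx) if spec.lesion_side == "right" else (i > cx)) & full
    cortex = brain & (j >= spec.cortex_min_index)
    pi, pj = spec.cpu_center_vox
    cpu_ipsi = ((i - pi) ** 2 + (j - pj) ** 2 <= spec.cpu_radius_vox**2) & brain
    core = cpu_ipsi & ipsi
    penumbra = cortex & ipsi & ~core
    hypo = core | penumbra
    masks = {
        "brain": brain,
        "ipsi_hemisphere": ipsi,
        "contra_hemisphere": contra,
        "cortex": cortex,
        "core": core,
        "penumbra": penumbra,
        "hypoperfused": hypo,
        "core_mirror": mirror(core, spec.midline_axis),
        "penumbra_mirror": mirror(penumbra, spec.midline_axis),
        "hypoperfused_mirror": mirror(hypo, spec.midline_axis),
    }
    return {k: _expand_slices(v, spec) for k, v in masks.items()}


def coil_profile(spec: PhantomSpec) -> np.ndarray:
    """Smooth multiplicative sensitivity field, mirror-symmetric exactly.

    Built from |i - centre| so that ``coil == mirror(coil)`` holds to the
    bit, which is what lets contralateral normalization cancel it.
    """
    nx, ny, i, j = _grids(spec)
    cx = (nx - 1) / 2.0
    sx, sy = spec.coil_sigma_vox
    d2 = (np.abs(i - cx) / sx) ** 2 + ((j - spec.coil_center_index) / sy) ** 2
    return _expand_slices(1.0 + spec.coil_amplitude * np.exp(-d2), spec)


# ---------------------------------------------------------------------------
# Signal models


def _check_nonneg(**kwargs):
    for name, val in kwargs.items():
        if np.any(np.asarray(val) < 0):
            raise ValueError(f"{name} must be non-negative")


def signal_dwi(s0, adc, b):
    """Mono-exponential diffusion attenuation ``S0 * exp(-b * ADC)``."""
    _check_nonneg(s0=s0, adc=adc, b=b)
    return s0 * np.exp(-np.asarray(b, dtype=float) * adc)


def signal_msme(s0, t2_ms, te_ms):
    """Spin-echo decay ``S0 * exp(-TE / T2)``; T2 may be ``np.inf``."""
    _check_nonneg(s0=s0, te_ms=te_ms)
    if np.any(np.asarray(t2_ms) <= 0):
        raise ValueError("t2_ms must be positive")
    return s0 * np.exp(-np.asarray(te_ms, dtype=float) / t2_ms)


def signal_sodium(
    concentration_rel,
    t2star_ms,
    te_ms=2.9,
    t_minutes=0.0,
    drift_rate_pct_per_h=0.0,
    t_ref_minutes=0.0,
):
    """Sodium signal with linear-in-time drift and T2* attenuation.

    ``concentration_rel`` is the tissue sodium level in percent of the
    contralateral reference and ``drift_rate_pct_per_h`` the drift in the
    same normalized units per hour, so the contralaterally-normalized
    slope map recovers the drift rate directly.
    """
    _check_nonneg(te_ms=te_ms)
    if np.any(np.asarray(t2star_ms) <= 0):
        raise ValueError("t2star_ms must be positive")
    dt_h = (np.asarray(t_minutes, dtype=float) - t_ref_minutes) / 60.0
    level = concentration_rel + np.asarray(drift_rate_pct_per_h) * dt_h
    return level * np.exp(-np.asarray(te_ms, dtype=float) / t2star_ms)


def add_rician_noise(image, sigma, rng):
    """Magnitude of a complex Gaussian perturbation of ``image``.

    The noiseless image is taken as the real channel; output is always
    non-negative and equals the input exactly when ``sigma == 0``.
    """
    image = np.asarray(image, dtype=float)
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return image.copy()
    re = image + sigma * rng.standard_normal(image.shape)
    im = sigma * rng.standard_normal(image.shape)
    return np.hypot(re, im)


# ---------------------------------------------------------------------------
# Ground truth


@dataclass
class GroundTruth:
    """Masks and realized (post between-subject-draw, pre-noise) parameters."""

    masks: dict
    ratios: dict  # quantity -> region -> timepoint -> % contralateral
    scale: float  # subject-global amplitude factor
    spec: PhantomSpec

    def ratio_map(self, quantity: str, timepoint: str) -> np.ndarray:
        """Voxel map of the true ipsi/contra ratio in %, 100 in healthy tissue."""
        out = np.full(self.masks["brain"].shape, 100.0)
        out[self.masks["penumbra"]] = self.ratios[quantity]["penumbra"][timepoint]
        out[self.masks["core"]] = self.ratios[quantity]["core"][timepoint]
        return out

    def true_map(self, quantity: str, timepoint: str) -> np.ndarray:
        """Voxel map of the true quantity in absolute units (ADC mm^2/s, T2 ms...)."""
        base = {
            "adc": self.spec.baseline["adc_mm2_s"],
            "t2": self.spec.baseline["t2_ms"],
            "sodium": self.spec.baseline["sodium_au"],
            "perfusion": self.spec.baseline["perfusion_au"],
        }[quantity]
        return base * self.ratio_map(quantity, timepoint) / 100.0

    def drift_map(self) -> np.ndarray:
        """Pre-reperfusion sodium drift in % of contralateral per hour."""
        out = np.zeros(self.masks["brain"].shape)
        out[self.masks["penumbra"]] = self.spec.drift_cortex_pct_per_h
        out[self.masks["core"]] = self.spec.drift_core_pct_per_h
        return out


# ---------------------------------------------------------------------------
# Subject generation


def _rng(spec: PhantomSpec, subject_index: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(spec.seed), int(subject_index), int(stream)])


_STREAM_RATIOS = 0
_STREAM_NOISE_BASE = 100  # + 10*timepoint + modality index


def _draw_ground_truth(spec: PhantomSpec, subject_index: int) -> GroundTruth:
    rng = _rng(spec, subject_index, _STREAM_RATIOS)
    ratios: dict = {}
    for q in QUANTITIES:  # fixed draw order => reproducible regardless of use
        ratios[q] = {}
        for r in REGIONS:
            ratios[q][r] = {}
            for k, tp in enumerate(TIMEPOINTS):
                m = spec.lesion_ratios[q][r]["mean"][k]
                s = spec.lesion_ratios[q][r]["sd"][k]
                ratios[q][r][tp] = float(np.clip(rng.normal(m, s), 5.0, 400.0))
    scale = float(max(0.1, 1.0 + spec.subject_scale_sd * rng.standard_normal()))
    return GroundTruth(compartment_masks(spec), ratios, scale, spec)


def _contra_brain(gt: GroundTruth) -> np.ndarray:
    return gt.masks["brain"] & gt.masks["contra_hemisphere"]


def _noisy_series(frames, sigma_abs, rng):
    return np.stack([add_rician_noise(f, sigma_abs, rng) for f in frames], axis=-1)


def _make_dwi(spec, gt, coil, tp, rng) -> ImageSeries:
    adc = gt.true_map("adc", tp)
    s0 = spec.baseline["s0_dwi"] * gt.scale * coil
    b_per_frame = [0.0] * spec.n_b0
    dirs: list = [None] * spec.n_b0
    unit = [(1.0, 0.0, 0.0), (0.0, 1.0, 0.0), (0.0, 0.0, 1.0)]
    for b in spec.b_values:
        for d in range(spec.n_directions):
            b_per_frame.append(float(b))
            dirs.append(list(unit[d % 3]))
    # isotropic diffusion: all directions share one signal
    frames = [signal_dwi(s0, adc, b) for b in b_per_frame]
    sigma = spec.noise_sigma["dwi"] * float(frames[0][_contra_brain(gt)].mean())
    return ImageSeries(
        frames=_noisy_series(frames, sigma, rng),
        voxel_size_mm=spec.voxel_size_mm,
        modality="dwi",
        frame_meta={"b_value": b_per_frame, "direction": dirs},
        meta={"timepoint": tp, "noise_sigma_abs": sigma},
    )


def _make_msme(spec, gt, coil, tp, rng) -> ImageSeries:
    t2 = gt.true_map("t2", tp)
    s0 = spec.baseline["s0_msme"] * gt.scale * coil
    te = [float(t) for t in spec.echo_times_ms]
    frames = [signal_msme(s0, t2, t) for t in te]
    sigma = spec.noise_sigma["msme"] * float(frames[0][_contra_brain(gt)].mean())
    return ImageSeries(
        frames=_noisy_series(frames, sigma, rng),
        voxel_size_mm=spec.voxel_size_mm,
        modality="msme",
        frame_meta={"te_ms": te},
        meta={"timepoint": tp, "noise_sigma_abs": sigma},
    )


def _make_sodium(spec, gt, coil, tp, rng) -> ImageSeries:
    level = gt.true_map("sodium", tp)  # a.u., contralateral == 100
    att = gt.scale * coil
    if tp == "pre":
        times = [float(t) for t in spec.sodium_times_min]
        drift_au = gt.drift_map() * spec.baseline["sodium_au"] / 100.0
    else:
        times = [0.0]
        drift_au = np.zeros_like(level)
    t_ref = times[0]
    frames = [
        att
        * signal_sodium(
            level,
            spec.baseline["t2star_ms"],
            spec.sodium_te_ms,
            t_minutes=t,
            drift_rate_pct_per_h=drift_au,
            t_ref_minutes=t_ref,
        )
        for t in times
    ]
    sigma = spec.noise_sigma["sodium"] * float(frames[0][_contra_brain(gt)].mean())
    return ImageSeries(
        frames=_noisy_series(frames, sigma, rng),
        voxel_size_mm=spec.voxel_size_mm,
        modality="sodium",
        frame_meta={"time_min": times},
        meta={
            "timepoint": tp,
            "te_ms": spec.sodium_te_ms,
            "t_ref_min": t_ref,
            "noise_sigma_abs": sigma,
        },
    )


def _make_perfusion(spec, gt, coil, tp, rng) -> ImageVolume:
    # Emitted directly as the perfusion-weighted (control - label) image;
    # full FAIR inversion-recovery modelling is out of scope.
    perf = gt.true_map("perfusion", tp) * gt.scale * coil
    sigma = spec.noise_sigma["perfusion"] * float(perf[_contra_brain(gt)].mean())
    return ImageVolume(
        data=add_rician_noise(perf, sigma, rng),
        voxel_size_mm=spec.voxel_size_mm,
        modality="perfusion",
        meta={"timepoint": tp, "noise_sigma_abs": sigma},
    )


_MODALITY_STREAMS = {"dwi": 1, "msme": 2, "sodium": 3, "perfusion": 4}


def generate_subject(spec: PhantomSpec, subject_index: int, timepoints=None):
    """Simulate one virtual subject.

    Returns ``(data, ground_truth)`` where ``data[timepoint][modality]``
    holds the :class:`~penumbra.images.ImageSeries` (or ``ImageVolume``
    for perfusion).  Identical ``(spec, subject_index)`` yield
    bit-identical output; random draws for the tissue ratios are made in
    a fixed order so that restricting ``timepoints`` does not change
    them.
    """
    if subject_index < 0:
        raise ValueError("subject_index must be >= 0")
    spec.validate()
    gt = _draw_ground_truth(spec, subject_index)
    coil = coil_profile(spec)
    tps = tuple(timepoints) if timepoints is not None else tuple(spec.timepoints)
    data: dict = {}
    for tp in tps:
        if tp not in TIMEPOINTS:
            raise ValueError(f"unknown timepoint {tp!r}")
        tpi = TIMEPOINTS.index(tp)
        data[tp] = {}
        for modality, maker in (
            ("dwi", _make_dwi),
            ("msme", _make_msme),
            ("sodium", _make_sodium),
            ("perfusion", _make_perfusion),
        ):
            stream = _STREAM_NOISE_BASE + 10 * tpi + _MODALITY_STREAMS[modality]
            data[tp][modality] = maker(spec, gt, coil, tp, _rng(spec, subject_index, stream))
    return data, gt


def subject_timepoints(spec: PhantomSpec, subject_index: int) -> tuple:
    """Timepoints acquired for this subject (non-survivors miss the 24 h scan)."""
    if (subject_index + 1) in tuple(spec.survivors):
        return tuple(spec.timepoints)
    return tuple(tp for tp in spec.timepoints if tp != "h24")


def generate_cohort(spec: PhantomSpec, n_subjects: int):
    """Yield ``(subject_index, data, ground_truth)`` honouring 24 h dropout."""
    for idx in range(int(n_subjects)):
        tps = subject_timepoints(spec, idx)
        data, gt = generate_subject(spec, idx, timepoints=tps)
        yield idx, data, gt
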