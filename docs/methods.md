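# Methods

## What the package computes

`penumbra-mri` implements the image-analysis chain used in pre-clinical
transient-ischemia (tMCAO) studies that combine hydrogen diffusion and
perfusion MRI with sodium (²³Na) MRI:

1. **Parameter maps.** Voxelwise apparent diffusion coefficient (ADC,
   mm²/s) from a multi-b-value diffusion series; voxelwise T2 (ms) from a
   multi-echo spin-echo series; a perfusion ratio map in percent of the
   homologous contralateral tissue.
2. **Lesion segmentation.** Acute core = perfusion strictly below 57 % of
   contralateral; subacute (24 h) core = T2 above the contralateral mean
   plus k·SD (k = 2 by default); hypoperfused territory = perfusion below
   an outer cutoff (90 % by default); penumbra = the perfusion–diffusion
   mismatch, hypoperfused minus core. Each thresholded mask keeps its
   largest connected component — a deterministic, reproducible stand-in
   for the manual ROI drawing used in animal studies.
3. **Quantification.** Every readout is normalized to the mirrored
   contralateral ROI (ipsilateral / contralateral × 100), which cancels
   any mirror-symmetric coil-sensitivity profile. The pre-reperfusion
   sodium time series (9 frames, 15–80 min after occlusion) yields a
   per-voxel slope map in %/h after frame-wise normalization to the
   contralateral caudate-putamen ROI. Group cells are mean ± SEM with a
   paired two-sided Student t-test between ipsilateral and contralateral
   ROI means (p ≤ 0.05 flags significance, no multiple-testing
   correction, matching common practice in this literature).

Because no animal data are redistributable, the package ships a
first-class synthetic phantom whose ground truth is parameterized from
the published group dynamics, and the test suite checks that the full
pipeline *recovers* those planted values.

## The phantom

A stylized 2-D coronal slice (64×64, 0.5 mm in-plane): an elliptical
brain, a vertical midline between the two central columns, a dorsal
cortical band (rows ≥ 40) and one caudate-putamen disc per hemisphere
(radius 8.5 vox). The right hemisphere is lesioned: the hypoperfused
territory is the right cortex plus right caudate putamen (the disc
touches the cortical band, so the territory is one connected component),
the core is the caudate-putamen disc, the penumbra the cortical band —
mirroring the histological outcome of a 90-min filament occlusion, where
the infarct consolidates subcortically while the cortex is salvaged.

Signal models per voxel (all closed-form, no k-space simulation):

* DWI: S(b) = S0·exp(−b·ADC); five b = 0 acquisitions plus b = 530 and
  1079 s/mm², three directions each. Diffusion is simulated isotropic
  (directions share one signal) because the readout is the
  direction-averaged scalar ADC.
* Spin echo: S(TE) = S0·exp(−TE/T2), 16 echoes, TE = 11–176 ms.
* Sodium: S(t) = (C + r·Δt)·exp(−TE/T2*), TE = 2.9 ms, T2* = 7 ms
  (mid-range of the 5–9 ms reported for rodent brain at 9.4 T). C is the
  tissue sodium level in % of the contralateral caudate putamen; the
  drift r is expressed in the same normalized units per hour, so the
  planted value is exactly what a contralaterally-normalized slope map
  measures: +20 %/h in the core territory, −10 %/h in the ipsilateral
  upper cortex, 0 elsewhere, over 9 frames spanning 15–80 min.
* Perfusion: emitted directly as the perfusion-weighted (control−label)
  difference image scaled by the planted perfusion ratio; ASL
  inversion-recovery kinetics are out of scope.

Every signal is multiplied by a smooth coil-sensitivity field built from
|x − midline|, hence *exactly* mirror-symmetric, and corrupted with
Rician noise (magnitude of a complex Gaussian) with σ = 5 % of the
contralateral mean signal per modality, i.e. contralateral SNR ≈ 20 —
the study states no SNR; this choice makes ROI-scale noise a small
contributor next to between-subject spread.

### Planted dynamics and between-subject variability

Sodium and ADC core/penumbra ratios at the three timepoints default to
the published group means (sodium penumbra 88/98/105, sodium core
101/123/168, ADC penumbra 91/95/96, ADC core 68/67/80 % contralateral).
Each subject draws every compartment ratio from a normal law centred on
those means.

The spread of that law is set to the published "±" values (e.g. 14 for
sodium penumbra before reperfusion). Although the table legend calls
those numbers SEMs, they are only statistically consistent with the
table's own p-values and significance stars when read as per-subject
SDs: "98 ± 11 (p = 0.528)" gives t = 0.18/p = 0.86 if 11 is the SEM but
t ≈ 0.58/p ≈ 0.57 if 11 is the SD; "91 ± 7*" is non-significant
(p = 0.23) under the SEM reading but p = 0.003 under the SD reading, and
the same holds for every starred cell. The generator therefore treats
the printed spreads as between-subject SDs.

T2 dynamics (core 100/108/135 %, penumbra 100/100/102 %) and perfusion
dynamics (core 40/75/90 %, penumbra 70/85/95 %) are not tabulated in the
source study; the defaults place the acute core well under the 57 % line,
the penumbra between the hypoperfusion cutoff and the core threshold,
and confine substantial T2 elevation (vasogenic edema) to the 24 h core.
Absolute contralateral values (ADC 0.75×10⁻³ mm²/s, T2 50 ms, T2* 7 ms,
sodium/perfusion 100 a.u.) are literature-typical placeholders — only
ratios matter downstream — and all are configurable. A per-subject
global amplitude factor (SD 3 %) emulates coil loading; it cancels in
every ratio.

Cohorts default to n = 10 with subjects 4, 5, 6 and 8 missing the 24 h
scan, reproducing the study's 10/10/6 design. All randomness derives
from `numpy` SeedSequence keys `[seed, subject_index, stream]`, so
identical (spec, subject) pairs are bit-identical and restricting the
simulated timepoints never changes the drawn tissue parameters.

## Numerical choices

* **ADC fit:** plain log-linear OLS over the b-level means (b = 0 frames
  averaged, directions averaged). All b-levels sit far above the noise
  floor at the default SNR, so unweighted OLS is unbiased to < 2 % at ROI
  scale and matches a brute-force grid-search minimizer of the same
  objective to grid resolution (tested).
* **T2 fit:** signal²-weighted log-linear regression — the standard
  linearization of the exponential least-squares problem. Plain log-OLS
  is offered (`weighting="uniform"`) but is noisy here: the last ~4 of
  16 echoes lie near the Rician floor and carry the largest log-domain
  leverage, tripling per-voxel T2 noise and breaking the k·SD
  hyperintensity rule. Both variants are exact on noiseless data.
* **Fit failures:** voxels with non-positive level means, or fits giving
  non-positive ADC/T2, are excluded from the fit mask and set to NaN —
  never silently zero. Per-voxel residual norms are kept as QC.
* **Perfusion ratio:** each voxel is divided by the brain-restricted
  mean of the 3×3 window around its mirrored position (window
  configurable); the neighbourhood suppresses single-voxel noise in the
  denominator. Voxels whose mirrored neighbourhood contains no brain are
  excluded.
* **Thresholds:** strict inequality at 57 % (boundary voxels excluded);
  k = 2 SD for T2 hyperintensity; 90 % hypoperfusion cutoff. The last
  two are conventions, prominently configurable in `PipelineConfig`, as
  the literature states no number for either.
* **Degenerate statistics:** identically-zero paired differences report
  p = 1 with a warning; single-subject cells report SEM 0 with a warning;
  fewer than two pairs is an error.
* **Midline:** a coordinate plane of the grid (mirror is `np.flip`); no
  registration or midline estimation is attempted — phantom series are
  born co-registered.

## What the phantom does and does not emulate

It emulates the acquisition geometry per modality, compartment tissue
dynamics, magnitude (Rician) noise, a symmetric receive profile,
between-subject biology and scan dropout. It does **not** emulate
k-space effects (partial echo, zero-filling), B0 inhomogeneity, motion,
partial-volume mixing at compartment boundaries, asymmetric coil
profiles, or registration error between sessions. Passing recovery
tests therefore demonstrates the correctness and statistical behaviour
of the analysis chain under the stated model, not robustness to those
real-data confounds.

## Problem sizes

The default study — 10 subjects × 3 timepoints on a 64×64 slice, with
11-frame DWI, 16-echo MSME, 9-frame sodium — runs the full pipeline in
well under a minute on one CPU; the replicate-stability check (10 full
cohorts) takes a few seconds more. These sizes were chosen to make the
group statistics meaningful (they reproduce the published design
exactly) while keeping the whole suite interactive.

## Known limitations and open points

* The significance-star stability check across 10 replicate cohorts
  (each cell's paired test matching the published star) passes in about
  6 of 10 replicates at the default settings. This is a power limit
  inherited from the published effect sizes themselves: with the printed
  spreads as between-subject SDs, the weakest cells detect at ~0.7–0.85
  power (sodium penumbra before reperfusion: |Δ| = 12, SD = 14, n = 10
  → non-central t power ≈ 0.70), so the probability that *all twelve*
  cells match in one replicate is ≈ 0.5, and demanding 8/10 replicates
  is beyond what the published variability supports. Shrinking the
  generator's SDs would make the check pass but would no longer
  represent the published data.
* Ratios are drawn independently across timepoints (no within-subject
  longitudinal correlation); only sodium and ADC spreads are anchored to
  published numbers.
* The subacute T2 rule can attach a few noisy cortical voxels to the
  core component along the cortex–caudate bridge; at default noise this
  costs < 0.05 Dice.
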