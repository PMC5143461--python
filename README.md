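# penumbra-mri

Combined sodium (²³Na), diffusion and perfusion MRI analysis of
transient ischemic stroke, built for pre-clinical (rodent tMCAO)
imaging groups who want a tested, scriptable alternative to one-off
analysis scripts — and a synthetic phantom to validate it against.

In acute stroke the perfusion–diffusion mismatch is the standard proxy
for salvageable tissue: the **core** is irreversibly injured (here:
perfusion < 57 % of contralateral acutely, or T2 hyperintensity beyond
contralateral mean + 2 SD subacutely), the **hypoperfused** territory is
everything under an outer perfusion cutoff, and the **penumbra** is the
mismatch between them. Because the apparent diffusion coefficient (ADC)
recovers spontaneously during the subacute phase, total tissue sodium —
which rises monotonically as ion homeostasis fails — is an attractive
time-independent viability marker; this package quantifies both side by
side.

## What it does

* **Phantom** (`penumbra.phantom`) — simulates co-registered multi-b
  DWI (b = 0 ×5, 530, 1079 s/mm², 3 directions), 16-echo spin-echo
  (TE = 11–176 ms), ASL-derived perfusion-weighted images and a 9-frame
  sodium series (TE = 2.9 ms, 15–80 min post-occlusion) for N virtual
  subjects at three timepoints, with ground-truth masks and parameters,
  mirror-symmetric coil profile and Rician noise.
* **Map fitting** (`penumbra.mapfit`) — voxelwise log-linear fits for
  ADC (mm²/s) and T2 (ms), and mirror-neighbourhood perfusion ratio
  maps (% contralateral).
* **Segmentation** (`penumbra.lesion`) — acute/subacute core, the
  hypoperfused territory, the mismatch penumbra, and contralateral
  mirror ROIs, with largest-component cleanup.
* **Quantification** (`penumbra.quant`) — contralateral-normalized ROI
  ratios (ipsi/contra × 100), per-voxel sodium slope maps in %/h, paired
  t-tests and a mean ± SEM group table.
* **Pipeline + CLI** (`penumbra.pipeline`, `penumbra.cli`) — end-to-end
  orchestration with NIfTI + JSON-sidecar I/O, YAML configs and a
  deterministic run manifest.

The model at the core of the quantification, per voxel and ROI:

* S(b) = S0·e^(−b·ADC), S(TE) = S0·e^(−TE/T2) (log-linear LS fits);
* perfusion ratio(x) = 100·P(x) / mean P(mirror-3×3(x));
* sodium slope(x) = OLS slope over time of 100·S(x,t)/mean S(ref,t),
  ref = contralateral caudate putamen, in %/h;
* group cells: mean ± SEM of 100·ipsi/contra across subjects, paired
  two-sided t-test, significance at p ≤ 0.05.

## Worked example

```python
from penumbra.pipeline import PipelineConfig, run_pipeline, table1_report

result = run_pipeline(PipelineConfig(seed=1))   # 10 subjects, 6 survive to 24 h
print(table1_report(result.summary).to_string(index=False))
print(result.slope_per_subject.groupby("region").mean_slope_pct_per_h.mean())
```

prints

```
                  measure before reperfusion (N=10) after reperfusion (N=10) 24 h after reperfusion (N=6)
Sodium penumbra (%contr.)                   83 ± 3*                  103 ± 4                      107 ± 3
    Sodium core (%contr.)                   101 ± 2                 126 ± 5*                     172 ± 7*
   ADC penumbra (%contr.)                   91 ± 3*                  96 ± 1*                      97 ± 1*
       ADC core (%contr.)                   68 ± 2*                  73 ± 4*                      85 ± 4*

region
core        19.656960
penumbra    -9.845096
```

Reading the table: before reperfusion, sodium is *reduced* in the
penumbra (83 %, significant) while core sodium is still normal (101 %) —
the window where low sodium plus moderately low ADC marks salvageable
tissue; after reperfusion core sodium climbs (126 % → 172 % at 24 h) as
membranes fail, while ADC in the core is depressed at every timepoint
(68 → 73 → 85 %, recovering above common viability thresholds by 24 h).
The slope lines are the pre-reperfusion sodium drift: ≈ +20 %/h in the
subcortical core territory and ≈ −10 %/h in the upper cortex. Stars mark
paired ipsi-vs-contra significance (p ≤ 0.05). These group values match
the phantom's planted dynamics — see `docs/methods.md` for what the
phantom does and does not emulate.

The same run from a shell:

```sh
penumbra run-all --subjects 10 --seed 1 --out runs/demo
penumbra report --run runs/demo --out table1.csv
```

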