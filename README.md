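# dwiresponse

Early therapy-response assessment of tumor xenografts from
diffusion-weighted MRI (DW-MRI), as a tested, reusable Python pipeline.

Anti-angiogenic and cytotoxic therapies change tumor microstructure days
before they change tumor size, and the apparent diffusion coefficient
(ADC) measured by DW-MRI is sensitive to exactly that change: cell death
raises water mobility, so the tumor ADC rises under effective therapy
while volume-based criteria still look inconclusive.  `dwiresponse`
implements the full quantitative chain of a two-group (therapy vs.
control) preclinical study built on that idea:

- **ADC mapping** — voxelwise fit of the monoexponential decay
  `S(b) = S0 * exp(-b * ADC)` over a multi-b-value series
  (9 weightings, b = 10…800 s/mm², no b = 0 image, so S0 is free),
- **registration** — translation-only alignment of the series along the
  b-value dimension by Fourier phase correlation with sub-voxel
  refinement, so bulk motion does not corrupt the decay curves,
- **VOI metrics** — median tumor ADC over a 3D volume of interest, voxel-
  count tumor volume from T2-geometry masks, percent growth
  `ΔVOL = 100·(V_F − V_B)/V_B` and ADC change `ΔADC = ADC_F − ADC_B`,
- **statistics** — paired Wilcoxon signed-rank and Mann-Whitney U tests
  (exact at study-sized samples), Pearson correlation, empirical ROC
  curves with Youden-optimal thresholds, DeLong's test for correlated
  AUCs, and a two-class Fisher linear discriminant (FLDA) combining ΔVOL
  and ΔADC into a single score,
- **synthetic data** — DWI phantoms with known ground-truth ADC, Rician
  noise and bulk motion, plus synthetic 12-vs-11 cohorts at the study's
  reported group parameters, so every stage is testable without any
  animal data.

I/O uses standard research-MRI formats: NIfTI-1 volumes and masks with
FSL-style `.bval` or JSON sidecars, CSV cohort tables (plus an XLSX import
helper), all with axis order `(x, y, slice)`.

## Worked example

`examples/synthetic_cohort_analysis.py` generates one synthetic cohort at
the study parameters and runs the complete analysis:

```text
therapy  dADC = +0.112 (SD 0.045) x 1e-3 mm^2/s, dVOL = +56.9 (SD 47.6) %
control  dADC = -0.022 (SD 0.063) x 1e-3 mm^2/s, dVOL = +88.3 (SD 20.0) %
Mann-Whitney p (dADC): 0.0000
Mann-Whitney p (dVOL): 0.0439
AUC(d_adc) = 0.962, optimal threshold 0.0847, sens 83%, spec 100%, accuracy 91%
AUC(d_vol_pct) = 0.750, optimal threshold 70.7, sens 67%, spec 91%, accuracy 78%
AUC(flda) = 0.962, optimal threshold -0.00357, sens 100%, spec 82%, accuracy 91%
FLDA weights: +0.0006 * dVOL[%] -1.0000 * dADC, below-threshold = therapy
DeLong p, FLDA vs dADC: 1.0000
```

Read: in this draw the therapy group's ADC rose by +0.112 × 10⁻³ mm²/s
while its growth (+57 %) lagged the control group's (+88 %); ΔADC alone
already separates the groups (AUC 0.962), volume change alone is weaker
(AUC 0.750), and the FLDA score — a weighted sum dominated here by ΔADC —
classifies with 91 % accuracy at its Youden-optimal threshold ("below
threshold = therapy").  Across many cohorts the expected ordering is
FLDA > ΔVOL > ΔADC in mean AUC; any single 23-animal draw can deviate.

The other examples cover the imaging side:
`phantom_adc_mapping.py` (noisy phantom → 0.15 % median-ADC error at
SNR 50), `registration_demo.py` (injected bulk motion recovered to
0.03 voxels; registration cuts the voxelwise ADC error ~3×) and
`image_pipeline_to_report.py` (sessions → cohort table → report).

A thin CLI wraps the same code paths:

```bash
dwiresponse simulate --config cfg.yaml --seed 1 --out out/   # phantom/cohort
dwiresponse image    --config cfg.yaml --out cohort.csv      # NIfTI → table
dwiresponse analyze  --cohort cohort.csv --out report.json   # table → report
```

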