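# marrowmap

Quantitative whole-body MRI of normal bone marrow: a tested pipeline from
multi-station diffusion-weighted (DWI) and Dixon volumes to per-subject
bone-marrow biomarkers and cohort-level normative statistics.

Bone marrow changes with age and sex — hematopoietic ("red") marrow converts
to fatty ("yellow") marrow — and these physiologic changes confound the
reading of whole-body MRI in myeloma and metastatic disease. Knowing the
normal ranges of marrow fat fraction, DW signal and diffusivity, and how they
move with age and sex, is a prerequisite for using them as disease markers.
This package implements the full measurement chain for four biomarkers:

- **%FF** — relative fat fraction from Dixon imaging, `%FF = Fat / (Water + Fat) x 100`;
- **ADC** (µm²/s) — apparent diffusion coefficient from a two-b-value DW pair,
  `ADC = ln(S_b50 / S_b900) / (900 − 50)` (the least-squares mono-exponential
  fit reduces to this closed form with two points);
- **nSI_b50 / nSI_b900** — DW signal normalized by the median psoas-muscle
  signal at the same b-value (dimensionless cellularity/water surrogates).

Per subject the pipeline: stacks the contiguous DWI stations, computes the
ADC map, extrapolates a computed high-b image
(`S(b*) = S_b900 · exp(−(b*−900)·ADC)`, default b* = 1500 s/mm²), segments
marrow by intensity thresholding (Otsu, restricted to the body support),
slice-matches and resamples the Dixon-grid %FF map onto the DWI grid, refines
the mask with the physiologic rules **ADC ≤ 1000 µm²/s and %FF ≥ 15 %**, and
reports the medians of all four parameters over the refined mask. Cohort
statistics cover Shapiro–Wilk-gated reference limits (mean ± 2 SD or 5th–95th
percentiles), Mann–Whitney/Kruskal–Wallis group comparisons, Spearman
correlations with age, ANCOVA, and the normative models

    %FF = 49 + 0.3 · Age            ADC = 480 + 53 · Sex − Age    (Sex: 0 = M, 1 = F)

Because no imaging data ships with the study this reproduces, a first-class
synthetic module (`marrowmap.synthcohort`) generates multi-station phantom
cohorts — DWI and Dixon channels on deliberately mismatched grids, Rician
noise, tissue ground truth following the normative age/sex structure — so
every stage is validated against known truth.

## Worked example

```bash
python analysis/01_simulate_cohort.py        # small on-disk demo cohort (scratch/fixtures)
python analysis/02_process_cohort.py         # full 100-subject in-memory cohort
python analysis/03_cohort_statistics.py      # statistics, tables, figure
```

The 100-subject run (10 per sex × 10-year age band, seed 42) prints:

```
100/100 subjects passed segmentation QC
cohort means: %FF 65.8%, ADC 451 um^2/s, nSI_b900 3.25, nSI_b50 1.46
  mean |recovered - truth| median_ff: 0.15 %
  mean |recovered - truth| median_adc: 0.385 um^2/s
  mean |recovered - truth| median_nsi_b900: 0.00634
n = 100
%FF ~ age: slope 0.290 %/yr, adj R^2 0.39
ADC ~ sex + age: sex +45.5, age -0.89, adj R^2 0.29
Spearman r(age, %FF): all 0.62 (men 0.66, women 0.59)
```

Reading: the image pipeline recovers each subject's ground-truth medians to a
fraction of a percent; the fitted normative coefficients land within sampling
error of the generating values (%FF slope 0.3 %/yr, ADC sex offset
53 µm²/s, ADC age slope −1 µm²/s/yr), and marrow fat fraction rises ~3 % per
decade with a moderate positive age correlation.

The same pipeline is available as a CLI
(`marrowmap simulate | process | cohort`); see `marrowmap --help`.

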