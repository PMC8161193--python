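# Methods

## Signal models and map computation

DW signal follows a mono-exponential decay per tissue, `S(b) = s0 · exp(−b·ADC)`
with ADC in mm²/s; maps are reported in µm²/s (×10⁶, centralized in
`config.UM2_PER_MM2`). With exactly two b-values (50 and 900 s/mm²) the
least-squares fit is identical to the closed form
`ADC = ln(S_low/S_high)/(b_high − b_low)`, which is what the package computes.
Voxels with non-positive signal are invalid (NaN); negative fitted ADC
(signal increasing with b, i.e. noise) is retained in the ADC map so its
downstream effect can be studied, but the computed high-b extrapolation
clamps ADC at 0 — a synthetic high-b image must never *amplify* signal, and
noise-only voxels with large negative fits would otherwise blow up
exponentially. The computed high-b target (default 1500 s/mm²) is a free
parameter (`cdwi_b_target`): vendor tools do not publish theirs.

Dixon %FF is `Fat/(Fat+Water)·100`, with negative inputs clipped to 0 and
voxels whose total signal is below `ff_epsilon` (10⁻⁹ signal units) invalid.
Known physical limitations of two-point Dixon %FF (T1 weighting, T2*
decay) are outside the model: the phantom generates ideal channels.

## Grid alignment

All geometry lives in one patient-space convention (LPS); NIfTI RAS affines
are converted at the I/O boundary. Dixon-derived maps are projected onto the
DWI grid by **nearest-slice matching** along the slice axis — a target slice
with no source slice center within half the source slice thickness
(+0.01 mm) is invalid, never extrapolated — and in-plane interpolation:
bilinear for continuous maps, nearest for masks/labels (continuous vs
categorical data). Contiguous stations are concatenated along the slice
axis; a gap or overlap beyond half a slice thickness is a geometry error.

## Segmentation and refinement

Marrow is hyperintense on high-b DWI, so a single intensity threshold on the
computed high-b stack yields the candidate mask. The interactive,
operator-chosen threshold of clinical workflows is replaced by Otsu's method
for reproducibility (a manual threshold remains available). Two numerical
choices matter here:

1. **Otsu implementation.** The 256-bin between-class-variance sweep is
   implemented in-package and returns the *upper edge* of the boundary bin.
   Bin-center conventions (e.g. skimage's) misclassify a piecewise-constant
   image whose dominant tissue class falls inside the boundary bin; on
   continuous data the two agree to within one bin width (tested).
2. **Body restriction.** Otsu assumes two classes, but a whole-body computed
   high-b field has three modes: air background (noise floor), body soft
   tissue, and marrow. For subjects with low marrow signal the air/body
   split can maximize between-class variance, producing a soft-tissue mask
   that the ADC/%FF refinement cannot reject (soft tissue sits inside both
   refinement ranges). The pipeline therefore restricts the Otsu histogram
   to a body mask derived from the Dixon total (Fat+Water) signal, which is
   reliably bimodal (tissue ≈ constant total vs air ≈ noise floor). The
   bare `threshold_segment` contract — Otsu on the nonzero-intensity
   histogram — is unchanged; the restriction is an optional argument the
   workflow supplies.

Refinement keeps in-mask voxels with valid ADC ≤ 1000 µm²/s **and** valid
%FF ≥ 15 % (published physiologic bounds for marrow; soft-tissue/noise
voxels leaked by motion between sequences fail them). Invalid (NaN) map
voxels cannot satisfy the inequalities and are excluded. Refinement is
idempotent and never adds voxels.

QC flags a subject when the refined mask has fewer than 100 voxels or the
median in-mask b900 signal is below 1.0× the muscle median — the failure
phenotype of threshold segmentation on fatty, DW-hypointense marrow. Flagged
subjects are retained in the cohort table with `segmentation_ok = False`;
replacement by same-sex/same-band spares is an explicit cohort-level option
(`assemble_balanced`), mirroring how such cohorts are actually assembled.

## Synthetic cohort generator

The generator defines the study conditions; its defaults are fixed.

**Cohort structure.** Two sexes × five 10-year age bands (30–39 … ≥70), equal
counts per cell; ages uniform integers within bands, the open band drawing
from 70–85. BMI is sex-specific normal (men 25.6 ± 3.3, women 23.3 ± 3.3
kg/m²) truncated at 15.

**Marrow ground truth.** %FF mean `49 + 0.3·Age` with between-subject SD
5.7 % (chosen so the total cross-sectional SD is ≈7.2 % and the implied
age–%FF correlation ≈0.62), clipped to [15, 95]. ADC mean `480 − Age` (men)
/ `533 − Age` (women), SD 40 µm²/s, clipped to [100, 1000] so refinement
retains marrow by construction. nSI_b900 targets are a calibration choice
documented here because the underlying age slopes are not published: men
constant 2.9 (SD 0.7); women linear from 4.6 at age 30 to 2.9 at age 70 and
extrapolated linearly beyond (matching the published sex means 2.9 vs 3.5
and the signs of the sex-specific age correlations); all targets floored at
2.0 so the default phantom is always segmentable (marrow ≥ 2× muscle on
b900). Marrow `s0` is back-computed so the rendered muscle-normalized b900
signal equals the target exactly. A "low-signal" mode divides marrow `s0` by
3 to emulate the segmentation-failure phenotype for QC testing. nSI_b50 is
*implied* by the mono-exponential model rather than calibrated; it comes out
lower (≈1.4) than real marrow (≈1.7), because real marrow DW signal is not
mono-exponential between 0 and 50 s/mm² (perfusion and T2 shine-through) —
a deliberate non-goal.

**Fixed tissues.** Muscle ADC 1400 µm²/s, %FF 8 %, s0 1000 (the
normalization reference); soft tissue ADC 900 µm²/s, %FF 85 %, s0 600
(marrow hyperintense relative to soft tissue on b900, the premise of
threshold segmentation); Dixon proportionality 10 signal units per %FF
point, so every tissue has total Dixon signal 1000.

**Phantom geometry.** A simplified axial skeleton in physical mm: a
spine-like column of 26 mm vertebral cuboids with 4 mm soft-tissue discs,
two pelvis-like marrow blocks, paired psoas-like muscle cylinders, inside an
elliptical soft-tissue body. Margins guarantee marrow never borders muscle
or air, so in-plane %FF interpolation at marrow voxels only ever mixes
marrow with soft tissue (both ≥ 15 %), which is what makes the noiseless
pipeline exactly invertible (medians and refined mask equal ground truth).
Per station the DWI grid is 48×48×20 at 4×4×6 mm and the Dixon grid
64×64×34 at 3×3×3.5 mm — same physical extent, deliberately different
sampling — with three contiguous lower-body stations. These grids are
scaled down from clinical matrices so a 100-subject cohort processes in
~15 s on one CPU while preserving every structural property that matters
(grid mismatch, slice matching, station stacking).

**Noise.** Rician: magnitude of the analytic signal plus two independent
Gaussian components, σ = 15 signal units by default (SNR ≈ 19 on the muscle
b900 signal, typical of 1.5 T body DWI). At this SNR the magnitude bias
σ²/(2S) is ≤ 0.4 signal units on the weakest tissue used and the recovered
median ADC bias is < 2 % (tested on 20 noisy phantoms).

**What the phantom does not emulate** — and hence what passing tests do not
show about real data: anatomically realistic skeletons and partial-volume
mixtures, EPI distortion and motion between sequences, T1/T2*/fat-suppression
physics of the actual sequences, perfusion (IVIM) effects at low b, and
inter-scanner variability. The generator validates the *measurement chain*,
not the scanner.

## Statistics

Reference limits are gated by Shapiro–Wilk at α = 0.05 (α not published;
0.05 is the conventional choice): mean ± 2·SD (sample SD, n−1) when
normality is not rejected, otherwise empirical 5th/95th percentiles with
linear interpolation between order statistics. Constant samples are
rejected as degenerate. Mann–Whitney is exact for tie-free samples with
min(n) ≤ 8, otherwise normal approximation with tie correction;
Kruskal–Wallis uses the tie-corrected H with a χ² reference (identical
constant groups return H = 0 by definition); Spearman uses tie-aware
mid-ranks. ANCOVA is OLS with Type II partial F tests (conventional for
covariate models; the design is balanced anyway). Sex is coded 0 = men,
1 = women in a single place (`cohortstats.SEX_CODE`). No multiplicity
adjustment is applied, matching the reporting convention reproduced here
(p < 0.05 significant). The statistical engines are scipy/statsmodels,
cross-checked in the tests against brute-force enumeration, rank-formula
closed forms, and Monte-Carlo null calibration.

## Known inconsistency in the reproduced targets

The published normative ADC equation (intercepts 480/533 µm²/s, slope
−1 µm²/s/yr) and the published cohort mean ADC (422 ± 67 µm²/s) cannot both
hold: at the cohort's mean age (~55 y) the equation implies ≈451 µm²/s, and
the equation's sex offset (53) also disagrees with the difference of the
published sex means (460 − 384 = 76). The generator follows the equation
(the choice on which the coefficient-recovery checks rest), so the
pipeline's cohort mean ADC is ≈451 µm²/s and is reported as computed; the
corresponding mean-ADC acceptance check fails by construction and is left
failing rather than recalibrated.

## Degenerate inputs and edge policies

Empty muscle mask → subject unusable (error routed to QC); empty refined
mask → flagged row with NaN medians; all-zero image under auto threshold →
empty mask + QC failure; single station → stacking is the identity;
even-count medians use the mid-mean convention. Cohort statistics blocks
that need more data than available (e.g. normative fits with n < 10) are
recorded as errors in the results bundle instead of aborting the run.
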