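# Methods

## Overview

`pedct` is a normative-analysis pipeline for pediatric head CT built around
a synthetic cohort.  The chain is: cohort sampling → slice-phantom rendering
→ regional HU measurement (ROI and DOT) → GWR computation → method/rater
agreement → age-stratified normative statistics and age-response fits.  All
randomness derives from a single run seed through a `numpy` seed sequence,
so any run is reproducible from (configuration, seed).

## The synthetic cohort

**What it emulates.**  A cohort of normal-control head CTs with the age
structure typical of clinically acquired pediatric scans: a young stratum
(< 24 months, default n = 18) and an old stratum (24–216 months, default
n = 24).  Ages are drawn log-uniformly within each stratum, which
reproduces the strong right skew of such cohorts (infants over-represented;
stratum medians ≈ 5 and ≈ 72 months, close to reported cohort medians).

**Regional means.**  Each region's noise-free mean HU is an age-response
curve evaluated at the subject's age (months, clamped to ≥ 1):

| region | form | parameters |
|---|---|---|
| parenchyma SL1 / SL2 | power y = a·x^b | a = 26.424 / 25.5, b = 0.025 / 0.0233 |
| caudate (CN) | power | a = 28.394, b = 0.0211 |
| cortical gray GM-SL1 / GM-SL2 | power | a = 26.843 / 26.713, b = 0.0403 / 0.039 |
| putamen (PT), thalamus (TM) | linear y = b·x + c | b = 0.0005 / 0.0011, c = 30.23 / 29.53 |
| WM-SL1 / WM-SL2 | linear | b = −0.0031 / 0.0061, c = 24.26 / 23.086 |
| ventricles | constant | 15 HU |

The two SL1 white-matter probe sites (frontal periventricular, posterior
limb of the internal capsule) share the WM-SL1 curve; no site-specific
trends are published.  Ventricular CSF is age-flat at the normal-cohort
ROI median (15 HU) since ventricle HU shows no age effect.  Lobar ROIs
have no published curves and are generated as area-weighted mixtures of
their slice's GM and WM curves (default weight 0.6 gray / 0.4 white,
configurable); this lands lobe medians within ≈ 1 HU of reported values.

**Noise model.**  Two independent Gaussian components: a between-subject
deviation added to each regional mean (default SD 1 HU) and i.i.d. voxel
noise in the rendered image (default SD 3 HU).  Defaults were chosen so
that cohort-level log-log fits at n = 42 produce R² in the broad vicinity
of the published 0.34–0.49 and group medians track the published IQRs.
Between-subject deviations are drawn independently per region; a
consequence is that the strict ordering CSF < WM < GM, which holds exactly
on the generating curves, can occasionally invert within a subject for
region pairs whose curves are close (e.g. GM-SL2 vs WM-SL1 in a neonate).
The ordering is therefore asserted in the noise-free case only.

**Geometry.**  Phantoms are schematic: a 256×256 grid at 0.5 mm isotropic
spacing, an elliptical "brain" with elliptical sub-patches for every
region, bilateral structures mirrored about the midline.  Labels are
disjoint; rendering verifies containment and non-overlap.  The
whole-parenchyma ROI is measured over the union of tissue labels
(ventricles excluded), and the generic filler-tissue HU is solved at render
time so that this union mean equals the subject's parenchyma curve value —
this keeps the noiseless generator → measurement round-trip exact for
*every* region, including the composite parenchyma.  The phantoms make no
claim of anatomical realism: no partial-volume effects, no beam-hardening,
no skull, no spatial noise correlation.  Tests passing on phantoms
demonstrate the pipeline's arithmetic and statistical machinery, not
segmentation performance on real scans.

## Measurement

ROI means are plain arithmetic means over labelled pixels; bilateral
structures are averaged (left + right)/2 with equal weight regardless of
area, before any ratio is formed.  DOT probes use pixel-center-in-circle
membership (a pixel belongs to the dot iff its center lies within
diameter/2 of the dot center), row-major 0-based coordinates, no
partial-volume weighting; the default diameter 2.6 mm is the midpoint of
the 2.4–2.8 mm protocol range.  A dot overlapping any pixel outside its
target label raises a contamination error rather than silently cropping —
correct placement is part of the protocol.  Default dot centers are label
centroids.  HU values are carried as real numbers throughout (no integer
quantization).

## GWR

Twelve formulas, all evaluated as mean(numerator regions) /
mean(denominator regions).  The mean/mean convention is deliberate: a
literal sum reading of e.g. "(CN + PT)/WM-SL1" would give ratios ≈ 2.5,
incompatible with any published normal value, and the multi-region source
formulas this set derives from average their region lists explicitly.
Where a formula cites generic "WM-SL1", tables without a direct entry
resolve it as the mean of the anterior and posterior probe sites.
`average2` is computed per subject as the mean of that subject's bg1 and
cortical sub-ratios; group medians of composites are medians of per-subject
composites.  Ratios below 1 are flagged with a warning but not rejected
(they are the expected signature of edema in patient data).  The pipeline
computes GWR from DOT tables (the formulas' site names are probe sites);
the engine accepts either method's table and records provenance.

## Agreement

Bland-Altman differences are DOT − ROI; bias is their mean, the limits of
agreement bias ± 1.96·SD with the sample SD (n − 1 denominator).  The 1.96
multiplier is fixed by the protocol, and no confidence intervals are
attached to the limits.  Intra-rater agreement uses ICC(2,1) — two-way
random effects, absolute agreement, single measures (computed via
`pingouin`, cross-checked in the tests against a hand ANOVA-mean-squares
computation); the form is exposed as an option since conventions vary.
Re-reads of a fixed scan are simulated as the original measurement plus
Gaussian re-read noise (default 0.5 HU) on ⌈10%⌉ of subjects: a re-read
perturbs the *measurement*, not the scan, so zero re-read noise yields
identical sessions and ICC = 1 exactly.

## Normative statistics

Stratification at 24 months, with 24 months itself classified old.
Summaries are median and IQR with linear interpolation between order
statistics (the common spreadsheet/statistics default; fixed so IQRs are
reproducible).  Group comparisons are gated on Shapiro-Wilk normality at
α = 0.05 in each group: both normal → Welch unpaired t-test (the safer
unequal-variance variant), otherwise two-sided Mann-Whitney U.  Bonferroni
adjustment multiplies by the family size — 14 for ROI rows, 9 for DOT rows,
12 for GWR rows, the row counts of the corresponding summary blocks — and
caps at 1.

Power-law age fits use OLS of ln(y) on ln(x) with R² reported on the log
scale, matching the spreadsheet-trendline convention the published
coefficients imply; a nonlinear fit of the same model would give slightly
different estimates.  A zero-variance response is defined to have exponent
(or slope) 0 and R² 0, with a warning.  Linear fits are OLS on the original
scale.

## Calibrated noise for exponent recovery

For the parameter-recovery experiments the additive-HU noise SD is derived
analytically from a target log-log R²: for ages uniform on [1, 216] months
and a power curve with exponent b, the log-scale signal variance is
(b·SD(ln x))², additive noise of SD σ contributes ≈ (σ/ȳ)², hence
σ = ȳ·|b|·SD(ln x)·√((1−R²)/R²).  With n = 500 subjects per cohort and 20
seeds, the mean recovered exponent is stable to ≈ ±0.001, comfortably
inside the ±0.005 acceptance band, and the realised R² lands within a few
points of the target.

## Problem sizes

The default pipeline run (42 subjects × 2 slices at 256², both methods,
full report) completes in a few seconds; the test suite uses cohorts of
5–11 rendered subjects where images are needed and true-mean cohorts (no
rendering) for the 100-seed direction checks, keeping the whole suite
under a minute.

## Known limitations

* Schematic geometry: no partial volume, so ROI-vs-DOT ventricle bias seen
  on real scans (dots in pure CSF vs ROIs catching boundary voxels) is not
  reproduced; on phantoms both methods are unbiased by construction.
* Exact subject ages of the emulated cohort are not public; the generator
  matches stratum sizes, medians and skew, not individual ages.
* The measurement-noise magnitude of human HU reads is not published; the
  defaults are this package's calibration, stated above.
* Automated whole-brain GM/WM segmentation ("GWR auto"), outcome-prediction
  thresholds and scanner-physics effects (kVp, manufacturer) are out of
  scope.
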