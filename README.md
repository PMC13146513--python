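# pedct

Normative Hounsfield-unit (HU) and gray-white-matter-ratio (GWR) analysis
for pediatric head CT.

## The problem

After cardiac arrest or traumatic brain injury, cerebral edema erases the
normal density contrast between gray and white matter on head CT.  The
gray-white matter ratio — GWR = HU(gray matter) / HU(white matter), ≈ 1.2–1.4
in healthy brain, falling toward 1 with edema — is a candidate prognostic
biomarker, but published thresholds come almost entirely from adults.  In
children the picture is complicated by maturation: myelination and tissue
density change rapidly in the first two years of life, so a "normal" GWR in
an infant differs from a normal GWR in a ten-year-old.

`pedct` implements, as a tested pipeline, the normative analysis needed to
quantify this: regional HU measurement on two axial slices by a segmented
region-of-interest (ROI) method and a circular-dot probe (DOT) method, twelve
GWR formulas from the adult and pediatric literature, ROI-vs-DOT agreement
(Bland-Altman, intraclass correlation), age-stratified normative tables
(young < 2 years vs old ≥ 2 years) and age-response curve fits.  Because real
pediatric normal-control scans cannot be shared, the package includes a
first-class synthetic-cohort generator: schematic 2D slice phantoms whose
regional means follow published age-response curves, e.g. parenchyma
HU(x) = 26.424·x^0.025 (x in months, power law) for gray-matter-dominated
regions and near-flat linear trends for white matter, with configurable
between-subject and voxel noise.  Every downstream stage is therefore
testable end to end, with known ground truth.

## The measurements

* **Slices** — SL1 at the basal-ganglia level (third ventricle visible) and
  SL2 at the supraventricular level.
* **ROI method** — mean HU over a segmented region: whole parenchyma (bone
  stripped), ventricles, caudate (CN), putamen (PT), thalamus (TM) and the
  lobes, bilaterally averaged.
* **DOT method** — mean HU in a 2.4–2.8 mm circular probe (default 2.6 mm,
  pixel-center-in-circle membership) placed in CN, PT, TM, cortical gray
  (GM-SL1, GM-SL2), frontal periventricular WM, posterior limb of the
  internal capsule, deep WM on SL2 and the ventricles.
* **GWR** — 12 formulas (basal-ganglia, single-nucleus, cortical and
  averaging variants), all read as mean(numerator regions) /
  mean(denominator regions); `average2` is the mean of the `bg1` and
  `cortical` sub-ratios.
* **Agreement** — Bland-Altman on DOT−ROI differences (bias ± 1.96·SD limits
  of agreement) and ICC(2,1) for simulated intra-rater re-reads of 10% of
  the cohort.

## Worked example

```python
from pedct import run_pipeline

res = run_pipeline(seed=1)   # 42 synthetic subjects: 18 young, 24 old

g = res.report["gwr_summary"].set_index("variable")
for fid in ("bg1", "cortical", "average2"):
    row = g.loc[fid]
    print(f"{fid:9s} young {row.median_young:.2f}  old {row.median_old:.2f}"
          f"  p_adj {row.p_adjusted:.4f}")
print("ICC:", {k: round(v, 3) for k, v in res.icc.items()})
```

prints

```
bg1       young 1.23  old 1.28  p_adj 0.0025
cortical  young 1.21  old 1.32  p_adj 0.0000
average2  young 1.21  old 1.31  p_adj 0.0000
ICC: {'SL1': 0.997, 'SL2': 0.996}
```

Young-stratum GWRs sit below old-stratum GWRs for the basal-ganglia,
cortical and averaging formulas (significant after Bonferroni correction
over the 12-formula family), the pattern expected when cortical gray-matter
HU rises with age while white matter stays flat; the intra-rater ICCs show
the simulated re-reads are highly reproducible.  `res.agreement` holds the
per-region Bland-Altman table (deep-nuclei bias well under 1 HU on these
phantoms) and `res.report["curve_fits"]` the per-region age-curve fits.

The same pipeline is scriptable from the shell:

```sh
pedct --seed 1 --outdir out simulate   # NIfTI phantoms + cohort.csv
pedct --outdir out measure             # hu.csv (ROI + DOT)
pedct --outdir out gwr                 # gwr.csv, 12 formulas per subject
pedct --outdir out agree               # agreement.csv + icc.json
pedct --outdir out norms               # normative summary tables
pedct --outdir out report              # figures
```

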