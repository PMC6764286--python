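# mgquant

Quantification of regional microglia depletion from microscopy images,
with a synthetic-data generator that provides exact ground truth for every
stage.

## The problem

Microglia — the resident macrophages of the CNS — depend on CSF1R
signalling for survival, and blocking its ligands (CSF1, IL-34) depletes
them with region-specific patterns: white-matter tracts (e.g. the
hippocampal fimbria) respond to CSF1 blockade, gray matter (cortex) to
IL-34 blockade.  Measuring that depletion requires a chain of image
quantification and statistics:

- **3D two-photon stacks** of GFP-labelled microglia (0.592 µm/pixel
  in-plane, 1.5 µm z-step): detect individual somata, report density as
  cells per mm³ of imaged volume, and per-cell size in µm³ from a mask
  covering soma and processes.  A 2D variant reports cells per mm² for
  spinal-cord sections (2.3649 µm/pixel).
- **Chromogenic IHC slides** (DAB on hematoxylin): segment tissue and
  stain by colour thresholding, count positive cell bodies with a
  minima-controlled watershed that splits touching cells, normalize to
  ROI area, and histogram per-cell 8-bit staining intensity in 5-unit
  bins.
- **FISH slides** (Csf1r / Csf1 / Il34 probes): detect puncta and report
  the percent of tissue area stained within an ROI.
- **Statistics**: percent depletion `100·(1 − mean_treated/mean_control)`
  per region, one-way ANOVA with Dunnett's many-to-one post-hoc test,
  Kolmogorov–Smirnov comparison of binned intensity histograms, simple
  OLS R² for concentration–response, and weighted 1/x quadratic
  calibration curves with back-calculation and LLOQ flagging (default
  0.0073 µM) for LC-MS drug quantitation.

Because the original animal imaging data are not deposited, every stage
is exercised against the `mgquant.synthetic` generators, which render
stacks, slides and multi-animal cohorts with programmed ground truth
(cell positions and counts, stained-area fractions, per-region depletion
fractions), all as pure functions of `(spec, seed)`.

## The statistics at the core

For groups *i* = 1..k compared against a shared control (group 0) with a
pooled variance estimate s² on ν = N − (k+1) degrees of freedom, Dunnett's
two-sided adjusted p-value for an observed statistic *t* is

P(max_j |T_j| ≥ t), with (T_1..T_k) jointly t-distributed with
correlation ρ_ij = λ_i λ_j, λ_i = √(n_i/(n_i+n_0)).

`mgquant.stats` evaluates this deterministically by conditioning on the
pooled-SD factor and a shared latent normal (double Gauss quadrature),
accurate to far below 1e−6; for k = 1 it reduces exactly to the two-sided
pooled t-test.

## Worked example

Simulate the default four-group, three-region cohort (n = 6/group,
3M/3F, lognormal between-animal CV 10%) and analyse it:

```bash
mgquant simulate --seed 2 --out cohort.csv
mgquant stats --cohort cohort.csv --control control --out depletion.csv
```

The pooled stratum of `depletion.csv` (seed 2):

```
       region      group  percent_depletion     se  p_adjusted
      fimbria anti-IL-34             5.6836 5.0100      0.3399
      fimbria  anti-CSF1            65.0452 1.9129      0.0000
      fimbria      combo            68.5007 1.4568      0.0000
       cortex anti-IL-34            46.6423 2.8703      0.0000
       cortex  anti-CSF1            12.6256 4.4169      0.0159
       cortex      combo            51.8752 3.2032      0.0000
dentate_gyrus anti-IL-34            26.6090 3.9564      0.0000
dentate_gyrus  anti-CSF1             4.8308 5.0986      0.6077
dentate_gyrus      combo            59.1119 2.5099      0.0000
```

Each row is one treatment group in one region: the estimated percent
depletion relative to the control mean (± delta-method SE) and the
Dunnett-adjusted p-value.  The programmed pattern — strong white-matter
depletion by anti-CSF1 (65% in fimbria), gray-matter depletion by
anti-IL-34, and the combination required in the mixed dentate gyrus — is
recovered with the expected significance calls.

The full image-level pipeline (render stacks per animal → detect cells →
densities → statistics, plus IHC and FISH stages) runs from a config:

```bash
mgquant run --seed 1 --out demo_run
```

and writes `cohort.csv`, `densities.csv`, `cells.csv`, `depletion.csv`
and a `manifest.json` with checksums; identical config + seed reproduces
byte-identical tables.

Single-image tools: `mgquant stacks --in stack.tif --min-volume 150`,
`mgquant ihc --slide s.tif --roi roi.json`, `mgquant fish --channel f.tif`.

## Layout

```
src/mgquant/
  synthetic.py   seeded generators with exact ground truth
  stacks.py      3D detection, density (mm^-3), per-cell size (um^3)
  ihc.py         tissue/stain segmentation, watershed counting, histograms
  fish.py        puncta detection, percent tissue area stained
  stats.py       depletion, ANOVA+Dunnett, binned KS, R^2, calibration
  io.py          TIFF/CSV/ROI readers and writers
  pipeline.py    configured multi-stage runs with manifest
  cli.py         command-line interface
docs/methods.md  models, defaults, numerical choices, limitations
```
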