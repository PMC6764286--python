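# Methods

This note documents the models behind mgquant, the defaults that matter,
what the synthetic generators do and do not emulate, and the numerical
choices made where the design was genuinely open.  No empirical claim here
goes beyond what the test suite and `scripts/acceptance.py` compute.

## 1. Synthetic data

The generators exist because the kind of study this package supports —
antibody- or inhibitor-mediated microglia depletion measured across brain
regions — does not typically deposit raw image stacks.  Every generator is
a pure function of `(spec, seed)`: one `numpy` Generator is created per
call and all draws flow from it, so identical inputs give bit-identical
arrays.

**3D stacks.** Cells are placed by rejection sampling with a hard pairwise
minimum separation (default 30 µm) and a 10,000-attempt cap per cell;
an infeasible spec raises `PlacementError` rather than looping forever.
Each cell is a soma (hard ball, radius drawn from 3.5–5.0 µm) with 2–6
processes — thin cylinders of 0.75 µm calibre, 8–15 µm long, radiating in
random directions with intensity tapering from 0.8× to 0.4× of the soma
level.  The whole field is blurred with a 0.5 µm Gaussian to soften
rasterized edges, then constant background (10) and additive Gaussian
noise (sd 20) are applied and the result clipped at zero.  With the
default foreground intensity of 100 this gives a signal-to-noise ratio
of 5.  The default voxel grid carries the two-photon acquisition
geometry: 0.592 µm/pixel in-plane, 1.5 µm z-step.

The per-cell `true_volume` is analytic (sphere + cylinders, overlaps
ignored); it anchors the size measurement at the modelling level, while
the rasterized-ball convergence check anchors it numerically.

What this is *not*: there is no point-spread function, no depth
attenuation, no photon (Poisson) statistics, no vasculature or meningeal
structures, and processes do not branch.  Passing tests therefore
demonstrate correctness of the measurement chain on well-posed images,
not robustness to every optical artefact of real two-photon data.

**IHC slides.** Tissue is a centred ellipse (rectangle above 75% area)
covering the requested fraction of the frame, coloured like hematoxylin
counterstain on a white background.  Positive cells are disks with a
radial shade profile darkest at the centre (0.55× at the centre to 1.0×
at the rim of the chromogen colour), composited darkest-wins.  A
configurable fraction of cells is laid out as touching pairs at
centre-to-centre distance 0.75·(r₁+r₂): the disks overlap into one
connected component, but each member keeps its own darkness minimum —
exactly the situation a minima-controlled watershed is meant to resolve.
Gaussian channel noise (sd 3) is added before quantizing to 8-bit.

**FISH slides.** The stained area is built from non-overlapping disks of
the programmed dot radius placed fully inside the tissue, with the dot
count chosen so the exact stained-pixel fraction is as close as the dot
granularity allows to the target; if that closest value is off by more
than 0.5 percentage points the spec is rejected as unreachable.  The
returned `true_percent` is an exact pixel count, which is what makes the
±0.5-point recovery contract meaningful.  100% coverage is special-cased
(signal = tissue); real RNAscope sections of highly expressed probes are
not literally saturated, so treat that case as a boundary check only.

**Cohorts.** A design lists groups (exactly one with zero depletion
everywhere — the control) and regions (baseline density in cells/mm³,
between-animal CV).  Animal-level expected density is
`baseline · (1 − depletion) · L`, with `L` lognormal, mean-preserving
(σ² = ln(1+CV²), µ = −σ²/2).  Sexes alternate M/F within group as pure
metadata; no sex effect is generated, matching the default analysis which
reports pooled and per-sex strata without an interaction model.  Baseline
densities (5,000–8,000 cells/mm³) were chosen once as typical adult mouse
parenchyma values (mean inter-cell spacing ~50–60 µm); the default design
couples a white-matter region depleted by one agent, a gray-matter region
depleted by the other, and a mixed region requiring the combination.

## 2. Stack quantification

The detection recipe is deliberately conventional, since the original
analysis routines in this field are typically unpublished Matlab code:

1. background subtraction: grey-scale opening with a box of half-size
   20 µm per axis (a separable stand-in for a rolling ball; exact for the
   flat backgrounds generated here), subtracted from the image;
2. Gaussian smoothing, σ = 1 µm, converted to voxels per axis — in µm
   because the axial pitch (1.5 µm) is ~2.5× the lateral pitch;
3. global Otsu threshold with a blank-image guard (below);
4. 26-connected components;
5. minimum-volume filter, default 150 µm³ (about a third of a 4.5 µm
   radius soma; safely below a soma plus any processes);
6. optionally, h-maxima-seeded watershed per component, h = 10% of the
   foreground dynamic range, splitting components that contain several
   intensity maxima.  Components without a detected maximum are kept
   whole, so the watershed count can never drop below the plain
   component count.

*Blank-image guard.* Otsu's criterion degenerates on images with no
foreground class: it bisects the noise, and the resulting near-percolating
mask would produce hundreds of false cells.  The split is accepted only if
the upper-class mean exceeds the lower-class median by at least 5 robust
background spreads (1.4826·MAD of the sub-threshold pixels); pure noise
produces a gap of ~2–3 spreads, genuine signal tens.  Otherwise the image
is declared signal-free and the detector returns no cells.

*Coordinates and sizes.* Voxel indices are 0-based, arrays (z, y, x);
a voxel centre sits at `(index + 0.5) · pitch`.  Cell size is voxel count
× (0.592² · 1.5) µm³ — at these pitches a single voxel is 0.5257 µm³.
Density is count divided by the full imaged volume in mm³ (area in mm²
for the 2D spinal-cord variant).  Per-animal pooling across multiple
stacks defaults to pooled counts / pooled volume, with mean-of-stacks as
an option.  Border-touching cells are counted but flagged, so size
summaries can exclude them.

## 3. IHC quantification

Tissue is everything darker than the white slide background (luminance
< 235) after closing, small-object removal (≥ 64 px) and hole filling.
Stain segmentation defaults to a hue/saturation criterion — circular hue
distance ≤ 0.08 from the reference chromogen colour and saturation ≥ 0.15
— which is insensitive to uniform brightness changes; an optical-density
colour-deconvolution mode (H-DAB matrix) is available for slides where
hue alone is ambiguous.

Counting inverts the usual bright-field logic: cells are *dark* in the
intensity image, so seeds are h-minima of the intensity landscape (depth
25.5, i.e. 10% of the 8-bit range) inside the stained mask, flooded by
watershed.  Objects below 20 µm² (a conservative nucleus scale) are
discarded.  Both normalization conventions — count (or stained area) per
ROI area and per tissue-within-ROI area — are reported, because published
descriptions are usually ambiguous between them.

Per-cell mean 8-bit intensity is histogrammed in the fixed bins
[0,5), [5,10), …, [250,255], the terminal bin absorbing 255 (the 256th
grey level has to live somewhere; this keeps 51 equal-width bins).

## 4. FISH quantification

`percent_area = 100 · |stain ∧ tissue ∧ roi| / |tissue ∧ roi|`, with the
whole-ROI denominator also reported.  The stain mask is a thresholded
channel (floored Otsu by default, fixed threshold as an option) — an
area-fraction semantic, deliberately distinct from the puncta count,
which uses Laplacian-of-Gaussian blob detection at the physical dot scale
(σ searched over 0.6–1.8× the nominal dot size).  The tissue mask comes
from the nuclear channel via smoothing, Otsu and closing when a DAPI
image is provided.

## 5. Statistics

**Depletion.** `100 · (1 − mean_treated / mean_control)` per region;
negative values (repopulation) are allowed; a zero control mean is an
error.  The SE is by the delta method from the two group-mean SEs,
treating groups as independent.

**ANOVA + Dunnett.** One-way ANOVA with the pooled within-group variance
on N − k degrees of freedom.  Dunnett's two-sided adjusted p-value is the
tail of max_j |T_j| under the equal-correlation multivariate t with
ρ_ij = λ_i λ_j, λ_i = √(n_i/(n_i+n_0)) — the standard generalization to
unequal group sizes.  It is evaluated by conditioning on the pooled-SD
factor W (a scaled chi variable) and the shared latent normal U, which
factorizes the joint probability into a product of univariate normal
CDFs; the two integrals use 120-node Gauss–Legendre (on W, over the
10⁻¹⁴–(1−10⁻¹⁴) quantile range) and 96-node Gauss–Hermite (on U).  The
result is deterministic and, in the k = 1 case where the exact answer is
the two-sided pooled t-test, agrees to ~10⁻¹⁴.  Pooled variance across
all groups is used for every comparison (the common convention; a
per-comparison-variance variant is not implemented).

**Binned KS.** D is the maximum CDF gap evaluated at the shared bin
boundaries — within-bin values are never reconstructed, so this is the
statistic of the binned distributions, slightly conservative relative to
unbinned data.  The p-value uses the asymptotic Kolmogorov distribution
at effective size n_a·n_b/(n_a+n_b).  When the histogram entries are
cells pooled across animals, the test treats cells as independent; that
is pseudo-replication with respect to animals, and p-values should be
read accordingly.

**Calibration.** `ratio = a + bx + cx²` minimizing Σ(yᵢ−f(xᵢ))²/xᵢ
(weights 1/x, undefined at zero, hence strictly positive standards; ≥ 4
distinct levels).  Back-calculation solves the quadratic with the
cancellation-free formula (one root via the q-trick, the partner via
Vieta) and accepts the real root inside the calibrated range with a 5%
extrapolation margin; results below the LLOQ (default 0.0073 µM) are
flagged, and a non-monotone fit over the calibrated range raises a
warning.  Concentration–response association is a plain OLS line with
R² = r².

## 6. Pipeline

Stages run in the fixed order simulate → stacks/ihc/fish → stats.  Every
per-item seed is derived from the run seed by hashing `(seed, stage,
index)`, so stage outputs are independent of execution order and a run is
reproducible byte-for-byte at the CSV level; the manifest records config
hash, package version, per-output SHA-256 and timestamps.  Problem sizes
in the bundled defaults (256×256×40-voxel stacks, ~5–10 cells each) were
chosen so a full demo run completes in well under a minute while still
exercising every code path; they are generator settings, not algorithmic
constants.

## 7. Known limitations

- Detection assumes sparse, bright, roughly convex somata; densely
  packed or highly ramified overlapping cells at real-tissue densities
  can merge or over-split in ways the synthetic benchmark does not probe.
- The rolling-box background estimate is exact only for flat backgrounds;
  strong shading gradients would call for a true rolling-ball or
  polynomial background model.
- The hue/saturation stain threshold presumes a chromogen whose hue is
  separated from the counterstain; for overlapping hues use the
  deconvolution mode.
- Dunnett p-values assume normal within-group errors with a common
  variance; the cohort generator's lognormal noise at CV 0.10 is close
  enough to normal that the simulated null familywise error matches 0.05,
  but heavy-tailed real data would need a rank-based alternative.
- The KS effective-sample-size caveat above: cells, not animals.
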