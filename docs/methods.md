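# Methods

## Problem and scope

The package quantifies en-face OCT angiograms and compares regional
skeletonized vessel densities between two diagnostic groups.  The
measurement chain (binarize → skeletonize → ETDRS sector densities → FAZ
metrics) mirrors a semi-automated ImageJ-style workflow; the statistical
chain mirrors an lme4-style repeated-measures analysis.  Because no patient
images are available, all validation runs on synthetic angiograms with
planted ground truth, and the statistical experiments run on densities
simulated directly from the planted linear model.

## Coordinate and calibration conventions

Images are square, origin top-left, x right / y down; pixel `(i, j)` has
center `(j + 0.5, i + 0.5)`.  The only physical calibration is
`mm_per_px = field_mm / width_px` (3 mm macula fields, 6 mm ONH fields).
The default working resolution is 512×512 px; nothing in the geometry
depends on pixel counts, so all sizes are configuration.

## Binarization

Niblack (`T = m + k·s`, bright-object convention, default `k = 0.2`) and
Phansalkar (`T = m(1 + p·e^{−qm} + k(s/r − 1))`, defaults `k = 0.25`,
`r = 0.5`, `p = 2`, `q = 10`) with a 15 px window, plus global and
per-window Otsu.  Defaults follow the standard local-threshold literature;
the original study reports no parameter values, so all are exposed in
configuration and echoed into sidecar metadata.  Site routing is macula →
Phansalkar, ONH → Niblack.  Intensities are normalized to [0, 1] (8-bit
input divided by 255; float input passed through unchanged, which preserves
the exact intensity-shift covariance of Niblack).  Borders use reflective
padding (edge pixel included — the `scipy.ndimage` "reflect" convention) to
avoid an artificial low-mean rim.  The vessel rule is strictly-greater with
a 1e-9 guard so floating-point dust in the windowed moments cannot flip
zero-variance ties; the guard is six orders of magnitude below the 1/255
quantum of real input.  Windowed mean/variance go through
`scipy.ndimage.uniform_filter`; correctness is checked against a
direct-summation per-pixel oracle, pixel for pixel.

Dark-vessel polarity is implemented as thresholding `1 − img` with the same
bright rule, equivalent to the classic dark-object Niblack with the sign of
`k` flipped.

## Skeletonization

Iterative morphological thinning to convergence
(`skimage.morphology.thin`).  The contract — skeleton ⊆ foreground, unit
width (no 2×2 block), 8-connected component count preserved, idempotent —
is what the analysis depends on, and is enforced by tests rather than by
commitment to a particular thinning operator.  Spur pruning exists but is
off by default; short side branches are genuine capillary signal in this
context.  Skeletonized density is the fraction of region pixels on the
skeleton.  The motivating property — insensitivity to vessel calibre — is
verified by drawing identical vessel trajectories with 1 px vs 3 px
brushes: skeleton density moves < 10% while mask density roughly triples.
Dilating a *whole* synthetic plexus instead would also merge neighbouring
vessels and re-route centerlines, which measures network geometry rather
than calibre, so that formulation is not used.

## ETDRS grid

Radii fixed at 0.5 / 1.5 / 3.0 mm (1/3/6 mm diameters).  Pixels are
assigned by the polar coordinates of their centers: half-open annuli
`(0.5, 1.5]` and `(1.5, 3.0]`, quadrants split on the ±45° diagonals with
half-open angular spans, so the masks partition the annulus exactly.  The
central ≤0.5 mm disc belongs to no region.  For 3 mm macula fields only the
inner ring fits: 4 regions.  Nasal/temporal flip with laterality; the
default map puts the temporal quadrant on the image left for OD.  A
misassignment here would invert the headline temporal finding, so the map
is config-overridable and unit-tested explicitly.  Grid placement emulates
manual centering: the grid starts at the geometric image center and is
translated by a recorded pixel offset; a grid whose annulus loses more than
1% of its area off-image raises a clipped-grid error (the sub-0.1% slivers
of a centered 6 mm grid on a 6 mm field are tolerated).  The site summary
is the unweighted mean of the regional densities (inner and outer sectors
have different areas, so an area-weighted variant would differ; unweighted
matches the per-region averaging of the emulated workflow).

## FAZ metrics

Area by the shoelace formula, perimeter by summed vertex distances, and
acircularity `P / (2√(πA))`, computed on the outline polygon in vector
form.  Pixel-edge counting would overestimate diagonal boundaries by up to
√2 and bias acircularity upward, so it is deliberately avoided; the
rasterization cross-checks in the tests use pixel-center counting for area
and a Crofton perimeter estimate.  Outlines are stored in pixel units and
scaled at metric time.  For unattended runs `auto_faz_outline` flood-fills
the avascular component containing the center pixel and extracts its
contour; a center pixel on a vessel or a fill reaching the border raises
the corresponding error (mirroring manual exclusion of images without a
determinable FAZ).

## Synthetic angiograms

Vessels are biased direction-persistent random walks with binary branching
(branch probability 0.08/step, depth ≤ 6, ≤ 32 walks per tree), drawn with
disc brushes of radius 0.5/1/1.5 px (widths 1–3 px, probabilities
0.55/0.35/0.10, branches one class thinner than their parent); step
mid-points are stamped so 2 px steps stay 8-connected.  ONH roots sit on
the disc margin heading radially outward; macula roots sit on the image
border heading inward.  Vessel pixels render at 0.85, background at 0.05,
with optional multiplicative speckle (Gaussian on log-intensity, sd 0.15 by
default, clipped to [0, 1]) — speckle-like, but a stand-in, not a
calibrated noise model.

Regional deficits: each ETDRS region carries a multiplicative factor on the
probability that a walk deposits pixels there.  Acceptance is drawn per
~16-step segment rather than per step, so a rejected draw removes a whole
capillary stretch (rarefaction) instead of dotting the vessel — per-step
rejection leaves the skeleton almost unchanged and would make planted
deficits invisible to the measurement chain.  All per-walk randomness is
pre-drawn from trajectories that do not depend on the multipliers, and the
growth stopping rule tracks density over territory outside the ETDRS
sectors (which no multiplier can touch).  Together these make runs at the
same seed exactly coupled: the deficit run draws a strict subset of the
baseline run's vessels, regional true density is monotone in the
multiplier, and unmodified regions are bit-identical.

The density target (default 0.06 in the never-modified corner territory)
puts the ETDRS annulus at a mask density near 0.35, comparable to binarized
vessel densities in real en-face scans.  Saturation still attenuates
planted deficits — overlapping vessels mean a multiplier of 0.5 yields a
measured temporal density ratio nearer 0.55–0.8 than 0.5 — which is why
the statistical calibration experiments plant effects directly on the
density scale instead of through images.

Macula scans carve an avascular zone at the center: a star-shaped polygon
(low-order cosine harmonics scaled by `faz_irregularity`, rescaled to the
target area exactly), ringed by a perivascular capillary margin stamped
just outside the outline so the zone is a bounded avascular component, as
in real maculas.  No vessel pixel lies strictly inside the polygon.  ONH
scans draw a bright 1.0 mm disc with a linear rim taper — a hard-edged disc
would leave a ring of spurious above-local-mean pixels under local
thresholding, and a 1.0 mm diameter keeps the disc inside the ETDRS central
circle so it never enters a measured region.

### Cohort simulation

Subjects carry diagnosis, age (normal, mean 35.7, sd 12.5, truncated to
[18, 70]), sex (male fractions 17/39 controls vs 39/51 cases — the
imbalance of the emulated cohort), and a random intercept; eyes add a
nested intercept; records add residual noise (defaults 0.02 / 0.01 / 0.02
on a base density of 0.12, with a planted age decline of 4e-4 per year).
The SSD temporal deficit δ multiplies the temporal density by (1 − δ),
either uniformly or split by age group (young = age ≤ 30).  Densities
outside [0, 1] are clipped and flagged.  `simulate_density_records`
produces these records directly (the workhorse for replicated model fits);
`generate_cohort` renders full macula + ONH image pairs per eye, planting
the deficit only in ONH scans (the emulated finding is peripapillary) and
drawing per-eye FAZ areas (sd 0.08 mm²) with an optional group scale
factor.  What image-level simulation does **not** emulate: projection and
motion artifacts, capillary plexus layering, signal-strength variation, and
vessel-scale anatomy beyond a branching walk — passing tests demonstrate
the measurement chain's correctness on its stated contract, not
performance on clinical images.

## Statistics

Mixed models are REML fits (`statsmodels` MixedLM) of
`density ~ diagnosis × quadrant (+ ring) + age + sex` with a subject random
intercept and an eye variance component nested in subject; the inferior
quadrant and the control group are reference levels.  A singular or
non-converged fit falls back to a subject-only intercept and, last, to OLS
— which is exactly right when the variance components are truly zero, and
identical for fixed effects in balanced designs.  Wald p-values use the
normal (z) approximation: Satterthwaite degrees of freedom are not
available in the fitting backend, and at the cluster counts this design
targets (dozens of subjects) the approximation is accurate — the type-I
calibration test pins this at 5% ± 3% empirically.

Ring collapse: the ONH model is first fit with the ring term; if its
p ≥ 0.05 the inner/outer densities are averaged per subject × eye ×
quadrant and the model refit without it.  Post hoc contrasts estimate the
control − SSD marginal difference per quadrant from the fixed-effect
covariance; BH adjustment is applied across exactly those four contrasts
(the FDR family is the quadrant set within one model, not all tests in a
study).  Stratified analyses (age ≤ 30 vs > 30; a subject aged exactly 30
is young) refit the full pipeline per stratum; their headline temporal
p-values are read raw, since the across-stratum comparison is not part of
any BH family.  A pooled model of the temporal records with a
diagnosis × age (centered, continuous) interaction tests whether the
diagnosis effect varies with age independent of the cutoff.  FAZ size and
acircularity are compared per eye by OLS on diagnosis; demographics use
Welch t and Pearson χ² without continuity correction (a covariate with no
variation in either group is reported with a warning and no p-value);
density–RNFL associations are Pearson correlations per quadrant ×
diagnosis × age stratum.

## Replicated experiments and problem sizes

Calibration and power checks simulate density records and refit the full
analysis per replicate: type-I error with 40 + 40 subjects and 200
replicates; young-only deficit recovery (δ_young = 0.3, δ_old = 0) with
45 + 45 subjects and 50 replicates, judged on raw stratum p-values;
monotonicity of the mean temporal contrast across δ ∈ {0.1, 0.2, 0.3} with
30 replicates each.  These sizes put the whole test suite at a few minutes
on one CPU while keeping Monte-Carlo error well inside the asserted bands
(e.g. binomial sd ≈ 1.5% at 200 replicates against a ±3% band).  Image
tests run at 256 px except where skeleton fidelity needs the default 512 px
(density–ground-truth correlation, FAZ recovery).

## Known limitations

- The generator's walk model produces a plexus whose regional coverage is
  radially inhomogeneous (denser near the ONH disc); regional comparisons
  should therefore use coupled same-seed runs or the planted ground truth,
  not cross-quadrant equality.
- Coverage saturation attenuates image-level planted deficits (see above).
- Threshold parameter defaults cannot claim to match the original study's
  operating point, which was chosen by subjective quality assessment and
  never reported.
- The speckle model is not calibrated to OCTA decorrelation statistics;
  segmentation performance on synthetic images (Jaccard ≥ 0.9 noise-free)
  does not transfer to clinical data.
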