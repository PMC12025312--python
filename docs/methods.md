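# Methods

This note records the scientific and numerical choices behind `choroidtex`:
what the pipeline computes, what the synthetic cohort generator does and does
not emulate, and where the design was genuinely open.

## Data model

A sample is one 2-D 8-bit image plus a binary choroid mask and eye-level
metadata (eye, patient, group ∈ {healthy, cscr, fellow}, modality). B-scans
use row-major, 0-based coordinates with rows as the depth axis. Choroid
boundaries are stored per column as inclusive row indices: `inner` (Bruch's
membrane side, depth fraction 0) and `outer` (choroid–scleral boundary,
depth fraction 1); columns without choroid carry a −1 sentinel and are
masked out of en face slices rather than zero-filled, so texture statistics
never see fill values.

En face reconstruction samples, for slice k of n, the intensity at
fractional depth (k + 0.5)/n between the boundaries with nearest-row lookup.
Bin centres avoid double-counting the boundary rows, and with flat
boundaries of thickness t = n the rule degenerates to slice k = row
inner + k exactly. Slices are equal-depth-fraction ("normalized thickness")
slabs, not equal-micron slabs: the downstream depth analysis is phrased in
percent of choroid thickness, which only makes sense on the normalized
scale.

## Feature registry (52 features)

Conventions the literature leaves open were fixed as follows and are
configurable where noted:

* Histogram statistics (energy, entropy, mode) use 256 unit-width bins
  centred on integers 0..255; entropy is in bits everywhere (FOS and all
  GLCM entropies). Mode ties resolve to the lowest bin.
* Histogram width is P90 − P10; skewness/kurtosis are standardized central
  moments with kurtosis reported as excess (constant ROI → 0 for both).
  Coefficient of variation is population std over mean; a zero-mean ROI
  (impossible for real tissue at 8 bits) reports CV = 0 with a warning.
* GLCM: distance 1, angles {0°, 45°, 90°, 135°}, 32 equal-width gray levels
  over the ROI min–max (stabilizes co-occurrence estimates on small
  irregular ROIs; `GLCMSpec.levels` is configurable), symmetric, normalized;
  only pixel pairs with both members in-mask are counted; the 14 Haralick
  statistics are averaged over the directions that have at least one valid
  pair. Degenerate marginals (zero variance) define correlation and the
  information measures as 0; the maximal correlation coefficient is the
  square root of the second-largest eigenvalue of
  Q(i,j) = Σ_k p(i,k)p(j,k)/(p_x(i)p_y(k)), clamped to [0, 1].
* Gabor: intensities are rescaled to [−0.5, 0.5] before filtering; the bank
  is 4 angles × 2 frequencies (0.1, 0.4 cycles/pixel) at bandwidth 1 octave;
  kernels are DC-corrected (zero mean) so constant images give exactly zero
  response; the complex response magnitude is computed over the full image
  with reflect padding and pooled (mean, std) over pixels whose kernel
  centre is in-mask. Convolution runs in the Fourier domain with kernel
  transfer functions cached per image shape; circular wrap-around is
  prevented by padding at least half the largest kernel on every side.
* Laws texture energy: 3×3 kernels from L3/E3/S3 outer products; the ROI
  mean is subtracted before filtering (Laws' illumination-removal step),
  which makes every energy — including the LL normalizer — exactly invariant
  to constant intensity shifts; energies are mean absolute responses over
  in-mask centres; mixed pairs average both kernel orders; LE, LS, EE, ES,
  SS are normalized by LL (all six are 0 for a constant image, which has no
  fluctuation energy).

## Group statistics

Features are z-scored across all images (population std; zero-variance
features are centred and left at 0 with a warning). Group differences use
Welch's unpaired t-test per feature at the image level, with Bonferroni
correction over the number of features tested (52 when all families are
included) at family-wise α = 0.05. Image-level testing replicates the
original study design even though images within an eye are correlated; an
eye-level aggregation mode (mean feature per eye, `unit="eye"`) is provided
for a clustering-aware alternative. Features are ranked within family by raw
p, ties broken by |t| then name.

## Classification

The classifier is L2-penalized logistic regression (unit penalty, intercept,
no class weighting); non-convergence triggers one retry at a stronger
penalty with a logged warning. Cross-validation is leave-one-eye-out: the
fold unit is the eye (the original design), with a leave-one-patient-out
option since a patient can contribute two eyes. Per fold, z-scoring
parameters are estimated on training images only. Accuracy is the per-eye
fraction of held-out images correct at threshold 0.5, summarized by the mean
over eyes with a 95% percentile bootstrap CI (1000 iterations, resampling
eyes). ROC-AUC is computed on pooled out-of-fold probabilities — a single
held-out eye contains one class, so per-eye AUC is undefined — and its CI
bootstraps eyes and re-pools; single-class bootstrap replicates are skipped.
The shuffle control permutes labels at the eye level (every image of an eye
keeps one reassigned label, group sizes preserved). Fellow transfer trains
once on all healthy+CSCR images and reports the fraction of fellow images
classified CSCR, with a CI over fellow eyes.

## Depth analysis

The en face stack is cut into consecutive windows covering 10% of normalized
choroid thickness each; the CV is repeated with training and test sets both
restricted to the window. The trend is the OLS slope of per-window mean
accuracy (in percent) on window-centre depth, reported per 10% depth step.
Its CI resamples eyes with replacement, recomputes each window's mean
accuracy from the eyes present, and refits (percentile interval, 1000
replicates, seeded); a regression-standard-error CI would ignore the
between-eye dependence of the windows, so resampling was chosen.

## Synthetic cohort generator

The generator is the test bed: it emulates the *structure* of a chorioretinal
OCT study, not retinal anatomy. Defaults mirror the emulated study design —
30 healthy / 39 CSCR / 20 fellow eyes, 500 b-scans and 100 en face slices
per eye — with `desk_scale()` (10 eyes/group, 20 b-scans, 50 slices,
64×256 px, base thickness 40 px) used throughout the tests and analysis
drivers to keep runs to minutes on one CPU.

Per b-scan: smooth sinusoidal choroid boundaries; constant tissue
reflectivity (default 120/255) times gamma-distributed multiplicative
speckle (shape 4, mean 1 — the standard first-order model of fully
developed OCT speckle); dark soft-edged elliptical vessel cross-sections
(aspect 1.5, darkening factor 0.7) placed by a Poisson process (default
0.002 vessels per choroid pixel, ≈6% area fraction in healthy eyes). A
vessel centred at normalized depth d has radius
`vessel_radius_base_px · group_multiplier · (1 + depth_gradient · d)`:
the group multiplier (healthy 1, CSCR and fellow 1.5 by default) encodes
pachyvessel dilation, and the depth gradient (default 1) the
choriocapillaris-to-Haller calibre progression, so the absolute group
difference in vessel size grows with depth.

Each eye additionally draws log-normal random effects (σ = 0.25) on
thickness, reflectivity, and vessel density, shared by all of its images.
Between-eye variability of this order matches reported between-subject
variation in choroidal thickness and is essential for honest evaluation:
without it, images are i.i.d. across eyes, and leave-one-eye-out under a
null configuration exhibits the well-known pessimistic leave-one-out bias
(mean accuracy systematically below 0.5 with a spuriously narrow CI). Eyes
are generated from independent seed-sequence spawns of the cohort seed, so
cohorts are bit-reproducible and grow consistently with eye counts.

What the generator does *not* emulate: anatomically realistic vasculature
(vessels are independent ellipses, not connected trees), device-specific
noise or shadowing, retinal layers above the choroid, motion artifacts, and
any intensity difference between groups beyond vessel geometry. Passing
tests therefore demonstrate that the pipeline recovers *constructed*
texture/geometry contrasts under realistic noise and clustering — not that
the features capture real CSCR biology.

## Calibration checks and their problem sizes

The test suite verifies, at desk scale: null calibration (no-effect cohorts,
10 eyes/group × 20 b-scans: the 95% accuracy CI should cover 0.5 across
seeds), shuffle-control calibration on strong-effect cohorts, effect and
depth-gradient recovery, transfer direction, and bootstrap coverage against
a known mean. Depth-recovery cohorts use 8 eyes/group, 12 b-scans, and
50-slice stacks (10 windows of 5 slices), with per-window bootstraps
reduced to 50 iterations — the windows' own CIs do not enter the slope fit,
which keeps its full 1000-replicate bootstrap.

The depth-recovery cohorts also use a distinct vessel operating point:
base radius 0.7 px, depth gradient 2, density 0.008, darkening 0.4. Under
the generative rule the radius *ratio* between groups is constant in depth,
so when vessels are resolvable at every depth the classifier's
discriminability — and hence accuracy — need not increase with depth at
all (measured: flat or even decreasing profiles, as large deep vessels
move energy below the filter bank's frequencies). A measurable positive
trend requires the biologically faithful regime in which shallow vessels
are sub-resolution (choriocapillaris calibre, lost in speckle) and grow
through the detection threshold toward Haller-layer calibre; the group
difference then becomes visible only at depth. The default desk-scale
cohort (3 px vessels, resolvable everywhere) keeps its flat-profile
behaviour, which the depth analysis reports as a slope CI containing 0.

Known limitations, measured on this generator:

* Under a null (or shuffled) cohort, the eye-bootstrap accuracy CI
  undercovers: across 60 null cohorts at 10 eyes/group the 95% interval
  contained 0.5 in ~80% of runs, not ≥95%. Two mechanisms combine.
  Leave-one-eye-out with fold-wise z-scoring is pessimistically biased (the
  held-out eye's class is always the training minority, mean null accuracy
  ≈ 0.48), and — more importantly — per-eye accuracies are positively
  correlated through the cohort-level chance direction the classifier
  learns, while resampling eyes treats them as exchangeable. Adding eyes
  tightens the interval faster than it shrinks the chance-direction spread,
  so coverage does not improve with cohort size. The same caveat applies to
  reading a single shuffle control's CI: the spread of shuffled accuracy
  across permutations is wider than any within-cohort CI suggests.
* Image-level t-tests ignore within-eye correlation (by design, with an
  eye-level aggregation option).
* The percentile bootstrap itself undercovers mildly at ~20 eyes even for
  i.i.d. values (measured ≈ 92–94% at nominal 95%).
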