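# Methods

## The problem and the measurement model

Terminal exhaustion of tumor-infiltrating CD8+ T cells (PD-1-high cells
that no longer respond to checkpoint blockade) correlates, in murine
FDG-PET, with a more heterogeneous intratumoral uptake pattern:
exhausted infiltrates locally suppress glucose consumption, punching
"cold spots" into an otherwise smoother uptake landscape. The pipeline
quantifies that pattern with gray-level texture features and condenses
it into a binary logistic **T-exhaustion score** over three PET
features,

```
score = −297.597 · InverseVariance(GLCM) + 178.689 · Homogeneity2(GLCM)
        + 1.088 · Kurtosis(IntensityHistogram) + 1.485
```

interpreted as the log-odds that a tumor's terminal-Tex fraction lies
above the cohort median; the probability is the logistic transform of
the score. The packaged model carries these printed coefficients
verbatim and is immutable. Whether the original C-index was computed on
the score or the probability is immaterial: the two are monotonically
related, so every rank-based quantity is identical.

Because the original mouse micro-PET/CT and cytometry data are not
public, the pipeline is exercised end-to-end on synthetic phantoms whose
ground truth is known by construction. Everything downstream of the
generator (SUV conversion, feature definitions, CCC filter, LASSO
screen, logistic score, evaluation metrics) is the analysis a real
study would run unchanged on real volumes.

## The phantom generator

Each subject is a 48³ voxel grid at 0.5 mm isotropic spacing holding a
co-aligned PET activity volume, a CT-like density volume, and an exact
ellipsoidal tumor mask (default semi-axes 3.9/3.6/3.3 mm ≈ 194 mm³, the
treatment-start volume of the murine models; 5.55 MBq injected dose,
20 g body weight). The PET lesion, modeled on the SUV scale and stored
as the corresponding activity concentration, is

```
uptake(x) = (base + smooth(x)) · exp(−cold(x) / base) + noise
```

- `smooth` — 40 broad Gaussian bumps (σ = 1.8 mm) normalized to a fixed
  ROI standard deviation of 0.15·gain·base: the benign large-scale
  uptake variation every lesion has. Normalizing the realized field
  keeps the baseline texture amplitude comparable across seeds.
- `cold` — 250 narrow suppression kernels (σ = 0.4 mm) with per-kernel
  depths uniform in [0.12, 0.24]·gain·t·base, where `t` is the
  subject's terminal-Tex fraction and `gain` the heterogeneity-coupling
  knob (default 1). Suppression acts multiplicatively (`exp(−cold/base)`)
  so overlapping kernels deepen smoothly and never clip to a flat
  floor — a hard floor would paradoxically *raise* measured homogeneity
  in deeply suppressed lesions.
- `noise` — additive Gaussian, default σ = 0.02 SUV, floored at 1% of
  base; full Poisson reconstruction noise is out of scope.

Kernel positions and depths are drawn once per subject seed and the
depths scale linearly with `t`, so a fixed-seed sweep over `t` moves
texture monotonically: Homogeneity2 and InverseVariance fall, Contrast
rises, ROI variance rises. This is the generator's central design
property, verified across seeds in the test suite.

The CT volume is a smooth density ellipsoid (sigmoid edge) with mild
seeded bumps and noise, independent of the exhaustion state — a texture
carrier so CT features are well defined, not a second biomarker channel.

**Exhaustion states.** The terminal-Tex fraction is drawn from a
truncated normal with per-timepoint mean/sd; early Tex occupies a fixed
90% of the remaining CD8+ pool (so early + terminal ≤ 1 always holds;
the complement population size is not otherwise constrained); PD-1 MFI
rises linearly with `t` under lognormal scatter. Calibrated
timecourses: LLC post-irradiation (0.40, 0.42, 0.73, 0.72, 0.30 at days
0/3/7/14/21 — baseline ≈ 40%, peak inside the observed 69.44–76.35%
band, day 21 below baseline), LLC under checkpoint inhibition (0.40 →
0.46, ICI-resistant), B16 under checkpoint inhibition (0.20 → 0.12,
reinvigorating). Intermediate-day means are implementation choices
consistent with the qualitative trajectories, not measured values.

**Test–retest pairs.** The lesion model is analytic in position, so a
retest scan is the same latent lesion evaluated at coordinates shifted
by a sub-voxel repositioning draw (per-axis Gaussian, default
σ = 0.25 mm), rescaled globally (1 + Gaussian, default σ = 0.02), with
the mask re-rasterized at the shifted position and independent extra
noise added. All-zero perturbation reproduces the test scan exactly.

**Cohorts.** Per-subject seeds derive from a master seed through
`SeedSequence`; the high/low label is assigned by the cohort median
split of the terminal-Tex fraction with ties to the low class
(deterministic). Cohort geometry is standardized: all subjects share
the template ellipsoid. Size variation was deliberately not added —
it injects feature variance that makes small cohorts separable and the
refit unstable — so shape features, while extracted, carry no
cohort-level signal and drop out of screening as constants.

## Feature extraction

PET features are computed on SUV (`activity × weight / dose`, no decay
correction); CT features on raw density. The catalogs are pinned by
shipped manifests: 61 PET features (17 intensity-direct, 12
intensity-histogram, 21 GLCM, 11 GLRLM) and 57 CT features (10 shape,
11 intensity-direct, 8 intensity-histogram, 18 GLCM, 10 GLRLM). The
exact composition of the original study's catalogs is not in its main
text; the manifests contain every feature its Table 1 names, match the
printed counts, and draw only from the named families.

- **Discretization**: fixed bin count (default 64 levels) over the ROI
  min–max; the maximum maps to the top level; a constant ROI maps to
  level 1. Fixed-bin-count makes all histogram/texture features
  invariant to positive affine intensity rescaling (asserted in tests);
  intensity-direct features are deliberately not invariant.
- **GLCM**: distance 1, the 13 unique 3D directions, symmetric (each
  ordered pair counted both ways), matrices summed over directions
  before normalization. Degenerate policies keep values finite:
  Correlation and the information measures are 0 when their
  denominators vanish; InverseVariance — a sum over off-diagonal
  entries only — is 0 for a purely diagonal matrix (the limit of
  vanishing off-diagonal mass).
- **GLRLM**: maximal same-level runs per direction (out-of-mask voxels
  break runs), summed over the 13 directions; run percentage divides
  the run count by in-mask voxels × directions.
- **Kurtosis** is Pearson (non-excess) `m4/m2²` with population
  moments for both flavors; the two Kurtosis features differ only in
  input (raw values vs discretized levels). Constant-ROI skewness and
  kurtosis are set to 0 and flagged.
- **Shape**: volume = voxel count × voxel volume; surface area from the
  marching-cubes mesh of the mask after slight Gaussian smoothing
  (σ = 0.6 voxel) — unsmoothed binary marching cubes overestimates a
  sphere's area by ≈ 8%, while the smoothed mesh brings a radius-10
  digital ball's Compactness2 within 5% of 1 and a side-40 cube's
  within 0.05 of π/6 (the mesh chamfers cube edges, an O(1/s) bias no
  estimator avoids while also handling spheres well). Convex hull over
  foreground voxel centers in physical coordinates.

Both texture matrix builders are validated exactly against brute-force
pair/run enumerators on random small ROIs.

## Robustness filtering

Lin's concordance correlation coefficient with population (1/n)
moments,

```
CCC = 2·s_xy / (s_x² + s_y² + (x̄ − ȳ)²),
```

computed per feature across subjects between test and retest tables; a
feature is retained iff CCC strictly exceeds the modality threshold
(CT 0.75, PET 0.65 — the original study's configuration; why the
thresholds differ per modality is not explained there and is treated as
given). Identical constant series count as perfectly reproducible (1);
the 1/(n−1) moment variant would differ negligibly. Replication of the
RIDER test–retest analysis would require an external download and is
not part of the pipeline or its tests.

## Selection and the score refit

LASSO screening regresses each exhaustion characteristic (early-Tex,
terminal-Tex, E/T, PD-1 MFI — and optionally the binary label) on the
robustness-passing features: L1-penalized linear regression for
continuous targets, L1-penalized logistic for the binary one. The
original description ("LASSO logistic regression" against continuous
characteristics) is ambiguous; both links are provided and reported.
Features are standardized internally; the penalty is chosen by
leave-one-out cross-validation at the smallest mean deviance (no
one-standard-error rule, for determinism); coefficients are reported on
the original scale. Under a null target this estimator retains an
occasional spurious feature (measured: ≤2 of 9 features in ~83% of
replicates, exactly zero in ~62%) — an accepted property of min-CV
LASSO without the 1-SE rule. Among strongly collinear texture features
the selected representative is effectively arbitrary; the final score
always uses the canonical trio.

The score refit is logistic regression of the median-split label on the
three named features. Features are standardized internally and a light
ridge penalty (C = 1000 on the standardized scale) stabilizes the fit:
for well-conditioned cohorts it is numerically indistinguishable from
the unpenalized fit, but when a small cohort is perfectly separable —
where unpenalized maximum likelihood does not exist and the optimizer
returns an exploded, arbitrary direction of the collinear features —
it bounds the coefficients and preserves out-of-cohort ranking.
Coefficients are mapped back to the original feature scale, and the
training median is stored with the model.

## Evaluation

- **C-index**: over all (high, low) label pairs, fraction ranked
  concordantly, ties 0.5 — equal to AUC for binary outcomes.
- **Brier score**: mean squared difference between predicted
  probability and the 0/1 label.
- **Calibration**: 5 equal-width probability bins by default (binning
  unstated in the original), empty bins omitted, counts conserved.

## The synthetic experiment

The training arm mirrors "checkpoint-inhibitor groups as training set":
n = 20 subjects alternating LLC-like and B16-like ICI timecourses over
days 0/7/22, spanning terminal-Tex ≈ 0.1–0.5. Robustness is established
on a separate 30-subject test–retest cohort; the three score features
must survive the PET filter or the run aborts. The validation arm
applies the frozen model to an independently seeded n = 20 post-
irradiation cohort (days 0–21, terminal-Tex up to ≈ 0.8), labeled by
its own median split. Default cohort sizes are n = 20 per arm — larger
than the original 3 mice/group/timepoint — chosen for statistical
stability of the synthetic benchmark. Every run is a pure function of
its configuration; the config hash is stamped into outputs and a
manifest lists artifacts with checksums.

## What passing tests do and do not show

The generator plants a strong, clean monotone texture signal with
controlled noise; real PET carries reconstruction artifacts, partial-
volume effects, motion, and biological confounders none of which are
modeled. Passing discrimination bounds on phantoms demonstrates that
the pipeline's machinery is correct and that the texture→exhaustion
coupling is recoverable end-to-end — not that the score generalizes to
real scanners or other tumor models. The packaged printed coefficients
live on the original study's (unpublished) feature scale: on these
phantoms the −297.597·InverseVariance term dominates and the packaged
model calls essentially everything low-exhaustion. It is shipped as a
reference artifact and for scoring data on a comparable scale; new
cohorts should use the refit.

## Known limitations

- No PET/CT registration, no DICOM, no decay correction, no wavelet or
  2D feature classes, no ICC/Bland–Altman alternatives to CCC.
- Median-split ties go to the low class by convention; other tie rules
  change labels only on exact ties.
- Multivariate logistic coefficient signs are unstable when
  InverseVariance and Homogeneity2 are nearly collinear (their
  univariate associations with exhaustion are both negative, and the
  published equation itself carries opposite multivariate signs);
  directionality claims are therefore tested univariately.
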