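# Methods

## Scope and data model

The pipeline operates on co-registered, skull-stripped multispectral brain
MRI — three channels per subject-visit (FLAIR-like, T2-like, MT/T1-like) on
one voxel grid — plus a longitudinal cognition table. Registration and skull
stripping are out of scope: mismatched grids are refused with an error, never
resampled. All volume arithmetic is voxel count × voxel volume (mm³),
reported in cm³; an interslice acquisition gap is carried as metadata only,
so gap tissue is deliberately not counted.

Because no clinical imaging ships with the package, a phantom generator
defines the study conditions, and every empirical claim in the test suite is
made against its ground truth.

## Phantom generator

Geometry: an ellipsoidal brain (semi-axes 80/88/82% of the half field of
view), a grey-matter shell outside a white-matter ellipsoid scaled to 78% of
the brain axes, and two ellipsoidal ventricles (CSF) flanking the midline.
The default grid is 96×96×24 voxels at 2×2×6 mm — clinical in-plane
resolution with the strong slice anisotropy typical of 2-D FLAIR
acquisitions, at desk-scale cost.

Lesions: `n_lesion_foci` centres (default 8) sampled uniformly among
white-matter voxels whose distance to the WM boundary leaves room for the
fully grown core plus rim (with an optional periventricular sampling bias,
default off = uniform). The lesion fraction field is 1 inside a core of
radius r_v = r₀ + g·v at visit v (default r₀ = 8 mm, growth g = 1.5 mm/yr
over 4 annual visits) and ramps linearly to 0 across a rim of width 4 mm;
white matter takes up the complement, so the four tissue fractions sum to 1
at every brain voxel and lesion fraction is non-decreasing in visit. If no
interior voxel can host the final-visit extent the requirement relaxes to
the baseline extent with a warning, and errors only if even that fails.

Intensities: channel k at voxel v is `Σ_t fraction_t(v)·signature(t,k)`,
multiplied by a smooth random bias field in [1−a, 1+a] (a = 0.05; a coarse
4×4×3 uniform grid upsampled by cubic splines), plus i.i.d. Gaussian noise
(σ = 4 intensity units against tissue contrasts of 10–85 units). Rician
noise is deliberately not used: the phantom operates far from the low-SNR
magnitude-image regime where the distinction matters, and the flag exists
for future work. Signatures encode the standard contrasts — FLAIR:
lesion 100 > GM 65 ≥ WM 55 > CSF 20; T2: CSF 100 > lesion 85 > GM 60 >
WM 50; MT: WM 85 > GM 60 > lesion 45 > CSF 15. The deliberate consequence is
that a ~50/50 WM-lesion mixture is closest to grey matter in feature space —
the real ambiguity partial-volume methods must survive. Background voxels
are exactly zero, which the threshold-based brain-mask stand-in exploits.

Cognition: each subject's latent domain score (speed, executive, memory)
follows the same linear model the statistics module fits —
`effect_main·log V + β_t·t + effect_interaction·log V·t + covariates +
ε_i`, with ε_i drawn per domain from an unstructured 4×4 covariance
(default variances 0.8–1.1, correlations 0.6^|i−j|). Defaults:
effect_main = −0.15 z per log cm³, effect_interaction = −0.05 z/yr per
log cm³, demographics matched to a typical elderly small-vessel-disease
cohort (age 74.2 ± 4.8, 57.7% women, education 11.7 ± 4.3 years), baseline
lesion volumes log-normal with mean 18.5 and SD 20.6 cm³, and 28% of
subjects losing their last visit (the published range of last-visit
missingness in such cohorts is 24–32%). Subtests are the latent plus
independent noise (SD 0.4 latent units) on published scales, with timed
tests (Trail making, Stroop, maze) emitted inverted — larger = slower — so
the scoring module's sign handling is genuinely exercised. The latent
scores are kept in the output (`latent_*` columns) as simulation ground
truth for recovery experiments.

What the phantom does *not* emulate: real anatomy (no gyri, no cortical
folding), multimodal within-tissue intensity distributions, MR physics
(TE/TR/TI are not simulated), motion or ghosting, infarcts and lacunes, and
spatially correlated noise. Passing tests therefore demonstrate that the
algorithms are correct and well calibrated under the stated forward model —
not that segmentation accuracy transfers to clinical data.

## Segmentation

Features are per-channel robust-normalized in-mask intensities
((x − median)/1.4826·MAD, with an SD fallback when the MAD degenerates to
zero on discrete noiseless data; truly constant channels are an error).
Normalization is per subject: cross-subject intensity pooling is neither
needed nor attempted.

Self-supervised seeds: 4-means groups are mapped to tissues by matching each
group's per-channel intensity ranks to canonical orderings (FLAIR: lesion
brightest, CSF darkest; T2: CSF brightest, WM darkest; MT: WM brightest,
lesion below GM); identical rank signatures across groups raise an
ambiguity error. Within each group the 10% of voxels nearest its centre
(configurable up to 25%) become seeds; on default phantoms seed purity
against ground truth is ≥ 99.9%.

The discriminative clustering minimizes
`J = Σ‖x−μ_c(v)‖² + λ Σ_seeds (1 − P(label|c(v)))` (λ = 10; distances are
O(1) after normalization) by alternating assignment and update, with
Laplace-α=1 label distributions, empty clusters re-seeded from the farthest
voxel, and ties broken toward the lowest cluster index. Because the
smoothed P is a function of the assignment, a sweep can in principle raise
J; the fitter evaluates J after each sweep and rolls the sweep back if it
would increase, so the recorded objective trace is non-increasing by
construction. With λ = 0 the procedure is exactly Lloyd's K-means, which a
scikit-learn run from the same initialization confirms to 1e-6.

Two design choices differ from an earlier plan and deserve their rationale:

* **K = 4 clusters by default.** With K well above the number of tissues,
  the clusters covering partial-volume voxels contain no seeds, and their
  Laplace-uniform label distributions flatten P(lesion|x) across the rim
  (measured: rim-bin probabilities pinned near 0.25, Pearson r against true
  fraction ≈ 0.65, and an empty DC33 category). At K = 4 every cluster is
  anchored by seeds and the soft memberships interpolate between informative
  clusters (r ≈ 0.86–0.92, populated DC33 band). The phantom's
  class-conditional densities are unimodal Gaussians, so one cluster per
  tissue is also the statistically appropriate complexity; data with
  multimodal tissue distributions need a larger K *together with* a seeding
  scheme that labels every mode.
* **Seed-informed initialization.** Farthest-point seeding placed initial
  centroids on intensity outliers and, in ~5% of replicate phantoms,
  collapsed GM and WM into one cluster. Initial centroids are therefore the
  per-tissue seed means (the natural use of self-generated labels);
  farthest-point selection remains for K > 4 extras and as the fallback when
  seeds are degenerate.

Soft memberships use a Gaussian kernel with temperature τ set to the RMS
*pairwise* within-cluster distance at convergence (τ² = 2·E‖x−μ‖²); the
pairwise reading widens the bridge between neighbouring clusters, which is
what graded partial-volume probabilities live on. Voxels are treated as
exchangeable — no spatial regularization — so probability maps are purely
intensity-driven.

## Staging and volumes

The percentage labels are read as thirds: with p = P(lesion|x), argmax =
lesion gives DC100 (p > 2/3) or DC66 (p ≤ 2/3, boundary inclusive to keep
the partition exhaustive); lesion second-most-probable with p ≥ 1/3 gives
DC33; otherwise NONE. DC33 ∩ (DC66 ∪ DC100) = ∅ by construction, and
V_DCHARD = V_DC66 + V_DC100 exactly. Dice of two empty masks is defined as
1 (perfect agreement on absence); empty vs non-empty is 0.

The conventional-segmentation surrogate thresholds each axial slice at the
in-mask mean + 2.5 SD (both computed after discarding the brightest 1%, so
lesions do not inflate their own threshold), then removes 26-connected
components below 5 voxels. It stands in for semi-automated operator marking,
which cannot be reproduced algorithmically; slices with fewer than 50
in-mask voxels are skipped with a warning. Because the threshold is
slice-adaptive, the mask is a level set of lesion fraction per slice, not
globally.

Progression: the fraction of baseline DC33 voxels lying inside follow-up
DCHARD is compared with the same fraction over baseline normal-appearing
white matter (category NONE, WM most probable); their ratio is the
enrichment. Zero DC33 voxels yield NaN with a warning rather than an error.

## Cognition scoring

Compounds are equal-weight means of baseline-standardized subtest z-scores:
speed = (Trail A + maze + digit cancellation)/3, executive =
((Stroop III−II) + (Trail B−A) + SDMT + verbal fluency)/4, memory =
(immediate recall + delayed recall + recognition + digit span)/4. Timed
measures (Trail A, Trail B−A, Stroop III−II, maze) are sign-flipped so
higher always means better. Norms are visit-0 mean and sample SD; follow-up
visits are scored with baseline norms (not re-standardized per visit), so
cohort decline appears as negative drift — the standard longitudinal choice.
A missing constituent leaves the compound missing; the mixed model absorbs
missingness.

## Mixed models

Time is a categorical 4-level factor with sum-to-zero contrasts, so the
volume main effect is the average-over-visits effect and the per-year
volume effects (β_v plus the year's interaction contrast) average exactly to
it. Volumes enter as log(V + ε) with ε one voxel volume (0.024 cm³) — the
smallest measurable nonzero volume — so zero volumes are well-defined.

Estimation maximizes the REML criterion over the log-Cholesky factor of the
unstructured 4×4 residual covariance (positive-definite by construction),
with analytic gradients, L-BFGS-B, and a Newton polish on a finite-difference
Hessian; subjects are grouped by observed-visit pattern so incomplete
subjects use the covariance submatrix of their visits. On balanced complete
data under saturated time means the estimate reproduces the n−1 sample
covariance to ~1e-8 — a closed-form identity used as a correctness check —
and fixed effects and covariance agree with an independent generalized
least squares implementation (nlme::gls with corSymm/varIdent) to ~1e-5.
Forcing Σ = σ²I (`structure="scaled_identity"`) reproduces OLS coefficients
exactly on complete balanced data.

Inference: the naive GLS covariance of the fixed effects ignores the
sampling variability of the estimated Σ and measured ~7% type-I error for
the 3-df interaction test at n = 100, so the coefficient covariance carries
the Kenward–Roger small-sample inflation (computed in the covariance-entry
parameterization, where the structure is linear and second-derivative terms
vanish; entry uncertainty maps from the log-Cholesky parameters by the
delta method), and multi-df F tests use the Kenward–Roger scale and
denominator df. Single-df contrasts use Satterthwaite df; a residual-df
fallback is available (`ddf_method="residual"`). Measured calibration of the
interaction test: ~4.5–6% rejection at nominal 5% over 500 null cohorts of
n = 100. α = 0.05 two-sided throughout, with no multiple-testing correction
across the 30-cell model grid — a reproduction choice, not a recommendation.
Non-convergence is flagged (`converged=False` with the gradient norm), never
silent; singular designs (constant or collinear predictors, a wholly
unobserved visit level) raise immediately.

## Simulation study designs (problem sizes)

* Type-I error: 500 null cohorts, n = 100 subjects, default dropout.
* Power curve: effect ∈ {0, −0.025, −0.05} z/yr per log cm³, 400 cohorts
  each at n = 300 (chosen so the three rejection rates separate cleanly).
* Slope recovery: 200 cohorts, n = 200, effect −0.05, 30% last-visit
  dropout; the mean of the per-year-slope estimates is compared with truth
  in Monte-Carlo SE units.
* Progression: 20 replicate default phantoms, baseline vs last visit.
* Recovery/calibration experiments fit the latent executive score directly,
  so the generating coefficients are the truth on the fitted scale.

## Numerical and degenerate-input choices

Geometry equality tolerance 1e-4 mm; probability-sum validation 1e-6 on
input, 1e-9 guaranteed on output; REML optimizer bounds log-diagonal
Cholesky entries to ±10 and returns a large penalized value (not a crash)
at numerically singular trial points; the REML start is the OLS residual
pairwise covariance with eigenvalues floored at 1e-4 of the largest. The
brain-mask stand-in closes 1-voxel noise gaps in-plane (zero-padded so the
closing cannot erode the array border) before the largest-component and
slice-wise hole-fill steps.

## Known limitations

Phantom realism bounds every claim: accuracy numbers (Dice ≈ 0.98 against
truth, partial-volume r ≈ 0.89) characterize the forward model, not clinical
MRI, where registration error, inhomogeneity, multimodal tissue classes and
pathology beyond WML (infarcts, lacunes — whose surrounding hyperintensity
clinical raters deliberately disregard) all degrade performance. The
conventional-segmentation surrogate is an explicit stand-in for operator
marking. The DC33 shell on spherical-focus phantoms is thin (a fraction of
a cm³), so its volume is a coarse quantity at 2×2×6 mm resolution. The
cognition generator ties all three domains to the same lesion-volume
coefficients and injects no independent signal for early-stage damage, so
incremental-prediction analyses on phantom cohorts are expected nulls.
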