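# wml-stager

Staging of white-matter lesions (WML) from multispectral brain MRI, and
longitudinal modelling of how each lesion stage predicts cognitive decline —
implemented as a fully testable pipeline on synthetic phantoms with known
ground truth.

WML are the core imaging marker of cerebral small vessel disease, but
conventional FLAIR segmentation only captures fully developed hyperintensity:
each voxel is either lesion or not, decided by an implicit intensity
threshold. Partial-volume voxels — tissue that is only fractionally lesioned —
fall below that threshold, yet they are exactly where early, "pre-visible"
damage lives. This package is for researchers who want to (a) recover
per-voxel tissue membership *probabilities* from co-registered FLAIR/T2/MT
volumes, (b) stage lesion tissue into small / intermediate / fully developed
partial-volume categories, and (c) test whether the earliest stage carries
independent prognostic information for cognitive decline.

## Method

**Segmentation.** In-mask voxels are robust-normalized feature vectors
x_v ∈ R³ (one dimension per pulse sequence). A coarse 4-means clustering,
mapped to tissues (CSF, GM, WM, lesion) by canonical per-channel intensity
rankings, self-generates a small set of confident seed labels — no annotator.
A discriminative clustering then minimizes

    J = Σ_v ‖x_v − μ_c(v)‖² + λ Σ_{v∈seeds} (1 − P(label_v | c(v)))

by coordinate descent, where P(·|c) is the Laplace-smoothed distribution of
seed labels in cluster c: clusters must be both compact and label-consistent.
Soft memberships follow from Gaussian-kernel responsibilities,
P(c|x) ∝ exp(−‖x−μ_c‖²/2τ²), and tissue probabilities are
P(t|x) = Σ_c P(t|c) P(c|x).

**Staging.** With p = P(lesion|x): voxels where lesion is the most probable
tissue are `DC100` (p > 2/3) or `DC66` (p ≤ 2/3); voxels where lesion is the
*second* most probable tissue with p ≥ 1/3 are `DC33` — sub-threshold,
early-stage lesion that conventional segmentation calls normal. Volumes
V_DC33, V_DC66, V_DC100 are voxel counts × voxel volume;
V_DCHARD = V_DC66 + V_DC100 is the estimate of the visible lesion, compared
against a conventional slice-wise mean + k·SD FLAIR threshold (V_FLAIR) by
the Dice coefficient 2|A∩B|/(|A|+|B|).

**Longitudinal statistics.** Cognitive outcomes (MMSE, VADAS, and speed /
executive / memory compounds built from baseline-standardized subtest
z-scores) are modelled per subject-visit as

    y_ij = β₀ + β_v log V_i + Σ_t β_t 1[j=t] + Σ_t β_vt log V_i·1[j=t]
           + β_a age_i + β_s sex_i + β_e edu_i + ε_ij,   ε_i ~ N(0, Σ)

with Σ an unstructured 4×4 within-subject covariance estimated by REML
(log-Cholesky parameterization, analytic gradients), time as a sum-to-zero
categorical factor so the volume main effect is the average-over-visits
effect, a 3-df F test for the volume×time interaction, per-year volume
contrasts, and Kenward–Roger small-sample adjustment with
Satterthwaite-style denominator df. Incomplete subjects contribute their
observed visits (missingness is absorbed, not imputed).

**Phantoms.** Because the clinical cohort behind this design is not public,
an ellipsoidal-brain phantom generates 3-channel volumes with known tissue
fractions: lesion foci in white matter with fully lesioned cores and linear
partial-volume rims, radial growth across four annual visits, smooth bias
fields, Gaussian noise, and matched cognition trajectories whose decline
slope depends on log lesion volume — so every step of the pipeline is tested
against ground truth.

## Worked example

```python
from wml_stager import phantom, dc_segment, lesion_volumes

cfg = phantom.PhantomConfig(rng_seed=0)          # 96x96x24 @ 2x2x6 mm
volumes, truth = phantom.generate_longitudinal_phantom(cfg)

tpm, model, seeds = dc_segment.segment_volume(volumes[0], seed=0)
cat = lesion_volumes.categorize_voxels(tpm)
flair_mask = lesion_volumes.segment_flair_conventional(
    volumes[0].get_channel("FLAIR"), volumes[0].brain_mask)
vs = lesion_volumes.compute_volumes(cat, flair_mask)
print(vs.V_DC33, vs.V_DC100, vs.dice_flair_dchard)
```

Running `python analysis/02_segment_and_stage.py` prints, for the default
phantom (true baseline lesion volume 33.98 cm³):

```
 visit_year  V_DC33  V_DC66  V_DC100  V_DCHARD  V_FLAIR  true_volume_cm3  dice_flair_dchard  dice_dchard_truth
          0   0.504   0.648   29.616    30.264   29.856           33.978              0.964              0.984
          3   2.352   2.160   84.888    87.048   67.248           96.499              0.868              0.952
```

V_DCHARD tracks the growing visible lesion (Dice ≥ 0.95 against the true
majority-lesion region), the conventional FLAIR surrogate agrees with it
imperfectly, and V_DC33 is a thin shell ahead of the visible boundary. The
partial-volume recovery curve at baseline has Pearson r = 0.888 between true
lesion fraction and estimated P(lesion) over 1342 rim voxels.
`python analysis/03_progression_overlap.py` shows why DC33 matters: over 20
replicate growth phantoms, 95–100% of baseline DC33 voxels convert to hard
lesion by the last visit, against a ~6% chance rate in normal-appearing
white matter (median enrichment ≈ 17) — early partial-volume voxels mark
future lesion sites. `python analysis/05_mixed_models.py` fits the full
3 predictors × 5 outcomes × {±V_FLAIR} mixed-model grid and writes the
main-effect / volume×time / per-year results table.

The `wml-stager` console script exposes the same steps
(`simulate`, `segment`, `volumes`, `progression`, `score`, `analyze`, and
`run` for the end-to-end pipeline with a hashed manifest).

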