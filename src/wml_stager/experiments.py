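"""Replicated simulation experiments over the phantom and the mixed model.

These drivers define the Monte-Carlo study designs the package reports:
interaction-test calibration (type-I error), power against the interaction
effect, recovery of the decline slope under last-visit dropout, the
partial-volume recovery curve, and progression enrichment over replicate
growth phantoms.  They are shared by the analysis scripts, the test suite
and the acceptance script so every number is produced by one code path.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from . import dc_segment, lesion_volumes
from .phantom import CognitionSimConfig, PhantomConfig, generate_longitudinal_phantom, simulate_cognition_cohort
from .longitudinal_stats import ModelSpec, fit_and_test

logger = logging.getLogger(__name__)


def _spawn_seeds(base_seed: int, n: int):
    ss = np.random.SeedSequence(base_seed)
    return [int(child.generate_state(1)[0] % (2**31)) for child in ss.spawn(n)]


def simulate_and_fit_interaction(
    seed: int,
    n_subjects: int,
    effect_interaction: float,
    dropout: float = 0.28,
    outcome: str = "latent_executive",
):
    """One replicate: simulate a cohort, fit the mixed model, test the interaction.

    Returns ``(p_interaction, slope)`` where ``slope`` is the least-squares
    slope of the per-year volume effects over visit years — the estimate of
    the decline-per-year-per-log-cm^3 interaction effect.
    """
    cfg = CognitionSimConfig(
        n_subjects=n_subjects,
        effect_interaction=effect_interaction,
        dropout_rate_last_visit=dropout,
        rng_seed=seed,
    )
    df = simulate_cognition_cohort(cfg)
    spec = ModelSpec(outcome=outcome, predictor="lesion_volume_cm3")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = fit_and_test(df, spec)
    slope = float(np.polyfit(res.per_year["year"], res.per_year["estimate"], 1)[0])
    return float(res.tests["volume_by_time"]["p"]), slope


def interaction_type1_error(
    n_reps: int = 500,
    n_subjects: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Rejection rate of the volume-by-time test under a true null."""
    pvals = [
        simulate_and_fit_interaction(s, n_subjects, 0.0)[0]
        for s in _spawn_seeds(seed, n_reps)
    ]
    pvals = np.asarray(pvals)
    return {
        "rejection_rate": float(np.mean(pvals < alpha)),
        "n_reps": n_reps,
        "n_subjects": n_subjects,
        "alpha": alpha,
    }


def interaction_power_curve(
    effects=(0.0, -0.025, -0.05),
    n_reps: int = 400,
    n_subjects: int = 300,
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Rejection rate of the interaction test at each effect size."""
    rows = []
    for j, eff in enumerate(effects):
        seeds = _spawn_seeds(seed + 101 * j, n_reps)
        pvals = np.array([
            simulate_and_fit_interaction(s, n_subjects, eff)[0] for s in seeds
        ])
        rows.append({
            "effect_interaction": eff,
            "power": float(np.mean(pvals < alpha)),
            "n_reps": n_reps,
            "n_subjects": n_subjects,
        })
    return pd.DataFrame(rows)


def interaction_recovery(
    n_reps: int = 200,
    n_subjects: int = 200,
    effect_interaction: float = -0.05,
    dropout: float = 0.30,
    seed: int = 0,
) -> dict:
    """Bias check for the decline slope under last-visit dropout.

    Reports the Monte-Carlo mean of the estimated interaction slope, its
    Monte-Carlo standard error, and the z-score of the deviation from truth.
    """
    slopes = [
        simulate_and_fit_interaction(s, n_subjects, effect_interaction, dropout)[1]
        for s in _spawn_seeds(seed + 7, n_reps)
    ]
    slopes = np.asarray(slopes)
    mc_se = float(np.std(slopes, ddof=1) / np.sqrt(n_reps))
    mean = float(np.mean(slopes))
    return {
        "mean_slope": mean,
        "mc_se": mc_se,
        "truth": effect_interaction,
        "z": (mean - effect_interaction) / mc_se,
        "n_reps": n_reps,
        "n_subjects": n_subjects,
        "dropout": dropout,
    }


def pv_recovery_stats(
    p_lesion: np.ndarray,
    true_fraction: np.ndarray,
    bins=(0.2, 0.4, 0.6, 0.8),
    half_width: float = 0.1,
    rim_range=(0.05, 0.95),
) -> dict:
    """Partial-volume recovery curve over rim voxels.

    Bins rim voxels by true lesion fraction and reports the mean estimated
    P(LESION) per bin, whether the bin means increase strictly, and the
    Pearson correlation between true fraction and estimated probability.
    """
    rim = (true_fraction > rim_range[0]) & (true_fraction < rim_range[1])
    bin_means = []
    for b in bins:
        sel = rim & (np.abs(true_fraction - b) < half_width)
        bin_means.append(float(p_lesion[sel].mean()) if sel.any() else np.nan)
    r = float(np.corrcoef(true_fraction[rim], p_lesion[rim])[0, 1])
    mono = all(
        bin_means[i] < bin_means[i + 1]
        for i in range(len(bin_means) - 1)
        if not (np.isnan(bin_means[i]) or np.isnan(bin_means[i + 1]))
    )
    return {
        "bins": list(bins),
        "bin_means": bin_means,
        "strictly_increasing": bool(mono),
        "pearson_r": r,
        "n_rim_voxels": int(rim.sum()),
    }


def segment_phantom_visit(volumes, visit: int, seed: int):
    """Segment one phantom visit with default parameters; returns the TPM."""
    tpm, _, _ = dc_segment.segment_volume(volumes[visit], seed=seed)
    return tpm


def progression_replicates(
    n_reps: int = 20,
    seed: int = 0,
    phantom_kwargs: dict = None,
) -> pd.DataFrame:
    """Baseline DC33 -> follow-up conversion over replicate growth phantoms.

    Each replicate draws a fresh phantom, segments baseline and final visit,
    stages both, and records the conversion fraction, the NAWM chance rate,
    and their ratio (enrichment).
    """
    phantom_kwargs = phantom_kwargs or {}
    rows = []
    for s in _spawn_seeds(seed + 31, n_reps):
        cfg = PhantomConfig(rng_seed=s, **phantom_kwargs)
        vols, truth = generate_longitudinal_phantom(cfg)
        tpm_b = segment_phantom_visit(vols, 0, s)
        tpm_f = segment_phantom_visit(vols, len(vols) - 1, s)
        cat_b = lesion_volumes.categorize_voxels(tpm_b)
        cat_f = lesion_volumes.categorize_voxels(tpm_f)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pr = lesion_volumes.progression_overlap(cat_b, cat_f, tpm_b)
        rows.append({
            "seed": s,
            "n_dc33_baseline": pr.n_dc33_baseline,
            "fraction_dc33_to_lesion": pr.fraction_dc33_to_lesion,
            "chance_rate": pr.chance_rate,
            "enrichment": pr.enrichment,
            "true_baseline_volume_cm3": float(truth.true_volumes[0]),
        })
    return pd.DataFrame(rows)
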