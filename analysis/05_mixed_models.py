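#!/usr/bin/env python
"""Fit the full predictor x outcome mixed-model grid on a synthetic cohort.

Builds a cohort of 120 subjects whose cognition declines with log baseline
lesion volume, attaches staged volume measurements as noisy proxies of the
true volume (V_DC100 dominant and highly correlated, V_DC33 small and weakly
correlated, mirroring the measurement structure of staged segmentation), and
fits all 3 predictors x 5 outcomes x {with, without} V_FLAIR adjustment.
The output table has the main-effect / volume-by-time / per-year layout.
"""

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from wml_stager import phantom
from wml_stager import longitudinal_stats as lstats

RESULTS = Path(__file__).resolve().parents[1] / "results"
RESULTS.mkdir(exist_ok=True)


def staged_volume_proxies(true_volumes, rng):
    """Noisy staged-volume measurements for a known true volume.

    V_DC100 carries most of the visible lesion and tracks truth tightly;
    V_DC66 is the thinner intermediate shell; V_DC33 is a small early-stage
    volume only weakly coupled to the current visible load; V_FLAIR
    approximates the hard DC volume.
    """
    n = true_volumes.size
    v = true_volumes
    out = pd.DataFrame({
        "V_DC100": 0.72 * v * np.exp(rng.normal(0, 0.15, n)),
        "V_DC66": 0.18 * v * np.exp(rng.normal(0, 0.30, n)),
        "V_DC33": 3.0 * (v / 18.5) ** 0.4 * np.exp(rng.normal(0, 0.55, n)),
    })
    out["V_FLAIR"] = (out.V_DC100 + out.V_DC66) * np.exp(rng.normal(0, 0.10, n))
    return out


def main():
    rng = np.random.default_rng(0)
    cfg = phantom.CognitionSimConfig(n_subjects=120, rng_seed=0)
    cohort = phantom.simulate_cognition_cohort(cfg)

    base = cohort.drop_duplicates("subject_id")[["subject_id", "lesion_volume_cm3"]]
    proxies = staged_volume_proxies(base["lesion_volume_cm3"].to_numpy(), rng)
    base = pd.concat([base.reset_index(drop=True), proxies], axis=1)
    merged = cohort.merge(base.drop(columns="lesion_volume_cm3"), on="subject_id")

    outcomes = ("mmse_total", "vadas_total", "latent_speed",
                "latent_executive", "latent_memory")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        grid = lstats.run_model_grid(merged, outcomes=outcomes)
    grid.to_csv(RESULTS / "model_grid.csv", index=False)

    show = grid[~grid.adjust_vflair][
        ["predictor", "outcome", "main_F", "main_p", "interaction_F",
         "interaction_p"]
    ].round(3)
    print("Unadjusted models (30-cell grid written to results/model_grid.csv):")
    print(show.to_string(index=False))
    n_sig_adj = int(grid[grid.adjust_vflair]["main_sig"].sum())
    print(f"\n{n_sig_adj}/15 main effects stay significant after V_FLAIR "
          "adjustment. In this cohort every staged volume proxies the same "
          "latent lesion load that drives cognition, so adjusting for "
          "V_FLAIR (nearly collinear with V_DCHARD) absorbs the signal — "
          "the expected null behaviour. Incremental predictive value of the "
          "early-stage volume requires early damage to carry information "
          "beyond the visible load, which this generator does not inject.")


if __name__ == "__main__":
    main()
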