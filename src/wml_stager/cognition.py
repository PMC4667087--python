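"""Compound cognitive domain scores from subtest data.

Three psychometric compounds are built as equal-weight means of
baseline-standardized subtest z-scores:

* speed and motor control = (Trail making A + maze + digit cancellation) / 3
* executive functions = ((Stroop III−II) + (Trail making B−A) + SDMT +
  verbal fluency) / 4
* memory = (immediate recall + delayed recall + word recognition +
  digit span) / 4

Timed measures (Trail A, Trail B−A, Stroop III−II, maze) are sign-flipped so
that higher always means better.  Z-scoring uses baseline (visit 0) means and
SDs at every visit, so cohort-level decline appears as negative drift; a
compound is missing whenever any constituent is missing (no imputation — the
longitudinal mixed model absorbs missingness).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: compound -> list of (derived measure, sign); sign -1 marks timed measures
COMPOUND_DEFINITIONS = {
    "compound_speed": [
        ("trail_a", -1),
        ("maze", -1),
        ("digit_cancellation", +1),
    ],
    "compound_executive": [
        ("stroop_iii_minus_ii", -1),
        ("trail_b_minus_a", -1),
        ("sdmt", +1),
        ("verbal_fluency", +1),
    ],
    "compound_memory": [
        ("word_recall_immediate", +1),
        ("word_recall_delayed", +1),
        ("word_recognition", +1),
        ("digit_span", +1),
    ],
}

GLOBAL_MEASURES = ("mmse_total", "vadas_total")


@dataclass
class BaselineNorms:
    """Baseline mean/SD and sign per derived measure used for z-scoring."""

    table: dict  # measure -> {"mean": float, "sd": float, "sign": int}

    def z(self, measure: str, values):
        e = self.table[measure]
        return e["sign"] * (np.asarray(values, float) - e["mean"]) / e["sd"]


def add_derived_measures(df: pd.DataFrame) -> pd.DataFrame:
    """Compute Stroop III−II and Trail B−A difference scores."""
    out = df.copy()
    out["stroop_iii_minus_ii"] = out["stroop_iii"] - out["stroop_ii"]
    out["trail_b_minus_a"] = out["trail_b"] - out["trail_a"]
    return out


def fit_baseline_norms(df: pd.DataFrame) -> BaselineNorms:
    """Mean and sample SD of every derived measure over visit-0 rows only."""
    base = df[df["visit_year"] == 0]
    if len(base) < 2:
        raise ValueError("need >= 2 baseline subjects to fit norms")
    table = {}
    for measures in COMPOUND_DEFINITIONS.values():
        for measure, sign in measures:
            vals = base[measure].dropna()
            if len(vals) < 2:
                raise ValueError(f"measure {measure!r}: fewer than 2 baseline values")
            sd = float(vals.std(ddof=1))
            if sd == 0:
                raise ValueError(f"measure {measure!r} has zero baseline SD")
            table[measure] = {"mean": float(vals.mean()), "sd": sd, "sign": sign}
    return BaselineNorms(table=table)


def compute_compound_scores(df: pd.DataFrame, norms: BaselineNorms) -> pd.DataFrame:
    """Attach the three compound columns; missing constituents => missing compound."""
    out = df.copy()
    for compound, measures in COMPOUND_DEFINITIONS.items():
        zs = np.column_stack([norms.z(m, out[m]) for m, _ in measures])
        with np.errstate(invalid="ignore"):
            score = zs.mean(axis=1)  # NaN if any constituent missing
        n_missing = int(np.isnan(score).sum() - out[measures[0][0]].isna().sum())
        if n_missing > 0:
            logger.info("%s: %d rows missing a constituent", compound, n_missing)
        out[compound] = score
    return out


def score_cohort(df: pd.DataFrame) -> tuple:
    """Derive measures, fit baseline norms, and attach compounds.

    Returns ``(scored DataFrame, BaselineNorms)``.
    """
    derived = add_derived_measures(df)
    norms = fit_baseline_norms(derived)
    return compute_compound_scores(derived, norms), norms
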