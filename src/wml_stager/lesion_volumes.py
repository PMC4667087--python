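"""Partial-volume lesion staging, derived volumes, and progression overlap.

Tissue probabilities are mapped to four mutually exclusive voxel categories:

* ``DC100`` — lesion is the most probable tissue with probability > 2/3;
* ``DC66``  — lesion is the most probable tissue otherwise;
* ``DC33``  — lesion is the *second* most probable tissue with
  probability >= 1/3 (below the decision threshold of conventional
  segmentation: early-stage, "pre-visible" lesion);
* ``NONE``  — everything else.

The hard lesion estimate is ``DCHARD = DC66 ∪ DC100`` and
``V_DCHARD = V_DC66 + V_DC100`` by construction.  The percentage labels are
read as thirds (2/3 and 1/3); the exact 2/3 boundary goes to DC66 and the
exact 1/3 boundary into DC33, making the partition exhaustive.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .dc_segment import TissueProbabilityMap
from .imaging_io import ChannelImage
from .phantom import TISSUES

logger = logging.getLogger(__name__)

CATEGORY_CODES = {"NONE": 0, "DC33": 1, "DC66": 2, "DC100": 3}
T_HIGH = 2.0 / 3.0
T_SMALL = 1.0 / 3.0
_LESION = TISSUES.index("LESION")


@dataclass
class LesionCategoryMap:
    """Integer category grid (codes in :data:`CATEGORY_CODES`) plus geometry."""

    codes: np.ndarray
    mask: np.ndarray
    voxel_size_mm: tuple
    t_high: float = T_HIGH
    t_small: float = T_SMALL

    def category_mask(self, *names) -> np.ndarray:
        sel = np.isin(self.codes, [CATEGORY_CODES[n] for n in names])
        return sel & self.mask

    @property
    def hard_lesion_mask(self) -> np.ndarray:
        return self.category_mask("DC66", "DC100")


@dataclass
class VolumeSummary:
    V_DC33: float
    V_DC66: float
    V_DC100: float
    V_DCHARD: float
    V_FLAIR: float
    dice_flair_dchard: float
    voxel_counts: dict


@dataclass
class ProgressionResult:
    n_dc33_baseline: int
    fraction_dc33_to_lesion: float
    chance_rate: float
    enrichment: float


def categorize_voxels(
    tpm: TissueProbabilityMap,
    t_high: float = T_HIGH,
    t_small: float = T_SMALL,
) -> LesionCategoryMap:
    """Assign every in-mask voxel to exactly one partial-volume category."""
    p = tpm.probs
    sums = p.sum(axis=1)
    if np.max(np.abs(sums - 1.0)) > 1e-6:
        raise ValueError("probability vectors must sum to 1")
    order = np.argsort(p, axis=1)  # ascending; [:, -1] = argmax
    top = order[:, -1]
    second = order[:, -2]
    p_les = p[:, _LESION]

    cat = np.zeros(p.shape[0], dtype=np.int8)
    is_top = top == _LESION
    cat[is_top & (p_les > t_high)] = CATEGORY_CODES["DC100"]
    cat[is_top & (p_les <= t_high)] = CATEGORY_CODES["DC66"]
    cat[(~is_top) & (second == _LESION) & (p_les >= t_small)] = CATEGORY_CODES["DC33"]

    codes = np.zeros(tpm.grid_shape, dtype=np.int8)
    codes[tuple(tpm.voxel_indices.T)] = cat
    return LesionCategoryMap(
        codes=codes, mask=tpm.mask, voxel_size_mm=tpm.voxel_size_mm,
        t_high=t_high, t_small=t_small,
    )


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|); both-empty masks agree perfectly (1)."""
    mask_a = np.asarray(mask_a, bool)
    mask_b = np.asarray(mask_b, bool)
    if mask_a.shape != mask_b.shape:
        raise ValueError(f"grid mismatch: {mask_a.shape} vs {mask_b.shape}")
    na, nb = int(mask_a.sum()), int(mask_b.sum())
    if na + nb == 0:
        return 1.0
    return 2.0 * int((mask_a & mask_b).sum()) / (na + nb)


def compute_volumes(
    cat: LesionCategoryMap,
    flair_mask: np.ndarray,
    voxel_size_mm=None,
) -> VolumeSummary:
    """Category volumes in cm^3 plus the Dice agreement with V_FLAIR."""
    voxel_size_mm = voxel_size_mm or cat.voxel_size_mm
    if flair_mask.shape != cat.codes.shape:
        raise ValueError("grid mismatch between category map and FLAIR mask")
    vox_cm3 = float(np.prod(voxel_size_mm)) / 1000.0
    counts = {
        name: int((cat.codes[cat.mask] == code).sum())
        for name, code in CATEGORY_CODES.items()
    }
    v33 = counts["DC33"] * vox_cm3
    v66 = counts["DC66"] * vox_cm3
    v100 = counts["DC100"] * vox_cm3
    return VolumeSummary(
        V_DC33=v33,
        V_DC66=v66,
        V_DC100=v100,
        V_DCHARD=v66 + v100,
        V_FLAIR=int(np.asarray(flair_mask, bool).sum()) * vox_cm3,
        dice_flair_dchard=dice(flair_mask, cat.hard_lesion_mask),
        voxel_counts=counts,
    )


def segment_flair_conventional(
    flair: ChannelImage,
    mask: np.ndarray,
    k_sd: float = 2.5,
    min_component_voxels: int = 5,
) -> np.ndarray:
    """Slice-wise local-threshold FLAIR lesion mask (conventional surrogate).

    Per axial slice the threshold is the in-mask mean plus ``k_sd`` standard
    deviations, both computed after discarding the brightest 1% (so the
    lesions themselves do not inflate the threshold).  26-connected
    components smaller than ``min_component_voxels`` are removed.  This
    stands in for the semi-automated operator marking used on clinical data,
    which cannot be reproduced algorithmically.
    """
    if k_sd <= 0:
        raise ValueError("k_sd must be positive")
    mask = np.asarray(mask, bool)
    data = flair.data
    out = np.zeros(mask.shape, dtype=bool)
    for z in range(mask.shape[2]):
        m = mask[:, :, z]
        vals = data[:, :, z][m]
        if vals.size < 50:
            if vals.size:
                warnings.warn(f"slice {z}: fewer than 50 in-mask voxels, skipped",
                              stacklevel=2)
            continue
        q99 = np.quantile(vals, 0.99)
        core = vals[vals <= q99]
        sd = core.std()
        if sd == 0:
            continue
        thr = core.mean() + k_sd * sd
        out[:, :, z] = m & (data[:, :, z] > thr)
    labels, n = ndimage.label(out, structure=np.ones((3, 3, 3), dtype=int))
    if n:
        sizes = np.bincount(labels.ravel())
        small = np.flatnonzero(sizes < min_component_voxels)
        out[np.isin(labels, small[small > 0])] = False
    return out


def progression_overlap(
    baseline: LesionCategoryMap,
    followup: LesionCategoryMap,
    baseline_tpm: TissueProbabilityMap,
) -> ProgressionResult:
    """Do baseline small-partial (DC33) voxels become hard lesion later?

    Compares the conversion rate of baseline DC33 voxels into follow-up
    DCHARD against the same rate over baseline normal-appearing white matter
    (category NONE with WM most probable) — the chance rate.  Enrichment
    above 1 means early partial-lesion voxels mark future lesion locations
    beyond chance.
    """
    if baseline.codes.shape != followup.codes.shape:
        raise ValueError("baseline and follow-up grids do not match")
    dc33 = baseline.category_mask("DC33")
    hard_followup = followup.hard_lesion_mask
    n33 = int(dc33.sum())
    if n33 == 0:
        warnings.warn("no DC33 voxels at baseline; conversion fraction undefined",
                      stacklevel=2)
        frac = float("nan")
    else:
        frac = float(hard_followup[dc33].mean())

    nawm = baseline.category_mask("NONE") & (baseline_tpm.hard_labels() == TISSUES.index("WM"))
    chance = float(hard_followup[nawm].mean()) if nawm.any() else float("nan")
    if chance > 0:
        enrichment = frac / chance
    else:
        enrichment = float("inf") if frac > 0 else float("nan")
    return ProgressionResult(
        n_dc33_baseline=n33,
        fraction_dc33_to_lesion=frac,
        chance_rate=chance,
        enrichment=enrichment,
    )
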