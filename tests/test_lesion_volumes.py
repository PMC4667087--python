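import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wml_stager import dc_segment, lesion_volumes, phantom
from wml_stager.dc_segment import TissueProbabilityMap
from wml_stager.imaging_io import ChannelImage, default_affine
from wml_stager.lesion_volumes import (
    CATEGORY_CODES,
    categorize_voxels,
    compute_volumes,
    dice,
    progression_overlap,
    segment_flair_conventional,
)

VOX = (2.0, 2.0, 6.0)


def tpm_from_probs(probs):
    probs = np.atleast_2d(np.asarray(probs, dtype=float))
    n = probs.shape[0]
    idx = np.column_stack([np.arange(n), np.zeros(n, int), np.zeros(n, int)])
    return TissueProbabilityMap(
        probs=probs, voxel_indices=idx, grid_shape=(n, 1, 1),
        voxel_size_mm=VOX, affine=default_affine(VOX),
    )


class TestCategorization:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ((0.05, 0.05, 0.10, 0.80), "DC100"),  # lesion dominant above 2/3
            ((0.05, 0.10, 0.35, 0.50), "DC66"),   # lesion dominant below 2/3
            ((0.05, 0.10, 0.50, 0.35), "DC33"),   # lesion second, above 1/3
            ((0.10, 0.20, 0.50, 0.20), "NONE"),   # below every rule
            # boundary behaviour: exactly 2/3 -> DC66, exactly 1/3 -> DC33
            ((1 / 9, 1 / 9, 1 / 9, 2 / 3), "DC66"),
            ((1 / 9, 1 / 9, 4 / 9, 1 / 3), "DC33"),
        ],
    )
    def test_category_rules(self, p, expected):
        cat = categorize_voxels(tpm_from_probs([p]))
        assert cat.codes[0, 0, 0] == CATEGORY_CODES[expected]

    def test_invalid_probability_vector_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            categorize_voxels(tpm_from_probs([(0.5, 0.5, 0.5, 0.5)]))

    @given(st.lists(
        st.tuples(*[st.floats(0.01, 1.0) for _ in range(4)]),
        min_size=1, max_size=60,
    ))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_partition_is_exclusive_and_exhaustive(self, raw):
        probs = np.array(raw)
        probs /= probs.sum(axis=1, keepdims=True)
        cat = categorize_voxels(tpm_from_probs(probs))
        in_mask = cat.codes[cat.mask]
        assert np.isin(in_mask, list(CATEGORY_CODES.values())).all()
        # DC33 and DCHARD are disjoint by construction of the single code grid
        assert not np.any(
            cat.category_mask("DC33") & cat.hard_lesion_mask
        )

    def test_dc_categories_match_probability_ranks(self, baseline_segmentation):
        tpm = baseline_segmentation["tpm"]
        cat = categorize_voxels(tpm)
        codes = cat.codes[tuple(tpm.voxel_indices.T)]
        les = tpm.tissues.index("LESION")
        order = np.argsort(tpm.probs, axis=1)
        hard = codes >= CATEGORY_CODES["DC66"]
        assert np.all(order[hard, -1] == les)
        small = codes == CATEGORY_CODES["DC33"]
        assert np.all(order[small, -2] == les)


class TestVolumes:
    def test_voxel_count_arithmetic(self):
        probs = np.tile((0.05, 0.05, 0.10, 0.80), (100, 1))
        cat = categorize_voxels(tpm_from_probs(probs))
        vs = compute_volumes(cat, np.zeros(cat.codes.shape, bool))
        assert vs.V_DC100 == pytest.approx(100 * 24.0 / 1000.0)  # 2.4 cm^3
        assert vs.V_DCHARD == vs.V_DC66 + vs.V_DC100

    def test_empty_map_gives_zero_volumes_and_full_dice(self):
        probs = np.tile((0.4, 0.3, 0.2, 0.1), (50, 1))
        cat = categorize_voxels(tpm_from_probs(probs))
        vs = compute_volumes(cat, np.zeros(cat.codes.shape, bool))
        assert vs.V_DC33 == vs.V_DC66 == vs.V_DC100 == 0.0
        assert vs.dice_flair_dchard == 1.0  # both masks empty: agreement

    def test_grid_mismatch_rejected(self):
        cat = categorize_voxels(tpm_from_probs(np.tile((0.7, 0.1, 0.1, 0.1), (5, 1))))
        with pytest.raises(ValueError, match="mismatch"):
            compute_volumes(cat, np.zeros((4, 1, 1), bool))


class TestDice:
    def test_identical_disjoint_and_partial(self):
        a = np.zeros((4, 4, 2), bool); a[:2] = True
        b = np.zeros((4, 4, 2), bool); b[2:] = True
        assert dice(a, a) == 1.0
        assert dice(a, b) == 0.0
        c = np.zeros((4, 4, 2), bool); c[1:3] = True
        assert dice(a, c) == pytest.approx(0.5)

    def test_formula_on_small_counts(self):
        a = np.zeros(6, bool); a[:3] = True
        b = np.zeros(6, bool); b[1:4] = True
        assert dice(a, b) == pytest.approx(2 * 2 / 6, abs=1e-4)  # 0.6667

    @given(st.integers(0, 2**12 - 1), st.integers(0, 2**12 - 1))
    @settings(deadline=None, max_examples=60, derandomize=True)
    def test_symmetry_and_identity(self, bits_a, bits_b):
        a = np.array([(bits_a >> i) & 1 for i in range(12)], bool)
        b = np.array([(bits_b >> i) & 1 for i in range(12)], bool)
        assert dice(a, b) == dice(b, a)
        if a.any():
            assert (dice(a, b) == 1.0) == np.array_equal(a, b)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dice(np.zeros((2, 2, 2), bool), np.zeros((2, 2, 3), bool))


class TestConventionalSegmentation:
    def test_uniform_slices_give_empty_mask(self):
        data = np.full((16, 16, 4), 50.0)
        flair = ChannelImage(data, VOX, default_affine(VOX), "FLAIR")
        out = segment_flair_conventional(flair, np.ones(data.shape, bool))
        assert not out.any()

    def test_small_components_removed(self):
        rng = np.random.default_rng(0)
        data = rng.normal(50, 1.0, (24, 24, 4))
        data[5, 5, 1] = 500.0  # single-voxel spike
        flair = ChannelImage(data, VOX, default_affine(VOX), "FLAIR")
        out = segment_flair_conventional(flair, np.ones(data.shape, bool),
                                         min_component_voxels=5)
        assert not out[5, 5, 1]

    def test_thin_slices_skipped_with_warning(self):
        data = np.random.default_rng(0).normal(50, 5, (6, 6, 3))
        mask = np.ones(data.shape, bool)  # 36 voxels per slice < 50
        flair = ChannelImage(data, VOX, default_affine(VOX), "FLAIR")
        with pytest.warns(UserWarning, match="fewer than 50"):
            out = segment_flair_conventional(flair, mask)
        assert not out.any()

    def test_recovers_lesion_level_set_on_noiseless_phantom(self):
        cfg = phantom.PhantomConfig(noise_sigma=0.0, bias_field_amplitude=0.0,
                                    rng_seed=6)
        volumes, truth = phantom.generate_longitudinal_phantom(cfg)
        out = segment_flair_conventional(
            volumes[0].get_channel("FLAIR"), volumes[0].brain_mask
        )
        frac = truth.fraction_maps[0]["LESION"]
        # slice-adaptive thresholding: within every slice the mask is a level
        # set of the true fraction (noiseless FLAIR is monotone in fraction)
        assert out.any()
        checked = 0
        for z in range(out.shape[2]):
            sel = out[:, :, z]
            if not sel.any():
                continue
            inside = frac[:, :, z][sel]
            outside = frac[:, :, z][volumes[0].brain_mask[:, :, z] & ~sel]
            assert 0.0 < inside.min() < 1.0
            assert inside.min() >= outside.max() - 1e-9
            checked += 1
        assert checked >= 3

    def test_invalid_k_sd_rejected(self):
        flair = ChannelImage(np.ones((8, 8, 2)), VOX, default_affine(VOX), "FLAIR")
        with pytest.raises(ValueError):
            segment_flair_conventional(flair, np.ones((8, 8, 2), bool), k_sd=0.0)


class TestProgression:
    def _cat_from_codes(self, codes, probs=None):
        codes = np.asarray(codes, dtype=np.int8).reshape(-1, 1, 1)
        mask = np.ones(codes.shape, bool)
        return lesion_volumes.LesionCategoryMap(codes=codes, mask=mask,
                                                voxel_size_mm=VOX)

    def test_identical_visits_convert_nothing(self):
        probs = np.array([
            (0.05, 0.10, 0.50, 0.35),   # DC33
            (0.05, 0.10, 0.35, 0.50),   # DC66
            (0.10, 0.10, 0.70, 0.10),   # NONE, WM top
            (0.10, 0.10, 0.70, 0.10),
        ])
        tpm = tpm_from_probs(probs)
        cat = categorize_voxels(tpm)
        res = progression_overlap(cat, cat, tpm)
        assert res.fraction_dc33_to_lesion == 0.0

    def test_full_rim_conversion_gives_fraction_one(self):
        base = np.array([
            (0.05, 0.10, 0.50, 0.35),   # DC33 -> will become lesion
            (0.10, 0.10, 0.70, 0.10),   # NAWM stays
        ])
        follow = np.array([
            (0.05, 0.05, 0.10, 0.80),   # now DC100
            (0.10, 0.10, 0.70, 0.10),
        ])
        tpm_b = tpm_from_probs(base)
        res = progression_overlap(
            categorize_voxels(tpm_b), categorize_voxels(tpm_from_probs(follow)), tpm_b
        )
        assert res.fraction_dc33_to_lesion == 1.0
        assert res.chance_rate == 0.0
        assert np.isinf(res.enrichment)

    def test_no_dc33_warns_and_returns_nan(self):
        probs = np.tile((0.10, 0.10, 0.70, 0.10), (4, 1))
        tpm = tpm_from_probs(probs)
        cat = categorize_voxels(tpm)
        with pytest.warns(UserWarning, match="DC33"):
            res = progression_overlap(cat, cat, tpm)
        assert np.isnan(res.fraction_dc33_to_lesion)

    def test_growth_phantom_enriches_above_chance(self, default_phantom,
                                                  baseline_segmentation):
        volumes, _ = default_phantom
        tpm_b = baseline_segmentation["tpm"]
        tpm_f, _, _ = dc_segment.segment_volume(volumes[-1], seed=0)
        res = progression_overlap(
            categorize_voxels(tpm_b), categorize_voxels(tpm_f), tpm_b
        )
        assert res.n_dc33_baseline > 0
        assert res.enrichment > 1.0


def test_hard_volume_nondecreasing_across_visits(default_phantom):
    volumes, _ = default_phantom
    hard = []
    for v, msv in enumerate(volumes):
        tpm, _, _ = dc_segment.segment_volume(msv, seed=0)
        cat = categorize_voxels(tpm)
        vs = compute_volumes(cat, np.zeros(cat.codes.shape, bool))
        hard.append(vs.V_DCHARD)
    assert all(b >= a - 1e-9 for a, b in zip(hard, hard[1:]))
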