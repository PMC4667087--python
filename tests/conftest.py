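import numpy as np
import pytest

from wml_stager import dc_segment, phantom


@pytest.fixture(scope="session")
def default_phantom():
    """Longitudinal phantom at the default study conditions (fixed seed)."""
    return phantom.generate_longitudinal_phantom(phantom.PhantomConfig(rng_seed=0))


@pytest.fixture(scope="session")
def baseline_features(default_phantom):
    volumes, _ = default_phantom
    return dc_segment.normalize_channels(volumes[0])


@pytest.fixture(scope="session")
def baseline_segmentation(default_phantom, baseline_features):
    """Seeds, cluster model and tissue probability map for the baseline visit."""
    seeds = dc_segment.generate_seed_labels(baseline_features, seed=0)
    model = dc_segment.fit_discriminative_clustering(baseline_features, seeds, seed=0)
    tpm = dc_segment.tissue_probabilities(model, baseline_features)
    return {"seeds": seeds, "model": model, "tpm": tpm}


@pytest.fixture(scope="session")
def small_phantom():
    """A light phantom for geometry-level tests."""
    cfg = phantom.PhantomConfig(
        grid_shape=(48, 48, 12),
        n_lesion_foci=3,
        focus_core_radius_mm=4.0,
        rim_width_mm=3.0,
        growth_rate_mm_per_year=1.0,
        rng_seed=7,
    )
    return phantom.generate_longitudinal_phantom(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
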