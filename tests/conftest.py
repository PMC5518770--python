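"""Shared fixtures: small geometries and cached simulation products.

Everything is generated programmatically at test time; session-scoped
fixtures cache the expensive simulation/GLM products that several test
modules share.
"""

import numpy as np
import pytest

from seqpos import bold, design, glm


@pytest.fixture(scope="session")
def small_geometry():
    return bold.make_geometry(shape=(12, 12, 12), seed=1, n_regions=2,
                              region_voxels=130, mask_fraction=0.5)


@pytest.fixture(scope="session")
def preset_design():
    return design.replicate_table_design(seed=5)


@pytest.fixture(scope="session")
def preset_regressors(preset_design):
    occurrences = design.enumerate_occurrences(preset_design)
    return design.combine_occurrences(occurrences, seed=5)


@pytest.fixture(scope="session")
def shared_run(small_geometry, preset_design):
    """One participant with a shared positional code at default amplitudes."""
    effect = bold.EffectConfig(sharing_mode="shared")
    truth = bold.sample_patterns(small_geometry, effect, seed=11)
    return bold.simulate_run(preset_design, small_geometry, truth, seed=12)


@pytest.fixture(scope="session")
def shared_betas(shared_run, preset_regressors):
    return glm.estimate_betas_ls2(shared_run, preset_regressors,
                                  enforce_exclusion=False)


@pytest.fixture(scope="session")
def quiet_noise():
    """Noise with no motion spikes, for tests that need clean scrubbing."""
    return bold.NoiseSpec(motion_spike_rate=0.0)


def make_toy_patterns(rng, n_per_class, n_voxels, centroids, noise_sd):
    """Cluster data: one centroid per class plus isotropic noise."""
    X, y = [], []
    for label, mu in centroids.items():
        X.append(mu + noise_sd * rng.standard_normal((n_per_class, n_voxels)))
        y.extend([label] * n_per_class)
    return np.vstack(X), np.array(y)


@pytest.fixture
def toy_clusters():
    return make_toy_patterns
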