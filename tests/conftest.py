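import dataclasses

import pytest

from mitopla import ImagingParams, SceneParams, generate_scene


@pytest.fixture(scope="session")
def imaging_params():
    return ImagingParams()


@pytest.fixture(scope="session")
def enriched_scene():
    """Small mitosis-enriched acquisition shared across imaging tests."""
    params = SceneParams(field_grid_count=6, mitotic_fraction=0.5, rng_seed=3)
    scene, stack = generate_scene(params)
    return params, scene, stack


@pytest.fixture(scope="session")
def quiet_params():
    """Noise-free, background-free parameters for flux-conservation tests."""
    return dataclasses.replace(
        SceneParams(),
        field_grid_count=1,
        z_planes=5,
        image_size_px=(64, 64),
        cells_per_field=(0, 0),
        background=(0.0, 0.0, 0.0),
        photon_noise_scale=0.0,
        read_noise_sd=0.0,
    )
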