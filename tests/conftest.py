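import dataclasses

import pytest

from vesselzoner.synthetic_histology import SceneConfig, generate_scene, render_channels

# A small section (1.6 x 2.56 mm at 4 um/px) that keeps every stage fast
# while preserving the planted structure: LL near the bed, HH in a band
# between the fronts.
TINY = SceneConfig(
    image_width_px=400,
    image_height_px=640,
    n_capillaries=30,
    bone_front_mm=0.4,
    granulation_front_mm=1.6,
    highhigh_band_center_mm=1.2,
    highhigh_band_sd_mm=0.3,
    lowlow_center_mm=0.5,
    lowlow_sd_mm=0.3,
    n_osx_spots=400,
    seed=42,
)


@pytest.fixture(scope="session")
def tiny_config():
    return TINY


@pytest.fixture(scope="session")
def tiny_scene():
    return generate_scene(TINY)


@pytest.fixture(scope="session")
def tiny_noiseless_rendered():
    cfg = dataclasses.replace(TINY, background_noise_sd=0.0)
    return render_channels(generate_scene(cfg))
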