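import pytest

from conemetrics import (DetectionConfig, RenderConfig, density_to_spacing,
                         generate_mosaic, register_frames, render_frames,
                         select_and_average)


@pytest.fixture(scope="session")
def default_rendered():
    """A default-rendered jittered mosaic with its registered average image,
    shared across detection tests."""
    density = 12375.0
    mosaic = generate_mosaic(density, (260.0, 260.0), jitter_sd=0.5, seed=42)
    stack = render_frames(mosaic, RenderConfig(), seed=7)
    img = select_and_average(register_frames(stack))
    return {"mosaic": mosaic, "stack": stack, "image": img,
            "density": density, "spacing": density_to_spacing(density)}


@pytest.fixture
def detection_config():
    return DetectionConfig()
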