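import numpy as np
import pytest

from chlorofuse import synthetic


def make_record(chl: float, plant_id: str | None = None,
                height_px: int = 190) -> synthetic.TraitRecord:
    """A hand-built trait record with a chosen true chlorophyll value."""
    return synthetic.TraitRecord(
        plant_id=plant_id or f"synthetic_chl{chl:.0f}",
        genotype="G01", water="HW", nutrient="HN", das=40,
        slw=0.005, chl_true=float(chl), chl_measured=float(chl),
        plant_height_px=height_px,
    )


@pytest.fixture(scope="session")
def noiseless_config() -> synthetic.RenderConfig:
    return synthetic.RenderConfig.noiseless(image_size=(128, 128), n_views=3)


@pytest.fixture(scope="session")
def default_config() -> synthetic.RenderConfig:
    return synthetic.RenderConfig(image_size=(128, 128), n_views=3)


@pytest.fixture(scope="session")
def mid_record() -> synthetic.TraitRecord:
    return make_record(300.0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
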