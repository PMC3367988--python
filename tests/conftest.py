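import numpy as np
import pytest

from benthoscan.config import BACKGROUND, TaxonSet
from benthoscan.synthetic import default_scene_spec, generate_image


@pytest.fixture(scope="session")
def taxa():
    return TaxonSet.uniform(["A", "B", BACKGROUND], d_taxon=5.0,
                            match_distance=5.0)


@pytest.fixture(scope="session")
def scene_spec():
    return default_scene_spec(width=240, height=200)


@pytest.fixture(scope="session")
def small_image(scene_spec):
    image, truth = generate_image(scene_spec, seed=11, image_id="img000")
    return image, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
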