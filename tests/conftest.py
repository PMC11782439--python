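import numpy as np
import pytest

from cvdshot.color_sim import ColorImage
from cvdshot.dataset import FixtureSpec, generate_fixtures


@pytest.fixture(scope="session")
def small_manifest(tmp_path_factory):
    """Tiny balanced fixture set (6 per class, 64 px) for protocol tests."""
    out = tmp_path_factory.mktemp("fixtures_small")
    spec = FixtureSpec(n_per_class=6, image_size=(64, 64), seed=11)
    return generate_fixtures(spec, out)


@pytest.fixture(scope="session")
def canonical_manifest(tmp_path_factory):
    """The canonical balanced n=100 fixture set (50 per class, 128 px)."""
    out = tmp_path_factory.mktemp("fixtures_canonical")
    return generate_fixtures(FixtureSpec(), out)


def random_srgb_image(rng, height=16, width=16, low=0.0, high=1.0):
    pixels = rng.uniform(low, high, size=(height, width, 3))
    return ColorImage(pixels, "srgb")
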