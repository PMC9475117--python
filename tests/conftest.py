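import numpy as np
import pytest

from endo3d.synthetic import DisparitySpec, TextureSpec, generate_tissue_texture


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def texture_64x128():
    return generate_tissue_texture(TextureSpec(seed=7, shape=(64, 128)))


@pytest.fixture(scope="session")
def small_pair(texture_64x128):
    """Left/right pair with constant disparity 4 px."""
    from endo3d.synthetic import generate_disparity_field, render_right_view
    d = generate_disparity_field(DisparitySpec("constant", 4.0), (64, 128))
    right = render_right_view(texture_64x128, d)
    return texture_64x128, right, d
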