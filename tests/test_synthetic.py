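"""Synthetic stereo fixture generators: determinism, contracts, warp oracle."""

import numpy as np
import pytest

from endo3d import imgio
from endo3d.synthetic import (DisparitySpec, StereoSample, TextureSpec,
                              generate_disparity_field, generate_tissue_texture,
                              load_dataset, make_dataset, render_right_view,
                              write_dataset)


class TestTexture:
    def test_shape_range_and_determinism(self):
        spec = TextureSpec(seed=1, shape=(128, 256))
        img = generate_tissue_texture(spec)
        assert img.shape == (128, 256, 3)
        assert img.min() >= 0.0 and img.max() <= 1.0
        np.testing.assert_array_equal(img, generate_tissue_texture(spec))

    def test_more_octaves_add_detail(self):
        a = generate_tissue_texture(TextureSpec(seed=5, octaves=1, vessel_count=0))
        b = generate_tissue_texture(TextureSpec(seed=5, octaves=3, vessel_count=0))
        assert np.abs(a - b).mean() > 0
        assert b.std() >= a.std() * 0.9  # extra octaves never flatten the image

    def test_tiny_shape_rejected(self):
        with pytest.raises(ValueError):
            TextureSpec(shape=(16, 64))


class TestDisparityField:
    def test_constant(self):
        d = generate_disparity_field(DisparitySpec("constant", 4.0), (64, 128))
        assert np.all(d == 4.0)

    def test_ramp_monotone(self):
        d = generate_disparity_field(DisparitySpec("ramp", 8.0), (32, 128))
        assert d[0, 0] == 0.0
        assert d[0, -1] == pytest.approx(8.0)
        assert np.all(np.diff(d, axis=1) >= 0)

    def test_blob_bounded_and_zero_at_borders(self):
        d = generate_disparity_field(DisparitySpec("blob", 6.0), (64, 128))
        assert d.max() <= 6.0 + 1e-6
        assert np.abs(d[0]).max() < 1e-5 and np.abs(d[:, 0]).max() < 1e-5
        assert np.abs(d[-1]).max() < 1e-5 and np.abs(d[:, -1]).max() < 1e-5

    def test_magnitude_validated_against_width(self):
        with pytest.raises(ValueError):
            generate_disparity_field(DisparitySpec("constant", 40.0), (64, 128))


class TestRenderRightView:
    def test_zero_disparity_is_identity(self, texture_64x128):
        d = np.zeros((64, 128), np.float32)
        np.testing.assert_array_equal(render_right_view(texture_64x128, d),
                                      texture_64x128)

    def test_integer_disparity_is_index_shift(self, texture_64x128):
        d = np.full((64, 128), 3.0, np.float32)
        right = render_right_view(texture_64x128, d)
        np.testing.assert_allclose(right[:, :-3], texture_64x128[:, 3:], atol=1e-6)

    def test_half_pixel_is_neighbour_average(self, texture_64x128):
        d = np.full((64, 128), 2.5, np.float32)
        right = render_right_view(texture_64x128, d)
        expect = 0.5 * (texture_64x128[:, 2:-1] + texture_64x128[:, 3:])
        np.testing.assert_allclose(right[:, :-3], expect[:, :125], atol=1e-6)

    def test_shape_mismatch_rejected(self, texture_64x128):
        with pytest.raises(ValueError):
            render_right_view(texture_64x128, np.zeros((32, 64), np.float32))


class TestMakeDataset:
    def test_deterministic_and_valid(self):
        kw = dict(texture=TextureSpec(shape=(64, 128)),
                  disparity=DisparitySpec("constant", 4.0), seed=7)
        a = make_dataset(4, **kw)
        b = make_dataset(4, **kw)
        for s, t in zip(a, b):
            s.validate()
            np.testing.assert_array_equal(s.left, t.left)
            np.testing.assert_array_equal(s.gt_disparity, t.gt_disparity)

    def test_no_smoke_means_clean_equals_left(self):
        for s in make_dataset(3, texture=TextureSpec(shape=(64, 64)),
                              disparity=DisparitySpec("constant", 3.0),
                              smoke_level="none", seed=1):
            np.testing.assert_array_equal(s.clean, s.left)

    def test_dense_smoke_brightens_every_sample(self):
        for s in make_dataset(5, texture=TextureSpec(shape=(64, 64)),
                              disparity=DisparitySpec("constant", 3.0),
                              smoke_level="dense", seed=2):
            assert s.left.mean() > s.clean.mean()

    def test_different_seeds_differ(self):
        a = make_dataset(2, texture=TextureSpec(shape=(64, 64)), seed=1)
        b = make_dataset(2, texture=TextureSpec(shape=(64, 64)), seed=2)
        assert np.abs(a[0].left - b[0].left).max() > 0


class TestDatasetIO:
    def test_roundtrip_png_pfm_manifest(self, tmp_path):
        samples = make_dataset(2, texture=TextureSpec(shape=(64, 64)),
                               disparity=DisparitySpec("ramp", 5.0), seed=3)
        write_dataset(samples, tmp_path / "ds")
        loaded = load_dataset(tmp_path / "ds")
        assert len(loaded) == 2
        # PNG quantizes to 8 bits; PFM is exact
        assert np.abs(loaded[0].left - samples[0].left).max() <= 1 / 255 + 1e-6
        np.testing.assert_allclose(loaded[0].gt_disparity,
                                   samples[0].gt_disparity, atol=1e-6)

    def test_pfm_roundtrip_exact(self, tmp_path):
        field = np.random.default_rng(0).random((17, 23)).astype(np.float32) * 30
        imgio.write_pfm(tmp_path / "d.pfm", field)
        np.testing.assert_array_equal(imgio.read_pfm(tmp_path / "d.pfm"), field)


def test_stereo_sample_invariants_enforced():
    img = np.zeros((8, 8, 3), np.float32)
    with pytest.raises(ValueError):
        StereoSample(left=img, right=np.zeros((8, 9, 3), np.float32)).validate()
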