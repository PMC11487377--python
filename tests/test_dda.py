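import numpy as np
import pytest

from sgknee.dda import (
    AugmentConfig,
    NormStats,
    augment_pipeline,
    center_crop,
    compute_norm_stats,
    layer_scale_apply,
    normalize,
    random_crop,
    spatial_erase,
    spatial_mixup,
)
from sgknee.volume_io import ExamVolume


def _vol(L=4, side=32, fill=None, rng=None, view="axial"):
    if fill is not None:
        data = np.full((L, side, side), fill, dtype=np.float32)
    else:
        data = rng.standard_normal((L, side, side)).astype(np.float32)
    return ExamVolume(data, view=view, exam_id="t")


class TestCrop:
    def test_output_is_contiguous_subwindow(self, rng):
        vol = _vol(L=3, side=256, rng=rng)
        out = random_crop(vol, 224, rng)
        assert out.shape == (3, 224, 224)
        # locate the window by matching the first layer
        found = False
        for top in range(33):
            for left in range(33):
                if np.array_equal(vol.data[:, top : top + 224, left : left + 224], out.data):
                    found = True
                    break
            if found:
                break
        assert found

    def test_full_size_crop_is_identity(self, rng):
        vol = _vol(L=2, side=16, rng=rng)
        np.testing.assert_array_equal(random_crop(vol, 16, rng).data, vol.data)

    def test_oversized_crop_rejected(self, rng):
        with pytest.raises(ValueError):
            random_crop(_vol(L=1, side=16, rng=rng), 17, rng)

    def test_center_crop_deterministic(self, rng):
        vol = _vol(L=2, side=32, rng=rng)
        a = center_crop(vol, 24)
        b = center_crop(vol, 24)
        np.testing.assert_array_equal(a.data, b.data)
        np.testing.assert_array_equal(a.data, vol.data[:, 4:28, 4:28])


class TestNormalize:
    def test_two_point_example(self):
        vol = ExamVolume(np.array([[[2.0, 4.0]]]).repeat(2, axis=2).reshape(1, 2, 2))
        out = normalize(vol, NormStats(m=3.0, std=1.0))
        np.testing.assert_allclose(np.unique(out.data), [-1.0, 1.0])

    def test_self_stats_give_zero_mean_unit_sd(self, rng):
        vol = _vol(L=5, side=16, rng=rng)
        stats = compute_norm_stats([vol])
        out = normalize(vol, stats)
        assert abs(out.data.mean()) < 1e-6
        assert abs(out.data.std() - 1.0) < 1e-5

    def test_zero_std_rejected(self):
        with pytest.raises(ValueError):
            NormStats(m=0.0, std=0.0)

    def test_affine_equivariance(self, rng):
        """normalize(a*v + b) with matching stats equals normalize(v)."""
        vol = _vol(L=3, side=8, rng=rng)
        stats = compute_norm_stats([vol])
        a, b = 2.5, -1.0
        shifted = ExamVolume(a * vol.data + b, view=vol.view)
        shifted_stats = NormStats(m=a * stats.m + b, std=a * stats.std)
        np.testing.assert_allclose(
            normalize(shifted, shifted_stats).data, normalize(vol, stats).data, atol=1e-5
        )


class TestSpatialErase:
    def test_half_ratio_zeroes_quarter_area(self, rng):
        vol = _vol(L=3, side=224, fill=1.0)
        out = spatial_erase(vol, 0.5, rng)
        for layer in out.data:
            assert int((layer == 0).sum()) == 112 * 112

    def test_zero_ratio_identity(self, rng):
        vol = _vol(L=2, side=16, rng=rng)
        np.testing.assert_array_equal(spatial_erase(vol, 0.0, rng).data, vol.data)

    def test_full_ratio_zeroes_everything(self, rng):
        vol = _vol(L=2, side=16, fill=3.0)
        assert np.all(spatial_erase(vol, 1.0, rng).data == 0)

    def test_area_mode_zeroes_ratio_fraction(self, rng):
        vol = _vol(L=1, side=100, fill=1.0)
        out = spatial_erase(vol, 0.25, rng, block_mode="area")
        assert int((out.data == 0).sum()) == 50 * 50

    def test_blocks_always_inside_bounds(self, rng):
        """No clipped block: zero count is exactly side^2 for every draw."""
        for ratio in (0.3, 0.5, 0.75, 0.9):
            side = 33
            s = round(side * ratio)
            vol = _vol(L=1, side=side, fill=1.0)
            for _ in range(200):
                out = spatial_erase(vol, ratio, rng)
                assert int((out.data == 0).sum()) == s * s


class TestSpatialMixup:
    def test_lambda_one_is_identity(self, rng):
        vol = _vol(L=4, side=20, rng=rng)
        out = spatial_mixup(vol, 0.5, rng, lam=1.0)
        np.testing.assert_array_equal(out.data, vol.data)

    def test_lambda_zero_copies_donor_block(self, rng):
        vol = _vol(L=2, side=12, rng=rng)
        out = spatial_mixup(vol, 0.5, rng, lam=0.0)
        s = 6
        # every changed pixel must exist somewhere in the other layer
        for layer in range(2):
            diff = out.data[layer] != vol.data[layer]
            changed = out.data[layer][diff]
            donor = vol.data[1 - layer]
            for val in changed:
                assert np.any(np.isclose(donor, val))

    def test_block_sum_is_convex_combination(self):
        """Mixed block total = lam*self + (1-lam)*donor, reconstructed exactly."""
        rng = np.random.default_rng(3)
        data = np.zeros((2, 10, 10), dtype=np.float32)
        data[0] = 1.0
        data[1] = 5.0
        vol = ExamVolume(data)
        lam = 0.3
        out = spatial_mixup(vol, 0.5, rng, lam=lam)
        block = out.data[0][out.data[0] != 1.0]
        assert block.size == 25
        np.testing.assert_allclose(block, lam * 1.0 + (1 - lam) * 5.0, atol=1e-6)

    def test_single_layer_rejected(self, rng):
        with pytest.raises(ValueError):
            spatial_mixup(_vol(L=1, side=8, rng=rng), 0.5, rng)


class TestLayerScale:
    def test_erase_exact_layer_count(self, rng):
        vol = _vol(L=20, side=8, fill=1.0)
        out = layer_scale_apply(vol, "erase", 0.25, rng)
        zero_layers = int(np.sum(np.all(out.data == 0, axis=(1, 2))))
        untouched = int(np.sum(np.all(out.data == 1.0, axis=(1, 2))))
        assert zero_layers == 5
        assert untouched == 15

    def test_zero_ratio_identity(self, rng):
        vol = _vol(L=6, side=8, rng=rng)
        out = layer_scale_apply(vol, "erase", 0.0, rng)
        np.testing.assert_array_equal(out.data, vol.data)

    def test_mixup_lambda_zero_copies_resized_donor(self, rng):
        vol = _vol(L=4, side=8, fill=2.0, view="axial")
        donor = _vol(L=3, side=16, fill=7.0, view="coronal")
        out = layer_scale_apply(
            vol, "mixup", 0.5, rng, donor_views={"coronal": donor}, lam=0.0
        )
        changed = np.sum(np.all(out.data == 7.0, axis=(1, 2)))
        assert changed == 2  # round(4 * 0.5)

    def test_mixup_without_donor_rejected(self, rng):
        with pytest.raises(ValueError):
            layer_scale_apply(_vol(L=4, side=8, fill=1.0), "mixup", 0.5, rng)


class TestPipeline:
    def test_no_ops_is_crop_normalize_only(self, three_views):
        cfg = AugmentConfig(
            crop_size=28, mode_probabilities={"erase": 0.0, "mixup": 0.0}, seed=3
        )
        stats = compute_norm_stats(three_views.values())
        out = augment_pipeline(three_views, cfg, stats, tag="x")
        for view, vol in out.items():
            assert vol.shape[1:] == (28, 28)
            assert vol.layers == three_views[view].layers

    def test_seed_reproducibility(self, three_views):
        cfg = AugmentConfig(crop_size=28, seed=9)
        stats = compute_norm_stats(three_views.values())
        a = augment_pipeline(three_views, cfg, stats, tag="e")
        b = augment_pipeline(three_views, cfg, stats, tag="e")
        for view in a:
            np.testing.assert_array_equal(a[view].data, b[view].data)

    def test_erase_zero_fraction_quarter_of_touched_layers(self):
        """With the side convention, erase at 0.5 zeroes ~25% of a layer."""
        cfg = AugmentConfig(
            crop_size=28, erase_ratio=0.5,
            mode_probabilities={"erase": 1.0, "mixup": 0.0}, seed=0,
        )
        data = np.abs(np.random.default_rng(0).standard_normal((6, 32, 32))) + 0.1
        views = {"axial": ExamVolume(data.astype(np.float32), view="axial")}
        stats = NormStats(m=0.0, std=1.0)
        fractions = []
        for i in range(100):
            out = augment_pipeline(views, cfg, stats, seed=i, tag="z")["axial"]
            zero_frac = (out.data == 0).mean(axis=(1, 2))
            touched = zero_frac[zero_frac > 0]
            if touched.size and touched.max() < 1.0:  # spatial draw, not layer erase
                fractions.extend(touched)
        assert abs(np.mean(fractions) - (14 / 28) ** 2) < 0.01
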