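"""Masked average pooling, scaled-cosine scoring, soft thresholding, resizing."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from protoseg.autodiff import Tensor
from protoseg.prototype import (
    downsample_mask,
    masked_average_pool,
    resize_to_mask,
    similarity_map,
    soft_threshold,
)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


class TestMaskedAveragePool:
    def test_two_by_two_grid_mean_of_selected_vectors(self):
        rng = np.random.default_rng(0)
        a, b, c, d = rng.normal(size=(4, 16))
        feats = np.stack([a, b, c, d], axis=1).reshape(16, 2, 2)
        mask = np.array([[1, 1], [0, 0]])
        np.testing.assert_allclose(masked_average_pool(feats, mask), (a + b) / 2, atol=1e-12)

    def test_constant_field_returns_the_constant(self):
        v = np.arange(8.0)
        feats = np.tile(v[:, None, None], (1, 3, 5))
        np.testing.assert_allclose(masked_average_pool(feats, np.eye(3, 5)), v)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            masked_average_pool(np.ones((4, 2, 2)), np.zeros((2, 2)))

    def test_matches_bruteforce_loop_on_large_random_grids(self):
        rng = np.random.default_rng(1)
        feats = rng.normal(size=(256, 64, 64))
        mask = (rng.uniform(size=(64, 64)) > 0.7).astype(int)
        expected = np.zeros(256)
        for i in range(64):
            for j in range(64):
                if mask[i, j]:
                    expected += feats[:, i, j]
        expected /= mask.sum()
        np.testing.assert_allclose(masked_average_pool(feats, mask), expected, atol=1e-6)


class TestSimilarityMap:
    def test_pixel_equal_to_prototype_scores_minus_alpha(self):
        rho = np.random.default_rng(0).normal(size=8)
        feats = np.tile(rho[:, None, None], (1, 2, 2))
        r = similarity_map(feats, rho, alpha=20.0)
        np.testing.assert_allclose(r, -20.0, atol=1e-6)

    def test_orthogonal_and_antiparallel_pixels(self):
        rho = np.array([1.0, 0.0])
        feats = np.stack(
            [np.array([[0.0, -3.0]]), np.array([[5.0, 0.0]])], axis=0
        )  # (2, 1, 2): pixel0 orthogonal, pixel1 = -3*rho
        r = similarity_map(feats, rho, alpha=20.0)
        assert r[0, 0] == pytest.approx(0.0, abs=1e-9)
        assert r[0, 1] == pytest.approx(20.0, abs=1e-6)

    def test_zero_feature_vector_scores_zero(self):
        feats = np.zeros((4, 1, 1))
        r = similarity_map(feats, np.ones(4), alpha=20.0)
        assert r[0, 0] == 0.0

    def test_zero_prototype_rejected(self):
        with pytest.raises(ValueError):
            similarity_map(np.ones((4, 2, 2)), np.zeros(4))

    @given(
        st.floats(min_value=0.01, max_value=100.0),
        st.floats(min_value=0.01, max_value=100.0),
        st.integers(min_value=0, max_value=2**31 - 1),
    )
    def test_invariant_to_positive_rescaling(self, s_feat, s_proto, seed):
        rng = np.random.default_rng(seed)
        feats = rng.normal(size=(8, 3, 3))
        rho = rng.normal(size=8)
        base = similarity_map(feats, rho)
        scaled = similarity_map(feats * s_feat, rho * s_proto)
        np.testing.assert_allclose(scaled, base, atol=1e-6)

    def test_scores_bounded_by_alpha(self):
        rng = np.random.default_rng(3)
        r = similarity_map(rng.normal(size=(16, 8, 8)), rng.normal(size=16), alpha=20.0)
        assert np.all(np.abs(r) <= 20.0 + 1e-9)


class TestSoftThreshold:
    def test_probability_half_exactly_at_beta(self):
        for beta in (-10.0, 0.0, 5.0):
            m = soft_threshold(np.array([[beta]]), beta)
            assert m[0, 0] == 0.5

    def test_closed_form_sigmoid_values(self):
        m = soft_threshold(np.array([[-20.0]]), 0.0)
        assert m[0, 0] == pytest.approx(1.0 - _sigmoid(-20.0), rel=1e-12)
        assert m[0, 0] == pytest.approx(1.0 - 2.061e-9, abs=1e-12)

    def test_limits_and_strict_monotonicity(self):
        r = np.linspace(-30, 10, 101)  # unsaturated range around beta=-10
        m = soft_threshold(r[None, :], -10.0)[0]
        assert np.all(np.diff(m) < 0)
        assert np.all((m > 0) & (m < 1))
        assert soft_threshold(np.array([[1e4]]), 0.0)[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_tensor_input_returns_tensor_with_gradient(self):
        r = Tensor(np.zeros((2, 2)), requires_grad=True)
        m = soft_threshold(r, 0.0)
        m.sum().backward()
        np.testing.assert_allclose(r.grad, -0.25)  # d/dr [1-sigma(r)] at 0


class TestResizeToMask:
    def test_identity_resize_preserves_values(self):
        x = np.random.default_rng(0).normal(size=(32, 32))
        np.testing.assert_allclose(resize_to_mask(x, (32, 32)), x, atol=1e-12)

    def test_constant_grid_stays_constant(self):
        out = resize_to_mask(np.full((4, 4), 3.3), (9, 7))
        np.testing.assert_allclose(out, 3.3)
        assert out.shape == (9, 7)

    def test_bilinear_upsample_of_step_pattern(self):
        out = resize_to_mask(np.array([[0.0, 0.0], [1.0, 1.0]]), (4, 4))
        # columns constant, rows monotone non-decreasing top to bottom
        np.testing.assert_allclose(out, out[:, [0]] * np.ones((1, 4)), atol=1e-12)
        assert np.all(np.diff(out[:, 0]) >= 0)
        np.testing.assert_allclose(out[:, 0], [0.0, 1 / 3, 2 / 3, 1.0], atol=1e-12)

    def test_channelwise_resize_matches_per_channel(self):
        x = np.random.default_rng(1).normal(size=(5, 6, 7))
        out = resize_to_mask(x, (13, 11))
        for c in range(5):
            np.testing.assert_allclose(out[c], resize_to_mask(x[c], (13, 11)), atol=1e-12)

    def test_invalid_target_rejected(self):
        with pytest.raises(ValueError):
            resize_to_mask(np.ones((4, 4)), (0, 5))


def test_downsample_mask_is_nearest_and_binary():
    mask = np.zeros((256, 256), np.uint8)
    mask[100:140, 60:200] = 1
    small = downsample_mask(mask, (32, 32))
    assert small.shape == (32, 32)
    assert set(np.unique(small)) <= {0, 1}
    assert small.sum() > 0


def test_self_scoring_separates_foreground_from_background():
    """MAP -> similarity -> threshold on separable features puts higher mean
    foreground probability on true-foreground pixels than on background."""
    rng = np.random.default_rng(7)
    mask = np.zeros((16, 16), np.uint8)
    mask[4:10, 5:12] = 1
    feats = rng.normal(0.0, 0.1, size=(32, 16, 16))
    feats[:16, mask == 1] += 2.0  # foreground pixels share a direction
    proto = masked_average_pool(feats, mask)
    m = soft_threshold(similarity_map(feats, proto), beta=-10.0)
    assert m[mask == 1].mean() > m[mask == 0].mean()
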