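import numpy as np
import pytest
from scipy import ndimage

from camdart.errors import DegenerateInputError
from camdart.image_model import ChannelPair, FrameSequence
from camdart.postprocess import (
    AffineTransform2D,
    apply_transform,
    compute_ratio,
    correct_bleaching_additive,
    correct_bleaching_biexponential,
    correct_bleaching_multiplicative,
    estimate_background,
    fit_biexponential,
    register_channels,
    subtract_background,
)

META = dict(pixel_size_um=0.368, frame_interval_s=0.1)


def as_seq(data):
    return FrameSequence(np.asarray(data, dtype=float), **META)


class TestRegistration:
    def test_identity_for_aligned_images(self, smooth_image):
        tf = register_channels(smooth_image, smooth_image)
        np.testing.assert_allclose(tf.matrix, np.eye(2), atol=0.01)
        assert np.all(np.abs(tf.offset) < 0.1)

    def test_recovers_known_subpixel_shift(self, smooth_image):
        shift = (2.3, -1.7)
        moving = ndimage.shift(smooth_image, shift, order=3, mode="reflect")
        tf = register_channels(smooth_image, moving, model="translation")
        # aligning `moving` must sample it at +shift: offset == shift
        np.testing.assert_allclose(tf.offset, shift, atol=0.25)

    def test_recovers_small_rotation(self, smooth_image):
        angle = np.deg2rad(2.0)
        center = ((smooth_image.shape[0] - 1) / 2, (smooth_image.shape[1] - 1) / 2)
        moving = AffineTransform2D.rotation(angle, center).apply(smooth_image)
        tf = register_channels(smooth_image, moving, model="affine")
        recovered = np.arctan2(tf.matrix[1, 0], tf.matrix[0, 0])
        assert abs(abs(recovered) - angle) < np.deg2rad(0.5)

    def test_constant_image_rejected(self):
        with pytest.raises(DegenerateInputError):
            register_channels(np.ones((32, 32)), np.ones((32, 32)))


class TestApplyTransform:
    def test_identity_is_noop(self, rng):
        seq = as_seq(rng.random((3, 16, 16)))
        out = apply_transform(seq, AffineTransform2D.identity())
        np.testing.assert_allclose(out.data, seq.data, atol=1e-12)

    def test_integer_shift_matches_index_oracle(self, rng):
        frame = rng.random((12, 14))
        seq = as_seq(frame[None])
        out = apply_transform(seq, AffineTransform2D.translation(3, -2), order=0)
        # oracle: explicit index-shift loop with zero fill
        expected = np.zeros_like(frame)
        for y in range(12):
            for x in range(14):
                sy, sx = y - 3, x + 2
                if 0 <= sy < 12 and 0 <= sx < 14:
                    expected[y, x] = frame[sy, sx]
        np.testing.assert_allclose(out.data[0], expected)

    def test_half_pixel_shifts_compose(self, smooth_image):
        seq = as_seq(smooth_image[None])
        once = apply_transform(
            apply_transform(seq, AffineTransform2D.translation(0.5, 0.0)),
            AffineTransform2D.translation(0.5, 0.0),
        )
        full = apply_transform(seq, AffineTransform2D.translation(1.0, 0.0))
        interior = np.s_[0, 3:-3, 3:-3]
        assert np.max(np.abs(once.data[interior] - full.data[interior])) < 0.5

    def test_per_frame_requires_matching_length(self, rng):
        seq = as_seq(rng.random((3, 8, 8)))
        with pytest.raises(ValueError):
            apply_transform(seq, [AffineTransform2D.identity()] * 2, mode="per_frame")


class TestBackground:
    def test_uniform_subtraction(self):
        out = subtract_background(as_seq(np.full((2, 4, 4), 10.0)), 4.0)
        np.testing.assert_allclose(out.data, 6.0)

    def test_clips_at_zero(self, rng):
        out = subtract_background(as_seq(rng.random((2, 8, 8))), 5.0)
        assert np.all(out.data == 0)

    def test_never_negative_property(self, rng):
        out = subtract_background(as_seq(rng.random((3, 8, 8)) * 10), 3.0)
        assert np.all(out.data >= 0)

    def test_negative_bg_rejected(self):
        with pytest.raises(ValueError):
            subtract_background(as_seq(np.ones((1, 4, 4))), -1.0)

    def test_percentile_estimator_two_level(self):
        frame = np.full((1, 100, 100), 5.0)
        frame[0, 40:60, 40:60] = 50.0  # "cell"
        assert estimate_background(as_seq(frame), percentile=1.0) == pytest.approx(5.0)


class TestRatio:
    def test_constant_channels(self):
        pair = ChannelPair(ch1=as_seq(np.full((2, 4, 4), 2.0)), ch2=as_seq(np.ones((2, 4, 4))))
        np.testing.assert_allclose(compute_ratio(pair).data, 2.0)

    def test_zero_denominator_masked_to_zero(self):
        ch2 = np.ones((1, 4, 4))
        ch2[0, 1, 1] = 0.0
        out = compute_ratio(ChannelPair(ch1=as_seq(np.ones((1, 4, 4))), ch2=as_seq(ch2)))
        assert out.data[0, 1, 1] == 0.0
        assert np.all(np.isfinite(out.data))

    def test_matches_elementwise_oracle(self, rng):
        a = rng.random((2, 6, 6)) + 0.5
        b = rng.random((2, 6, 6)) + 0.5
        out = compute_ratio(ChannelPair(ch1=as_seq(a), ch2=as_seq(b)))
        expected = np.empty_like(a)
        for t in range(2):
            for y in range(6):
                for x in range(6):
                    expected[t, y, x] = a[t, y, x] / b[t, y, x]
        np.testing.assert_allclose(out.data, expected)

    def test_clip_saturates_but_keeps_masked_zero(self):
        ch1 = np.full((1, 2, 2), 10.0)
        ch2 = np.ones((1, 2, 2))
        ch2[0, 0, 0] = 0.0
        out = compute_ratio(ChannelPair(ch1=as_seq(ch1), ch2=as_seq(ch2)), clip=(1.0, 5.0))
        assert out.data[0, 0, 0] == 0.0
        assert out.data[0, 1, 1] == 5.0

    def test_no_nonfinite_for_any_input(self, rng):
        a = rng.random((2, 8, 8))
        b = rng.random((2, 8, 8))
        b[b < 0.3] = 0.0
        out = compute_ratio(ChannelPair(ch1=as_seq(a), ch2=as_seq(b)))
        assert np.all(np.isfinite(out.data))


def bleach_stack(rng, means):
    """Random stack whose central 6x6 'cell' has the given per-frame means."""
    t = len(means)
    data = rng.random((t, 12, 12)) * 2 + 1
    masks = np.zeros((t, 12, 12), dtype=bool)
    masks[:, 3:9, 3:9] = True
    for i, m in enumerate(means):
        cell = data[i, 3:9, 3:9]
        data[i, 3:9, 3:9] = cell - cell.mean() + m
    return as_seq(data), masks


class TestBleachingFrameWise:
    def test_additive_hand_computed_offsets(self, rng):
        seq, masks = bleach_stack(rng, [10.0, 8.0, 6.0])
        out = correct_bleaching_additive(seq, masks, target_mean=10.0)
        offsets = out.data - seq.data
        np.testing.assert_allclose(offsets[0], 0.0, atol=1e-12)
        np.testing.assert_allclose(offsets[1], 2.0, atol=1e-12)
        np.testing.assert_allclose(offsets[2], 4.0, atol=1e-12)
        for t in range(3):
            assert out.data[t][masks[t]].mean() == pytest.approx(10.0, rel=1e-12)

    def test_multiplicative_hand_computed_scales(self, rng):
        seq, masks = bleach_stack(rng, [10.0, 8.0])
        out = correct_bleaching_multiplicative(seq, masks, target_mean=10.0)
        scales = out.data / seq.data
        np.testing.assert_allclose(scales[0], 1.0, rtol=1e-12)
        np.testing.assert_allclose(scales[1], 1.25, rtol=1e-12)

    def test_constant_stack_unchanged(self):
        seq = as_seq(np.full((3, 6, 6), 5.0))
        masks = np.ones((3, 6, 6), dtype=bool)
        for fn in (correct_bleaching_additive, correct_bleaching_multiplicative):
            np.testing.assert_allclose(fn(seq, masks, target_mean=5.0).data, 5.0)

    def test_multiplicative_linearity_in_target(self, rng):
        seq, masks = bleach_stack(rng, [10.0, 8.0, 9.0])
        one = correct_bleaching_multiplicative(seq, masks, target_mean=5.0)
        two = correct_bleaching_multiplicative(seq, masks, target_mean=10.0)
        np.testing.assert_allclose(two.data, 2 * one.data, rtol=1e-12)

    @pytest.mark.parametrize("fn", [correct_bleaching_additive, correct_bleaching_multiplicative])
    def test_masked_mean_constant_on_random_stacks(self, rng, fn):
        means = 10.0 - 0.5 * np.arange(6)  # bleaching-like decreasing trace
        seq, masks = bleach_stack(rng, means)
        out = fn(seq, masks)
        target = seq.data[0][masks[0]].mean()
        for t in range(6):
            assert out.data[t][masks[t]].mean() == pytest.approx(target, rel=1e-9)

    def test_empty_mask_names_frame(self, rng):
        seq, masks = bleach_stack(rng, [10.0, 8.0])
        masks[1] = False
        with pytest.raises(DegenerateInputError, match="frame 1"):
            correct_bleaching_additive(seq, masks)


class TestBiexponentialFit:
    def test_parameter_recovery_noiseless(self):
        t = np.linspace(0, 50, 120)
        y = 5.0 + 3.0 * np.exp(-t / 2.0) + 1.0 * np.exp(-t / 20.0)
        model = fit_biexponential(t, y)
        a, b1, t1, b2, t2 = model.params
        assert a == pytest.approx(5.0, rel=0.01)
        assert t1 == pytest.approx(2.0, rel=0.01)
        assert t2 == pytest.approx(20.0, rel=0.01)
        assert b1 == pytest.approx(3.0, rel=0.01)
        assert b2 == pytest.approx(1.0, rel=0.01)

    def test_constant_trace_is_flat_fit(self):
        t = np.linspace(0, 10, 20)
        model = fit_biexponential(t, np.full(20, 7.0))
        a, b1, _, b2, _ = model.params
        assert a == pytest.approx(7.0, abs=1e-6)
        assert abs(b1) < 1e-6 and abs(b2) < 1e-6

    def test_correction_restores_initial_mean(self, rng):
        t = np.arange(60) * 0.1
        trace = 5.0 + 3.0 * np.exp(-t / 0.8) + 1.0 * np.exp(-t / 4.0)
        data = np.repeat(trace[:, None, None], 64, axis=1).reshape(60, 8, 8)
        seq = as_seq(data)
        masks = np.ones((60, 8, 8), dtype=bool)
        corrected, model = correct_bleaching_biexponential(seq, masks)
        means = corrected.data.mean(axis=(1, 2))
        np.testing.assert_allclose(means, means[0], rtol=1e-6)
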