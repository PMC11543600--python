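"""Ratiometric GP: pixel identities, masking, bias from photoblueing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from photoblue.gp import gp_change_series, gp_map, gp_pixel, membrane_mask
from photoblue.synth import (
    PhotoKineticsParams,
    TwoChannelImage,
    make_membrane_scene,
    synth_two_channel_stack,
)

KINETICS_ON = PhotoKineticsParams(k_blue=0.02, k_bleach_red=0.02, k_bleach_blue=0.005)
KINETICS_OFF = PhotoKineticsParams()
KINETICS_PAINT = PhotoKineticsParams(
    k_blue=0.02, k_bleach_red=0.02, k_bleach_blue=0.005, replenishment=True
)


class TestGpPixel:
    def test_arithmetic_identities(self):
        assert gp_pixel(3.0, 1.0) == pytest.approx(0.5)
        assert gp_pixel(5.0, 5.0) == 0.0
        assert gp_pixel(4.0, 0.0) == 1.0

    def test_zero_sum_is_undefined(self):
        assert np.isnan(gp_pixel(0.0, 0.0))

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            gp_pixel(-1.0, 2.0)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(
        ib=st.floats(0.0, 1e6),
        ir=st.floats(0.0, 1e6),
        scale=st.floats(1e-3, 1e3),
    )
    def test_antisymmetry_and_scale_invariance(self, ib, ir, scale):
        if ib + ir == 0:
            return
        g = gp_pixel(ib, ir)
        assert gp_pixel(ir, ib) == pytest.approx(-g, abs=1e-12)
        assert gp_pixel(scale * ib, scale * ir) == pytest.approx(g, abs=1e-9)
        assert -1.0 <= g <= 1.0


class TestMask:
    def test_uniform_image_fully_included(self):
        img = TwoChannelImage(np.full((8, 8), 10.0), np.full((8, 8), 10.0))
        assert membrane_mask(img, 0.5).all()

    def test_saturated_pixel_excluded(self):
        ib = np.full((4, 4), 100.0)
        ir = np.full((4, 4), 100.0)
        ib[1, 2] = 65535.0
        img = TwoChannelImage(ib, ir, saturation_value=65535.0)
        mask = membrane_mask(img, 0.001)
        assert not mask[1, 2]
        assert mask.sum() == 15

    def test_noiseless_stripe_recovered_exactly(self):
        gp_true, stripe = make_membrane_scene((32, 32), (10, 20), 0.1)
        stack = synth_two_channel_stack(
            gp_true, stripe, KINETICS_OFF, n_frames=1, counts=100.0, seed=None,
            background_counts=1.0,
        )
        mask = membrane_mask(stack.frames[0], 0.5)
        np.testing.assert_array_equal(mask, stripe)

    def test_bad_threshold_rejected(self):
        img = TwoChannelImage(np.ones((4, 4)), np.ones((4, 4)))
        with pytest.raises(ValueError):
            membrane_mask(img, 0.0)


class TestGpMap:
    def test_noiseless_mean_equals_truth(self):
        gp_true, stripe = make_membrane_scene(gp_value=0.2)
        stack = synth_two_channel_stack(
            gp_true, stripe, KINETICS_OFF, n_frames=1, counts=500.0, seed=None
        )
        m = gp_map(stack.frames[0], stripe)
        assert m.mean_gp == pytest.approx(0.2, abs=1e-12)

    def test_homogeneous_region_mean_independent_of_mask_subset(self):
        gp_true, stripe = make_membrane_scene(gp_value=-0.4)
        stack = synth_two_channel_stack(
            gp_true, stripe, KINETICS_OFF, n_frames=1, counts=500.0, seed=None
        )
        half = stripe.copy()
        half[:, 32:] = False
        full = gp_map(stack.frames[0], stripe)
        part = gp_map(stack.frames[0], half)
        assert part.mean_gp == pytest.approx(full.mean_gp, abs=1e-12)

    def test_poisson_noise_mean_bias_bound(self):
        # ~1e3 membrane pixels at 500 counts: the ROI mean is within 0.01
        gp_true, stripe = make_membrane_scene((64, 64), (24, 40), -0.3)
        stack = synth_two_channel_stack(
            gp_true, stripe, KINETICS_OFF, n_frames=1, counts=500.0, seed=11
        )
        m = gp_map(stack.frames[0], stripe)
        assert m.n_pixels_used >= 1000
        assert abs(m.mean_gp - (-0.3)) < 0.01

    def test_empty_mask_flagged(self):
        img = TwoChannelImage(np.ones((4, 4)), np.ones((4, 4)))
        m = gp_map(img, np.zeros((4, 4), dtype=bool))
        assert not m.valid and np.isnan(m.mean_gp)


class TestSeries:
    def make_stack(self, kinetics, seed=21, n_frames=31):
        gp_true, stripe = make_membrane_scene()
        return synth_two_channel_stack(
            gp_true, stripe, kinetics, n_frames=n_frames, counts=500.0, seed=seed
        )

    def test_no_photoreaction_series_is_flat(self):
        series = gp_change_series(self.make_stack(KINETICS_OFF))
        assert np.all(np.abs(series.delta_gp) < 0.01)

    def test_photoblueing_biases_gp_upward(self):
        series = gp_change_series(self.make_stack(KINETICS_ON))
        assert series.delta_gp[-1] > 0.1
        # expected-trend check on a smoothed series (noise ~1e-3)
        assert np.all(np.diff(series.delta_gp) > -0.01)

    def test_exchangeable_probe_stays_true(self):
        series = gp_change_series(self.make_stack(KINETICS_PAINT))
        assert abs(series.delta_gp[30]) < 0.01

    def test_noiseless_apparent_gp_exceeds_truth_under_conversion(self):
        gp_true, stripe = make_membrane_scene(gp_value=-0.3)
        stack = synth_two_channel_stack(
            gp_true, stripe, KINETICS_ON, n_frames=10, counts=500.0, seed=None
        )
        m = gp_map(stack.frames[9], stripe)
        assert m.mean_gp > -0.3

    def test_bias_monotone_in_conversion_rate(self):
        # stronger conversion kinetics produce a larger terminal GP bias
        deltas = []
        for k_blue in (0.0, 0.005, 0.01, 0.02, 0.04):
            kin = PhotoKineticsParams(k_blue=k_blue, k_bleach_red=0.02)
            gp_true, stripe = make_membrane_scene()
            stack = synth_two_channel_stack(
                gp_true, stripe, kin, n_frames=16, counts=500.0, seed=None
            )
            deltas.append(gp_change_series(stack).delta_gp[-1])
        assert np.all(np.diff(deltas) > 0)

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError):
            gp_change_series(self.make_stack(KINETICS_OFF, n_frames=1))

    def test_mixture_mean_between_region_values(self):
        gp_true, stripe = make_membrane_scene(gp_value=-0.2)
        gp_true[30:40, :] = 0.4
        stack = synth_two_channel_stack(
            gp_true, stripe, KINETICS_OFF, n_frames=1, counts=500.0, seed=None
        )
        m = gp_map(stack.frames[0], stripe)
        assert -0.2 < m.mean_gp < 0.4
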