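"""Mixing quantification: profiles, AMI, slope, dilution interpolation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from chipscreen.exceptions import InvalidInputError, NoContrastError, UndefinedIndexError
from chipscreen.mixer import (
    ChannelImage,
    IntensityProfile,
    absolute_mixing_index,
    auto_normalize,
    estimate_dilution,
    extract_profile,
    mixing_vs_flowrate,
    normalize_profile,
    profile_slope,
)

profiles = hnp.arrays(
    float,
    st.integers(3, 40),
    elements=st.floats(0.0, 255.0, allow_nan=False),
)


def make_profile(values):
    values = np.asarray(values, dtype=float)
    return IntensityProfile(np.arange(values.size, dtype=float), values)


class TestExtractProfile:
    def test_constant_image(self):
        img = ChannelImage(np.full((10, 20), 7.0))
        profile = extract_profile(img, "luma")
        assert np.allclose(profile.intensities, 7.0)
        assert profile.n == 20

    def test_blue_channel_of_rgb(self):
        px = np.zeros((4, 6, 3))
        px[..., 2] = np.arange(6)[np.newaxis, :]
        profile = extract_profile(ChannelImage(px), "blue")
        assert np.allclose(profile.intensities, np.arange(6))

    def test_grayscale_luma_is_identity(self):
        px = np.arange(12.0).reshape(3, 4)
        assert np.allclose(
            extract_profile(ChannelImage(px), "luma").intensities, px.mean(axis=0)
        )

    def test_roi_restricts_columns_and_offsets_positions(self):
        px = np.tile(np.arange(10.0), (6, 1))
        img = ChannelImage(px, pixel_size=2.0, roi=(1, 5, 3, 8))
        profile = extract_profile(img, "luma")
        assert np.allclose(profile.intensities, np.arange(3, 8))
        assert np.allclose(profile.positions, np.arange(3, 8) * 2.0)

    def test_roi_out_of_bounds(self):
        with pytest.raises(InvalidInputError):
            ChannelImage(np.zeros((5, 5)), roi=(0, 6, 0, 5))

    def test_bad_selector(self):
        with pytest.raises(InvalidInputError):
            extract_profile(ChannelImage(np.zeros((4, 4, 3))), "magenta")


class TestNormalizeProfile:
    @pytest.mark.parametrize(
        "value, expected", [(30.0, 1.0), (10.0, 0.0), (20.0, 0.5), (40.0, 1.0), (0.0, 0.0)]
    )
    def test_mapping_and_clamping(self, value, expected):
        profile = normalize_profile(make_profile([value] * 3), 10.0, 30.0)
        assert np.allclose(profile.intensities, expected)

    def test_degenerate_refs_rejected(self):
        with pytest.raises(InvalidInputError):
            normalize_profile(make_profile([1, 2, 3]), 5.0, 5.0)

    def test_auto_normalize_spans_unit_interval(self):
        ps = [make_profile([10, 20, 30]), make_profile([15, 25, 35])]
        normed = auto_normalize(ps)
        assert min(p.intensities.min() for p in normed) == 0.0
        assert max(p.intensities.max() for p in normed) == 1.0


class TestAbsoluteMixingIndex:
    def test_step_profile_is_one(self):
        assert absolute_mixing_index(make_profile([0, 0, 2, 2])) == pytest.approx(1.0)

    def test_frozen_example(self):
        # sigma = sqrt(2/300), mean = 0.5
        assert absolute_mixing_index(make_profile([0.4, 0.5, 0.6])) == pytest.approx(
            0.16330, abs=1e-5
        )

    def test_constant_profile_is_zero(self):
        assert absolute_mixing_index(make_profile([0.7] * 8)) == 0.0

    def test_zero_mean_undefined(self):
        with pytest.raises(UndefinedIndexError):
            absolute_mixing_index(make_profile([0.0, 0.0, 0.0]))

    @given(values=profiles, scale=st.floats(1e-3, 1e3))
    def test_scale_invariance(self, values, scale):
        if values.mean() == 0:
            values = values + 1.0
        base = absolute_mixing_index(make_profile(values))
        scaled = absolute_mixing_index(make_profile(values * scale))
        assert scaled == pytest.approx(base, rel=1e-9)

    @given(values=profiles, shift=st.floats(0.1, 100.0))
    def test_constant_shift_decreases_ami_of_nonconstant_profile(self, values, shift):
        if np.ptp(values) == 0:
            values = values + np.linspace(0, 1, values.size)
        if values.mean() == 0:
            values = values + 0.5
        assert absolute_mixing_index(make_profile(values + shift)) < absolute_mixing_index(
            make_profile(values)
        )


class TestProfileSlope:
    def test_linear_profile_recovers_coefficient(self):
        x = np.linspace(0, 100, 21)
        profile = IntensityProfile(x, 0.003 * x + 0.1)
        assert profile_slope(profile) == pytest.approx(0.003, rel=1e-9)

    def test_constant_profile_zero(self):
        assert profile_slope(make_profile([5.0] * 6)) == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_v_is_zero(self):
        profile = make_profile([2.0, 1.0, 0.0, 1.0, 2.0])
        assert profile_slope(profile) == pytest.approx(0.0, abs=1e-12)

    def test_unsigned_mode(self):
        x = np.linspace(0, 10, 5)
        profile = IntensityProfile(x, -0.2 * x + 3)
        assert profile_slope(profile, signed=False) == pytest.approx(0.2, rel=1e-9)


class TestEstimateDilution:
    def _image(self, level, noise=None):
        px = np.full((8, 8), float(level))
        if noise is not None:
            px = px + noise
        return ChannelImage(px)

    def test_linear_ladder(self):
        images = [self._image(v) for v in (200, 150, 100, 0)]
        assert np.allclose(estimate_dilution(images), [100, 75, 50, 0])

    def test_affine_invariance(self):
        levels = (180, 120, 60, 20)
        base = estimate_dilution([self._image(v) for v in levels])
        transformed = estimate_dilution([self._image(3.0 * v + 11.0) for v in levels])
        assert np.allclose(base, transformed)

    def test_no_contrast(self):
        with pytest.raises(NoContrastError):
            estimate_dilution([self._image(200)] * 4)


class TestMixingVsFlowrate:
    def test_collinear_points(self):
        pairs = [(1.0, 0.01), (2.0, 0.03), (5.0, 0.09), (10.0, 0.19)]
        slope, intercept, r2 = mixing_vs_flowrate(pairs)
        assert slope == pytest.approx(0.02, rel=1e-9)
        assert intercept == pytest.approx(-0.01, rel=1e-6)
        assert r2 == pytest.approx(1.0)

    def test_too_few_points(self):
        with pytest.raises(InvalidInputError):
            mixing_vs_flowrate([(1.0, 0.1), (2.0, 0.2)])

    def test_repeated_x_rejected(self):
        with pytest.raises(InvalidInputError):
            mixing_vs_flowrate([(1.0, 0.1), (1.0, 0.2), (1.0, 0.3)])
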