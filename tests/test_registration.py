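"""Fourier-domain NCC, subpixel parabola refinement, and shift application."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rtmc import (
    SceneSpec,
    apply_shift,
    make_highpass_kernel,
    ncc_fourier,
    ncc_spatial_oracle,
    register_frame,
    render_scene,
    subpixel_peak,
)
from rtmc.exceptions import (
    DegenerateInputError,
    DimensionError,
    UndefinedCorrelationError,
)
from rtmc.filtering import highpass_filter
from rtmc.registration import NCCMap, RegistrationParams, _parabola_offset


class TestSpatialOracle:
    def test_self_correlation_is_one(self, rng):
        f = rng.random((24, 24))
        assert ncc_spatial_oracle(f, f, 0, 0) == pytest.approx(1.0, abs=1e-12)

    def test_invariant_to_positive_linear_rescaling(self, rng):
        f = rng.random((24, 24))
        assert ncc_spatial_oracle(f, 2 * f + 5, 0, 0) == pytest.approx(1.0, abs=1e-12)

    def test_negated_image_anticorrelates(self, rng):
        f = rng.random((24, 24))
        assert ncc_spatial_oracle(f, -f, 0, 0) == pytest.approx(-1.0, abs=1e-12)

    def test_zero_variance_patch_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            ncc_spatial_oracle(np.ones((16, 16)), np.random.rand(16, 16), 0, 0)


class TestFourierNCC:
    def test_matches_spatial_oracle_on_random_pairs(self, rng):
        # the central correctness property: the FFT path reproduces the
        # brute-force overlap correlation at every unmasked lag
        for _ in range(10):
            f1 = rng.standard_normal((32, 32))
            f2 = rng.standard_normal((32, 32))
            m = ncc_fourier(f1, f2, max_shift=8)
            for iy in range(m.values.shape[0]):
                for ix in range(m.values.shape[1]):
                    if m.valid[iy, ix]:
                        u, v = m.lag(iy, ix)
                        assert m.values[iy, ix] == pytest.approx(
                            ncc_spatial_oracle(f1, f2, u, v), abs=1e-6
                        )

    def test_identical_frames_peak_at_zero_lag(self, rng):
        f = rng.random((48, 48))
        m = ncc_fourier(f, f, max_shift=10)
        c = m.max_shift
        assert m.values[c, c] == pytest.approx(1.0, abs=1e-6)
        assert np.nanargmax(m.values) == c * m.values.shape[1] + c

    def test_linear_gray_value_invariance(self, rng):
        f = rng.random((48, 48))
        m = ncc_fourier(3.0 * f + 11.0, f, max_shift=10)
        c = m.max_shift
        assert m.values[c, c] == pytest.approx(1.0, abs=1e-6)

    def test_values_bounded_and_window_shape(self, rng):
        m = ncc_fourier(rng.random((40, 40)), rng.random((40, 40)), max_shift=6)
        assert m.values.shape == (13, 13)
        finite = m.values[m.valid]
        assert np.all(finite <= 1.0 + 1e-6) and np.all(finite >= -1.0 - 1e-6)

    def test_size_mismatch_rejected(self, rng):
        with pytest.raises(DimensionError):
            ncc_fourier(rng.random((32, 32)), rng.random((32, 16)), max_shift=4)

    def test_constant_images_fully_masked(self):
        with pytest.raises(DegenerateInputError):
            ncc_fourier(np.ones((32, 32)), np.ones((32, 32)), max_shift=4)


def _map_from_values(values, max_shift):
    values = np.asarray(values, dtype=float)
    return NCCMap(values=values, valid=np.isfinite(values), max_shift=max_shift)


class TestSubpixelPeak:
    def test_symmetric_neighbors_give_zero_offset(self):
        v = np.full((5, 5), 0.1)
        v[2, 2] = 1.0
        v[2, 1] = v[2, 3] = 0.6
        v[1, 2] = v[3, 2] = 0.7
        res = subpixel_peak(_map_from_values(v, 2))
        assert res.dx == 0.0 and res.dy == 0.0 and not res.integer_fallback

    def test_hand_computed_three_point_parabola(self):
        # left 0.8, center 1.0, right 0.9 along x
        v = np.full((5, 5), 0.0)
        v[2, 2] = 1.0
        v[2, 1], v[2, 3] = 0.8, 0.9
        v[1, 2] = v[3, 2] = 0.5
        res = subpixel_peak(_map_from_values(v, 2))
        expected = (0.8 - 0.9) / (2 * 0.8 - 4 * 1.0 + 2 * 0.9)
        assert res.dx == pytest.approx(expected, abs=1e-12)
        assert res.dy == 0.0

    @settings(derandomize=True, max_examples=50)
    @given(
        delta=st.floats(-0.49, 0.49),
        curvature=st.floats(0.05, 2.0),
    )
    def test_recovers_true_quadratic_vertex(self, delta, curvature):
        # samples from an exact parabola with vertex within +-0.5 of the peak
        xs = np.arange(-2, 3)
        quad = 1.0 - curvature * (xs - delta) ** 2
        v = np.full((5, 5), -10.0)
        v[2, :] = quad
        v[1, 2] = v[3, 2] = quad[2] - curvature  # symmetric in y
        res = subpixel_peak(_map_from_values(v, 2))
        assert res.dx == pytest.approx(delta, abs=1e-10)
        assert res.dy == pytest.approx(0.0, abs=1e-10)

    def test_offsets_clamped_to_half_pixel(self):
        assert abs(_parabola_offset(0.999999, 1.0, 0.0)) <= 0.5
        assert _parabola_offset(0.5, 0.5, 0.5) == 0.0  # flat: zero denominator

    def test_peak_at_window_edge_falls_back_to_integer(self):
        v = np.zeros((5, 5))
        v[0, 2] = 1.0
        res = subpixel_peak(_map_from_values(v, 2))
        assert res.integer_fallback
        assert (res.dx, res.dy) == (0.0, -2.0)

    def test_fully_masked_map_rejected(self):
        with pytest.raises(DegenerateInputError):
            subpixel_peak(_map_from_values(np.full((5, 5), np.nan), 2))


class TestApplyShift:
    def test_zero_shift_is_identity(self, rng):
        f = rng.random((32, 32))
        np.testing.assert_array_equal(apply_shift(f, 0, 0), f)

    def test_integer_shift_equals_exact_translation(self, rng):
        f = rng.random((32, 32))
        out = apply_shift(f, 3, -2)  # 3 columns right, 2 rows up
        expected = np.zeros_like(f)
        expected[:30, 3:] = f[2:, :29]
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_integer_shift_invertible_on_interior(self, rng):
        f = rng.random((32, 32))
        back = apply_shift(apply_shift(f, 4, -3), -4, 3)
        np.testing.assert_allclose(back[4:-4, 4:-4], f[4:-4, 4:-4], atol=1e-12)


class TestRegisterFrame:
    @pytest.fixture(scope="class")
    def filtered_scene(self):
        base = render_scene(SceneSpec(seed=5))
        kernel = make_highpass_kernel(10)
        return base, kernel, highpass_filter(base, kernel)

    def test_identical_frame_registers_at_origin(self, filtered_scene):
        _, _, tpl = filtered_scene
        res = register_frame(tpl, tpl)
        assert res.dx == pytest.approx(0.0, abs=1e-9)
        assert res.dy == pytest.approx(0.0, abs=1e-9)
        assert res.peak_ncc == pytest.approx(1.0, abs=1e-6)

    def test_integer_translation_recovered_exactly(self, filtered_scene):
        base, kernel, tpl = filtered_scene
        moved = highpass_filter(apply_shift(base, 3, -2), kernel)
        res = register_frame(moved, tpl)
        assert round(res.dx) == 3 and round(res.dy) == -2
        assert abs(res.dx - 3) < 0.05 and abs(res.dy + 2) < 0.05

    def test_subpixel_translation_within_02_px(self, filtered_scene):
        base, kernel, tpl = filtered_scene
        moved = highpass_filter(apply_shift(base, 2.3, -1.7), kernel)
        res = register_frame(moved, tpl)
        assert res.dx == pytest.approx(2.3, abs=0.2)
        assert res.dy == pytest.approx(-1.7, abs=0.2)

    def test_antisymmetry(self, filtered_scene):
        base, kernel, _ = filtered_scene
        a = highpass_filter(apply_shift(base, 1.5, -2.5), kernel)
        b = highpass_filter(base, kernel)
        fwd = register_frame(a, b)
        rev = register_frame(b, a)
        assert fwd.dx == pytest.approx(-rev.dx, abs=0.1)
        assert fwd.dy == pytest.approx(-rev.dy, abs=0.1)

    def test_gain_offset_invariance(self, filtered_scene):
        base, kernel, tpl = filtered_scene
        moved = highpass_filter(apply_shift(base, 2.3, -1.7), kernel)
        res1 = register_frame(moved, tpl)
        res2 = register_frame(1.7 * moved + 0.3, tpl)
        assert res2.dx == pytest.approx(res1.dx, abs=1e-6)
        assert res2.dy == pytest.approx(res1.dy, abs=1e-6)

    def test_subpixel_part_never_exceeds_half_pixel(self, filtered_scene, rng):
        # the parabola offsets are clamped, so the fractional part of any
        # estimate stays within half a pixel of the integer peak
        base, kernel, tpl = filtered_scene
        m = RegistrationParams().max_shift
        for _ in range(5):
            d = rng.uniform(-8, 8, 2)
            moved = highpass_filter(apply_shift(base, *d), kernel)
            res = register_frame(moved, tpl)
            assert abs(res.dx - round(res.dx)) <= 0.5 + 1e-12
            assert abs(res.dy - round(res.dy)) <= 0.5 + 1e-12
            assert abs(res.dx) <= m + 0.5 and abs(res.dy) <= m + 0.5
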