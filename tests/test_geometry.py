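"""FWHM / radius measurement: closed forms, invariances, brute-force oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import vasomotion as vm
from vasomotion import synthetic as syn
from vasomotion.errors import (
    NoPeakError,
    OutOfBoundsError,
    TraceRejectedError,
    UnboundedProfileError,
)
from vasomotion.images import FrameStack, ReslicedKymograph


def brute_force_crossings(values, half):
    """All half-height crossings by exhaustive segment intersection.

    A crossing is any segment with exactly one endpoint strictly below
    half height (a sample exactly at half is on the "above" side, per
    the walk-to-first-sample-strictly-below rule).
    """
    crossings = []
    for i in range(len(values) - 1):
        lo, hi = values[i], values[i + 1]
        if (lo < half) != (hi < half):
            crossings.append(i + (half - lo) / (hi - lo))
    return crossings


class TestProfileFwhm:
    def test_top_hat_width(self):
        profile = np.array([0, 0, 1, 1, 1, 1, 1, 0, 0], float)
        m = vm.profile_fwhm(profile, pixel_size_um=1.0)
        assert m.width_um == pytest.approx(5.0)

    def test_gaussian_closed_form(self):
        x = np.arange(200, dtype=float)
        sigma = 4.0
        profile = np.exp(-0.5 * ((x - 100) / sigma) ** 2)
        m = vm.profile_fwhm(profile, pixel_size_um=1.0, smooth_px=1)
        assert m.width_um == pytest.approx(2 * np.sqrt(2 * np.log(2)) * sigma, abs=0.1)

    def test_symmetric_triangle_exact(self):
        # linear flanks: interpolation is exact, half-width 3 px each side
        profile = np.array([0, 0, 1, 2, 3, 2, 1, 0, 0], float) / 3.0
        m = vm.profile_fwhm(profile, pixel_size_um=1.0, smooth_px=1)
        assert m.width_um == pytest.approx(3.0)

    def test_flat_profile_raises(self):
        with pytest.raises(NoPeakError):
            vm.profile_fwhm(np.full(10, 7.0))

    def test_peak_at_edge_unbounded(self):
        with pytest.raises(UnboundedProfileError):
            vm.profile_fwhm(np.array([5.0, 4.0, 3.0, 2.0, 1.0]), smooth_px=1)

    @given(
        scale=st.floats(0.1, 100.0),
        offset=st.floats(-50.0, 50.0),
        sigma=st.floats(2.0, 8.0),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_affine_intensity_invariance(self, scale, offset, sigma):
        """FWHM is unchanged by positive rescaling or constant offset."""
        x = np.arange(120, dtype=float)
        base = np.exp(-0.5 * ((x - 60) / sigma) ** 2)
        w0 = vm.profile_fwhm(base, smooth_px=1).width_um
        w1 = vm.profile_fwhm(scale * base + offset, smooth_px=1).width_um
        assert w1 == pytest.approx(w0, rel=1e-9)

    @given(seed=st.integers(0, 500))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_mirror_invariance_and_oracle(self, seed):
        """Width is mirror-invariant, and the walk-out crossings agree with
        exhaustive segment intersection on coarse random profiles."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(7, 31))
        values = rng.integers(0, 6, n).astype(float)
        center = n // 2
        values[center] = 8.0  # guarantee an interior global peak
        values[0] = values[-1] = 0.0
        m = vm.profile_fwhm(values, smooth_px=1)
        m_rev = vm.profile_fwhm(values[::-1], smooth_px=1)
        assert m_rev.width_um == pytest.approx(m.width_um, rel=1e-12)
        half = (values.max() + values.min()) / 2
        crossings = brute_force_crossings(values, half)
        left = max(c for c in crossings if c <= center)
        right = min(c for c in crossings if c >= center)
        assert m.left_crossing_px == pytest.approx(left, abs=1e-9)
        assert m.right_crossing_px == pytest.approx(right, abs=1e-9)


class TestHalfRadius:
    def test_arithmetic_contract(self):
        # wide soft band: right crossing at 62.5, midline at 50
        x = np.arange(100, dtype=float)
        profile = np.where(np.abs(x - 50) <= 12, 1.0, 0.0)
        profile[62] = 1.0
        profile[63] = 0.0  # crossing at 62.5
        m = vm.profile_half_radius(profile, midline_px=50.0, side="right",
                                   pixel_size_um=0.994, smooth_px=1)
        assert m.width_um == pytest.approx(12.5 * 0.994)

    def test_symmetric_profile_left_equals_right(self):
        x = np.arange(101, dtype=float)
        profile = np.exp(-0.5 * ((x - 50) / 6.0) ** 2)
        left = vm.profile_half_radius(profile, 50.0, "left", smooth_px=1)
        right = vm.profile_half_radius(profile, 50.0, "right", smooth_px=1)
        assert left.width_um == pytest.approx(right.width_um, rel=1e-9)

    @given(mid_shift=st.floats(-3.0, 3.0), sigma=st.floats(3.0, 8.0))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_left_plus_right_equals_fwhm(self, mid_shift, sigma):
        """Radii on both sides of any interior midline sum to the diameter."""
        x = np.arange(121, dtype=float)
        profile = np.exp(-0.5 * ((x - 60) / sigma) ** 2)
        mid = 60.0 + mid_shift
        left = vm.profile_half_radius(profile, mid, "left", smooth_px=1).width_um
        right = vm.profile_half_radius(profile, mid, "right", smooth_px=1).width_um
        fwhm = vm.profile_fwhm(profile, smooth_px=1).width_um
        assert left + right == pytest.approx(fwhm, rel=1e-9)

    def test_no_crossing_on_requested_side(self):
        # monotone rise: the peak sits at the right edge, no right crossing
        profile = np.array([0.0, 1.0, 2.0, 3.0, 4.0, 5.0])
        with pytest.raises(UnboundedProfileError):
            vm.profile_half_radius(profile, 2.0, "right", smooth_px=1)
        # left side works fine
        assert vm.profile_half_radius(profile, 2.0, "left", smooth_px=1).width_um > 0


class TestReslice:
    def test_constant_stack_constant_kymograph(self):
        stack = FrameStack(np.full((4, 10, 10), 3.0), 1.0, 1.0)
        path = np.column_stack((np.full(8, 4.5), np.linspace(1, 8, 8)))
        kymo = vm.reslice(stack, path)
        assert kymo.data.shape == (4, 8)
        assert np.all(kymo.data == 3.0)

    def test_integer_row_path_is_exact_copy(self):
        rng = np.random.default_rng(0)
        stack = FrameStack(rng.uniform(0, 10, (3, 6, 12)), 1.0, 1.0)
        path = np.column_stack((np.full(12, 2.0), np.arange(12, dtype=float)))
        kymo = vm.reslice(stack, path)
        np.testing.assert_allclose(kymo.data, stack.data[:, 2, :])

    def test_out_of_bounds_path_names_point(self):
        stack = FrameStack(np.zeros((2, 5, 5)), 1.0, 1.0)
        path = np.array([[1.0, 1.0], [2.0, 2.0], [9.0, 3.0]])
        with pytest.raises(OutOfBoundsError, match="point 2"):
            vm.reslice(stack, path)


class TestExtractTrace:
    @pytest.fixture
    def movie(self):
        osc = syn.OscillationSpec(
            base_level=20.0, frequency_hz=0.1, amplitude_frac=0.03, noise_sd=0.0,
            duration_s=120.0, seed=2,
        )
        spec = syn.VesselMovieSpec(oscillation=osc, image_shape=(64, 8), pixel_size_um=0.994)
        return syn.make_vessel_movie(spec), spec

    def _column_kymo(self, stack, col=4.0):
        rows = np.arange(stack.data.shape[1], dtype=float)
        return vm.reslice(stack, np.column_stack((rows, np.full(rows.size, col))))

    def test_noiseless_recovery_within_half_pixel(self, movie):
        stack, spec = movie
        kymo = self._column_kymo(stack)
        trace = vm.extract_trace(kymo, mode="radius", smooth_px=1)
        err = np.abs(trace.values - stack.ground_truth["radius_um"])
        assert err.max() <= 0.5 * spec.pixel_size_um
        assert not trace.flags.any()
        # trace extrema reflect the 3% oscillation around 20 um
        assert trace.values.max() == pytest.approx(20.6, abs=0.5 * spec.pixel_size_um)
        assert trace.values.min() == pytest.approx(19.4, abs=0.5 * spec.pixel_size_um)

    def test_diameter_mode_doubles_radius(self, movie):
        stack, spec = movie
        kymo = self._column_kymo(stack)
        trace = vm.extract_trace(kymo, mode="diameter", smooth_px=1)
        err = np.abs(trace.values - 2 * stack.ground_truth["radius_um"])
        assert err.max() <= 0.5 * spec.pixel_size_um

    def test_constant_movie_constant_trace(self):
        osc = syn.OscillationSpec(
            base_level=10.0, amplitude_frac=0.0, noise_sd=0.0, duration_s=60.0, seed=0
        )
        stack = syn.make_vessel_movie(
            syn.VesselMovieSpec(oscillation=osc, image_shape=(48, 6))
        )
        kymo = self._column_kymo(stack, col=3.0)
        trace = vm.extract_trace(kymo, mode="diameter", smooth_px=1)
        assert np.ptp(trace.values) == pytest.approx(0.0, abs=1e-9)
        assert not trace.flags.any()

    def test_all_background_movie_rejected(self):
        kymo = ReslicedKymograph(np.full((30, 20), 5.0), 1.0, 1.0)
        with pytest.raises(TraceRejectedError):
            vm.extract_trace(kymo, mode="diameter")

    def test_failed_frames_interpolated_and_flagged(self):
        rng = np.random.default_rng(3)
        x = np.arange(20, dtype=float)
        good = np.exp(-0.5 * ((x - 10) / 3.0) ** 2) + 0.01 * rng.uniform(size=20)
        data = np.tile(good, (20, 1))
        data[5] = 1.0  # flat frame -> measurement failure
        kymo = ReslicedKymograph(data, 1.0, 1.0)
        trace = vm.extract_trace(kymo, mode="diameter", smooth_px=1)
        assert trace.flags[5] and trace.flags.sum() == 1
        assert trace.values[5] == pytest.approx((trace.values[4] + trace.values[6]) / 2)
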