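"""Velocimetry, flux, and the capillary stall classifier."""

import itertools

import numpy as np
import pytest

import vasomotion as vm
from vasomotion import synthetic as syn
from vasomotion.errors import DegenerateStreakError, LengthMismatchError
from vasomotion.images import LineScanKymograph
from conftest import make_trace


def kymo_stub(line_period_s=0.002, pixel_size_um=0.994, shape=(32, 64)):
    return LineScanKymograph(
        data=np.zeros(shape), line_period_s=line_period_s, pixel_size_um=pixel_size_um
    )


class TestManualVelocity:
    def test_direct_arithmetic(self):
        """20 px at 0.994 um/px over 10 lines of 2 ms -> 0.994 mm/s."""
        kymo = kymo_stub()
        result = vm.streak_velocity(kymo, [((0, 5.0), (10, 25.0))])
        assert result.velocity_mm_s == pytest.approx(0.994)

    def test_endpoint_order_irrelevant(self):
        kymo = kymo_stub()
        a = vm.streak_velocity(kymo, [((0, 5.0), (10, 25.0))])
        b = vm.streak_velocity(kymo, [((10, 25.0), (0, 5.0))])
        assert a.velocity_mm_s == pytest.approx(b.velocity_mm_s)

    def test_mirror_flips_sign(self):
        kymo = kymo_stub()
        fwd = vm.streak_velocity(kymo, [((0, 5.0), (10, 25.0))])
        rev = vm.streak_velocity(kymo, [((0, 25.0), (10, 5.0))])
        assert rev.velocity_mm_s == pytest.approx(-fwd.velocity_mm_s)

    def test_mean_over_streaks_and_direction_convention(self):
        kymo = kymo_stub()
        streaks = [((0, 0.0), (10, 20.0)), ((5, 0.0), (15, 10.0))]
        r = vm.streak_velocity(kymo, streaks, positive_direction=-1)
        expected = -np.mean([20 / 10, 10 / 10]) * 0.994 / 0.002 / 1000
        assert r.velocity_mm_s == pytest.approx(expected)

    def test_degenerate_streak(self):
        with pytest.raises(DegenerateStreakError):
            vm.streak_velocity(kymo_stub(), [((3, 1.0), (3, 9.0))])


class TestAutoVelocity:
    @pytest.mark.parametrize("v", [0.2, 1.0, 5.0, 13.0])
    def test_recovery_within_5_percent(self, v):
        spec = syn.FlowSpec(velocity_mm_s=v, cell_rate_hz=30.0, n_lines=256, seed=3)
        kymo = syn.make_linescan_kymograph(spec)
        r = vm.auto_streak_velocity(kymo)
        assert r.velocity_mm_s == pytest.approx(v, rel=0.05)

    def test_zero_velocity(self):
        spec = syn.FlowSpec(velocity_mm_s=0.0, cell_rate_hz=10.0, n_lines=256, seed=1)
        r = vm.auto_streak_velocity(syn.make_linescan_kymograph(spec))
        assert abs(r.velocity_mm_s) < 0.01

    def test_mirror_flips_sign(self):
        spec = syn.FlowSpec(velocity_mm_s=2.0, cell_rate_hz=30.0, n_lines=256, seed=6)
        kymo = syn.make_linescan_kymograph(spec)
        mirrored = LineScanKymograph(
            data=kymo.data[:, ::-1].copy(),
            line_period_s=kymo.line_period_s,
            pixel_size_um=kymo.pixel_size_um,
        )
        a = vm.auto_streak_velocity(kymo)
        b = vm.auto_streak_velocity(mirrored)
        assert b.velocity_mm_s == pytest.approx(-a.velocity_mm_s, rel=0.02)

    def test_pure_noise_reports_no_flow(self):
        spec = syn.FlowSpec(velocity_mm_s=1.0, cell_rate_hz=0.0, noise_sd=5.0,
                            n_lines=256, seed=2)
        r = vm.auto_streak_velocity(syn.make_linescan_kymograph(spec))
        assert r.velocity_mm_s is None

    def test_time_axis_stretch_equivariance(self):
        """Doubling the line period halves the velocity read from the same image."""
        spec = syn.FlowSpec(velocity_mm_s=3.0, cell_rate_hz=30.0, n_lines=256, seed=9)
        kymo = syn.make_linescan_kymograph(spec)
        slow = LineScanKymograph(
            data=5.0 * kymo.data,  # intensity rescaling is also irrelevant
            line_period_s=2 * kymo.line_period_s,
            pixel_size_um=kymo.pixel_size_um,
        )
        a = vm.auto_streak_velocity(kymo)
        b = vm.auto_streak_velocity(slow)
        assert b.velocity_mm_s == pytest.approx(a.velocity_mm_s / 2, rel=1e-6)


class TestFlux:
    def test_direct_arithmetic(self):
        kymo = kymo_stub(line_period_s=6.0 / 32, shape=(32, 64))  # 6 s total
        assert vm.flux(kymo, 12).flux_cells_per_s == pytest.approx(2.0)

    def test_zero_streaks(self):
        assert vm.flux(kymo_stub(), 0).flux_cells_per_s == 0.0

    def test_poisson_rate_recovery(self):
        """Mean flux over 100 seeds approaches the generator cell rate."""
        rate = 25.0
        fluxes = []
        for seed in range(100):
            spec = syn.FlowSpec(velocity_mm_s=1.0, cell_rate_hz=rate, n_lines=256, seed=seed)
            kymo = syn.make_linescan_kymograph(spec)
            count = kymo.ground_truth["n_streaks"]
            fluxes.append(vm.flux(kymo, count).flux_cells_per_s)
        assert np.mean(fluxes) == pytest.approx(rate, rel=0.10)


class TestFlowingIndicator:
    def test_constant_trace_all_non_flowing(self):
        fl = vm.flowing_indicator(make_trace(np.full(50, 9.0)))
        assert not fl.any()

    def test_high_variance_everywhere_all_flowing(self):
        spec = syn.StallSpec(stall_intervals=(), seed=3)
        trace = vm.mean_roi_trace(syn.make_capillary_movie(spec), np.ones((8, 8), bool))
        assert vm.flowing_indicator(trace).all()

    def test_ground_truth_stall_recovered_within_one_frame(self):
        spec = syn.StallSpec(stall_intervals=((40, 10),), seed=7)
        trace = vm.mean_roi_trace(syn.make_capillary_movie(spec), np.ones((8, 8), bool))
        nonflowing = np.flatnonzero(~vm.flowing_indicator(trace))
        assert nonflowing.size > 0
        assert 39 <= nonflowing.min() <= 41
        assert 48 <= nonflowing.max() <= 50

    def test_too_short_rejected(self):
        with pytest.raises(vm.errors.TraceTooShortError):
            vm.flowing_indicator(make_trace(np.array([1.0, 2.0]), dt=1.0), window_frames=3)


def brute_longest_false_run(seq):
    best = run = 0
    for f in seq:
        run = 0 if f else run + 1
        best = max(best, run)
    return best


class TestStallClassify:
    @pytest.mark.parametrize("length,expected", [(10, True), (9, False)])
    def test_criterion_boundary(self, length, expected):
        flowing = np.ones(200, bool)
        flowing[50 : 50 + length] = False
        assert vm.stall_classify(flowing).stalled is expected

    def test_separated_runs_not_merged(self):
        flowing = np.ones(200, bool)
        flowing[20:25] = False
        flowing[26:31] = False  # two runs of 5 with a gap
        assert vm.stall_classify(flowing).stalled is False

    def test_length_mismatch(self):
        with pytest.raises(LengthMismatchError):
            vm.stall_classify(np.ones(100, bool))

    @pytest.mark.parametrize("min_frames", [1, 3, 10])
    def test_exhaustive_oracle_short_sequences(self, min_frames):
        """Classifier equals a brute-force run scan on all sequences <= length 12."""
        for n in range(1, 13):
            for bits in itertools.product((True, False), repeat=n):
                report = vm.stall_classify(
                    np.array(bits), stall_min_frames=min_frames, record_frames=n
                )
                expected = brute_longest_false_run(bits) >= min_frames
                assert report.stalled == expected


class TestStallRate:
    def test_rates(self):
        def rep(stalled):
            return vm.StallReport(np.ones(5, bool), stalled, 0)

        assert vm.stall_rate([rep(True)] + [rep(False)] * 19) == pytest.approx(5.0)
        assert vm.stall_rate([rep(False)] * 10) == 0.0
        assert vm.stall_rate([rep(True)] * 4) == 100.0
        with pytest.raises(ValueError):
            vm.stall_rate([])

    def test_end_to_end_snr3_recovery(self):
        """Generator stall specs recovered exactly at SNR 3 over 50 seeds."""
        for seed in range(50):
            for intervals, expect in [(((60, 30),), True), ((), False), (((100, 4),), False)]:
                spec = syn.StallSpec(
                    stall_intervals=intervals, transit_signal_sd=6.0, noise_sd=2.0,
                    seed=seed,
                )
                trace = vm.mean_roi_trace(
                    syn.make_capillary_movie(spec), np.ones((8, 8), bool)
                )
                report = vm.stall_classify(vm.flowing_indicator(trace))
                assert report.stalled is expect, (seed, intervals)
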