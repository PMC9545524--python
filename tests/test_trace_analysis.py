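"""Trace statistics: frame averaging, windowed velocities, segmentation,
pause/switch calling, duration fits."""

import numpy as np
import pytest

from motorpair.gillespie import Trajectory
from motorpair.synthetic import TraceSpec, gen_segmented_trace
from motorpair.trace_analysis import (
    SampledTrace,
    Segment,
    SegmentSet,
    classify_fast_slow,
    classify_segment,
    count_directional_switches,
    distribution_peak,
    fit_exponential,
    frame_average,
    instantaneous_velocities,
    segment_trace,
    time_fractions,
    trace_velocity,
    weighted_velocity_distribution,
)


def make_traj(times, cargo):
    """Minimal trajectory with a given piecewise-constant cargo path."""
    times = np.asarray(times, dtype=float)
    cargo = np.asarray(cargo, dtype=float)
    z = np.zeros_like(times)
    b = np.ones_like(times, dtype=bool)
    return Trajectory(times, cargo, z, z, b, b, np.empty(0, dtype=np.int8), False)


def linear_trace(v, duration, frame_dt=0.286):
    n = int(duration / frame_dt) + 1
    return SampledTrace(v * frame_dt * np.arange(n), frame_dt=frame_dt)


class TestFrameAverage:
    def test_constant_cargo_gives_constant_frames(self):
        traj = make_traj([0.0, 5.0], [10.0, 10.0])
        trace = frame_average(traj, 0.286)
        assert np.allclose(trace.positions, 10.0)
        assert trace.n_frames == int(5.0 / 0.286)

    def test_mid_frame_step_averages_to_half(self):
        traj = make_traj([0.0, 0.143, 1.0], [0.0, 8.0, 8.0])
        trace = frame_average(traj, 0.286)
        assert trace.positions[0] == pytest.approx(4.0)
        assert np.allclose(trace.positions[1:], 8.0)

    def test_stepped_linear_motion_stays_on_the_line(self):
        # 100 nm/s realized as 8 nm steps every 0.08 s
        times = np.arange(0, 10.0, 0.08)
        cargo = 8.0 * np.arange(times.size)
        trace = frame_average(make_traj(times, cargo), 0.286)
        # frame k's mean sits at the window midpoint of the ramp, within
        # half-step quantization
        expected = 100.0 * (np.arange(trace.n_frames) + 0.5) * 0.286
        # within half-step quantization (8/2 = 4 nm) plus frame-alignment slack
        assert np.max(np.abs(trace.positions - expected)) < 4.5

    def test_too_short_trajectory_rejected(self):
        with pytest.raises(ValueError):
            frame_average(make_traj([0.0, 0.1], [0.0, 0.0]), 0.286)


class TestInstantaneousVelocities:
    def test_constant_velocity_recovered_exactly(self):
        v = instantaneous_velocities(linear_trace(100.0, 20.0))
        assert v.size > 0
        assert np.allclose(v, 100.0)

    def test_stationary_trace_gives_zeros(self):
        trace = SampledTrace(np.zeros(40), frame_dt=0.286)
        assert np.allclose(instantaneous_velocities(trace), 0.0)

    def test_two_segment_trace_splits_windows(self):
        spec = TraceSpec(plan=[(100.0, 5.0), (-100.0, 5.0)], noise_sigma=0.0)
        trace, _ = gen_segmented_trace(spec, np.random.default_rng(0))
        v = instantaneous_velocities(trace)
        plus = np.sum(v > 50)
        minus = np.sum(v < -50)
        assert abs(plus - minus) <= 1 and plus + minus >= v.size - 1

    def test_window_count_and_trailing_discard(self):
        # 10 frames = 9 intervals -> three 3-interval windows, 0 left over
        trace = SampledTrace(np.arange(10.0), frame_dt=0.286)
        assert instantaneous_velocities(trace, window=1.0).size == 3

    def test_short_trace_yields_empty(self):
        trace = SampledTrace(np.zeros(3), frame_dt=0.286)
        assert instantaneous_velocities(trace, window=1.0).size == 0

    def test_slope_variant_matches_on_noiseless_linear(self):
        trace = linear_trace(50.0, 10.0)
        assert np.allclose(
            instantaneous_velocities(trace, slope=True), 50.0, atol=1e-9
        )


class TestDistributionPeak:
    def test_degenerate_sample_returns_common_value(self):
        assert distribution_peak([7.0] * 50) == 7.0

    def test_symmetric_unimodal_peaks_near_zero(self, rng):
        v = rng.normal(0, 50, size=5000)
        assert abs(distribution_peak(v)) < 0.2 * 50  # well inside one sd

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            distribution_peak([])


class TestTraceVelocity:
    def test_net_displacement_over_duration(self):
        trace = SampledTrace([0.0, 290.0, 580.0], frame_dt=1.0)
        assert trace_velocity(trace) == pytest.approx(290.0)

    def test_zero_net_displacement(self):
        trace = SampledTrace([0.0, 100.0, 0.0], frame_dt=1.0)
        assert trace_velocity(trace) == 0.0

    def test_equals_duration_weighted_segment_mean(self):
        spec = TraceSpec(plan=[(200.0, 4.004), (0.0, 4.004), (-80.0, 4.004)],
                         noise_sigma=0.0)
        trace, truth = gen_segmented_trace(spec, np.random.default_rng(0))
        weighted = np.sum(truth.velocities * truth.durations) / np.sum(
            truth.durations
        )
        # equal up to the one-frame-per-boundary quantization of segments
        assert trace_velocity(trace) == pytest.approx(weighted, abs=5.0)


@pytest.mark.parametrize(
    "vel, threshold, expected",
    [
        (290.0, 250.0, "fast"),   # the typical fast DDB-Kin1 trace
        (-28.0, 125.0, "slow"),   # the typical DDB-Kin2 trace
        (250.0, 250.0, "slow"),   # boundary is strict
    ],
)
def test_classify_fast_slow(vel, threshold, expected):
    assert classify_fast_slow(vel, threshold) == expected


class TestSegmentation:
    def test_constant_velocity_is_one_segment(self, rng):
        spec = TraceSpec(plan=[(150.0, 20.0)], noise_sigma=15.0)
        trace, _ = gen_segmented_trace(spec, rng)
        segs = segment_trace(trace)
        assert len(segs) == 1
        assert segs.segments[0].velocity == pytest.approx(150.0, abs=10.0)

    def test_noiseless_two_segment_breakpoint_recovery(self):
        spec = TraceSpec(plan=[(0.0, 10.0), (200.0, 10.0)], noise_sigma=0.0)
        trace, truth = gen_segmented_trace(spec, np.random.default_rng(0))
        segs = segment_trace(trace)
        assert len(segs) == 2
        true_break = truth.segments[0].end_frame  # last frame of the 0 nm/s phase
        assert abs(segs.segments[0].end_frame - true_break) <= 1
        assert segs.segments[0].velocity == pytest.approx(0.0, abs=5.0)
        assert segs.segments[1].velocity == pytest.approx(200.0, abs=5.0)

    def test_sub_threshold_velocity_change_is_merged(self):
        spec = TraceSpec(plan=[(100.0, 10.0), (105.0, 10.0)], noise_sigma=0.0)
        trace, _ = gen_segmented_trace(spec, np.random.default_rng(0))
        segs = segment_trace(trace, min_dv=10.0)
        assert len(segs) == 1

    def test_adjacent_segments_differ_by_min_dv(self, rng):
        spec = TraceSpec(
            plan=[(0.0, 6.0), (300.0, 6.0), (0.0, 6.0), (-250.0, 6.0)],
            noise_sigma=20.0,
        )
        trace, _ = gen_segmented_trace(spec, rng)
        segs = segment_trace(trace)
        v = segs.velocities
        assert np.all(np.abs(np.diff(v)) >= 10.0)

    def test_coverage_and_velocity_consistency(self, rng):
        spec = TraceSpec(plan=[(0.0, 8.0), (250.0, 8.0)], noise_sigma=20.0)
        trace, _ = gen_segmented_trace(spec, rng)
        segs = segment_trace(trace)
        assert segs.segments[0].start_frame == 0
        assert segs.segments[-1].end_frame == trace.n_frames - 1
        for s in segs:
            raw = trace.positions[s.end_frame] - trace.positions[s.start_frame]
            span = (s.end_frame - s.start_frame) * trace.frame_dt
            # fitted slope agrees with the raw endpoint velocity within noise
            assert s.velocity == pytest.approx(raw / span, abs=12.0)
        # durations count frames, so they sum to n_frames * frame_dt
        assert segs.total_duration == pytest.approx(
            trace.total_duration + trace.frame_dt
        )

    def test_min_segment_duration_enforced(self, rng):
        spec = TraceSpec(plan=[(0.0, 5.0), (400.0, 5.0)], noise_sigma=25.0)
        trace, _ = gen_segmented_trace(spec, rng)
        for s in segment_trace(trace):
            assert s.duration >= 3 * trace.frame_dt - 1e-9

    def test_breakpoint_recovery_many_noiseless_fixtures(self):
        # velocity jumps >= 20 nm/s, segments >= 3 frames: exact recovery +-1
        rng = np.random.default_rng(5)
        for _ in range(10):
            n_seg = rng.integers(2, 5)
            vels, last = [], 0.0
            for _ in range(n_seg):
                jump = rng.uniform(20, 300) * rng.choice([-1, 1])
                last = last + jump
                vels.append(last)
            plan = [(v, float(rng.uniform(2.0, 8.0))) for v in vels]
            trace, truth = gen_segmented_trace(
                TraceSpec(plan=plan, noise_sigma=0.0), rng
            )
            segs = segment_trace(trace)
            true_breaks = [s.end_frame for s in truth.segments[:-1]]
            got_breaks = [s.end_frame for s in segs.segments[:-1]]
            assert len(got_breaks) == len(true_breaks)
            for a, b in zip(got_breaks, true_breaks):
                assert abs(a - b) <= 1

    def test_noise_robust_velocity_recovery(self):
        # sigma <= 30 nm, segments >= 2 s: velocities within 10 nm/s
        rng = np.random.default_rng(17)
        spec = TraceSpec(plan=[(0.0, 6.0), (300.0, 6.0), (-200.0, 6.0)],
                         noise_sigma=30.0)
        trace, truth = gen_segmented_trace(spec, rng)
        segs = segment_trace(trace)
        assert len(segs) == 3
        for got, want in zip(segs.velocities, truth.velocities):
            assert abs(got - want) <= 10.0

    def test_too_short_trace_degenerates_with_warning(self):
        # two frames is below the three-frame minimum segment
        trace = SampledTrace([0.0, 10.0], frame_dt=0.286)
        with pytest.warns(UserWarning):
            segs = segment_trace(trace)
        assert len(segs) == 1

    def test_minimal_three_frame_trace_is_one_clean_segment(self):
        segs = segment_trace(SampledTrace([0.0, 10.0, 20.0], frame_dt=0.286))
        assert len(segs) == 1


@pytest.mark.parametrize(
    "disp, expected",
    [(50.0, "pause"), (-50.0, "pause"), (-200.0, "minus"), (73.0, "plus"),
     (-73.0, "minus"), (72.99, "pause")],
)
def test_classify_segment_pixel_rule(disp, expected):
    seg = Segment(0, 10, disp / 2.86, 2.86, disp, "pause")
    assert classify_segment(seg) == expected


def segset_from_states(states, seg_frames=10, frame_dt=0.286):
    """Hand-built contiguous SegmentSet with prescribed motility states."""
    n = len(states) * seg_frames
    trace = SampledTrace(np.zeros(max(n, 2)), frame_dt=frame_dt)
    segs = []
    disp_for = {"pause": 10.0, "plus": 200.0, "minus": -200.0}
    for i, state in enumerate(states):
        d = disp_for[state]
        dur = seg_frames * frame_dt
        segs.append(
            Segment(i * seg_frames, (i + 1) * seg_frames - 1, d / dur, dur, d, state)
        )
    segs[-1].end_frame = max(n, 2) - 1
    return SegmentSet(segs, trace)


class TestSwitchesAndFractions:
    @pytest.mark.parametrize(
        "states, expected",
        [
            (["plus", "minus"], 1),
            (["plus", "pause", "plus"], 0),
            (["plus", "pause", "minus"], 0),  # pause breaks the sequence
            (["minus", "plus", "minus"], 2),
            (["pause", "pause"], 0),
        ],
    )
    def test_switch_counting_adjacent_only(self, states, expected):
        assert count_directional_switches(segset_from_states(states))[0] == expected

    def test_skip_pauses_variant_sees_through_pauses(self):
        segs = segset_from_states(["plus", "pause", "minus"])
        assert count_directional_switches(segs, skip_pauses=True)[0] == 1

    def test_switch_frequency_per_second(self):
        # one switch in a 100 s trace -> 0.01 per second
        segs = segset_from_states(["plus", "minus"], seg_frames=175, frame_dt=0.286)
        count, freq = count_directional_switches(segs)
        assert count == 1
        assert freq == pytest.approx(0.01, abs=5e-4)

    def test_time_fractions_all_pause(self):
        assert time_fractions(segset_from_states(["pause", "pause"])) == (1, 0, 0)

    def test_time_fractions_equal_split_and_sum(self):
        frac = time_fractions(segset_from_states(["plus", "minus"]))
        assert frac == pytest.approx((0.0, 0.5, 0.5))
        assert sum(frac) == pytest.approx(1.0, abs=1e-9)


class TestWeightedVelocityDistribution:
    def test_duration_rounding_rule(self):
        segs = segset_from_states(["plus"], seg_frames=12)  # 3.432 s -> 3 copies
        out = weighted_velocity_distribution([segs])
        assert out.size == 3
        assert np.allclose(out, segs.segments[0].velocity)

    def test_sub_half_second_segment_contributes_nothing(self):
        segs = segset_from_states(["plus"], seg_frames=2, frame_dt=0.2)
        # min_frames not enforced on hand-built sets; duration 0.4 s rounds to 0
        assert weighted_velocity_distribution([segs]).size == 0

    def test_pauses_excluded_by_default_included_on_request(self):
        segs = segset_from_states(["plus", "pause", "minus"], seg_frames=7)
        total_rounded = sum(int(round(s.duration)) for s in segs)
        moving_rounded = sum(
            int(round(s.duration)) for s in segs if s.state != "pause"
        )
        assert weighted_velocity_distribution([segs]).size == moving_rounded
        assert (
            weighted_velocity_distribution([segs], include_pauses=True).size
            == total_rounded
        )


class TestFitExponential:
    def test_identical_durations_have_tight_ci(self, rng):
        fit = fit_exponential([2.5] * 50, n_boot=200, rng=rng)
        assert fit.mean_duration == 2.5
        assert fit.ci95_low == fit.ci95_high == 2.5

    def test_recovers_known_mean_with_bracketing_ci(self, rng):
        data = rng.exponential(5.0, size=1000)
        fit = fit_exponential(data, n_boot=500, rng=rng)
        # 0.5 is ~3 standard errors of the mean at n = 1000
        assert fit.mean_duration == pytest.approx(5.0, abs=0.5)
        # the bootstrap band always brackets the sample mean ...
        assert fit.ci95_low <= data.mean() <= fit.ci95_high
        # ... and its width is on the analytic standard-error scale
        se = 5.0 / np.sqrt(data.size)
        assert 2.5 * se < fit.ci95_high - fit.ci95_low < 5.5 * se

    def test_scale_equivariance(self):
        data = np.random.default_rng(3).exponential(2.0, size=200)
        f1 = fit_exponential(data, n_boot=300, rng=np.random.default_rng(9))
        f3 = fit_exponential(3 * data, n_boot=300, rng=np.random.default_rng(9))
        assert f3.mean_duration == pytest.approx(3 * f1.mean_duration)
        assert f3.ci95_low == pytest.approx(3 * f1.ci95_low)
        assert f3.ci95_high == pytest.approx(3 * f1.ci95_high)

    def test_too_few_observations_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_exponential([1.0], rng=rng)
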