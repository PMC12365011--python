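"""Segmentation, trimming, and fork/origin/termination pairing."""

import numpy as np
import pytest
from scipy import stats

from forktrace.segmentation import (SegmentationParams, call_forks,
                                    candidate_segments, positive_calls,
                                    trim_segment)
from forktrace.simulate import SimulationConfig, simulate_experiment, truth_compare

from conftest import make_track

PARAMS = SegmentationParams()


class TestPositiveCalls:
    def test_strict_threshold(self):
        track = make_track(0, 30_000, step=10_000)
        track.p_brdu = np.array([0.9, 0.5, 0.1])
        np.testing.assert_array_equal(
            positive_calls(track, "BrdU", 0.5), [True, False, False])

    def test_all_zero(self):
        track = make_track(0, 30_000)
        assert not positive_calls(track, "EdU", 0.5).any()

def test_simulator_true_positive_rate():
    """Positives in a labelled region occur at the Beta-emission TPR."""
    cfg = SimulationConfig(n_reads=16, origin_rate_per_mb=3.0,
                           latest_fire_minutes=0.0, chase_decay_minutes=0.0)
    tracks, truth = simulate_experiment(cfg, seed=5)
    tpr = stats.beta.sf(0.5, *cfg.emission_pos)  # P(Beta(8,2) > 0.5)
    checked = 0
    for rid, s, e in truth.reads:
        track = next(t for t in tracks if t.read_id == rid)
        for tf in truth.forks_on_read(s, e):
            lo, hi = tf.brdu_interval
            sel = (track.positions >= lo) & (track.positions < hi)
            n = int(sel.sum())
            if n < 200:
                continue
            frac = positive_calls(track, "BrdU", 0.5)[sel].mean()
            sigma = np.sqrt(tpr * (1 - tpr) / n)
            assert abs(frac - tpr) < 3 * sigma + 1e-9
            checked += 1
    assert checked >= 3


class TestCandidateSegments:
    def test_single_labelled_region_brute_force(self):
        """One EdU region at [5, 15) kb: the called segment agrees with an
        exhaustive window scan and lies within one window of the truth."""
        track = make_track(0, 30_000, step=10, edu_regions=[(5000, 15_000)])
        segs = candidate_segments(track, "EdU", PARAMS)
        assert len(segs) == 1
        seg = segs[0]
        assert abs(seg.start - 5000) <= PARAMS.window_size
        assert abs(seg.end - 15_000) <= PARAMS.window_size

        # independent oracle: qualify every grid window directly
        calls = track.p_edu > 0.5
        qualifying = []
        for w_start in range(0, 30_000, PARAMS.window_size):
            sel = (track.positions >= w_start) & (track.positions < w_start + PARAMS.window_size)
            if sel.sum() >= PARAMS.min_window_thymidines and calls[sel].mean() >= 0.3:
                qualifying.append(w_start)
        assert seg.start == qualifying[0]
        assert seg.end == qualifying[-1] + PARAMS.window_size

    def test_uniform_false_positives_yield_nothing(self):
        """5% scattered positives never reach the 0.3 window floor."""
        rng = np.random.default_rng(0)
        track = make_track(0, 50_000, step=10)
        track.p_brdu = np.where(rng.random(len(track)) < 0.05, 0.9, 0.1)
        assert candidate_segments(track, "BrdU", PARAMS) == []
        # oracle: no window qualifies
        calls = track.p_brdu > 0.5
        for w_start in range(0, 50_000, PARAMS.window_size):
            sel = (track.positions >= w_start) & (track.positions < w_start + PARAMS.window_size)
            assert calls[sel].mean() < 0.3

    def test_two_separated_regions_give_two_segments(self):
        track = make_track(0, 40_000, step=10,
                           brdu_regions=[(5000, 12_000), (20_000, 30_000)])
        segs = candidate_segments(track, "BrdU", PARAMS)
        assert len(segs) == 2
        assert segs[0].end <= segs[1].start


class TestTrimSegment:
    def test_uniform_segment_unchanged(self):
        track = make_track(0, 30_000, step=10, brdu_regions=[(5000, 15_000)])
        (seg,) = candidate_segments(track, "BrdU", PARAMS)
        trimmed, too_short = trim_segment(track, seg, PARAMS)
        assert not too_short
        assert (trimmed.start, trimmed.end) == (seg.start, seg.end)

    def test_half_incorporation_head_trimmed(self):
        """First 2 kb at half the plateau call rate: the start advances ~2 kb."""
        positions = np.arange(0, 12_000, 10)
        p = np.zeros(len(positions))
        in_head = positions < 2000
        p[in_head] = np.where((positions[in_head] // 10) % 5 < 2, 0.9, 0.1)  # 40%
        p[~in_head] = np.where((positions[~in_head] // 10) % 5 < 4, 0.9, 0.1)  # 80%
        track = make_track(0, 12_000, step=10)
        track.p_brdu = p
        from forktrace.trackio import Segment
        seg = Segment("r1", "chr1", 0, 12_000, "BrdU")
        trimmed, _ = trim_segment(track, seg, PARAMS)
        assert 1900 <= trimmed.start <= 2100
        assert trimmed.end == seg.end

    def test_negative_edges_removed_exactly(self):
        track = make_track(0, 10_000, step=10, brdu_regions=[(1000, 9000)])
        from forktrace.trackio import Segment
        seg = Segment("r1", "chr1", 0, 10_000, "BrdU")
        trimmed, _ = trim_segment(track, seg, PARAMS)
        assert abs(trimmed.start - 1000) <= 10
        assert abs(trimmed.end - 9000) <= 10

    def test_too_short_returned_flagged(self):
        track = make_track(0, 30_000, step=10, brdu_regions=[(5000, 7000)])
        from forktrace.trackio import Segment
        seg = Segment("r1", "chr1", 5000, 7000, "BrdU")
        trimmed, too_short = trim_segment(track, seg, PARAMS)
        assert too_short and (trimmed.start, trimmed.end) == (5000, 7000)

    def test_idempotent_on_simulator_segments(self, clean_sim):
        tracks, _ = clean_sim
        n_checked = 0
        for track in tracks:
            for analogue in ("EdU", "BrdU"):
                for seg in candidate_segments(track, analogue, PARAMS):
                    once, flag1 = trim_segment(track, seg, PARAMS)
                    twice, flag2 = trim_segment(track, once, PARAMS)
                    if flag1 or flag2:
                        continue
                    assert (once.start, once.end) == (twice.start, twice.end)
                    n_checked += 1
        assert n_checked >= 10


class TestCallForks:
    def test_simple_rightward_fork(self):
        track = make_track(0, 45_000, step=10, edu_regions=[(10_000, 20_000)],
                           brdu_regions=[(20_000, 35_000)])
        forks, origins, terminations = call_forks(track, PARAMS)
        assert len(forks) == 1 and not origins and not terminations
        fork = forks[0]
        assert fork.direction == "rightward"
        assert abs(fork.track_start - 10_000) <= PARAMS.window_size
        assert abs(fork.track_end - 35_000) <= PARAMS.window_size

    def test_diverging_pattern_gives_origin(self):
        """BrdU, EdU, EdU, BrdU is two diverging forks around an origin."""
        track = make_track(0, 60_000, step=10,
                           brdu_regions=[(5000, 20_000), (37_000, 52_000)],
                           edu_regions=[(21_000, 28_000), (29_500, 36_500)])
        forks, origins, terminations = call_forks(track, PARAMS)
        assert len(forks) == 2
        assert {f.direction for f in forks} == {"leftward", "rightward"}
        assert len(origins) == 1
        chrom, o_start, o_end, read_id = origins[0]
        assert 27_000 <= o_start <= o_end <= 30_500
        assert all("origin_member" in f.flags for f in forks)
        assert all("on_read_with_origin" in f.flags for f in forks)

    def test_merged_edu_origin_is_split(self):
        """An origin that fired during the EdU pulse leaves one merged EdU
        region flanked by BrdU on both sides; it is split at the midpoint."""
        track = make_track(0, 60_000, step=10,
                           brdu_regions=[(5000, 20_000), (34_000, 49_000)],
                           edu_regions=[(20_000, 34_000)])
        forks, origins, _ = call_forks(track, PARAMS)
        assert len(forks) == 2 and len(origins) == 1
        left, right = sorted(forks, key=lambda f: f.track_start)
        assert left.direction == "leftward" and right.direction == "rightward"
        assert abs(left.edu_segment.end - 27_000) <= PARAMS.window_size

    def test_merged_brdu_termination_is_split(self):
        """Converging forks share a continuous BrdU region (EdU-BrdU-EdU)."""
        track = make_track(0, 70_000, step=10,
                           edu_regions=[(5000, 12_500), (47_500, 55_000)],
                           brdu_regions=[(12_500, 47_500)])
        forks, origins, terminations = call_forks(track, PARAMS)
        assert len(forks) == 2 and len(terminations) == 1 and not origins
        assert {f.direction for f in forks} == {"leftward", "rightward"}
        chrom, t_start, t_end, _ = terminations[0]
        assert abs((t_start + t_end) / 2 - 30_000) <= PARAMS.window_size
        assert all("termination_member" in f.flags for f in forks)

    def test_unpaired_segment_gives_no_fork(self):
        track = make_track(0, 45_000, step=10, edu_regions=[(10_000, 20_000)])
        forks, origins, terminations = call_forks(track, PARAMS)
        assert forks == [] and origins == [] and terminations == []

    def test_forks_never_overlap_on_read(self, clean_sim):
        tracks, _ = clean_sim
        for track in tracks:
            forks, _, _ = call_forks(track, PARAMS)
            forks.sort(key=lambda f: f.track_start)
            for a, b in zip(forks, forks[1:]):
                assert a.track_end <= b.track_start


def test_noise_free_parameter_recovery():
    """Called spans match ground truth within one window on clean data."""
    cfg = SimulationConfig(noise_free=True, stall_probability=0.0,
                           fork_speed_sd=0.0, fork_speed_mean=1.5,
                           n_reads=80, origin_rate_per_mb=3.0,
                           latest_fire_minutes=0.0, chase_decay_minutes=0.0)
    tracks, truth = simulate_experiment(cfg, seed=2024)
    calls = []
    for t in tracks:
        forks, _, _ = call_forks(t, PARAMS)
        calls.extend(forks)
    res = truth_compare(calls, truth, tolerance=PARAMS.window_size)
    assert res["n_truth"] >= 10
    assert res["precision"] == 1.0
    assert res["recall"] == 1.0
    assert res["mean_boundary_error"] <= PARAMS.window_size
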