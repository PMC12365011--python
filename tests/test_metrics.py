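"""Fork speed, exclusion rules, stall windows, and the nonlinear scaling."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from forktrace.metrics import (STALL_V3, STALL_V4, SpeedExcluded, SpeedParams,
                               StallParams, fork_speed, stall_scale,
                               stall_score, stall_windows)
from forktrace.segmentation import call_forks
from forktrace.simulate import SimulationConfig, simulate_experiment

from conftest import make_fork, make_track


def reference_stall_scale(R: float, alpha: float, beta: float) -> float:
    """Independent evaluation of the scaling formula with math-module ops."""
    val = alpha * math.log(1 + math.exp(beta * (R - 1))) - alpha * math.log(1 + math.exp(-beta))
    return max(val, 0.0)


class TestForkSpeed:
    def test_arithmetic(self):
        fork = make_fork(edu=(10_000, 17_000), brdu=(17_000, 31_000))
        speed = fork_speed(fork, 0, 50_000, SpeedParams())
        assert speed == pytest.approx(21.0 / 15.0)  # 1.4 kb/min

    def test_origin_on_read_excluded(self):
        fork = make_fork(flags={"on_read_with_origin"})
        out = fork_speed(fork, 0, 50_000)
        assert isinstance(out, SpeedExcluded) and out.reason == "origin_on_read"

    def test_termination_on_read_excluded(self):
        fork = make_fork(flags={"on_read_with_termination"})
        out = fork_speed(fork, 0, 50_000)
        assert out.reason == "termination_on_read"

    def test_near_read_end_excluded(self):
        # track ends 1 kb from the read end: inside the 3 kb margin
        fork = make_fork(edu=(10_000, 20_000), brdu=(20_000, 49_000))
        out = fork_speed(fork, 0, 50_000)
        assert isinstance(out, SpeedExcluded) and out.reason == "near_read_end"

    def test_speed_recovery_on_simulation(self):
        """Constant-speed forks are recovered well within the window bound."""
        cfg = SimulationConfig(noise_free=True, stall_probability=0.0,
                               fork_speed_sd=0.0, fork_speed_mean=1.5,
                               n_reads=60, origin_rate_per_mb=3.0,
                               latest_fire_minutes=0.0, chase_decay_minutes=0.0)
        tracks, truth = simulate_experiment(cfg, seed=42)
        bound = 2 * 1000 / 1000 / 15.0  # 2 windows over the pulse, kb/min
        n = 0
        for t in tracks:
            forks, _, _ = call_forks(t)
            for f in forks:
                sp = fork_speed(f, t.ref_start, t.ref_end)
                if isinstance(sp, SpeedExcluded):
                    continue
                assert abs(sp - 1.5) <= bound
                n += 1
        assert n >= 10


class TestStallWindows:
    def _track_and_fork(self, p_inside, p_outside):
        """20 thymidines per 2-kb window (step 100); BrdU fork ending at 30 kb."""
        track = make_track(0, 50_000, step=100,
                           edu_regions=[(10_000, 17_000)],
                           brdu_regions=[(17_000, 30_000)])
        fork = make_fork(edu=(10_000, 17_000), brdu=(17_000, 30_000))
        inside = (track.positions >= 28_000) & (track.positions < 30_000)
        outside = (track.positions >= 30_000) & (track.positions < 32_000)
        track.p_brdu[inside] = p_inside
        track.p_brdu[outside] = p_outside
        return track, fork

    def test_counting(self):
        track, fork = self._track_and_fork(0.9, 0.1)
        # 16/20 positive inside, 4/20 outside
        inside = (track.positions >= 28_000) & (track.positions < 30_000)
        outside = (track.positions >= 30_000) & (track.positions < 32_000)
        track.p_brdu[inside] = np.where(np.arange(inside.sum()) < 16, 0.9, 0.1)
        track.p_brdu[outside] = np.where(np.arange(outside.sum()) < 4, 0.9, 0.1)
        res = stall_windows(track, fork, STALL_V3)
        assert res.ok
        assert res.B == pytest.approx(0.8)
        assert res.A == pytest.approx(0.2)

    def test_off_read_decline(self):
        track = make_track(0, 31_000, step=100, edu_regions=[(10_000, 17_000)],
                           brdu_regions=[(17_000, 30_000)])
        fork = make_fork(edu=(10_000, 17_000), brdu=(17_000, 30_000))
        res = stall_windows(track, fork, STALL_V3)
        assert res.declined == "off_read"

    def test_indel_decline(self):
        track, fork = self._track_and_fork(0.9, 0.1)
        track.gaps = [(29_000, 150)]
        assert stall_windows(track, fork, STALL_V3).declined == "indel_in_window"
        track.gaps = [(29_000, 80)]  # under the 100 bp limit: fine
        assert stall_windows(track, fork, STALL_V3).ok

    def test_termination_member_decline(self):
        track, fork = self._track_and_fork(0.9, 0.1)
        fork.flags.add("termination_member")
        assert stall_windows(track, fork, STALL_V3).declined == "termination_member"

    def test_too_few_thymidines_decline(self):
        track = make_track(0, 50_000, step=500,  # 4 thymidines per 2-kb window
                           edu_regions=[(10_000, 17_000)],
                           brdu_regions=[(17_000, 30_000)])
        fork = make_fork(edu=(10_000, 17_000), brdu=(17_000, 30_000))
        assert stall_windows(track, fork, STALL_V3).declined == "too_few_thymidines"

    def test_leftward_windows_mirrored(self):
        track = make_track(0, 50_000, step=100,
                           brdu_regions=[(20_000, 33_000)],
                           edu_regions=[(33_000, 40_000)])
        fork = make_fork(direction="leftward", brdu=(20_000, 33_000),
                         edu=(33_000, 40_000))
        res = stall_windows(track, fork, STALL_V3)
        assert res.ok
        assert res.B == pytest.approx(1.0)  # inside window [20k, 22k): labelled
        assert res.A == pytest.approx(0.0)  # outside [18k, 20k): unlabelled


class TestStallScale:
    @pytest.mark.parametrize("params", [STALL_V3, STALL_V4], ids=["v3", "v4"])
    def test_zero_at_zero(self, params):
        assert stall_scale(0.0, params) == 0.0

    def test_frozen_values_v3(self):
        # independent evaluations of the printed formula
        assert stall_scale(1.0, STALL_V3) == pytest.approx(0.9990677, abs=1e-6)
        assert stall_scale(0.5, STALL_V3) == pytest.approx(0.2368802, abs=1e-6)

    @pytest.mark.parametrize("params", [STALL_V3, STALL_V4], ids=["v3", "v4"])
    def test_near_one_at_one(self, params):
        assert 0.99 < stall_scale(1.0, params) <= 1.0

    @pytest.mark.parametrize("params", [STALL_V3, STALL_V4], ids=["v3", "v4"])
    def test_matches_reference_on_grid(self, params):
        grid = np.linspace(-0.5, 1.0, 301)
        ours = stall_scale(grid, params)
        ref = [reference_stall_scale(r, params.alpha, params.beta) for r in grid]
        np.testing.assert_allclose(ours, ref, atol=1e-12)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.floats(-1.0, 1.0), st.floats(-1.0, 1.0))
    def test_monotone(self, r1, r2):
        lo, hi = sorted((r1, r2))
        for params in (STALL_V3, STALL_V4):
            assert stall_scale(lo, params) <= stall_scale(hi, params) + 1e-12

    def test_negative_raw_score_clamped(self):
        assert stall_scale(-0.4, STALL_V3) >= 0.0


class TestStallScore:
    def test_chained_oracle(self):
        """B=0.8, A=0.2 gives R=0.75 and the scaled score from the formula."""
        track = make_track(0, 50_000, step=100,
                           edu_regions=[(10_000, 17_000)],
                           brdu_regions=[(17_000, 30_000)])
        fork = make_fork(edu=(10_000, 17_000), brdu=(17_000, 30_000))
        inside = (track.positions >= 28_000) & (track.positions < 30_000)
        outside = (track.positions >= 30_000) & (track.positions < 32_000)
        track.p_brdu[inside] = np.where(np.arange(inside.sum()) < 16, 0.9, 0.1)
        track.p_brdu[outside] = np.where(np.arange(outside.sum()) < 4, 0.9, 0.1)
        res = stall_score(track, fork, STALL_V3)
        assert res.R == pytest.approx(0.75)
        assert res.score == pytest.approx(reference_stall_scale(0.75, 1.55, 3.0), abs=1e-9)

    def test_equal_frequencies_score_zero(self):
        track = make_track(0, 50_000, step=100,
                           edu_regions=[(10_000, 17_000)],
                           brdu_regions=[(17_000, 32_000)])
        fork = make_fork(edu=(10_000, 17_000), brdu=(17_000, 30_000))
        res = stall_score(track, fork, STALL_V3)  # label continues outside: B == A
        assert res.R == pytest.approx(0.0)
        assert res.score == 0.0

    def test_zero_b_declined(self):
        track = make_track(0, 50_000, step=100)  # no BrdU at all
        fork = make_fork(edu=(10_000, 17_000), brdu=(17_000, 30_000))
        assert stall_score(track, fork, STALL_V3).declined == "zero_B"


def test_stall_contrast_on_simulation():
    """Abruptly stopped forks score high; run-through forks score low."""
    cfg = SimulationConfig(stall_probability=0.5, n_reads=250,
                           origin_rate_per_mb=3.0, latest_fire_minutes=0.0)
    tracks, truth = simulate_experiment(cfg, seed=7)
    by_read = {rid: (s, e) for rid, s, e in truth.reads}
    stalled, run_through = [], []
    for t in tracks:
        forks, _, _ = call_forks(t)
        for f in forks:
            res = stall_score(t, f, STALL_V3)
            if not res.ok:
                continue
            mid = (f.track_start + f.track_end) // 2
            s, e = by_read[t.read_id]
            cand = [tf for tf in truth.forks_on_read(s, e, min_segment=1, edge_margin=0)
                    if tf.direction == f.direction
                    and tf.track_interval[0] - 2000 <= mid <= tf.track_interval[1] + 2000]
            if len(cand) != 1 or cand[0].terminated:
                continue
            (stalled if cand[0].stalled else run_through).append(res.score)
    assert len(stalled) >= 10 and len(run_through) >= 10
    assert np.median(stalled) > 0.8
    assert np.median(run_through) < 0.2
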