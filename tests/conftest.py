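"""Shared fixtures: deterministic hand-built tracks and simulated datasets."""

from __future__ import annotations

import numpy as np
import pytest

from forktrace.trackio import AnalogueTrack, ForkCall, Segment


def make_track(ref_start: int, ref_end: int, step: int = 10,
               edu_regions=(), brdu_regions=(), p_pos: float = 1.0,
               p_neg: float = 0.0, read_id: str = "r1", chrom: str = "chr1",
               gaps=None) -> AnalogueTrack:
    """Build a deterministic track: thymidines every ``step`` bp, with the
    named analogue probability ``p_pos`` inside its regions, ``p_neg``
    elsewhere."""
    positions = np.arange(ref_start, ref_end, step)

    def paint(regions):
        p = np.full(len(positions), p_neg)
        for lo, hi in regions:
            p[(positions >= lo) & (positions < hi)] = p_pos
        return p

    return AnalogueTrack(read_id=read_id, chrom=chrom, ref_start=ref_start,
                         ref_end=ref_end, strand="+", positions=positions,
                         p_edu=paint(edu_regions), p_brdu=paint(brdu_regions),
                         gaps=gaps if gaps is not None else [])


def make_fork(read_id="r1", chrom="chr1", direction="rightward",
              edu=(10_000, 20_000), brdu=(20_000, 35_000), flags=()) -> ForkCall:
    e = Segment(read_id, chrom, *edu, "EdU")
    b = Segment(read_id, chrom, *brdu, "BrdU")
    return ForkCall(read_id, chrom, direction, e, b, set(flags))


@pytest.fixture
def clean_sim():
    """Noise-free, stall-free, constant-speed simulation: the parameter-
    recovery reference dataset."""
    from forktrace.simulate import SimulationConfig, simulate_experiment

    cfg = SimulationConfig(noise_free=True, stall_probability=0.0,
                           fork_speed_sd=0.0, fork_speed_mean=1.5,
                           n_reads=60, origin_rate_per_mb=3.0,
                           latest_fire_minutes=0.0, chase_decay_minutes=0.0)
    tracks, truth = simulate_experiment(cfg, seed=42)
    return tracks, truth
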