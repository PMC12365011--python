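"""Segment reads into analogue-positive regions and pair them into forks.

A read labelled during a sequential EdU-then-BrdU pulse carries, for each
replication fork that traversed it, an EdU-positive track followed (in the
fork's direction of travel) by a BrdU-positive track.  This module finds
candidate analogue-positive segments with a sliding genomic window, trims
each segment back to its plateau incorporation level, and pairs EdU/BrdU
segments into forks; diverging fork pairs yield origin calls and
converging pairs yield termination calls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from forktrace.trackio import AnalogueTrack, ForkCall, Segment

logger = logging.getLogger(__name__)

OTHER = {"EdU": "BrdU", "BrdU": "EdU"}


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable parameters of segmentation and fork pairing.

    call_threshold
        Probability above which an analogue call is positive (strict).
    window_size
        Genomic sliding-window length in bp.
    window_fraction_floor
        Minimum positive-call fraction for a window to join a candidate
        segment.
    min_track_length
        Candidate runs shorter than this (bp) are discarded.
    max_pair_gap
        Maximum gap (bp) between an EdU and a BrdU segment when pairing
        into a fork; analogue detection tends to leave a small gap between
        the two tracks, so pairing tolerates a bounded one.
    min_window_thymidines
        Windows with fewer thymidines than this never qualify (guards
        AT-poor windows, since window arithmetic is genomic rather than
        thymidine-count).
    """

    call_threshold: float = 0.5
    window_size: int = 1000
    window_fraction_floor: float = 0.3
    min_track_length: int = 1000
    max_pair_gap: int = 5000
    min_window_thymidines: int = 5

    def __post_init__(self) -> None:
        if not 0.0 < self.call_threshold < 1.0:
            raise ValueError("call_threshold must be in (0, 1)")
        if self.window_size <= 0:
            raise ValueError("window_size must be positive")
        if not 0.0 < self.window_fraction_floor < 1.0:
            raise ValueError("window_fraction_floor must be in (0, 1)")


def positive_calls(track: AnalogueTrack, analogue: str, threshold: float = 0.5) -> np.ndarray:
    """Boolean per thymidine position: probability strictly above threshold."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    return track.probs(analogue) > threshold


def _window_fraction(positions: np.ndarray, calls: np.ndarray, start: int, end: int,
                     min_n: int) -> tuple[float, int]:
    """Positive-call fraction over thymidines in genomic window [start, end)."""
    lo = np.searchsorted(positions, start, side="left")
    hi = np.searchsorted(positions, end, side="left")
    n = hi - lo
    if n == 0:
        return 0.0, 0
    return float(calls[lo:hi].sum()) / n, int(n)


def candidate_segments(track: AnalogueTrack, analogue: str,
                       params: SegmentationParams = SegmentationParams()) -> list[Segment]:
    """Maximal runs of qualifying windows for one analogue.

    The read is tiled with non-overlapping ``window_size`` windows anchored
    at ``ref_start``.  A window qualifies when it holds at least
    ``min_window_thymidines`` thymidines, its positive-call fraction for
    `analogue` is at least ``window_fraction_floor``, and that fraction
    strictly exceeds the other analogue's.  Maximal runs of qualifying
    windows become segments; runs shorter than ``min_track_length`` are
    discarded.
    """
    pos = track.positions
    if len(pos) == 0:
        return []
    calls_a = positive_calls(track, analogue, params.call_threshold)
    calls_b = positive_calls(track, OTHER[analogue], params.call_threshold)

    w = params.window_size
    starts = np.arange(track.ref_start, track.ref_end, w)
    qualifies = np.zeros(len(starts), dtype=bool)
    for i, s in enumerate(starts):
        frac_a, n = _window_fraction(pos, calls_a, s, s + w, params.min_window_thymidines)
        if n < params.min_window_thymidines:
            continue
        frac_b, _ = _window_fraction(pos, calls_b, s, s + w, params.min_window_thymidines)
        qualifies[i] = frac_a >= params.window_fraction_floor and frac_a > frac_b

    segments: list[Segment] = []
    i = 0
    while i < len(starts):
        if not qualifies[i]:
            i += 1
            continue
        j = i
        while j + 1 < len(starts) and qualifies[j + 1]:
            j += 1
        seg_start = int(starts[i])
        seg_end = int(min(starts[j] + w, track.ref_end))
        if seg_end - seg_start >= params.min_track_length:
            segments.append(Segment(track.read_id, track.chrom, seg_start, seg_end, analogue))
        i = j + 1
    return segments


def trim_segment(track: AnalogueTrack, segment: Segment,
                 params: SegmentationParams = SegmentationParams()) -> tuple[Segment, bool]:
    """Trim a segment back to its plateau incorporation level.

    The average incorporation ``f*`` (positive-call fraction) is computed
    over the middle third of the segment.  A window of ``window_size`` bp
    is advanced inward from each end, anchored at successive thymidine
    positions, until it meets a window whose positive fraction reaches
    ``f*``; the segment is cut to the outer edges of the first qualifying
    windows.

    Returns ``(segment, too_short)``.  A segment too short to hold a
    middle third plus a window at each end is returned unchanged with
    ``too_short=True``.
    """
    pos = track.positions
    calls = positive_calls(track, segment.analogue, params.call_threshold)
    w = params.window_size

    if segment.length < 3 * w:
        return segment, True

    third = segment.length // 3
    mid_lo, mid_hi = segment.start + third, segment.end - third
    f_star, n_mid = _window_fraction(pos, calls, mid_lo, mid_hi, 1)
    if n_mid == 0:
        return segment, True

    lo = np.searchsorted(pos, segment.start, side="left")
    hi = np.searchsorted(pos, segment.end, side="left")
    anchors = pos[lo:hi]
    if len(anchors) == 0:
        return segment, True

    new_start = segment.start
    for i, a in enumerate(anchors):
        if a + w > segment.end:
            break
        frac, n = _window_fraction(pos, calls, a, a + w, params.min_window_thymidines)
        if n >= params.min_window_thymidines and frac >= f_star:
            # the first window already meets the plateau level: no advance,
            # the boundary stays where candidate detection put it
            new_start = segment.start if i == 0 else int(a)
            break
    else:
        return segment, True

    new_end = segment.end
    for i, a in enumerate(anchors[::-1]):
        # right-anchored window (a is the last thymidine inside it)
        if a + 1 - w < segment.start:
            break
        frac, n = _window_fraction(pos, calls, a + 1 - w, a + 1, params.min_window_thymidines)
        if n >= params.min_window_thymidines and frac >= f_star:
            new_end = segment.end if i == 0 else int(a) + 1
            break
    else:
        return segment, True

    if new_end - new_start <= 0 or new_start < segment.start or new_end > segment.end:
        return segment, True
    return replace(segment, start=new_start, end=new_end), False


def _segment_gap(left: Segment, right: Segment) -> int:
    return right.start - left.end


def call_forks(track: AnalogueTrack,
               params: SegmentationParams = SegmentationParams()
               ) -> tuple[list[ForkCall], list[tuple[str, int, int, str]], list[tuple[str, int, int, str]]]:
    """Call forks, origins, and terminations on one read.

    Candidate segments of both analogues are detected and trimmed, then
    adjacent (EdU, BrdU) segments with a gap of at most ``max_pair_gap``
    are paired: EdU-then-BrdU in reference order is a rightward fork,
    BrdU-then-EdU a leftward fork.  Each segment joins at most one fork;
    when a segment could pair to both sides the smaller gap wins.  Two
    diverging forks whose EdU segments are adjacent form an origin (the
    gap between the inner EdU ends); two converging forks whose BrdU
    segments are adjacent form a termination.

    Returns ``(forks, origins, terminations)`` with origins/terminations
    as ``(chrom, start, end, read_id)`` intervals.
    """
    segments: list[Segment] = []
    for analogue in ("EdU", "BrdU"):
        for seg in candidate_segments(track, analogue, params):
            trimmed, _ = trim_segment(track, seg, params)
            segments.append(trimmed)
    segments.sort(key=lambda s: s.start)

    # A segment tightly flanked by the opposite analogue on both sides is a
    # merged junction: two converging forks share a continuous BrdU region
    # (E-B-E, a termination) and two diverging forks that fired from one
    # origin during the EdU pulse share a continuous EdU region (B-E-B, an
    # origin).  Split such segments at their midpoint so each half can pair
    # with its own partner; with symmetric fork speeds the midpoint is the
    # meeting/origin point.
    split_gap = params.window_size
    flanked = [
        k for k in range(1, len(segments) - 1)
        if (segments[k - 1].analogue != segments[k].analogue
            and segments[k + 1].analogue != segments[k].analogue
            and _segment_gap(segments[k - 1], segments[k]) <= split_gap
            and _segment_gap(segments[k], segments[k + 1]) <= split_gap
            and segments[k].length >= 2)
    ]
    for k in reversed(flanked):
        seg = segments[k]
        mid = (seg.start + seg.end) // 2
        segments[k:k + 1] = [replace(seg, end=mid), replace(seg, start=mid)]

    # pair adjacent opposite-analogue segments: maximise the number of
    # forks, then minimise the total pairing gap (dynamic programme on the
    # ordered segment sequence, so an E-B-E-B series of same-direction
    # forks pairs each EdU track with its own BrdU track)
    n = len(segments)

    def pairable(i: int) -> int | None:
        a, b = segments[i], segments[i + 1]
        if a.analogue == b.analogue:
            return None
        gap = _segment_gap(a, b)
        return gap if 0 <= gap <= params.max_pair_gap else None

    best: list[tuple[int, int]] = [(0, 0)] * (n + 1)  # (pairs, -total gap)
    take: list[bool] = [False] * (n + 1)
    for i in range(1, n + 1):
        best[i], take[i] = best[i - 1], False
        if i >= 2:
            gap = pairable(i - 2)
            if gap is not None:
                cand = (best[i - 2][0] + 1, best[i - 2][1] - gap)
                if cand > best[i]:
                    best[i], take[i] = cand, True

    forks: list[ForkCall] = []
    i = n
    while i > 0:
        if take[i]:
            a, b = segments[i - 2], segments[i - 1]
            if a.analogue == "EdU":
                forks.append(ForkCall(track.read_id, track.chrom, "rightward", a, b))
            else:
                forks.append(ForkCall(track.read_id, track.chrom, "leftward", b, a))
            i -= 2
        else:
            i -= 1
    forks.sort(key=lambda f: f.track_start)

    # origins: leftward fork then rightward fork with adjacent EdU segments
    origins: list[tuple[str, int, int, str]] = []
    terminations: list[tuple[str, int, int, str]] = []
    for k in range(len(forks) - 1):
        f1, f2 = forks[k], forks[k + 1]
        if f1.direction == "leftward" and f2.direction == "rightward":
            gap = f2.edu_segment.start - f1.edu_segment.end
            if 0 <= gap <= params.max_pair_gap:
                origins.append((track.chrom, f1.edu_segment.end, f2.edu_segment.start, track.read_id))
                f1.flags.add("origin_member")
                f2.flags.add("origin_member")
        elif f1.direction == "rightward" and f2.direction == "leftward":
            gap = f2.brdu_segment.start - f1.brdu_segment.end
            if 0 <= gap <= params.max_pair_gap:
                terminations.append((track.chrom, f1.brdu_segment.end, f2.brdu_segment.start, track.read_id))
                f1.flags.add("termination_member")
                f2.flags.add("termination_member")

    for fork in forks:
        if origins:
            fork.flags.add("on_read_with_origin")
        if terminations:
            fork.flags.add("on_read_with_termination")
        if (fork.track_start - track.ref_start < params.window_size
                or track.ref_end - fork.track_end < params.window_size):
            fork.flags.add("near_read_end")
    return forks, origins, terminations
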