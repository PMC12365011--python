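"""Per-fork metrics: fork speed with exclusion rules, and the stall score.

Fork speed is the genomic span of the fork track (far end of the EdU
segment to far end of the BrdU segment) divided by the total analogue
pulse duration.  Speeds are unreliable for forks that fired from an
origin or terminated during the pulse, or whose track runs off the read,
so those forks are excluded rather than reported.

The stall score quantifies how abruptly BrdU incorporation ends at the
BrdU end of the fork track.  B is the fraction of thymidines called
BrdU-positive in a 2-kb window just inside the BrdU segment end; A is the
same fraction in the 2-kb window just outside.  The raw score

    R = (B - A) / B

is passed through a softplus-style nonlinear scaling

    score = alpha * log(1 + exp(beta * (R - 1))) - alpha * log(1 + exp(-beta))

which maps the raw-score range of healthy forks (roughly 0.2-0.4) close
to 0 and is conservative in the 0.6-0.9 range, so only high-confidence
stalls score near 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Union

import numpy as np

from forktrace.trackio import AnalogueTrack, ForkCall

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SpeedParams:
    """Fork-speed parameters: total pulse duration and read-end margin."""

    pulse_minutes: float = 15.0
    read_end_margin: int = 3000

    def __post_init__(self) -> None:
        if self.pulse_minutes <= 0:
            raise ValueError("pulse_minutes must be positive")


@dataclass(frozen=True)
class StallParams:
    """Stall-score parameters.

    ``alpha``/``beta`` control the nonlinear scaling; the two published
    presets are :data:`STALL_V3` (detection model v3.1.2) and
    :data:`STALL_V4` (v4.0.3, whose cleaner analogue calls needed a
    retuned scaling to keep scores comparable).
    """

    alpha: float = 1.55
    beta: float = 3.0
    window: int = 2000
    call_threshold: float = 0.5
    max_indel: int = 100
    min_thymidines: int = 10

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be positive")


STALL_V3 = StallParams(alpha=1.55, beta=3.0)
STALL_V4 = StallParams(alpha=2.63, beta=1.0)
STALL_PRESETS = {"v3": STALL_V3, "v4": STALL_V4}


@dataclass(frozen=True)
class SpeedExcluded:
    """A fork excluded from speed analysis, with the rule that fired."""

    reason: str  # origin_on_read | termination_on_read | near_read_end


@dataclass
class StallResult:
    """Window frequencies, raw score, and scaled stall score for one fork.

    If ``declined`` is set the numeric fields that could not be computed
    are ``nan``; otherwise ``score`` is in [0, 1] and ``R = (B - A)/B``.
    """

    B: float = float("nan")
    A: float = float("nan")
    R: float = float("nan")
    score: float = float("nan")
    declined: str | None = None  # off_read | termination_member | indel_in_window | zero_B | too_few_thymidines

    @property
    def ok(self) -> bool:
        return self.declined is None


def fork_speed(fork: ForkCall, read_start: int, read_end: int,
               params: SpeedParams = SpeedParams()) -> Union[float, SpeedExcluded]:
    """Fork speed in kb/min, or :class:`SpeedExcluded` with a reason.

    Excluded when the fork sits on a read with a called origin or
    termination, or when its track starts or ends within
    ``read_end_margin`` bp of the read end.
    """
    if "on_read_with_origin" in fork.flags or "origin_member" in fork.flags:
        return SpeedExcluded("origin_on_read")
    if "on_read_with_termination" in fork.flags or "termination_member" in fork.flags:
        return SpeedExcluded("termination_on_read")
    if (fork.track_start - read_start < params.read_end_margin
            or read_end - fork.track_end < params.read_end_margin):
        return SpeedExcluded("near_read_end")
    return (fork.track_end - fork.track_start) / 1000.0 / params.pulse_minutes


def _window_brdu_fraction(track: AnalogueTrack, start: int, end: int,
                          threshold: float) -> tuple[float, int]:
    lo = np.searchsorted(track.positions, start, side="left")
    hi = np.searchsorted(track.positions, end, side="left")
    n = int(hi - lo)
    if n == 0:
        return 0.0, 0
    frac = float((track.p_brdu[lo:hi] > threshold).sum()) / n
    return frac, n


def _gap_in_window(track: AnalogueTrack, start: int, end: int, max_indel: int) -> bool:
    if track.gaps is None:
        # no indel information on this track: the indel decline rule is
        # disabled rather than silently assumed clean
        logger.warning("track %s has no indel annotations; indel decline rule disabled",
                       track.read_id)
        return False
    for pos, length in track.gaps:
        if length > max_indel and start <= pos < end:
            return True
    return False


def stall_windows(track: AnalogueTrack, fork: ForkCall,
                  params: StallParams = StallParams()) -> StallResult:
    """Compute the inside (B) and outside (A) BrdU-positive fractions.

    The windows are each ``params.window`` bp of genomic length, anchored
    at the BrdU end of the fork track: for a rightward fork the inside
    window is immediately left of the track end and the outside window
    immediately right; a leftward fork mirrors this.
    """
    if "termination_member" in fork.flags or "on_read_with_termination" in fork.flags:
        return StallResult(declined="termination_member")
    w = params.window
    end = fork.brdu_end
    if fork.direction == "rightward":
        inside = (end - w, end)
        outside = (end, end + w)
    else:
        inside = (end, end + w)
        outside = (end - w, end)
    if outside[0] < track.ref_start or outside[1] > track.ref_end:
        return StallResult(declined="off_read")
    if inside[0] < track.ref_start or inside[1] > track.ref_end:
        return StallResult(declined="off_read")
    if (_gap_in_window(track, *inside, params.max_indel)
            or _gap_in_window(track, *outside, params.max_indel)):
        return StallResult(declined="indel_in_window")
    B, n_in = _window_brdu_fraction(track, *inside, params.call_threshold)
    A, n_out = _window_brdu_fraction(track, *outside, params.call_threshold)
    if n_in < params.min_thymidines or n_out < params.min_thymidines:
        return StallResult(declined="too_few_thymidines")
    return StallResult(B=B, A=A)


def stall_scale(R, params: StallParams = StallParams()):
    """Nonlinear scaling of the raw score onto [0, 1].

    ``alpha * log(1 + exp(beta*(R-1))) - alpha * log(1 + exp(-beta))``,
    clamped below at zero.  Exactly zero at R = 0 and monotone
    non-decreasing in R; both published presets map R = 1 to just
    under 1.
    """
    R = np.asarray(R, dtype=np.float64)
    val = params.alpha * (np.log1p(np.exp(params.beta * (R - 1.0)))
                          - np.log1p(np.exp(-params.beta)))
    out = np.maximum(val, 0.0)
    return float(out) if out.ndim == 0 else out


def stall_score(track: AnalogueTrack, fork: ForkCall,
                params: StallParams = StallParams()) -> StallResult:
    """Full stall-score computation: windows, raw score, scaling, declines."""
    res = stall_windows(track, fork, params)
    if not res.ok:
        return res
    if res.B == 0.0:
        return StallResult(B=res.B, A=res.A, declined="zero_B")
    R = (res.B - res.A) / res.B
    res.R = R
    res.score = stall_scale(R, params)
    return res
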