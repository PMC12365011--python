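"""Pulse-chase labelling simulator with ground truth.

Emulates the standard sequential-labelling protocol — a 5-minute EdU
pulse, a 10-minute BrdU pulse, then a thymidine chase — on a synthetic
genome.  Replication origins fire at random times; each origin launches a
leftward and a rightward fork with its own speed.  A fork lays an
EdU-labelled interval over the DNA it replicates during the EdU pulse and
a BrdU-labelled interval during the BrdU pulse; a stalled fork stops
abruptly mid-pulse, and converging forks from adjacent origins are
truncated at their meeting point (a termination).  Reads are sampled from
the genome and per-thymidine analogue probabilities are emitted from Beta
distributions (or exactly 0/1 in noise-free mode).

Emission is per-thymidine independent noise, not a sequence-context
model: sufficient to exercise thresholding, trimming, fork pairing, and
stall logic, which all operate on the probability tracks alone.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from forktrace.trackio import AnalogueTrack, ForkCall

EDU_START = 0.0  # pulse clock zero


@dataclass(frozen=True)
class SimulationConfig:
    """Simulation parameters; defaults emulate the standard protocol.

    Pulse durations are minutes; speeds are kb/min.  ``at_fraction`` is
    the AT content of the synthetic genome, so thymidines occur per base
    at ``at_fraction / 2``.  Labelled thymidines emit analogue
    probabilities from ``Beta(emission_pos)`` and unlabelled from
    ``Beta(emission_neg)``; ``noise_free=True`` replaces both with exact
    1/0 emissions.  ``prefire_minutes`` is how long before the EdU pulse
    origins may have fired (forks from long-fired origins are far from
    their origin and appear as isolated forks on reads).
    """

    genome_length: int = 5_000_000
    at_fraction: float = 0.6
    n_reads: int = 50
    read_n50: int = 90_000
    read_sigma: float = 0.5
    min_read_length: int = 20_000
    origin_rate_per_mb: float = 4.0
    fork_speed_mean: float = 1.4
    fork_speed_sd: float = 0.3
    stall_probability: float = 0.0
    pulse_edu_minutes: float = 5.0
    pulse_brdu_minutes: float = 10.0
    chase_minutes: float = 20.0
    prefire_minutes: float = 45.0
    emission_pos: tuple[float, float] = (8.0, 2.0)
    emission_neg: tuple[float, float] = (2.0, 8.0)
    noise_free: bool = False
    indel_rate_per_mb: float = 0.0
    chrom: str = "chrS"
    latest_fire_minutes: float | None = None  # None: origins may fire up to the EdU pulse end
    chase_decay_minutes: float = 3.0  # gradual BrdU run-off for unstalled forks; 0 = abrupt

    def __post_init__(self) -> None:
        if self.pulse_edu_minutes <= 0 or self.pulse_brdu_minutes <= 0:
            raise ValueError("pulse durations must be positive")
        if self.stall_probability < 0 or self.origin_rate_per_mb < 0:
            raise ValueError("rates must be non-negative")

    @property
    def pulse_end(self) -> float:
        return self.pulse_edu_minutes + self.pulse_brdu_minutes


@dataclass
class TrueFork:
    """Ground truth for one simulated fork."""

    fork_id: int
    origin_id: int
    direction: str  # rightward | leftward
    speed_kb_min: float
    t_fire: float
    stalled: bool
    stall_time: float  # minutes on the pulse clock; inf if not stalled
    terminated: bool
    stop_time: float  # min(stall, termination, end of BrdU pulse)
    edu_interval: tuple[int, int] | None  # genome bp, half-open; None if no EdU laid
    brdu_interval: tuple[int, int] | None
    tail_interval: tuple[int, int] | None = None  # chase run-off region (unstalled forks)

    @property
    def track_interval(self) -> tuple[int, int] | None:
        ivals = [iv for iv in (self.edu_interval, self.brdu_interval) if iv is not None]
        if not ivals:
            return None
        return min(iv[0] for iv in ivals), max(iv[1] for iv in ivals)


@dataclass
class GroundTruth:
    """Full ground-truth record of one simulated experiment."""

    forks: list[TrueFork]
    origins: list[tuple[int, float]]  # (position, fire time)
    terminations: list[tuple[int, float]]  # (position, meeting time)
    reads: list[tuple[str, int, int]]  # (read_id, start, end) on the genome
    config: SimulationConfig

    def forks_on_read(self, read_start: int, read_end: int,
                      min_segment: int = 1500, edge_margin: int = 1000) -> list[TrueFork]:
        """Truth forks recoverable from a read.

        A fork is recoverable when its whole track lies at least
        ``edge_margin`` bp inside the read (mirroring the caller's
        near-read-end flag) and both analogue intervals are at least
        ``min_segment`` bp, so that a correct caller has enough signal to
        find both segments.
        """
        out = []
        for f in self.forks:
            if f.edu_interval is None or f.brdu_interval is None:
                continue
            iv = f.track_interval
            if iv[0] < read_start + edge_margin or iv[1] > read_end - edge_margin:
                continue
            if (f.edu_interval[1] - f.edu_interval[0] < min_segment
                    or f.brdu_interval[1] - f.brdu_interval[0] < min_segment):
                continue
            out.append(f)
        return out

    def sibling_edu_gap(self, fork: TrueFork) -> float:
        """Gap (bp) between a fork's EdU interval and its origin sibling's."""
        sib = next(f for f in self.forks
                   if f.origin_id == fork.origin_id and f.fork_id != fork.fork_id)
        if fork.edu_interval is None or sib.edu_interval is None:
            return float("inf")
        lo = min(fork.edu_interval[1], sib.edu_interval[1])
        hi = max(fork.edu_interval[0], sib.edu_interval[0])
        return max(0.0, hi - lo)

    def fork_table(self) -> pd.DataFrame:
        rows = []
        for f in self.forks:
            rows.append({
                "fork_id": f.fork_id, "origin_id": f.origin_id,
                "direction": f.direction, "speed_kb_min": f.speed_kb_min,
                "t_fire": f.t_fire, "stalled": f.stalled,
                "stall_time": f.stall_time, "terminated": f.terminated,
                "edu_start": f.edu_interval[0] if f.edu_interval else np.nan,
                "edu_end": f.edu_interval[1] if f.edu_interval else np.nan,
                "brdu_start": f.brdu_interval[0] if f.brdu_interval else np.nan,
                "brdu_end": f.brdu_interval[1] if f.brdu_interval else np.nan,
            })
        return pd.DataFrame(rows)


def _fork_position(x0: float, sign: int, v_bp_min: float, t_fire: float,
                   stop_time: float, t: float) -> float:
    """Fork tip position at pulse-clock time t (frozen after stop_time)."""
    t_eff = min(t, stop_time)
    if t_eff <= t_fire:
        return x0
    return x0 + sign * v_bp_min * (t_eff - t_fire)


def _label_interval(x0: float, sign: int, v: float, t_fire: float, stop: float,
                    t_lo: float, t_hi: float) -> tuple[int, int] | None:
    """Genomic interval replicated during [t_lo, t_hi), or None if empty."""
    a = _fork_position(x0, sign, v, t_fire, stop, max(t_lo, t_fire))
    b = _fork_position(x0, sign, v, t_fire, stop, t_hi)
    lo, hi = (a, b) if a <= b else (b, a)
    lo_i, hi_i = int(round(lo)), int(round(hi))
    if hi_i - lo_i < 1:
        return None
    return lo_i, hi_i


def simulate_experiment(config: SimulationConfig,
                        seed: int) -> tuple[list[AnalogueTrack], GroundTruth]:
    """Run one simulated pulse-chase experiment.

    Deterministic for a given (config, seed).  Returns the per-read
    probability tracks and the full ground truth.
    """
    rng = np.random.default_rng(seed)
    cfg = config
    edu_end = cfg.pulse_edu_minutes
    brdu_end = cfg.pulse_end

    # --- origins and forks --------------------------------------------------
    n_origins = rng.poisson(cfg.origin_rate_per_mb * cfg.genome_length / 1e6)
    origin_pos = np.sort(rng.uniform(0, cfg.genome_length, size=n_origins))
    latest = edu_end if cfg.latest_fire_minutes is None else cfg.latest_fire_minutes
    fire_times = rng.uniform(-cfg.prefire_minutes, latest, size=n_origins)

    forks: list[TrueFork] = []
    fork_state = []  # (x0, sign, v_bp, t_fire, stall_time)
    for oid in range(n_origins):
        for sign, direction in ((-1, "leftward"), (1, "rightward")):
            v = max(0.1, rng.normal(cfg.fork_speed_mean, cfg.fork_speed_sd))
            stalled = rng.random() < cfg.stall_probability
            stall_time = (rng.uniform(edu_end, brdu_end) if stalled else np.inf)
            fork_state.append({
                "origin_id": oid, "sign": sign, "direction": direction,
                "x0": origin_pos[oid], "v_bp": v * 1000.0,
                "t_fire": fire_times[oid], "stall_time": stall_time,
                "stop_time": min(stall_time, brdu_end), "terminated": False,
            })

    # --- terminations: adjacent converging forks meet -----------------------
    terminations: list[tuple[int, float]] = []
    for oid in range(n_origins - 1):
        right = fork_state[2 * oid + 1]      # rightward fork of origin oid
        left = fork_state[2 * (oid + 1)]     # leftward fork of origin oid+1

        def gap(t: float) -> float:
            xr = _fork_position(right["x0"], 1, right["v_bp"], right["t_fire"],
                                right["stop_time"], t)
            xl = _fork_position(left["x0"], -1, left["v_bp"], left["t_fire"],
                                left["stop_time"], t)
            return xl - xr

        if gap(brdu_end) > 0:
            continue
        lo, hi = min(right["t_fire"], left["t_fire"]), brdu_end
        if gap(lo) <= 0:  # origins overlap pathologically; skip
            continue
        for _ in range(60):  # bisection on the (non-increasing) gap
            mid = 0.5 * (lo + hi)
            if gap(mid) > 0:
                lo = mid
            else:
                hi = mid
        t_meet = hi
        x_meet = _fork_position(right["x0"], 1, right["v_bp"], right["t_fire"],
                                right["stop_time"], t_meet)
        for fs in (right, left):
            if t_meet < fs["stop_time"]:
                fs["stop_time"] = t_meet
                fs["terminated"] = True
        if right["terminated"] or left["terminated"]:
            terminations.append((int(round(x_meet)), t_meet))

    tails = []  # (lo, hi, anchor_x, sign, length) for chase run-off decay
    for fid, fs in enumerate(fork_state):
        edu_iv = _label_interval(fs["x0"], fs["sign"], fs["v_bp"], fs["t_fire"],
                                 fs["stop_time"], EDU_START, edu_end)
        brdu_iv = _label_interval(fs["x0"], fs["sign"], fs["v_bp"], fs["t_fire"],
                                  fs["stop_time"], edu_end, brdu_end)
        tail_iv = None
        # a fork that ran through the whole pulse keeps incorporating BrdU at
        # declining levels during the chase as the analogue pool is diluted
        if (cfg.chase_decay_minutes > 0 and brdu_iv is not None
                and fs["stop_time"] >= brdu_end and fs["t_fire"] < brdu_end):
            x15 = _fork_position(fs["x0"], fs["sign"], fs["v_bp"], fs["t_fire"],
                                 brdu_end, brdu_end)
            tail_len = fs["v_bp"] * cfg.chase_decay_minutes
            if fs["sign"] > 0:
                tail_iv = (int(round(x15)), int(round(x15 + tail_len)))
            else:
                tail_iv = (int(round(x15 - tail_len)), int(round(x15)))
            if tail_iv[1] - tail_iv[0] >= 1:
                tails.append((tail_iv[0], tail_iv[1], x15, fs["sign"], tail_len))
            else:
                tail_iv = None
        forks.append(TrueFork(
            fork_id=fid, origin_id=fs["origin_id"], direction=fs["direction"],
            speed_kb_min=fs["v_bp"] / 1000.0, t_fire=fs["t_fire"],
            stalled=np.isfinite(fs["stall_time"]), stall_time=fs["stall_time"],
            terminated=fs["terminated"], stop_time=fs["stop_time"],
            edu_interval=edu_iv, brdu_interval=brdu_iv, tail_interval=tail_iv,
        ))
    tails.sort()

    # --- thymidine lattice --------------------------------------------------
    thy_mask = rng.random(cfg.genome_length) < cfg.at_fraction / 2.0
    thy_pos = np.flatnonzero(thy_mask)

    # label maps as sorted interval lists per analogue
    edu_ivals = sorted(f.edu_interval for f in forks if f.edu_interval)
    brdu_ivals = sorted(f.brdu_interval for f in forks if f.brdu_interval)

    def labelled(positions: np.ndarray, ivals: list[tuple[int, int]]) -> np.ndarray:
        mask = np.zeros(len(positions), dtype=bool)
        for lo, hi in ivals:
            a = np.searchsorted(positions, lo, side="left")
            b = np.searchsorted(positions, hi, side="left")
            mask[a:b] = True
        return mask

    # --- reads --------------------------------------------------------------
    mu = np.log(cfg.read_n50) - cfg.read_sigma ** 2
    tracks: list[AnalogueTrack] = []
    reads: list[tuple[str, int, int]] = []
    for i in range(cfg.n_reads):
        length = int(rng.lognormal(mu, cfg.read_sigma))
        length = max(cfg.min_read_length, min(length, cfg.genome_length - 1))
        start = int(rng.integers(0, cfg.genome_length - length))
        end = start + length
        read_id = f"simread_{i:05d}"
        reads.append((read_id, start, end))

        lo = np.searchsorted(thy_pos, start, side="left")
        hi = np.searchsorted(thy_pos, end, side="left")
        pos = thy_pos[lo:hi]
        n = len(pos)
        is_edu = labelled(pos, edu_ivals)
        is_brdu = labelled(pos, brdu_ivals)
        # chase run-off: thymidines in a tail are BrdU-labelled with a
        # probability that decays linearly with distance from the pulse end
        tail_m = np.zeros(n)
        for t_lo, t_hi, anchor, sign, t_len in tails:
            a = np.searchsorted(pos, t_lo, side="left")
            b = np.searchsorted(pos, t_hi, side="left")
            if b > a:
                dist = sign * (pos[a:b] - anchor)
                tail_m[a:b] = np.maximum(tail_m[a:b], np.clip(1.0 - dist / t_len, 0.0, 1.0))
        if cfg.noise_free:
            p_edu = is_edu.astype(np.float64)
            p_brdu = np.maximum(is_brdu.astype(np.float64), tail_m)
        else:
            ap, bp_ = cfg.emission_pos
            an, bn = cfg.emission_neg
            p_edu = rng.beta(an, bn, size=n)
            p_brdu = rng.beta(an, bn, size=n)
            if is_edu.any():
                p_edu[is_edu] = rng.beta(ap, bp_, size=int(is_edu.sum()))
            is_brdu_eff = is_brdu | (rng.random(n) < tail_m)
            if is_brdu_eff.any():
                p_brdu[is_brdu_eff] = rng.beta(ap, bp_, size=int(is_brdu_eff.sum()))
        gaps: list[tuple[int, int]] = []
        if cfg.indel_rate_per_mb > 0:
            n_indels = rng.poisson(cfg.indel_rate_per_mb * length / 1e6)
            for _ in range(n_indels):
                gaps.append((int(rng.integers(start, end)), int(rng.integers(10, 300))))
            gaps.sort()
        tracks.append(AnalogueTrack(
            read_id=read_id, chrom=cfg.chrom, ref_start=start, ref_end=end,
            strand="+" if rng.random() < 0.5 else "-",
            positions=pos, p_edu=p_edu, p_brdu=p_brdu, gaps=gaps,
        ))

    truth = GroundTruth(forks=forks, origins=list(zip((int(p) for p in origin_pos), fire_times)),
                        terminations=terminations, reads=reads, config=cfg)
    return tracks, truth


# ---------------------------------------------------------------------------
# Call-vs-truth comparison


def truth_compare(calls: Sequence[ForkCall], truth: GroundTruth,
                  tolerance: int = 1000, min_segment: int = 1500,
                  edge_margin: int = 1000, max_pair_gap: int = 5000,
                  isolated_only: bool = True) -> dict:
    """Precision/recall of fork calls against simulator ground truth.

    A call matches a recoverable truth fork (see
    :meth:`GroundTruth.forks_on_read`) on the same read when directions
    agree and both track-boundary offsets are at most ``tolerance`` bp.

    With ``isolated_only`` (the default) forks whose boundaries are not
    independently recoverable on a given read are excluded symmetrically
    from both sides of the comparison: calls flagged ``near_read_end``
    (the fork is only partially visible), ``origin_member`` or
    ``termination_member`` (the fork shares a merged or abutting segment
    with a sibling, so its inner boundary is a split estimate rather than
    an observed edge), or overlapping such a non-isolated truth fork; and
    truth forks that terminated during the pulse or whose origin
    sibling's EdU track is callable on the same read within
    ``max_pair_gap``.  Precision is NA (``nan``) when there are no calls.

    Returns a dict with precision, recall, n_calls, n_truth,
    mean_boundary_error (bp, over matched pairs).
    """
    if isolated_only:
        calls = [c for c in calls
                 if not c.flags & {"near_read_end", "origin_member", "termination_member"}]
    else:
        calls = list(calls)
    read_bounds = {rid: (s, e) for rid, s, e in truth.reads}
    truth_by_read: dict[str, list[TrueFork]] = {}
    scored_by_read: dict[str, set[int]] = {}
    excluded_by_read: dict[str, list[tuple[int, int]]] = {}
    n_truth = 0
    for rid, (s, e) in read_bounds.items():
        # matchable: anything fully on the read a caller could legitimately
        # report; scored: clearly interior forks with comfortably callable
        # segments, which a correct caller must recover (the buffer between
        # the two avoids counting borderline edge cases either way)
        recoverable = truth.forks_on_read(s, e, min_segment=1, edge_margin=0)
        scored = {f.fork_id
                  for f in truth.forks_on_read(s, e, min_segment=min_segment,
                                               edge_margin=edge_margin + 500)}
        excluded_ivals: list[tuple[int, int]] = []
        if isolated_only:
            def visible(iv: tuple[int, int] | None) -> bool:
                # enough of the interval on the read to form a segment call
                return iv is not None and min(iv[1], e) - max(iv[0], s) >= 1000

            def adjacent(a: tuple[int, int] | None, b: tuple[int, int] | None) -> bool:
                if a is None or b is None:
                    return False
                gap = max(a[0], b[0]) - min(a[1], b[1])
                return gap <= max_pair_gap

            def isolated(f: TrueFork) -> bool:
                if f.terminated:
                    return False
                for g in truth.forks:
                    if g.fork_id == f.fork_id:
                        continue
                    # a neighbouring fork whose EdU track abuts ours reads as
                    # an origin; an abutting BrdU track reads as a termination
                    if visible(g.edu_interval) and adjacent(f.edu_interval, g.edu_interval):
                        return False
                    if visible(g.brdu_interval) and adjacent(f.brdu_interval, g.brdu_interval):
                        return False
                return True

            for f in truth.forks:
                iv = f.track_interval
                if iv and iv[1] > s and iv[0] < e and not isolated(f):
                    excluded_ivals.append(iv)
            recoverable = [f for f in recoverable if isolated(f)]
            scored &= {f.fork_id for f in recoverable}
        truth_by_read[rid] = recoverable
        scored_by_read[rid] = scored
        excluded_by_read[rid] = excluded_ivals
        n_truth += len(scored)
    if isolated_only:
        calls = [c for c in calls
                 if not any(c.track_start < hi and c.track_end > lo
                            for lo, hi in excluded_by_read.get(c.read_id, []))]

    matched_truth: set[tuple[str, int]] = set()
    n_matched_calls = 0
    boundary_errors: list[float] = []
    for call in calls:
        best = None
        for tf in truth_by_read.get(call.read_id, []):
            if (call.read_id, tf.fork_id) in matched_truth:
                continue
            if tf.direction != call.direction:
                continue
            lo, hi = tf.track_interval
            err = max(abs(call.track_start - lo), abs(call.track_end - hi))
            if err <= tolerance and (best is None or err < best[0]):
                best = (err, tf)
        if best is not None:
            matched_truth.add((call.read_id, best[1].fork_id))
            n_matched_calls += 1
            boundary_errors.append(0.5 * (abs(call.track_start - best[1].track_interval[0])
                                          + abs(call.track_end - best[1].track_interval[1])))
    n_matched_scored = sum(1 for rid, fid in matched_truth
                           if fid in scored_by_read.get(rid, ()))
    precision = n_matched_calls / len(calls) if calls else float("nan")
    recall = n_matched_scored / n_truth if n_truth else float("nan")
    return {
        "precision": precision,
        "recall": recall,
        "n_calls": len(calls),
        "n_truth": n_truth,
        "mean_boundary_error": float(np.mean(boundary_errors)) if boundary_errors else float("nan"),
    }
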