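"""Replication timing (Trep) from multi-fraction profiles and S-phase trends.

Multi-fraction replication-timing data (Repli-Seq-like) give, for each
50-kb genomic bin, a signal per S-phase fraction.  The cumulative
normalised signal over fractions approximates the proportion of cells in
which the bin has replicated by each hour; fitting a logistic sigmoid
gives Trep, the time at which the bin is half-replicated.  Forks are
assigned the Trep of the 50-kb bin containing their track midpoint, and
metric-versus-Trep trends are tested by ordinary least squares on the
per-hour medians with a one-sided slope test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)

BIN_SIZE = 50_000


@dataclass
class TimingProfile:
    """Replication-timing signal for one 50-kb bin.

    ``hours`` are the S-phase hours of the fractions; ``signal`` the
    per-fraction signal (arbitrary units; normalised internally).
    """

    chrom: str
    bin_start: int
    hours: np.ndarray
    signal: np.ndarray

    def __post_init__(self) -> None:
        self.hours = np.asarray(self.hours, dtype=np.float64)
        self.signal = np.asarray(self.signal, dtype=np.float64)
        if self.bin_start % BIN_SIZE:
            raise ValueError(f"bin_start {self.bin_start} not on the {BIN_SIZE}-bp grid")
        if len(self.hours) != len(self.signal):
            raise ValueError("hours and signal must have equal length")


@dataclass
class TrendResult:
    """Per-hour medians and the one-sided regression test on them."""

    hours: np.ndarray
    medians: np.ndarray
    slope: float
    intercept: float
    pearson_r: float
    p_value: float
    alternative: str  # "greater" (slope > 0) or "less" (slope < 0)
    n_forks_per_hour: np.ndarray


def _logistic(t: np.ndarray, trep: float, k: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-k * (t - trep)))


def fit_trep(profile: TimingProfile, max_residual: float = 0.15) -> float:
    """Least-squares logistic fit of the cumulative normalised signal.

    Returns Trep (hours, the half-replication time) or ``nan`` when the
    fit fails or the root-mean-square residual exceeds ``max_residual``
    (non-monotone garbage signal).
    """
    if len(profile.hours) < 4:
        return float("nan")
    total = profile.signal.sum()
    if total <= 0:
        return float("nan")
    cum = np.cumsum(profile.signal) / total
    t = profile.hours
    trep0 = float(np.interp(0.5, cum, t))
    try:
        popt, _ = optimize.curve_fit(_logistic, t, cum, p0=[trep0, 1.0],
                                     maxfev=5000)
    except (RuntimeError, ValueError):
        return float("nan")
    trep, k = popt
    if k <= 0 or not (t.min() - 2 <= trep <= t.max() + 2):
        return float("nan")
    rms = float(np.sqrt(np.mean((_logistic(t, *popt) - cum) ** 2)))
    if rms > max_residual:
        return float("nan")
    return float(trep)


def profiles_to_trep(profiles: list[TimingProfile]) -> pd.DataFrame:
    """Fit Trep for every bin; failed bins carry ``nan``."""
    rows = [{"chrom": p.chrom, "bin_start": p.bin_start, "trep": fit_trep(p)}
            for p in profiles]
    return pd.DataFrame(rows)


def read_timing_profiles(path) -> list[TimingProfile]:
    """Read a tab-separated timing file: chrom, bin_start, then one signal
    column per fraction named by its S-phase hour (e.g. ``h2.5``)."""
    df = pd.read_csv(path, sep="\t")
    hour_cols = [c for c in df.columns if c not in ("chrom", "bin_start")]
    hours = np.array([float(str(c).lstrip("h")) for c in hour_cols])
    return [
        TimingProfile(chrom=row["chrom"], bin_start=int(row["bin_start"]),
                      hours=hours, signal=row[hour_cols].to_numpy(dtype=float))
        for _, row in df.iterrows()
    ]


def assign_trep(forks: pd.DataFrame, trep_table: pd.DataFrame) -> pd.DataFrame:
    """Annotate a fork table with the Trep of the bin holding its midpoint.

    ``forks`` needs ``chrom``, ``track_start``, ``track_end`` columns.
    Forks in bins without a (finite) Trep, or on chromosomes absent from
    the table, are dropped with a log message.  A midpoint exactly on a
    bin boundary belongs to the right-hand (half-open) bin.
    """
    lut = {(r.chrom, int(r.bin_start)): r.trep
           for r in trep_table.itertuples() if np.isfinite(r.trep)}
    mid = (forks["track_start"] + forks["track_end"]) // 2
    bin_start = (mid // BIN_SIZE) * BIN_SIZE
    trep = [lut.get((c, int(b)), np.nan) for c, b in zip(forks["chrom"], bin_start)]
    out = forks.copy()
    out["trep"] = trep
    n_dropped = int(np.isnan(out["trep"]).sum())
    if n_dropped:
        logger.info("dropped %d forks without a Trep assignment", n_dropped)
    return out.dropna(subset=["trep"]).reset_index(drop=True)


def sphase_trend(forks: pd.DataFrame, metric: str, alternative: str,
                 min_hours: int = 3, min_forks_per_hour: int = 5) -> TrendResult:
    """Test how a per-fork metric changes with replication time.

    Forks are grouped by the integer hour of their Trep (floor); the
    per-hour median of ``metric`` is regressed on the hour by ordinary
    least squares.  The p-value is one-sided under ``alternative``
    (``"greater"``: slope > 0, the expectation for fork speed;
    ``"less"``: slope < 0, the expectation for stall score).
    """
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")
    if metric not in forks.columns:
        raise ValueError(f"metric column {metric!r} not in fork table")
    df = forks.dropna(subset=[metric, "trep"])
    hour = np.floor(df["trep"]).astype(int)
    groups = df.groupby(hour)[metric]
    counts = groups.size()
    keep = counts[counts >= min_forks_per_hour]
    if len(keep) < min_hours:
        raise ValueError(
            f"need >= {min_hours} hours with >= {min_forks_per_hour} forks; "
            f"got {len(keep)}")
    hours = keep.index.to_numpy(dtype=float)
    medians = groups.median()[keep.index].to_numpy(dtype=float)
    res = stats.linregress(hours, medians, alternative=alternative)
    return TrendResult(
        hours=hours, medians=medians, slope=float(res.slope),
        intercept=float(res.intercept), pearson_r=float(res.rvalue),
        p_value=float(res.pvalue), alternative=alternative,
        n_forks_per_hour=keep.to_numpy(),
    )
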