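"""Data model and readers/writers for analogue-probability tracks and fork calls.

The on-disk track format is a plain-text "detect" dialect: one record per
read, a ``>`` header carrying the mapping coordinates, then one line per
thymidine position with the probability that the base is EdU and the
probability that it is BrdU.  All coordinates are 0-based half-open,
reference-space, throughout the package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Minimum mapped read length (bp) used for fork calling.
MIN_MAPPED_LENGTH = 20_000

#: Declared column order of the detect dialect.
DIALECT_COLUMNS = ("pos", "p_EdU", "p_BrdU")


class TrackParseError(ValueError):
    """Raised when a detect-format file violates the dialect."""


@dataclass
class AnalogueTrack:
    """One sequenced read's per-thymidine EdU/BrdU probabilities.

    Parameters
    ----------
    read_id : str
        Unique read identifier.
    chrom : str
        Reference sequence name.
    ref_start, ref_end : int
        Mapped interval on the reference, 0-based half-open.
    strand : str
        ``'+'`` or ``'-'``.  Recorded for provenance; fork direction is
        defined purely in reference coordinates.
    positions : ndarray of int
        Reference coordinates of thymidine sites, strictly increasing.
    p_edu, p_brdu : ndarray of float
        Analogue probabilities per position, each in [0, 1].
    gaps : list of (int, int)
        Alignment insertions/deletions as ``(position, length_bp)``.
        ``None`` means "no indel information" (distinct from "no indels"),
        which disables the indel-based stall decline rule.
    """

    read_id: str
    chrom: str
    ref_start: int
    ref_end: int
    strand: str
    positions: np.ndarray
    p_edu: np.ndarray
    p_brdu: np.ndarray
    gaps: list[tuple[int, int]] | None = field(default_factory=list)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.p_edu = np.asarray(self.p_edu, dtype=np.float64)
        self.p_brdu = np.asarray(self.p_brdu, dtype=np.float64)
        self.validate()

    def validate(self) -> None:
        n = len(self.positions)
        if len(self.p_edu) != n or len(self.p_brdu) != n:
            raise ValueError(
                f"{self.read_id}: probability arrays must match positions "
                f"({n} positions, {len(self.p_edu)} EdU, {len(self.p_brdu)} BrdU)"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.read_id}: strand must be '+' or '-', got {self.strand!r}")
        if n:
            if np.any(np.diff(self.positions) <= 0):
                raise ValueError(f"{self.read_id}: positions must be strictly increasing")
            if self.positions[0] < self.ref_start or self.positions[-1] >= self.ref_end:
                raise ValueError(
                    f"{self.read_id}: positions must lie within [ref_start, ref_end)"
                )
        for p, name in ((self.p_edu, "p_EdU"), (self.p_brdu, "p_BrdU")):
            if n and (p.min() < 0.0 or p.max() > 1.0):
                raise ValueError(f"{self.read_id}: {name} outside [0, 1]")

    @property
    def mapped_length(self) -> int:
        return self.ref_end - self.ref_start

    def __len__(self) -> int:
        return len(self.positions)

    def probs(self, analogue: str) -> np.ndarray:
        """Return the probability vector for ``'EdU'`` or ``'BrdU'``."""
        if analogue == "EdU":
            return self.p_edu
        if analogue == "BrdU":
            return self.p_brdu
        raise ValueError(f"unknown analogue {analogue!r}")


@dataclass(frozen=True)
class Segment:
    """A contiguous analogue-positive interval on one read."""

    read_id: str
    chrom: str
    start: int
    end: int
    analogue: str  # "EdU" or "BrdU"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"segment start {self.start} >= end {self.end}")
        if self.analogue not in ("EdU", "BrdU"):
            raise ValueError(f"analogue must be EdU or BrdU, got {self.analogue!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ForkCall:
    """A paired EdU+BrdU track with direction, span, and quality flags.

    The fork track spans from the far end of the EdU segment to the far
    end of the BrdU segment: for a rightward fork that is the EdU start to
    the BrdU end; a leftward fork mirrors this.
    """

    read_id: str
    chrom: str
    direction: str  # "rightward" or "leftward"
    edu_segment: Segment
    brdu_segment: Segment
    flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.direction not in ("rightward", "leftward"):
            raise ValueError(f"direction must be rightward/leftward, got {self.direction!r}")
        if self.direction == "rightward" and self.edu_segment.end > self.brdu_segment.start:
            raise ValueError("rightward fork requires the EdU segment entirely left of BrdU")
        if self.direction == "leftward" and self.brdu_segment.end > self.edu_segment.start:
            raise ValueError("leftward fork requires the BrdU segment entirely left of EdU")

    @property
    def track_start(self) -> int:
        if self.direction == "rightward":
            return self.edu_segment.start
        return self.brdu_segment.start

    @property
    def track_end(self) -> int:
        if self.direction == "rightward":
            return self.brdu_segment.end
        return self.edu_segment.end

    @property
    def track_length(self) -> int:
        return self.track_end - self.track_start

    @property
    def brdu_end(self) -> int:
        """The genomic coordinate where BrdU incorporation ends.

        Right end of the track for a rightward fork, left end for a
        leftward fork (mirror).
        """
        return self.track_end if self.direction == "rightward" else self.track_start


# ---------------------------------------------------------------------------
# Detect-dialect I/O


def write_tracks(tracks: Iterable[AnalogueTrack], path: str | Path) -> None:
    """Write tracks in the detect dialect (6-decimal probabilities)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("#columns: " + "\t".join(DIALECT_COLUMNS) + "\n")
        for t in tracks:
            fh.write(f">{t.read_id} {t.chrom} {t.ref_start} {t.ref_end} {t.strand}\n")
            if t.gaps:
                for pos, length in t.gaps:
                    fh.write(f"#gap {pos} {length}\n")
            for pos, pe, pb in zip(t.positions, t.p_edu, t.p_brdu):
                fh.write(f"{pos}\t{pe:.6f}\t{pb:.6f}\n")


def read_tracks(path: str | Path) -> list[AnalogueTrack]:
    """Parse a detect-dialect file into :class:`AnalogueTrack` records.

    Raises
    ------
    TrackParseError
        On a malformed header, non-monotonic positions, or a probability
        outside [0, 1]; the message names the offending line and record.
    """
    path = Path(path)
    tracks: list[AnalogueTrack] = []
    header: tuple[str, str, int, int, str] | None = None
    positions: list[int] = []
    p_edu: list[float] = []
    p_brdu: list[float] = []
    gaps: list[tuple[int, int]] = []
    saw_gap_annotation = False
    record_no = 0

    def flush(lineno: int) -> None:
        nonlocal header
        if header is None:
            return
        read_id, chrom, start, end, strand = header
        try:
            tracks.append(
                AnalogueTrack(
                    read_id=read_id, chrom=chrom, ref_start=start, ref_end=end,
                    strand=strand,
                    positions=np.array(positions, dtype=np.int64),
                    p_edu=np.array(p_edu, dtype=np.float64),
                    p_brdu=np.array(p_brdu, dtype=np.float64),
                    gaps=list(gaps) if (gaps or saw_gap_annotation) else [],
                )
            )
        except ValueError as exc:
            raise TrackParseError(
                f"{path}: record {record_no} (read {read_id!r}, ending line {lineno}): {exc}"
            ) from exc
        header = None

    lineno = 0
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("#gap "):
                parts = line.split()
                if len(parts) != 3:
                    raise TrackParseError(f"{path}: line {lineno}: malformed gap annotation")
                gaps.append((int(parts[1]), int(parts[2])))
                saw_gap_annotation = True
                continue
            if line.startswith("#"):
                continue
            if line.startswith(">"):
                flush(lineno - 1)
                parts = line[1:].split()
                if len(parts) != 5:
                    raise TrackParseError(
                        f"{path}: line {lineno}: malformed header (expected "
                        f"'>read_id chrom ref_start ref_end strand', got {line!r})"
                    )
                record_no += 1
                try:
                    header = (parts[0], parts[1], int(parts[2]), int(parts[3]), parts[4])
                except ValueError as exc:
                    raise TrackParseError(f"{path}: line {lineno}: non-integer coordinate") from exc
                positions, p_edu, p_brdu, gaps = [], [], [], []
                saw_gap_annotation = False
                continue
            if header is None:
                raise TrackParseError(f"{path}: line {lineno}: data before first record header")
            parts = line.split("\t")
            if len(parts) != 3:
                raise TrackParseError(
                    f"{path}: line {lineno}: expected 3 tab-separated fields, got {len(parts)}"
                )
            try:
                pos = int(parts[0])
                pe = float(parts[1])
                pb = float(parts[2])
            except ValueError as exc:
                raise TrackParseError(f"{path}: line {lineno}: unparseable value") from exc
            if not (0.0 <= pe <= 1.0 and 0.0 <= pb <= 1.0):
                raise TrackParseError(
                    f"{path}: line {lineno} (record {record_no}): probability outside [0, 1]"
                )
            if positions and pos <= positions[-1]:
                raise TrackParseError(
                    f"{path}: line {lineno} (record {record_no}): positions not "
                    f"strictly increasing ({positions[-1]} then {pos})"
                )
            positions.append(pos)
            p_edu.append(pe)
            p_brdu.append(pb)
    flush(lineno)
    return tracks


# ---------------------------------------------------------------------------
# Fork-call BED output


def write_fork_bed(forks: Sequence[ForkCall], path: str | Path) -> None:
    """Write fork calls as a BED6+ file sorted by chrom then start.

    Columns: chrom, track_start, track_end, read_id, score (0), strand
    ('+' rightward, '-' leftward), direction, flags (comma-joined or '.').
    Records with a non-positive span are refused.
    """
    path = Path(path)
    rows = []
    for fork in forks:
        if fork.track_start >= fork.track_end:
            raise ValueError(
                f"refusing fork on {fork.read_id}: start {fork.track_start} >= end {fork.track_end}"
            )
        strand = "+" if fork.direction == "rightward" else "-"
        flags = ",".join(sorted(fork.flags)) if fork.flags else "."
        rows.append((fork.chrom, fork.track_start, fork.track_end,
                     fork.read_id, 0, strand, fork.direction, flags))
    rows.sort(key=lambda r: (r[0], r[1], r[2]))
    with path.open("w") as fh:
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def write_interval_bed(intervals: Sequence[tuple[str, int, int, str]], path: str | Path) -> None:
    """Write origin/termination intervals as BED4 (chrom, start, end, read_id).

    Zero-length point intervals (origin at a segment junction) are written
    with end = start + 1 so the record remains a valid BED interval.
    """
    rows = sorted(intervals, key=lambda r: (r[0], r[1]))
    with Path(path).open("w") as fh:
        for chrom, start, end, name in rows:
            if end <= start:
                end = start + 1
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")
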