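"""End-to-end orchestration: tracks -> forks -> per-fork metric tables.

``fork_table`` is the workhorse: it runs segmentation, fork pairing,
speed, stall scoring, and signature fractions over a collection of
tracks and returns one tidy per-fork DataFrame carrying provenance
columns (run id, replicate id, condition).  ``run_pipeline`` wraps it
with file I/O and a JSON manifest recording versions, parameters, seeds,
and per-stage record counts, so a run can be audited and reproduced.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

import forktrace
from forktrace.metrics import (STALL_PRESETS, SpeedParams, StallParams,
                               fork_speed, stall_score)
from forktrace.segmentation import SegmentationParams, call_forks
from forktrace.signatures import _segment_fractions
from forktrace.simulate import SimulationConfig, simulate_experiment
from forktrace.trackio import (AnalogueTrack, read_tracks, write_fork_bed,
                               write_interval_bed, write_tracks)

logger = logging.getLogger(__name__)


def fork_table(tracks: list[AnalogueTrack],
               seg_params: SegmentationParams = SegmentationParams(),
               speed_params: SpeedParams = SpeedParams(),
               stall_params: StallParams = StallParams(),
               run_id: str = "run0", replicate_id: str = "rep1",
               condition: str = "untreated") -> tuple[pd.DataFrame, list, list]:
    """Call forks on every track and compute the full per-fork table.

    Returns ``(table, origins, terminations)``.  The table holds one row
    per fork with coordinates, direction, flags, speed or exclusion
    reason, the stall quantities (B, A, R, score or decline reason), the
    four analogue-incorporation fractions, and provenance columns.
    """
    rows = []
    all_origins: list = []
    all_terminations: list = []
    for track in tracks:
        forks, origins, terminations = call_forks(track, seg_params)
        all_origins.extend(origins)
        all_terminations.extend(terminations)
        for fork in forks:
            sp = fork_speed(fork, track.ref_start, track.ref_end, speed_params)
            st = stall_score(track, fork, stall_params)
            edu_fe, edu_fb = _segment_fractions(track, fork.edu_segment.start,
                                                fork.edu_segment.end,
                                                seg_params.call_threshold)
            brdu_fe, brdu_fb = _segment_fractions(track, fork.brdu_segment.start,
                                                  fork.brdu_segment.end,
                                                  seg_params.call_threshold)
            rows.append({
                "read_id": fork.read_id, "chrom": fork.chrom,
                "track_start": fork.track_start, "track_end": fork.track_end,
                "direction": fork.direction,
                "flags": ",".join(sorted(fork.flags)) if fork.flags else "",
                "edu_start": fork.edu_segment.start, "edu_end": fork.edu_segment.end,
                "brdu_start": fork.brdu_segment.start, "brdu_end": fork.brdu_segment.end,
                "speed": sp if isinstance(sp, float) else np.nan,
                "speed_excluded": "" if isinstance(sp, float) else sp.reason,
                "B": st.B, "A": st.A, "R": st.R,
                "stall_score": st.score,
                "stall_declined": st.declined or "",
                "frac_brdu_in_edu": edu_fb, "frac_edu_in_edu": edu_fe,
                "frac_edu_in_brdu": brdu_fe, "frac_brdu_in_brdu": brdu_fb,
                "run_id": run_id, "replicate_id": replicate_id,
                "condition": condition,
            })
    columns = ["read_id", "chrom", "track_start", "track_end", "direction",
               "flags", "edu_start", "edu_end", "brdu_start", "brdu_end",
               "speed", "speed_excluded", "B", "A", "R", "stall_score",
               "stall_declined", "frac_brdu_in_edu", "frac_edu_in_edu",
               "frac_edu_in_brdu", "frac_brdu_in_brdu",
               "run_id", "replicate_id", "condition"]
    table = pd.DataFrame(rows, columns=columns)
    return table, all_origins, all_terminations


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with path.open("rb") as fh:
        for block in iter(lambda: fh.read(1 << 16), b""):
            h.update(block)
    return h.hexdigest()


def run_pipeline(config: dict, out_dir: str | Path) -> dict:
    """Run simulate-or-read -> segment -> metrics and write a manifest.

    ``config`` keys:

    * ``input``: either ``{"simulate": {<SimulationConfig fields>, "seed": int}}``
      or ``{"detect": <path>}``;
    * optional ``segmentation`` / ``speed`` / ``stall`` parameter dicts
      (``stall`` may instead be a preset name ``"v3"``/``"v4"``);
    * optional ``run_id`` / ``replicate_id`` / ``condition`` provenance.

    Outputs under ``out_dir``: ``tracks.detect`` (if simulated),
    ``forks.bed``, ``origins.bed``, ``terminations.bed``, ``forks.tsv``,
    ``manifest.json``.  Returns the manifest dict.  A stage failure
    raises after writing a partial manifest naming the failed stage.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "forktrace", "version": forktrace.__version__,
        "config": config, "stages": {}, "counts": {},
    }

    def fail(stage: str, exc: Exception):
        manifest["failed_stage"] = stage
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise exc

    # --- stage: input -------------------------------------------------------
    inp = config.get("input", {})
    try:
        if "simulate" in inp:
            sim_kwargs = dict(inp["simulate"])
            seed = sim_kwargs.pop("seed", 0)
            sim_cfg = SimulationConfig(**sim_kwargs)
            tracks, truth = simulate_experiment(sim_cfg, seed)
            detect_path = out_dir / "tracks.detect"
            write_tracks(tracks, detect_path)
            truth.fork_table().to_csv(out_dir / "truth_forks.tsv", sep="\t", index=False)
            manifest["stages"]["input"] = {"mode": "simulate", "seed": seed,
                                           "sim_config": asdict(sim_cfg)}
        elif "detect" in inp:
            detect_path = Path(inp["detect"])
            if not detect_path.exists():
                raise FileNotFoundError(f"detect file not found: {detect_path}")
            tracks = read_tracks(detect_path)
            manifest["stages"]["input"] = {"mode": "read", "path": str(detect_path),
                                           "sha256": _sha256(detect_path)}
        else:
            raise ValueError("config['input'] must contain 'simulate' or 'detect'")
    except Exception as exc:  # noqa: BLE001 - manifest must name the stage
        fail("input", exc)
    manifest["counts"]["tracks"] = len(tracks)

    # --- stage: segmentation + metrics -------------------------------------
    seg_params = SegmentationParams(**config.get("segmentation", {}))
    speed_params = SpeedParams(**config.get("speed", {}))
    stall_cfg = config.get("stall", "v3")
    stall_params = (STALL_PRESETS[stall_cfg] if isinstance(stall_cfg, str)
                    else StallParams(**stall_cfg))
    try:
        table, origins, terminations = fork_table(
            tracks, seg_params, speed_params, stall_params,
            run_id=config.get("run_id", "run0"),
            replicate_id=config.get("replicate_id", "rep1"),
            condition=config.get("condition", "untreated"))
    except Exception as exc:  # noqa: BLE001
        fail("segmentation", exc)

    from forktrace.trackio import ForkCall, Segment  # local to avoid cycle confusion

    forks_for_bed = []
    for r in table.itertuples():
        edu = Segment(r.read_id, r.chrom, r.edu_start, r.edu_end, "EdU")
        brdu = Segment(r.read_id, r.chrom, r.brdu_start, r.brdu_end, "BrdU")
        flags = set(r.flags.split(",")) if r.flags else set()
        forks_for_bed.append(ForkCall(r.read_id, r.chrom, r.direction, edu, brdu, flags))
    write_fork_bed(forks_for_bed, out_dir / "forks.bed")
    write_interval_bed(origins, out_dir / "origins.bed")
    write_interval_bed(terminations, out_dir / "terminations.bed")
    table.to_csv(out_dir / "forks.tsv", sep="\t", index=False)

    manifest["stages"]["segmentation"] = {"params": asdict(seg_params)}
    manifest["stages"]["metrics"] = {"speed": asdict(speed_params),
                                     "stall": asdict(stall_params)}
    manifest["counts"].update({
        "forks": int(len(table)),
        "origins": len(origins),
        "terminations": len(terminations),
        "speeds_reported": int(table["speed"].notna().sum()),
        "stall_scores_reported": int((table["stall_declined"] == "").sum()),
    })
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
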