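"""Readers and writers for the package's delimited-text tables.

All tables are CSV with unit-suffixed column names.  Track tables use
minutes (imaging convention); trajectory and retention tables use hours
(circulation convention).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from tcellsim.circulation import CellTrajectory
from tcellsim.track_stats import (
    MIN_TRACK_MINUTES,
    RetentionPoint,
    Track,
    TrackSet,
    VideoMeta,
)

__all__ = [
    "TRACK_COLUMNS",
    "read_tracks",
    "write_tracks",
    "read_video_meta",
    "write_video_meta",
    "write_trajectories",
    "read_trajectories",
    "write_retention_points",
    "read_retention_points",
    "write_fit_result",
]

logger = logging.getLogger("tcellsim")

TRACK_COLUMNS = [
    "experiment_id",
    "video_id",
    "track_id",
    "cell_class",
    "t_min",
    "x_um",
    "y_um",
    "z_um",
]

VIDEO_COLUMNS = [
    "video_id",
    "experiment_id",
    "time_post_transfer_h",
    "entry_offset_h",
    "duration_min",
    "dose_pM",
    "peptide",
]


def write_tracks(tracks: TrackSet, path) -> None:
    rows = []
    for tr in tracks:
        for k in range(tr.n_frames):
            rows.append(
                (
                    tr.experiment_id,
                    tr.video_id,
                    tr.track_id,
                    tr.cell_class,
                    tr.t[k],
                    tr.xyz[k, 0],
                    tr.xyz[k, 1],
                    tr.xyz[k, 2],
                )
            )
    pd.DataFrame(rows, columns=TRACK_COLUMNS).to_csv(path, index=False)


def read_tracks(
    path,
    videos: Optional[Sequence[VideoMeta]] = None,
    min_track_minutes: float = MIN_TRACK_MINUTES,
) -> TrackSet:
    """Read a track table, validate it, and apply the 2-min duration filter.

    Schema violations raise with the offending track id; the number of
    dropped short tracks is logged.
    """
    df = pd.read_csv(path)
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    tracks: List[Track] = []
    dropped = 0
    for (exp, vid, tid, cls), grp in df.groupby(
        ["experiment_id", "video_id", "track_id", "cell_class"], sort=False
    ):
        t = grp["t_min"].to_numpy(dtype=float)
        if np.any(np.diff(t) <= 0):
            bad = int(np.argmax(np.diff(t) <= 0))
            raise ValueError(
                f"{path}: track {tid!r} has non-monotone timestamps near row "
                f"{grp.index[bad]}"
            )
        tr = Track(
            track_id=str(tid),
            cell_class=str(cls),
            video_id=str(vid),
            experiment_id=str(exp),
            t=t,
            xyz=grp[["x_um", "y_um", "z_um"]].to_numpy(dtype=float),
        )
        if tr.duration < min_track_minutes:
            dropped += 1
            continue
        tracks.append(tr)
    if dropped:
        logger.warning("dropped %d track(s) shorter than %.0f min", dropped, min_track_minutes)
    return TrackSet(tracks, videos or ())


def write_video_meta(videos: Sequence[VideoMeta], path) -> None:
    rows = [
        (
            v.video_id,
            v.experiment_id,
            v.time_post_transfer,
            v.entry_offset,
            v.duration_min,
            v.dose_pM,
            v.peptide,
        )
        for v in videos
    ]
    pd.DataFrame(rows, columns=VIDEO_COLUMNS).to_csv(path, index=False)


def read_video_meta(path) -> List[VideoMeta]:
    df = pd.read_csv(path)
    missing = [c for c in VIDEO_COLUMNS[:5] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    out = []
    for _, row in df.iterrows():
        out.append(
            VideoMeta(
                video_id=str(row["video_id"]),
                experiment_id=str(row["experiment_id"]),
                time_post_transfer=float(row["time_post_transfer_h"]),
                entry_offset=float(row["entry_offset_h"]),
                duration_min=float(row["duration_min"]),
                dose_pM=None if pd.isna(row.get("dose_pM")) else float(row["dose_pM"]),
                peptide=None if pd.isna(row.get("peptide")) else str(row["peptide"]),
            )
        )
    return out


def write_trajectories(trajectories: Sequence[CellTrajectory], path) -> None:
    rows = []
    for cid, traj in enumerate(trajectories):
        for ep in traj.episodes:
            rows.append((cid, ep.compartment, ep.t_entry, ep.t_exit, traj.outcome))
    pd.DataFrame(
        rows, columns=["cell_id", "compartment", "t_entry_h", "t_exit_h", "outcome"]
    ).to_csv(path, index=False)


def read_trajectories(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_retention_points(points: Sequence[RetentionPoint], path) -> None:
    rows = [
        (
            p.experiment_id,
            p.video_id,
            p.time_post_entry,
            p.raw_fraction,
            p.control_fraction,
            p.corrected_fraction,
            p.duration_weight,
            p.ci_low,
            p.ci_high,
        )
        for p in points
    ]
    pd.DataFrame(
        rows,
        columns=[
            "experiment_id",
            "video_id",
            "time_post_entry_h",
            "raw_fraction",
            "control_fraction",
            "corrected_fraction",
            "duration_weight_min",
            "ci_low",
            "ci_high",
        ],
    ).to_csv(path, index=False)


def read_retention_points(path) -> List[RetentionPoint]:
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        out.append(
            RetentionPoint(
                time_post_entry=float(row["time_post_entry_h"]),
                raw_fraction=float(row["raw_fraction"]),
                control_fraction=float(row["control_fraction"]),
                corrected_fraction=float(row["corrected_fraction"]),
                duration_weight=float(row["duration_weight_min"]),
                experiment_id=str(row["experiment_id"]),
                video_id=None if pd.isna(row["video_id"]) else str(row["video_id"]),
                ci_low=None if pd.isna(row["ci_low"]) else float(row["ci_low"]),
                ci_high=None if pd.isna(row["ci_high"]) else float(row["ci_high"]),
            )
        )
    return out


def write_fit_result(fit, path) -> None:
    """Serialize a FitResult to JSON."""
    payload = {
        "family": fit.spec.family,
        "parameters": fit.params,
        "rss_logit": fit.rss,
        "n_points": fit.n_points,
        "n_parameters": fit.n_parameters,
        "bic": fit.bic,
    }
    Path(path).write_text(json.dumps(payload, indent=2))
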