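"""Synthetic two-photon-like track sets with known priming ground truth.

The generator emulates the statistical structure of intravital imaging
experiments after synchronized LN entry: per experiment, a few ~1 h videos
are imaged at staggered times; cognate cells move as persistent random
walks until their (hidden) retention time, then switch to low-motility
arrest jitter; control cells walk throughout.  Tracks are censored by an
exponential in-view duration truncated to the imaging window, reproducing
the shorter tracks of motile cells that the duration-weighted retention
estimator corrects for.

Free motion is a velocity-jump walk (constant speed, exponential
persistence, uniform reorientation) whose long-time motility coefficient is
M = v²·τ_p/3; the defaults (v = 9.49 µm/min, τ_p = 2 min) give the 60
µm²/min two-photon scale.  Arrest is Brownian jitter far below the gate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from tcellsim.priming import PrimingParams, sample_retention_time
from tcellsim.track_stats import Track, TrackSet, VideoMeta

__all__ = [
    "SyntheticExperimentSpec",
    "generate_track_set",
    "generate_circulation_fixture",
    "FIXTURE_NAMES",
]

FRAME_MINUTES = 1.0 / 3.0  # 20 s frame interval


@dataclass(frozen=True)
class SyntheticExperimentSpec:
    """Study design of a synthetic two-photon experiment set.

    ``doses`` maps dose labels to priming parameters; experiments cycle
    through the doses (6 experiments over 3 doses = 2 experiments per dose,
    emulating independent repeats).  Video start times are hours post cell
    transfer; LN entry lags transfer by ``entry_offset`` hours.
    """

    n_experiments: int = 6
    doses: Tuple[Tuple[str, PrimingParams], ...] = (
        ("low", PrimingParams.signal_integration(8.0, 1.0)),
    )
    video_times_post_transfer: Tuple[float, ...] = (2.0, 5.0, 8.0)
    cognate_per_video: int = 120
    control_per_video: int = 120
    video_minutes: float = 60.0
    entry_offset: float = 1.0
    speed: float = 9.49  # µm/min, free-walk speed
    persistence_min: float = 2.0  # persistence time of the velocity-jump walk
    arrest_motility: float = 2.0  # µm²/min Brownian jitter once arrested (near-stationary)
    mean_view_minutes: float = 20.0  # exponential in-view duration
    min_track_minutes: float = 2.0

    def __post_init__(self) -> None:
        if self.n_experiments <= 0 or self.cognate_per_video < 0 or self.control_per_video <= 0:
            raise ValueError("counts must be positive")
        if not self.doses:
            raise ValueError("need at least one dose")
        if self.arrest_motility >= 0.5 * self.free_motility:
            raise ValueError("arrested motility must be far below free motility")

    @property
    def free_motility(self) -> float:
        """Long-time motility coefficient of the free walk (µm²/min)."""
        return self.speed**2 * self.persistence_min / 3.0


def _simulate_walk_batch(
    n_cells: int,
    n_frames: int,
    arrest_frame: np.ndarray,
    spec: SyntheticExperimentSpec,
    rng: np.random.Generator,
) -> np.ndarray:
    """Positions (n_cells, n_frames, 3): persistent walk, then arrest jitter.

    ``arrest_frame[i]`` is the first frame at which cell i is arrested
    (>= n_frames means never within this video).
    """
    dt = FRAME_MINUTES
    pos = np.zeros((n_cells, n_frames, 3))
    direction = rng.normal(size=(n_cells, 3))
    direction /= np.linalg.norm(direction, axis=1, keepdims=True)
    sigma_arrest = np.sqrt(2.0 * spec.arrest_motility * dt)
    p_turn = 1.0 - np.exp(-dt / spec.persistence_min)
    for f in range(1, n_frames):
        turn = rng.random(n_cells) < p_turn
        if np.any(turn):
            nd = rng.normal(size=(int(np.sum(turn)), 3))
            nd /= np.linalg.norm(nd, axis=1, keepdims=True)
            direction[turn] = nd
        arrested = f > arrest_frame  # arrest applies after the arrest frame
        step = spec.speed * dt * direction
        step[arrested] = rng.normal(0.0, sigma_arrest, size=(int(np.sum(arrested)), 3))
        pos[:, f] = pos[:, f - 1] + step
    return pos


def generate_track_set(
    spec: SyntheticExperimentSpec, rng: np.random.Generator
) -> Tuple[TrackSet, pd.DataFrame]:
    """Generate tracks plus the per-cell ground truth.

    Returns the TrackSet (with video metadata) and a DataFrame with one row
    per cell: experiment, video, cell class, dose label, true retention time
    in hours post LN entry (NaN for controls, who never arrest), and the
    generating parameters.
    """
    tracks: List[Track] = []
    videos: List[VideoMeta] = []
    truth_rows = []
    n_frames_total = int(round(spec.video_minutes / FRAME_MINUTES)) + 1
    for e in range(spec.n_experiments):
        dose_label, params = spec.doses[e % len(spec.doses)]
        exp_id = f"exp{e:02d}"
        for v, tpt in enumerate(spec.video_times_post_transfer):
            vid_id = f"{exp_id}_v{v}"
            videos.append(
                VideoMeta(
                    video_id=vid_id,
                    experiment_id=exp_id,
                    time_post_transfer=tpt,
                    entry_offset=spec.entry_offset,
                    duration_min=spec.video_minutes,
                    peptide=dose_label,
                )
            )
            n_cog, n_ctl = spec.cognate_per_video, spec.control_per_video
            n_cells = n_cog + n_ctl
            # retention times (hours post LN entry) for cognate cells
            a_h = sample_retention_time(params, rng, size=n_cog)
            video_start_post_entry = tpt - spec.entry_offset
            arrest_min = (a_h - video_start_post_entry) * 60.0
            arrest_frame = np.full(n_cells, n_frames_total + 1, dtype=float)
            arrest_frame[:n_cog] = np.maximum(arrest_min, 0.0) / FRAME_MINUTES
            pos = _simulate_walk_batch(n_cells, n_frames_total, arrest_frame, spec, rng)
            t_grid = np.arange(n_frames_total) * FRAME_MINUTES
            # censor to an in-view interval per cell
            start = rng.uniform(0.0, spec.video_minutes - spec.min_track_minutes, size=n_cells)
            view = spec.min_track_minutes + rng.exponential(spec.mean_view_minutes, size=n_cells)
            end = np.minimum(start + view, spec.video_minutes)
            for i in range(n_cells):
                mask = (t_grid >= start[i]) & (t_grid <= end[i])
                if np.sum(mask) < 2:
                    continue
                cls = "cognate" if i < n_cog else "control"
                tracks.append(
                    Track(
                        track_id=f"{vid_id}_c{i:03d}",
                        cell_class=cls,
                        video_id=vid_id,
                        experiment_id=exp_id,
                        t=t_grid[mask],
                        xyz=pos[i][mask],
                    )
                )
                truth_rows.append(
                    {
                        "experiment_id": exp_id,
                        "video_id": vid_id,
                        "track_id": f"{vid_id}_c{i:03d}",
                        "cell_class": cls,
                        "dose": dose_label,
                        "retention_time_h": float(a_h[i]) if i < n_cog else np.nan,
                        "required_contacts": params.required_contacts,
                        "success_rate_per_h": params.success_rate,
                    }
                )
    truth = pd.DataFrame(truth_rows)
    return TrackSet(tracks, videos), truth


# ---------------------------------------------------------------------------
# Circulation / capture scenario fixtures
# ---------------------------------------------------------------------------

FIXTURE_NAMES = (
    "baseline",
    "listeria_like",
    "influenza_like",
    "hsv_like",
    "fig_hypothetical",
)


def generate_circulation_fixture(name: str, seed: int = 1, cohort_size: int = 2000) -> dict:
    """Seeded scenario configuration for a named infection experiment.

    * ``baseline`` — pure surveillance, no dLNs.
    * ``listeria_like`` — systemic infection: target organ is the spleen.
    * ``influenza_like`` — local lung infection draining to 9 single-sphere
      LNs.
    * ``hsv_like`` — footpad infection draining to 2 single-sphere LNs with
      a 9-fold entry-rate ramp over the first 4.5 days.
    * ``fig_hypothetical`` — hypothetical infection in 25% of LN spheres
      with a 1/h cognate encounter rate and 8 required contacts.
    """
    base = {
        "name": name,
        "seed": seed,
        "cohort_size": cohort_size,
        "horizon_hours": 336.0,
        "body": {
            "spleen_entry_rate_per_h": 1.0,
            "total_ln_entry_rate_per_h": 1.5,
            "dln_count": 0,
            "ramp": None,
        },
        "transit": {"kind": "stochastic", "t_det_hours": None},
        "priming": None,
        "targets": [],
    }
    if name == "baseline":
        return base
    if name == "listeria_like":
        base["targets"] = ["spleen"]
        base["horizon_hours"] = 120.0
        return base
    if name == "influenza_like":
        base["body"]["dln_count"] = 9
        base["targets"] = ["dln"]
        base["horizon_hours"] = 168.0
        return base
    if name == "hsv_like":
        base["body"]["dln_count"] = 2
        base["body"]["ramp"] = {
            "fold_increase": 9.0,
            "ramp_end_days": 4.5,
            "shape": "linear",
        }
        base["targets"] = ["dln"]
        base["horizon_hours"] = 168.0
        base["priming"] = {
            "contact_rate_per_h": 1.0,
            "success_prob": 1.0,
            "required_contacts": 8.0,
        }
        return base
    if name == "fig_hypothetical":
        base["body"]["dln_count"] = 10  # ~25% of the 39 spheres
        base["dln_fraction"] = 0.25
        base["priming"] = {
            "contact_rate_per_h": 1.0,
            "success_prob": 1.0,
            "required_contacts": 8.0,
        }
        base["targets"] = ["dln"]
        base["horizon_hours"] = 480.0
        return base
    raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
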