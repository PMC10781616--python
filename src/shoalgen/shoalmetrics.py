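"""Sociability phenotypes from tracked schooling trajectories.

Input is an open-field trial: per-frame 2-D positions of a focal fish and
its stimulus group (8 fish total by default, filmed at 25 Hz in a 55 cm
arena), with a validity mask marking tracking dropouts. Outputs are the
four collective-motion phenotypes used for the sociability axis:

- alignment: per valid frame, the length of the sum of two unit vectors —
  the focal fish's heading and the heading of the centroid of the tracked
  non-focal fish; the trial score is the median over frames, in [0, 2].
  Frames with fewer than 6 of 8 tracked individuals are excluded.
- attraction: median distance from the focal fish to its nearest tracked
  neighbour (cm; smaller = more attracted).
- activity: median group speed (cm/s) from Savitzky–Golay-smoothed
  first-differences of the coordinate time series (window 13 frames,
  degree 3 — the closest odd window to half a second at 25 Hz).
- polarization: per frame, the length of the mean unit heading over
  tracked individuals; median over frames, in [0, 1].

Trials with less than 70% complete tracks are flagged by the QC filter.
Headings are forward displacements between consecutive frames; frames
with zero displacement or missing positions have undefined headings.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

SAVGOL_WINDOW = 13
SAVGOL_DEGREE = 3
COMPLETENESS_THRESHOLD = 0.70
MIN_TRACKED_FOR_ALIGNMENT = 6


@dataclass
class Trajectory:
    """One open-field trial: frame x individual x (x, y) positions in cm."""

    positions: np.ndarray  # (n_frames, n_ind, 2)
    valid_mask: Optional[np.ndarray] = None  # (n_frames, n_ind) bool
    frame_rate: float = 25.0
    arena_diameter: float = 55.0
    focal_index: int = 0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 2:
            raise ValueError("positions must have shape (frames, individuals, 2)")
        if self.positions.shape[0] < 2:
            raise ValueError("a trajectory needs at least 2 frames")
        if self.valid_mask is None:
            self.valid_mask = np.isfinite(self.positions).all(axis=2)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.valid_mask.shape != self.positions.shape[:2]:
            raise ValueError("valid_mask shape mismatch")
        if not 0 <= self.focal_index < self.positions.shape[1]:
            raise ValueError("focal_index out of range")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.positions.shape[1]


@dataclass
class SociabilityPhenotype:
    alignment: float
    attraction: float
    activity: float
    polarization: float
    completeness: float
    n_valid_frames: int
    qc_pass: bool

    def as_dict(self) -> dict:
        return {
            "alignment": self.alignment,
            "attraction": self.attraction,
            "activity": self.activity,
            "polarization": self.polarization,
            "completeness": self.completeness,
            "n_valid_frames": self.n_valid_frames,
            "qc_pass": self.qc_pass,
        }


def compute_headings(traj: Trajectory) -> tuple[np.ndarray, np.ndarray]:
    """Unit heading vectors from forward displacement.

    Heading at frame t is the normalized displacement from t to t+1;
    masked when either position is missing or the displacement is zero.
    Returns (headings (n_frames-1, n_ind, 2), mask (n_frames-1, n_ind)).
    """
    if traj.n_frames < 2:
        raise ValueError("headings need at least 2 frames")
    disp = traj.positions[1:] - traj.positions[:-1]
    ok = traj.valid_mask[1:] & traj.valid_mask[:-1]
    norm = np.linalg.norm(disp, axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = disp / norm[:, :, None]
    ok = ok & (norm > 0) & np.isfinite(norm)
    unit[~ok] = np.nan
    return unit, ok


def focal_alignment(traj: Trajectory, include_focal_in_centroid: bool = False) -> float:
    """Alignment score: median over frames of ||u_focal + u_centroid||.

    u_centroid is the unit displacement of the centroid of the tracked
    non-focal fish (the focal fish can be included via the switch, for
    the alternative reading of the group direction). A frame counts only
    if the focal heading exists and at least 6 of the 8 group members are
    tracked across the step. Returns NaN if no frame qualifies.
    """
    _, ok = compute_headings(traj)
    f = traj.focal_index
    step_valid = traj.valid_mask[1:] & traj.valid_mask[:-1]
    others = np.ones(traj.n_individuals, bool)
    if not include_focal_in_centroid:
        others[f] = False
    scores = []
    for t in range(traj.n_frames - 1):
        tracked = step_valid[t]
        if tracked.sum() < MIN_TRACKED_FOR_ALIGNMENT or not ok[t, f]:
            continue
        sel = tracked & others
        if sel.sum() == 0:
            continue
        d = traj.positions[t + 1, sel].mean(axis=0) - traj.positions[t, sel].mean(axis=0)
        n = np.linalg.norm(d)
        if n == 0:
            continue
        u_c = d / n
        step = traj.positions[t + 1, f] - traj.positions[t, f]
        u_f = step / np.linalg.norm(step)
        scores.append(np.linalg.norm(u_f + u_c))
    if not scores:
        return float("nan")
    return float(np.median(scores))


def focal_attraction(traj: Trajectory) -> float:
    """Median nearest-neighbour distance (cm) of the focal fish."""
    f = traj.focal_index
    mask = traj.valid_mask.copy()
    focal_ok = mask[:, f].copy()
    mask[:, f] = False
    d = np.linalg.norm(traj.positions - traj.positions[:, f : f + 1, :], axis=2)
    d[~mask] = np.inf
    nn = d.min(axis=1)
    use = focal_ok & np.isfinite(nn)
    if not use.any():
        return float("nan")
    return float(np.median(nn[use]))


def _smoothed_speeds(pos: np.ndarray, mask: np.ndarray, frame_rate: float) -> np.ndarray:
    """Per-individual speeds from Savitzky–Golay-smoothed first differences.

    The finite difference of x and y is smoothed over contiguous valid
    runs of at least the filter window; shorter runs are dropped.
    Returns a flat array of speeds (cm/s).
    """
    n_frames, n_ind, _ = pos.shape
    speeds = []
    for i in range(n_ind):
        idx = np.flatnonzero(mask[:, i])
        if idx.size < SAVGOL_WINDOW + 1:
            continue
        for run in np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1):
            if run.size < SAVGOL_WINDOW + 1:
                continue
            d = np.diff(pos[run, i, :], axis=0) * frame_rate
            smooth = savgol_filter(d, SAVGOL_WINDOW, SAVGOL_DEGREE, axis=0)
            speeds.append(np.linalg.norm(smooth, axis=1))
    if not speeds:
        return np.empty(0)
    return np.concatenate(speeds)


def group_activity(traj: Trajectory) -> float:
    """Median speed (cm/s) over all individuals and frames."""
    if traj.n_frames < SAVGOL_WINDOW + 1:
        raise ValueError(
            f"activity needs at least {SAVGOL_WINDOW + 1} frames, got {traj.n_frames}"
        )
    speeds = _smoothed_speeds(traj.positions, traj.valid_mask, traj.frame_rate)
    if speeds.size == 0:
        return float("nan")
    return float(np.median(speeds))


def group_polarization(traj: Trajectory) -> float:
    """Median over frames of the group polarization order parameter."""
    unit, ok = compute_headings(traj)
    n_tracked = ok.sum(axis=1)
    frames = n_tracked >= 2
    if not frames.any():
        return float("nan")
    sums = np.nansum(np.where(ok[:, :, None], unit, 0.0), axis=1)
    pol = np.linalg.norm(sums, axis=1) / np.maximum(n_tracked, 1)
    return float(np.median(pol[frames]))


def qc_completeness(traj: Trajectory) -> tuple[float, bool]:
    """Fraction of frame x individual cells tracked; pass iff >= 70%."""
    completeness = float(traj.valid_mask.mean())
    return completeness, bool(completeness >= COMPLETENESS_THRESHOLD)


def phenotype_trial(traj: Trajectory) -> SociabilityPhenotype:
    """All four metrics plus QC for one trial."""
    completeness, ok = qc_completeness(traj)
    _, hmask = compute_headings(traj)
    activity = group_activity(traj) if traj.n_frames >= SAVGOL_WINDOW + 1 else float("nan")
    return SociabilityPhenotype(
        alignment=focal_alignment(traj),
        attraction=focal_attraction(traj),
        activity=activity,
        polarization=group_polarization(traj),
        completeness=completeness,
        n_valid_frames=int(hmask.any(axis=1).sum()),
        qc_pass=ok,
    )


def trajectory_from_long(
    df: pd.DataFrame,
    focal_id,
    frame_rate: float = 25.0,
    arena_diameter: float = 55.0,
) -> Trajectory:
    """Build a Trajectory from a long table (frame, id, x_cm, y_cm).

    The focal individual becomes index 0; missing (frame, id) cells are
    masked.
    """
    ids = sorted(df["id"].unique(), key=lambda v: (v != focal_id, str(v)))
    if ids[0] != focal_id:
        raise ValueError(f"focal id {focal_id!r} absent from table")
    frames = np.arange(int(df["frame"].min()), int(df["frame"].max()) + 1)
    pos = np.full((len(frames), len(ids), 2), np.nan)
    fidx = pd.Series(np.arange(len(frames)), index=frames)
    iidx = {v: k for k, v in enumerate(ids)}
    rows = fidx[df["frame"]].to_numpy()
    cols = df["id"].map(iidx).to_numpy()
    pos[rows, cols, 0] = df["x_cm"].to_numpy()
    pos[rows, cols, 1] = df["y_cm"].to_numpy()
    return Trajectory(
        positions=pos,
        frame_rate=frame_rate,
        arena_diameter=arena_diameter,
        focal_index=0,
    )


def phenotype_table(trials: dict[str, Trajectory]) -> pd.DataFrame:
    """Phenotype + QC table for a mapping of trial name -> Trajectory."""
    rows = []
    for name, traj in trials.items():
        rec = phenotype_trial(traj).as_dict()
        rec["trial"] = name
        rows.append(rec)
    return pd.DataFrame(rows).set_index("trial")
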