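"""Collective-durotaxis track statistics.

Summarizes cell-track tables (track id, frame, time, x, y) exported by an
external tracker: per-track total distance traveled, net displacement and
mean speed; population displacement distribution and skewness; and the
displacement of the monolayer's leading edge along the stiffness-gradient
axis.  A right-skewed displacement distribution indicates that a small
minority of cells (leaders) moves far while the bulk stays static; a
near-symmetric one indicates collective, low-speed migration.

"Displacement" in the population summary means total path length per track
(matching how migratory activity is usually histogrammed for monolayers);
net displacement is reported alongside for transparency.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TrackTable",
    "TrackMetrics",
    "clean_tracks",
    "track_metrics",
    "field_summary",
    "leading_edge_displacement",
]


@dataclass
class TrackTable:
    """Track table with columns track_id, frame, t_h, x_um, y_um."""

    data: pd.DataFrame
    gradient_axis: Optional[np.ndarray] = None  # unit vector
    frame_interval: Optional[float] = None  # h

    def __post_init__(self) -> None:
        required = {"track_id", "frame", "t_h", "x_um", "y_um"}
        if not required.issubset(self.data.columns):
            raise ValueError(f"track table needs columns {sorted(required)}")
        for _, g in self.data.groupby("track_id"):
            if np.any(np.diff(g["frame"].to_numpy()) <= 0):
                raise ValueError("frames within a track must be strictly increasing")
        if self.gradient_axis is not None:
            v = np.asarray(self.gradient_axis, dtype=float)
            n = np.linalg.norm(v)
            if n == 0:
                raise ValueError("gradient axis must be a nonzero vector")
            self.gradient_axis = v / n


@dataclass
class TrackMetrics:
    track_id: object
    total_distance: float  # um
    net_displacement: np.ndarray  # (dx, dy) um
    mean_speed: float  # um/h

    @property
    def net_magnitude(self) -> float:
        return float(np.linalg.norm(self.net_displacement))


def clean_tracks(table: TrackTable, max_gap: int = 2) -> TrackTable:
    """Interpolate short frame gaps; split tracks at longer ones.

    Gaps of up to ``max_gap`` missing frames are filled by linear
    interpolation in time; longer gaps split the track into separately
    numbered segments.  Counts are attached as ``table.gap_log``.
    """
    rows = []
    n_interp = n_split = 0
    for tid, g in table.data.groupby("track_id"):
        g = g.sort_values("frame")
        frames = g["frame"].to_numpy()
        gaps = np.diff(frames) - 1
        seg = 0
        segments = [[0]]
        for i, gap in enumerate(gaps):
            if gap > max_gap:
                seg += 1
                n_split += 1
                segments.append([])
            segments[-1].append(i + 1)
        for si, idxs in enumerate(segments):
            sub = g.iloc[idxs]
            new_id = tid if len(segments) == 1 else f"{tid}_{si}"
            frames_s = sub["frame"].to_numpy()
            full = np.arange(frames_s[0], frames_s[-1] + 1)
            if len(full) > len(frames_s):
                n_interp += len(full) - len(frames_s)
                interp = {"frame": full}
                for col in ("t_h", "x_um", "y_um"):
                    interp[col] = np.interp(full, frames_s, sub[col].to_numpy())
                sub = pd.DataFrame(interp)
            else:
                sub = sub[["frame", "t_h", "x_um", "y_um"]]
            sub = sub.assign(track_id=new_id)
            rows.append(sub)
    out = TrackTable(pd.concat(rows, ignore_index=True),
                     gradient_axis=table.gradient_axis,
                     frame_interval=table.frame_interval)
    out.gap_log = {"interpolated_frames": n_interp, "splits": n_split}
    return out


def track_metrics(table: TrackTable) -> tuple[list[TrackMetrics], int]:
    """Per-track motility metrics.

    total distance = sum of step lengths; mean speed = total distance over
    elapsed time; net displacement = last minus first position.  Tracks with
    a single point are skipped; their count is returned alongside.
    """
    metrics: list[TrackMetrics] = []
    skipped = 0
    for tid, g in table.data.groupby("track_id"):
        g = g.sort_values("frame")
        if len(g) < 2:
            skipped += 1
            continue
        xy = g[["x_um", "y_um"]].to_numpy(dtype=float)
        steps = np.linalg.norm(np.diff(xy, axis=0), axis=1)
        total = float(steps.sum())
        elapsed = float(g["t_h"].iloc[-1] - g["t_h"].iloc[0])
        metrics.append(TrackMetrics(
            track_id=tid,
            total_distance=total,
            net_displacement=xy[-1] - xy[0],
            mean_speed=total / elapsed if elapsed > 0 else np.nan,
        ))
    return metrics, skipped


def adjusted_skewness(values: np.ndarray) -> Optional[float]:
    """Adjusted Fisher-Pearson standardized third moment.

    ``G1 = g1 * sqrt(n (n-1)) / (n-2)`` — the estimator mainstream
    statistics packages print, so reported skewness values are directly
    comparable.  Returns None for degenerate (zero-variance) samples.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 3 or np.std(values) == 0:
        return None
    return float(stats.skew(values, bias=False))


def field_summary(metrics: Sequence[TrackMetrics], bins: int = 30) -> dict:
    """Population summary: mean speed/displacement, histogram, skewness."""
    if len(metrics) < 3:
        raise ValueError("need >= 3 tracks for a population summary")
    dist = np.array([m.total_distance for m in metrics])
    net = np.array([m.net_magnitude for m in metrics])
    speeds = np.array([m.mean_speed for m in metrics])
    skew = adjusted_skewness(dist)
    counts, edges = np.histogram(dist, bins=bins)
    return {
        "n_tracks": len(metrics),
        "mean_speed": float(np.nanmean(speeds)),
        "mean_total_distance": float(dist.mean()),
        "mean_net_displacement": float(net.mean()),
        "skewness": skew,
        "skewness_defined": skew is not None,
        "histogram": {"counts": counts.tolist(), "edges": edges.tolist()},
    }


def leading_edge_displacement(
    table: TrackTable, edge_quantile: float = 0.95
) -> float:
    """Advance of the monolayer's leading edge along the gradient axis (um).

    The edge position at each frame is the ``edge_quantile`` of all cell
    coordinates projected on the gradient axis (a quantile, not the maximum,
    to resist spurious detections); the reported displacement is the edge
    position at the last frame minus that at the first.
    """
    if table.gradient_axis is None:
        raise ValueError("gradient axis must be declared")
    frames = np.sort(table.data["frame"].unique())
    if len(frames) < 2:
        raise ValueError("need >= 2 frames")
    axis = table.gradient_axis

    def edge(frame) -> float:
        sub = table.data[table.data["frame"] == frame]
        proj = sub[["x_um", "y_um"]].to_numpy(dtype=float) @ axis
        return float(np.quantile(proj, edge_quantile))

    return edge(frames[-1]) - edge(frames[0])
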