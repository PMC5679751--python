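"""Time-lapse trajectory analysis.

The pipeline mirrors how gastrulation tracking data are quantified: tracks
are aligned at the onset of mesendoderm internalization (t = 0), the
observation span is cut into equal-length time windows (default four),
segments with fewer than five points in a window are discarded, and the
first window is excluded from aggregate statistics.  Per cell and window
the metrics are:

* ``path_length`` — summed per-frame step magnitudes (µm);
* ``net_displacement`` — straight-line first-to-last distance (µm);
* ``straightness`` — net_displacement / path_length ∈ [0, 1]
  (1 = perfectly straight, 0 = closed loop);
* ``speed`` — path_length divided by the segment's elapsed time (µm/min).

Directionality is summarized by a displacement-weighted rose histogram:
every per-frame step adds its magnitude to the angular bin of its movement
direction in the anatomical compass frame, and bin weights are normalized
to proportions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .embryo_geometry import DirectionConvention, EmbryoGeometry, movement_angle
from .track_io import TrackSet

__all__ = [
    "WindowedSegment",
    "CellWindowMetrics",
    "RoseHistogram",
    "align_at_onset",
    "bin_into_windows",
    "path_length",
    "net_displacement",
    "straightness",
    "speed",
    "rose_histogram",
    "compute_window_metrics",
    "summarize_by_genotype",
    "metrics_to_frame",
]

DEFAULT_MIN_POINTS = 5


@dataclass
class WindowedSegment:
    """The part of one track that falls inside one time window."""

    track_id: str
    window_index: int
    t: np.ndarray
    xy: np.ndarray
    window_start: float
    window_end: float

    @property
    def n_points(self) -> int:
        return int(self.t.size)

    def passes_filter(self, min_points: int = DEFAULT_MIN_POINTS) -> bool:
        return self.n_points >= min_points


@dataclass(frozen=True)
class CellWindowMetrics:
    track_id: str
    window_index: int
    n_points: int
    path_length: float
    net_displacement: float
    straightness: float | None  # None when path_length == 0 (undefined)
    speed: float


@dataclass(frozen=True)
class RoseHistogram:
    """Displacement-weighted circular histogram of movement directions."""

    bin_edges: np.ndarray  # degrees, length n_bins + 1, ascending
    weights: np.ndarray  # summed step magnitudes per bin
    n_cells: int

    @property
    def proportions(self) -> np.ndarray:
        total = self.weights.sum()
        if total == 0:
            raise ValueError("rose histogram has zero total weight")
        return self.weights / total

    def bin_of(self, angle_deg: float) -> int:
        """Index of the bin containing an angle (periodic)."""
        a = (angle_deg - self.bin_edges[0]) % 360.0 + self.bin_edges[0]
        idx = int(np.searchsorted(self.bin_edges, a, side="right") - 1)
        return min(idx, len(self.weights) - 1)

    def proportion_toward(self, direction: str, conv: DirectionConvention) -> float:
        """Proportion in the bin containing a cardinal anatomical direction."""
        return float(self.proportions[self.bin_of(conv.angle_of(direction))])


def align_at_onset(ts: TrackSet) -> TrackSet:
    """Shift all timestamps so internalization onset becomes t = 0.

    Points before onset are retained with negative times (downstream
    windowing starts at 0, so they never enter window statistics).
    """
    if ts.internalization_onset is None:
        raise ValueError(f"embryo {ts.embryo_id}: internalization_onset unset")
    onset = ts.internalization_onset
    last = max((tr.t[-1] for tr in ts.tracks), default=None)
    if last is None or last <= onset:
        raise ValueError(
            f"embryo {ts.embryo_id}: onset at {onset} min is at or after the "
            "last timestamp of every track; nothing to analyze"
        )
    return replace(
        ts,
        tracks=[tr.shifted(onset) for tr in ts.tracks],
        internalization_onset=0.0,
    )


def observation_span(ts: TrackSet) -> float:
    """Span T from onset (t = 0) to the last timestamp present."""
    return float(max(tr.t[-1] for tr in ts.tracks))


def bin_into_windows(
    ts: TrackSet, n_windows: int = 4, *, span: float | None = None
) -> list[WindowedSegment]:
    """Cut [0, T] into ``n_windows`` equal windows and assign track points.

    Windows are half-open ``[start, end)``; the final window is closed at
    T so every point is assigned exactly once.  A 180-min span with four
    windows gives boundaries at 0, 45, 90, 135, 180 min.  Segments are
    returned for every (track, window) pair with at least one point;
    filtering by minimum point count happens downstream.
    """
    if n_windows < 1:
        raise ValueError("n_windows must be >= 1")
    T = observation_span(ts) if span is None else float(span)
    if T <= 0:
        raise ValueError("observation span must be positive")
    edges = np.linspace(0.0, T, n_windows + 1)
    segs: list[WindowedSegment] = []
    for tr in ts.tracks:
        idx = np.floor(tr.t / (T / n_windows)).astype(int)
        idx[tr.t >= T] = n_windows - 1  # close the last window at T
        for w in range(n_windows):
            mask = (idx == w) & (tr.t >= 0) & (tr.t <= T)
            if mask.any():
                segs.append(
                    WindowedSegment(
                        track_id=tr.track_id,
                        window_index=w,
                        t=tr.t[mask],
                        xy=tr.xy[mask],
                        window_start=float(edges[w]),
                        window_end=float(edges[w + 1]),
                    )
                )
    return segs


def _steps(seg: WindowedSegment) -> np.ndarray:
    return np.diff(seg.xy, axis=0)


def path_length(seg: WindowedSegment) -> float:
    """Summed per-frame step magnitudes over the segment (µm)."""
    if seg.n_points < 2:
        raise ValueError("path_length needs at least 2 points")
    return float(np.linalg.norm(_steps(seg), axis=1).sum())


def net_displacement(seg: WindowedSegment) -> float:
    """Straight-line distance between first and last point (µm)."""
    if seg.n_points < 2:
        raise ValueError("net_displacement needs at least 2 points")
    return float(np.linalg.norm(seg.xy[-1] - seg.xy[0]))


def straightness(seg: WindowedSegment, *, reciprocal: bool = False) -> float:
    """Straightness index net/path in [0, 1].

    ``reciprocal=True`` returns path/net instead (>= 1), for comparison
    with conventions that divide the other way.  A segment that never
    moves has undefined straightness and raises ``ValueError``; aggregate
    helpers mark it as missing instead.
    """
    pl = path_length(seg)
    if pl == 0:
        raise ValueError("straightness undefined for zero path length")
    nd = net_displacement(seg)
    if reciprocal:
        if nd == 0:
            raise ValueError("reciprocal straightness undefined for zero net")
        return pl / nd
    return nd / pl


def speed(seg: WindowedSegment) -> float:
    """Path length divided by the segment's elapsed time (µm/min)."""
    if seg.n_points < 2:
        raise ValueError("speed needs at least 2 points")
    dt = float(seg.t[-1] - seg.t[0])
    if dt <= 0:
        raise ValueError("zero elapsed time")
    return path_length(seg) / dt


def rose_histogram(
    segs: list[WindowedSegment],
    geom: EmbryoGeometry | None = None,
    conv: DirectionConvention | None = None,
    n_bins: int = 8,
    *,
    min_points: int = DEFAULT_MIN_POINTS,
    center_on_cardinals: bool = True,
) -> RoseHistogram:
    """Displacement-weighted directional histogram over qualifying segments.

    Each consecutive step in each segment passing the minimum-point filter
    adds its magnitude to the bin of its movement angle.  Zero-magnitude
    steps carry no direction and are skipped.  With
    ``center_on_cardinals`` (default) bins are centered on the compass
    directions, so a bin sits symmetrically around exactly-animal motion.
    """
    conv = conv or DirectionConvention()
    half = 180.0 / n_bins if center_on_cardinals else 0.0
    edges = np.linspace(-half, 360.0 - half, n_bins + 1)
    weights = np.zeros(n_bins)
    n_cells = 0
    for seg in segs:
        if not seg.passes_filter(min_points):
            continue
        steps = _steps(seg)
        mags = np.linalg.norm(steps, axis=1)
        contributed = False
        for step, mag in zip(steps, mags):
            if mag == 0:
                continue
            ang = movement_angle(step, conv, geom)
            a = (ang - edges[0]) % 360.0 + edges[0]
            b = min(int(np.searchsorted(edges, a, side="right") - 1), n_bins - 1)
            weights[b] += mag
            contributed = True
        n_cells += contributed
    if n_cells == 0:
        raise ValueError("no qualifying segments for rose histogram")
    if weights.sum() == 0:
        raise ValueError("rose histogram has zero total weight")
    return RoseHistogram(bin_edges=edges, weights=weights, n_cells=n_cells)


def compute_window_metrics(
    ts: TrackSet,
    n_windows: int = 4,
    *,
    min_points: int = DEFAULT_MIN_POINTS,
    exclude_first_window: bool = True,
    span: float | None = None,
) -> list[CellWindowMetrics]:
    """Aligned-and-binned per-cell metrics for one embryo.

    Only segments with at least ``min_points`` points enter; the first
    window is excluded by default.  Segments with zero path length get
    ``straightness=None`` and are skipped by aggregation.
    """
    if ts.internalization_onset not in (None, 0.0):
        ts = align_at_onset(ts)
    out: list[CellWindowMetrics] = []
    for seg in bin_into_windows(ts, n_windows, span=span):
        if exclude_first_window and seg.window_index == 0:
            continue
        if not seg.passes_filter(min_points):
            continue
        pl = path_length(seg)
        out.append(
            CellWindowMetrics(
                track_id=seg.track_id,
                window_index=seg.window_index,
                n_points=seg.n_points,
                path_length=pl,
                net_displacement=net_displacement(seg),
                straightness=(net_displacement(seg) / pl) if pl > 0 else None,
                speed=speed(seg),
            )
        )
    return out


def metrics_to_frame(
    metrics: list[CellWindowMetrics],
    *,
    embryo_id: str = "",
    genotype: str = "",
) -> pd.DataFrame:
    """Tidy per-cell-per-window metrics table."""
    cols = [
        "embryo_id", "genotype", "track_id", "window", "n_points",
        "path_length_um", "net_displacement_um", "straightness",
        "speed_um_min",
    ]
    return pd.DataFrame(
        [
            {
                "embryo_id": embryo_id,
                "genotype": genotype,
                "track_id": m.track_id,
                "window": m.window_index,
                "n_points": m.n_points,
                "path_length_um": m.path_length,
                "net_displacement_um": m.net_displacement,
                "straightness": m.straightness,
                "speed_um_min": m.speed,
            }
            for m in metrics
        ],
        columns=cols,
    )


def summarize_by_genotype(frame: pd.DataFrame) -> pd.DataFrame:
    """Per-genotype, per-window mean ± SEM of straightness and speed.

    Input is the tidy frame from :func:`metrics_to_frame` (possibly
    concatenated over embryos).  Groups with a single cell get SEM 0 and
    ``sem_defined=False``.  Empty groups are simply absent.
    """
    if frame.empty:
        warnings.warn("no metrics to summarize", stacklevel=2)
        return pd.DataFrame(
            columns=["genotype", "window", "n_cells",
                     "straightness_mean", "straightness_sem",
                     "speed_mean", "speed_sem", "sem_defined"]
        )
    rows = []
    for (gt, w), grp in frame.groupby(["genotype", "window"]):
        n = len(grp)
        sem_defined = n > 1
        rows.append(
            {
                "genotype": gt,
                "window": w,
                "n_cells": n,
                "straightness_mean": grp["straightness"].mean(),
                "straightness_sem": grp["straightness"].sem() if sem_defined else 0.0,
                "speed_mean": grp["speed_um_min"].mean(),
                "speed_sem": grp["speed_um_min"].sem() if sem_defined else 0.0,
                "sem_defined": sem_defined,
            }
        )
    return pd.DataFrame(rows)
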