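"""Reading and writing cell-track tables.

Two dialects are supported: a subset of the TrackMate XML schema (the spot
and edge core — features, filters and views are ignored) and a plain CSV
table with columns ``track_id, t_min, x, y`` plus optional lineage columns.
Both produce the same in-memory :class:`TrackSet`.

Times are minutes throughout.  z coordinates, if present, are dropped with
a warning: the analysis operates on lateral-view 2D projections.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from lxml import etree

from .embryo_geometry import EmbryoGeometry

__all__ = [
    "Track",
    "TrackSet",
    "TrackSchemaError",
    "read_trackmate_xml",
    "read_tracks_csv",
    "write_tracks_csv",
]

log = logging.getLogger(__name__)

FATES = ("alive", "divided", "died")


class TrackSchemaError(ValueError):
    """Input track data violates the expected schema."""


@dataclass
class Track:
    """One cell trajectory: strictly increasing times and 2D positions."""

    track_id: str
    t: np.ndarray  # minutes, shape (n,)
    xy: np.ndarray  # shape (n, 2)
    parent_id: str | None = None  # set for daughters of a division
    fate: str = "alive"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, float)
        self.xy = np.asarray(self.xy, float).reshape(-1, 2)
        if self.t.size == 0:
            raise ValueError(f"track {self.track_id}: needs at least one point")
        if self.t.size != len(self.xy):
            raise ValueError(f"track {self.track_id}: t and xy length mismatch")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError(
                f"track {self.track_id}: timestamps not strictly increasing"
            )
        if self.fate not in FATES:
            raise ValueError(f"track {self.track_id}: unknown fate {self.fate!r}")

    @property
    def n_points(self) -> int:
        return int(self.t.size)

    def shifted(self, dt: float) -> "Track":
        return replace(self, t=self.t - dt)


@dataclass
class TrackSet:
    """All tracks of one embryo plus acquisition and genotype metadata."""

    embryo_id: str
    genotype: str
    tracks: list[Track]
    geometry: EmbryoGeometry | None = None
    internalization_onset: float | None = None  # minutes
    frame_interval: float = field(default=1.0)  # minutes; ≤3 in the acquisitions

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        ids = [tr.track_id for tr in self.tracks]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate track_ids in TrackSet")

    def __len__(self) -> int:
        return len(self.tracks)

    def __iter__(self):
        return iter(self.tracks)


# -- TrackMate XML ----------------------------------------------------------

_TIME_TO_MIN = {
    "min": 1.0, "minute": 1.0, "minutes": 1.0,
    "s": 1 / 60, "sec": 1 / 60, "second": 1 / 60, "seconds": 1 / 60,
    "ms": 1 / 60000, "frame": None,
}


def read_trackmate_xml(
    path,
    *,
    embryo_id: str | None = None,
    genotype: str = "unknown",
    geometry: EmbryoGeometry | None = None,
    internalization_onset: float | None = None,
    frame_interval: float | None = None,
) -> TrackSet:
    """Parse the spot/edge core of a TrackMate XML export.

    One :class:`Track` is produced per linear branch: a division (a spot
    with two outgoing edges) ends the parent track and starts two daughter
    tracks carrying ``parent_id``.  Merges (two incoming edges) are
    rejected — the biology here has divisions, not fusions.

    Spot times are converted to minutes from the file's declared time
    units; ``frame_interval`` (minutes) overrides this by rescaling frame
    indices, and is required when the file declares frame units.
    """
    path = Path(path)
    root = etree.parse(str(path)).getroot()
    log.info("TrackMate file %s declares version %r", path.name, root.get("version"))

    model = root.find("Model")
    if model is None:
        raise TrackSchemaError("no <Model> element")
    spots_el = model.find("AllSpots")
    if spots_el is None:
        raise TrackSchemaError("missing <AllSpots> element")
    tracks_el = model.find("AllTracks")
    if tracks_el is None:
        raise TrackSchemaError("missing <AllTracks> element")

    tunit = (model.get("timeunits") or "min").lower()
    if tunit not in _TIME_TO_MIN:
        raise TrackSchemaError(f"unsupported time units {tunit!r}")
    tscale = _TIME_TO_MIN[tunit]
    if tscale is None and frame_interval is None:
        raise TrackSchemaError(
            "file declares frame time units; frame_interval (minutes) required"
        )

    spots: dict[str, tuple[float, float, float]] = {}  # id -> (t_min, x, y)
    saw_z = False
    for sp in spots_el.iter("Spot"):
        sid = sp.get("ID")
        if sid in spots:
            raise TrackSchemaError(f"duplicate spot id {sid}")
        if tscale is None:
            t = float(sp.get("FRAME", sp.get("POSITION_T"))) * frame_interval
        else:
            t = float(sp.get("POSITION_T")) * tscale
        x, y = float(sp.get("POSITION_X")), float(sp.get("POSITION_Y"))
        if sp.get("POSITION_Z") not in (None, "0.0", "0"):
            saw_z = True
        spots[sid] = (t, x, y)
    if saw_z:
        warnings.warn(
            "z coordinates present in TrackMate file; dropped (2D analysis)",
            stacklevel=2,
        )

    out: list[Track] = []
    for tr_el in tracks_el.iter("Track"):
        name = tr_el.get("name") or tr_el.get("TRACK_ID") or str(len(out))
        succ: dict[str, list[str]] = {}
        pred: dict[str, list[str]] = {}
        nodes: set[str] = set()
        for e in tr_el.iter("Edge"):
            s, tgt = e.get("SPOT_SOURCE_ID"), e.get("SPOT_TARGET_ID")
            for sid in (s, tgt):
                if sid not in spots:
                    raise TrackSchemaError(f"edge references unknown spot {sid}")
            # orient each edge forward in time
            if spots[s][0] > spots[tgt][0]:
                s, tgt = tgt, s
            succ.setdefault(s, []).append(tgt)
            pred.setdefault(tgt, []).append(s)
            nodes.update((s, tgt))
        if not nodes:  # a track with a single spot and no edges is legal
            continue
        for sid, ps in pred.items():
            if len(ps) > 1:
                raise TrackSchemaError(
                    f"track {name}: spot {sid} has {len(ps)} incoming edges "
                    "(merge events are not supported)"
                )
        roots = [n for n in nodes if n not in pred]
        branch_no = 0
        # walk each linear branch; a 2+-way split ends the branch
        stack: list[tuple[str, str | None]] = [(r, None) for r in sorted(roots)]
        while stack:
            node, parent_branch = stack.pop()
            chain = [node]
            while len(succ.get(chain[-1], [])) == 1:
                chain.append(succ[chain[-1]][0])
            branch_id = f"{name}.{branch_no}" if (branch_no or parent_branch) else name
            branch_no += 1
            pts = sorted(spots[sid] for sid in chain)
            t = np.array([p[0] for p in pts])
            if np.any(np.diff(t) <= 0):
                raise TrackSchemaError(
                    f"track {name}: non-monotone spot times along branch"
                )
            children = succ.get(chain[-1], [])
            fate = "divided" if len(children) >= 2 else "alive"
            out.append(
                Track(
                    track_id=branch_id,
                    t=t,
                    xy=np.array([(p[1], p[2]) for p in pts]),
                    parent_id=parent_branch,
                    fate=fate,
                )
            )
            for ch in children:
                stack.append((ch, branch_id))

    # single-spot tracks: spots never referenced by any edge
    used = set()
    for tr_el in tracks_el.iter("Track"):
        for e in tr_el.iter("Edge"):
            used.add(e.get("SPOT_SOURCE_ID"))
            used.add(e.get("SPOT_TARGET_ID"))
    # reorient: used ids may have been swapped, but the set is the same
    lonely = [sid for sid in spots if sid not in used]
    for sid in lonely:
        t, x, y = spots[sid]
        out.append(Track(track_id=f"spot-{sid}", t=np.array([t]), xy=np.array([[x, y]])))

    return TrackSet(
        embryo_id=embryo_id or path.stem,
        genotype=genotype,
        tracks=out,
        geometry=geometry,
        internalization_onset=internalization_onset,
        frame_interval=frame_interval
        if frame_interval is not None
        else _infer_frame_interval(out),
    )


def _infer_frame_interval(tracks: list[Track]) -> float:
    diffs = np.concatenate([np.diff(tr.t) for tr in tracks if tr.n_points > 1] or [[1.0]])
    return float(np.min(diffs)) if diffs.size else 1.0


# -- CSV dialect ------------------------------------------------------------

_CSV_REQUIRED = ["track_id", "t_min", "x", "y"]


def read_tracks_csv(
    path,
    *,
    embryo_id: str | None = None,
    genotype: str = "unknown",
    geometry: EmbryoGeometry | None = None,
    internalization_onset: float | None = None,
    frame_interval: float | None = None,
) -> TrackSet:
    """Read the plain CSV track dialect.

    Required columns: ``track_id, t_min, x, y``; optional ``parent_id`` and
    ``fate``.  Rows out of time order within a track are sorted with a
    warning.  An empty file with a header yields a TrackSet of 0 tracks.
    """
    df = pd.read_csv(path, dtype={"track_id": str})
    missing = [c for c in _CSV_REQUIRED if c not in df.columns]
    if missing:
        raise TrackSchemaError(f"track CSV missing columns: {missing}")
    if "z" in df.columns and df["z"].abs().sum() > 0:
        warnings.warn("z column present in track CSV; dropped (2D analysis)",
                      stacklevel=2)
    tracks: list[Track] = []
    for tid, grp in df.groupby("track_id", sort=True):
        if not grp["t_min"].is_monotonic_increasing:
            warnings.warn(
                f"track {tid}: rows out of time order; reordered", stacklevel=2
            )
            grp = grp.sort_values("t_min")
        parent = None
        if "parent_id" in grp.columns and pd.notna(grp["parent_id"].iloc[0]):
            parent = str(grp["parent_id"].iloc[0])
        fate = "alive"
        if "fate" in grp.columns and pd.notna(grp["fate"].iloc[0]):
            fate = str(grp["fate"].iloc[0])
        tracks.append(
            Track(
                track_id=str(tid),
                t=grp["t_min"].to_numpy(float),
                xy=grp[["x", "y"]].to_numpy(float),
                parent_id=parent,
                fate=fate,
            )
        )
    return TrackSet(
        embryo_id=embryo_id or Path(path).stem,
        genotype=genotype,
        tracks=tracks,
        geometry=geometry,
        internalization_onset=internalization_onset,
        frame_interval=frame_interval or _infer_frame_interval(tracks),
    )


def write_tracks_csv(ts: TrackSet, path) -> None:
    """Write a TrackSet in the CSV dialect (6 significant digits)."""
    rows = []
    for tr in ts.tracks:
        for (t, (x, y)) in zip(tr.t, tr.xy):
            rows.append(
                {
                    "track_id": tr.track_id,
                    "t_min": t,
                    "x": x,
                    "y": y,
                    "parent_id": tr.parent_id if tr.parent_id is not None else "",
                    "fate": tr.fate,
                }
            )
    cols = ["track_id", "t_min", "x", "y", "parent_id", "fate"]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False, float_format="%.6g")


def tracks_to_frame(ts: TrackSet) -> pd.DataFrame:
    """Long-format view of a TrackSet (one row per point)."""
    rows = []
    for tr in ts.tracks:
        for (t, (x, y)) in zip(tr.t, tr.xy):
            rows.append((ts.embryo_id, ts.genotype, tr.track_id, t, x, y))
    return pd.DataFrame(
        rows, columns=["embryo_id", "genotype", "track_id", "t_min", "x", "y"]
    )
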