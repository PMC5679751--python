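"""Proliferation and death quantification from tracked lineages.

Endodermal proliferation is scored in discrete observation windows (three
in the original acquisitions, spanning 20, 54 and 20 frames): the percent
proliferation of a window is 100 × divisions / cells present at the
window's start, and the per-embryo value is the unweighted mean over
windows.  Cells born from a division mid-window are counted in the
starting population of the next window only.  Deaths are summarized as a
per-embryo count and fraction of tracked cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .track_io import TrackSet

__all__ = [
    "ObservationWindow",
    "proliferation_rate",
    "embryo_proliferation",
    "observe_windows",
    "death_summary",
]

DEFAULT_FRAME_SPANS = (20, 54, 20)  # frames per observation window


@dataclass(frozen=True)
class ObservationWindow:
    index: int
    start: float  # minutes
    end: float
    n_cells_at_start: int
    n_divisions: int
    n_deaths: int

    def __post_init__(self) -> None:
        if min(self.n_cells_at_start, self.n_divisions, self.n_deaths) < 0:
            raise ValueError("window counts must be non-negative")


def proliferation_rate(win: ObservationWindow) -> float:
    """Percent proliferation: 100 × divisions / cells at window start."""
    if win.n_cells_at_start == 0:
        raise ValueError(f"window {win.index}: zero cells at start")
    return 100.0 * win.n_divisions / win.n_cells_at_start


def embryo_proliferation(
    wins: list[ObservationWindow], *, n_windows: int = 3
) -> float:
    """Per-embryo percent proliferation: mean over the observation windows."""
    if len(wins) != n_windows:
        raise ValueError(f"expected {n_windows} windows, got {len(wins)}")
    return float(np.mean([proliferation_rate(w) for w in wins]))


def observe_windows(
    ts: TrackSet,
    frame_spans: tuple[int, ...] = DEFAULT_FRAME_SPANS,
    *,
    start: float = 0.0,
) -> list[ObservationWindow]:
    """Count divisions and deaths of a TrackSet in consecutive windows.

    Window boundaries are ``start`` plus cumulative ``frame_spans`` times
    the frame interval.  A track's division (fate ``divided``) or death
    (fate ``died``) is dated at its last timestamp.  A cell counts toward
    a window's starting population when its track spans the window start.
    """
    bounds = start + np.concatenate(
        [[0.0], np.cumsum(np.asarray(frame_spans, float) * ts.frame_interval)]
    )
    wins = []
    for i in range(len(frame_spans)):
        lo, hi = bounds[i], bounds[i + 1]
        n_start = sum(1 for tr in ts.tracks if tr.t[0] <= lo <= tr.t[-1])
        n_div = sum(
            1
            for tr in ts.tracks
            if tr.fate == "divided" and lo <= tr.t[-1] < hi
        )
        n_die = sum(
            1 for tr in ts.tracks if tr.fate == "died" and lo <= tr.t[-1] < hi
        )
        wins.append(
            ObservationWindow(
                index=i,
                start=float(lo),
                end=float(hi),
                n_cells_at_start=n_start,
                n_divisions=n_div,
                n_deaths=n_die,
            )
        )
    return wins


def death_summary(ts: TrackSet) -> tuple[int, float]:
    """Per-embryo death count and fraction of tracked cells that died."""
    n = len(ts.tracks)
    deaths = sum(1 for tr in ts.tracks if tr.fate == "died")
    return deaths, (deaths / n if n else 0.0)


def events_table(ts: TrackSet, wins: list[ObservationWindow] | None = None) -> pd.DataFrame:
    """Tidy per-event table (division/death) with optional window index."""
    rows = []
    for tr in ts.tracks:
        if tr.fate not in ("divided", "died"):
            continue
        t_ev = float(tr.t[-1])
        w_idx = None
        if wins:
            for w in wins:
                if w.start <= t_ev < w.end:
                    w_idx = w.index
                    break
        rows.append(
            {
                "embryo_id": ts.embryo_id,
                "track_id": tr.track_id,
                "event": "division" if tr.fate == "divided" else "death",
                "t_min": t_ev,
                "window_index": w_idx,
            }
        )
    return pd.DataFrame(
        rows, columns=["embryo_id", "track_id", "event", "t_min", "window_index"]
    )
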