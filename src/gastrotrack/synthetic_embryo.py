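"""Synthetic embryo generator.

Produces track sets, snapshot position records and lineage events with the
statistical structure the analysis pipeline is designed to detect, so the
whole pipeline is testable without microscopy data.

The model is a biased random walk in the 2D lateral plane: cells start in
a band near the margin (low percent embryo height) and each frame take a
step ``drift · Δt + N(0, σ²I)``, where the drift vector points animally
(and optionally dorsally/vegetally) in the anatomical frame.  The
wild-type preset migrates animally faster than the mutant preset, which
has reduced animal drift and smaller steps — the qualitative genotype
contrast of impaired animal-pole-directed migration.  Division splits a
track into two daughters at a frame boundary; death terminates a track.
Both are scheduled per observation window with fixed per-window
probabilities, so division probability is directly recoverable by the
proliferation metrics.

No cell–cell interactions, no epiboly surface flow, no confinement to the
embryo outline: the minimal model whose summary statistics (speed,
straightness, directional bias) are well defined analytically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np
from scipy import stats

from .embryo_geometry import CellPosition, EmbryoGeometry, OutOfEmbryoError
from .position_analysis import EmbryoCellRecord
from .track_io import Track, TrackSet

__all__ = [
    "SimulationParams",
    "GENOTYPE_PRESETS",
    "params_for",
    "simulate_tracks",
    "simulate_snapshot",
    "expected_speed",
]


@dataclass(frozen=True)
class SimulationParams:
    """Biased-random-walk simulation settings.

    Units: minutes, µm.  Defaults emulate a 180-min lateral-view
    acquisition (~50% → 85% epiboly) at 2-min frame intervals, with
    animal-ward drift typical of internalized mesendoderm.
    """

    n_cells: int = 100
    duration: float = 180.0  # minutes, ~50% to ~85% epiboly
    frame_interval: float = 2.0  # minutes (acquisitions used <= 3)
    drift_animal: float = 0.4  # µm/min toward the animal pole
    drift_dorsal: float = 0.0  # µm/min toward dorsal
    drift_vegetal: float = 0.0  # µm/min toward vegetal (opposes animal)
    noise_sigma: float = 1.5  # µm per step, isotropic
    division_prob_per_window: float = 0.05
    death_prob_per_window: float = 0.02
    n_event_windows: int = 3
    height: float = 600.0  # µm, animal-vegetal extent
    width: float = 600.0  # µm, lateral extent
    start_height_band: tuple[float, float] = (5.0, 20.0)  # percent height
    start_lateral_band: tuple[float, float] = (-0.25, 0.25)  # width fraction
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.duration < self.frame_interval:
            raise ValueError("duration must cover at least one frame interval")
        for name in (
            "drift_animal", "drift_dorsal", "drift_vegetal", "noise_sigma",
            "division_prob_per_window", "death_prob_per_window",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_cells < 0 or self.n_event_windows < 1:
            raise ValueError("n_cells >= 0 and n_event_windows >= 1 required")
        if self.height <= 0 or self.width <= 0:
            raise ValueError("height and width must be positive")

    @property
    def n_frames(self) -> int:
        """Number of steps; positions exist at frames 0..n_frames."""
        return int(np.floor(self.duration / self.frame_interval + 1e-9))

    def geometry(self) -> EmbryoGeometry:
        """Canonical frame: vegetal at origin, animal up, dorsal +x."""
        return EmbryoGeometry(
            animal_pole=np.array([0.0, self.height]),
            vegetal_pole=np.array([0.0, 0.0]),
            dorsal_ref=np.array([self.width / 2, self.height / 2]),
            height=self.height,
            width=self.width,
        )

    def drift_step(self) -> np.ndarray:
        """Deterministic per-frame displacement in image coordinates."""
        return (
            np.array([self.drift_dorsal, self.drift_animal - self.drift_vegetal])
            * self.frame_interval
        )


# Presets encode the genotype contrast the time-lapse comparisons probe:
# mutants migrate animally less and move with smaller steps.
GENOTYPE_PRESETS: dict[str, dict[str, Any]] = {
    "wildtype": {},
    "mutant": {
        "drift_animal": 0.1,
        "noise_sigma": 1.5 * 0.8,
        "death_prob_per_window": 0.06,
    },
}


def params_for(genotype: str, **overrides) -> SimulationParams:
    """SimulationParams for a named genotype preset, with overrides."""
    if genotype not in GENOTYPE_PRESETS:
        raise KeyError(
            f"unknown preset {genotype!r}; have {sorted(GENOTYPE_PRESETS)}"
        )
    kw = dict(GENOTYPE_PRESETS[genotype])
    kw.update(overrides)
    return SimulationParams(**kw)


def _window_start_frames(p: SimulationParams) -> np.ndarray:
    """Frame index at which each event window begins."""
    return np.floor(
        np.linspace(0, p.n_frames, p.n_event_windows + 1)[:-1]
    ).astype(int)


def simulate_tracks(
    p: SimulationParams,
    *,
    embryo_id: str = "sim",
    genotype: str = "wildtype",
) -> TrackSet:
    """Simulate one embryo's track set; fully reproducible from the seed.

    Cells present at an event-window start draw division and death fates
    with the per-window probabilities; the event is placed at a uniformly
    chosen frame within the window (earlier event wins if both occur).
    Daughters of a division start one noise step away from the split
    position and become eligible for events at the next window start.
    """
    rng = np.random.default_rng(p.seed)
    n_frames = p.n_frames
    win_starts = _window_start_frames(p)
    drift = p.drift_step()

    # initial positions: a band just above the margin, centered laterally
    lo_h, hi_h = p.start_height_band
    lo_l, hi_l = p.start_lateral_band
    y0 = rng.uniform(lo_h / 100.0, hi_h / 100.0, p.n_cells) * p.height
    x0 = rng.uniform(lo_l, hi_l, p.n_cells) * p.width

    tracks: list[Track] = []
    # FIFO queue keeps rng draw order deterministic
    queue: list[tuple[str, int, np.ndarray, str | None]] = [
        (f"c{i:04d}", 0, np.array([x0[i], y0[i]]), None) for i in range(p.n_cells)
    ]
    qi = 0
    while qi < len(queue):
        tid, birth, pos0, parent = queue[qi]
        qi += 1
        # schedule the first event in an eligible window, if any
        end_frame, fate = n_frames, "alive"
        for w, ws in enumerate(win_starts):
            if ws < birth:
                continue
            we = win_starts[w + 1] if w + 1 < len(win_starts) else n_frames
            if we <= ws:
                continue
            divides = rng.random() < p.division_prob_per_window
            dies = rng.random() < p.death_prob_per_window
            f_div = int(rng.integers(ws, we)) if divides else None
            f_die = int(rng.integers(ws, we)) if dies else None
            if dies and (not divides or f_die <= f_div):
                end_frame, fate = f_die, "died"
                break
            if divides:
                end_frame, fate = f_div, "divided"
                break
        n_steps = end_frame - birth
        steps = drift + rng.normal(0.0, p.noise_sigma, (n_steps, 2))
        xy = np.vstack([pos0, pos0 + np.cumsum(steps, axis=0)]) if n_steps else pos0[None, :]
        t = (birth + np.arange(n_steps + 1)) * p.frame_interval
        tracks.append(Track(track_id=tid, t=t, xy=xy, parent_id=parent, fate=fate))
        if fate == "divided" and end_frame + 1 <= n_frames:
            for d in range(2):
                dpos = xy[-1] + drift + rng.normal(0.0, p.noise_sigma, 2)
                queue.append((f"{tid}.{d}", end_frame + 1, dpos, tid))
        elif fate == "divided":
            # split scheduled at the final frame: daughters unobservable
            tracks[-1] = replace(tracks[-1], fate="alive")

    return TrackSet(
        embryo_id=embryo_id,
        genotype=genotype,
        tracks=tracks,
        geometry=p.geometry(),
        internalization_onset=0.0,
        frame_interval=p.frame_interval,
    )


def simulate_snapshot(
    p: SimulationParams,
    stage_time: float,
    *,
    embryo_id: str = "sim",
    genotype: str = "wildtype",
    marker: str = "sox17",
) -> EmbryoCellRecord:
    """Cell positions at one stage, as a snapshot record.

    Runs the track simulation and reads off every live cell's position at
    the frame nearest ``stage_time``.  Cells that have wandered outside
    the embryo's height range are clipped out with a warning.
    """
    if not (0.0 <= stage_time <= p.duration):
        raise ValueError(
            f"stage_time {stage_time} outside simulated range [0, {p.duration}]"
        )
    ts = simulate_tracks(p, embryo_id=embryo_id, genotype=genotype)
    geom = p.geometry()
    t_snap = round(stage_time / p.frame_interval) * p.frame_interval
    cells: list[CellPosition] = []
    n_clipped = 0
    for tr in ts.tracks:
        if not (tr.t[0] <= t_snap <= tr.t[-1]):
            continue
        k = int(round((t_snap - tr.t[0]) / p.frame_interval))
        try:
            cells.append(CellPosition.from_xy(tr.xy[k], geom))
        except OutOfEmbryoError:
            n_clipped += 1
    if n_clipped:
        warnings.warn(
            f"{n_clipped} cells outside the embryo at t={t_snap} min; clipped",
            stacklevel=2,
        )
    return EmbryoCellRecord(
        embryo_id=embryo_id,
        genotype=genotype,
        marker=marker,
        cells=cells,
        geometry=geom,
    )


def expected_speed(p: SimulationParams) -> float:
    """Analytic mean pipeline speed (µm/min) under the step model.

    A step is drift·Δt plus isotropic Gaussian noise, so its magnitude is
    Rice-distributed with ν = |drift|·Δt and scale σ.  The pipeline speed
    is mean step magnitude over Δt; for σ → 0 this is the drift magnitude
    and for pure noise the Rayleigh mean σ√(π/2)/Δt.
    """
    nu = float(np.linalg.norm(p.drift_step()))
    if p.noise_sigma == 0:
        return nu / p.frame_interval
    mean_mag = stats.rice.mean(b=nu / p.noise_sigma, scale=p.noise_sigma)
    return float(mean_mag) / p.frame_interval
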