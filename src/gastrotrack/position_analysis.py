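"""Snapshot position analyses.

From stained lateral-view snapshots, cell positions are normalized to
percent embryo height and restricted to a lateral window — cells on or
within 10% of the embryo width from the center of the lateral side.  On
that selection the module computes: per-embryo cell counts (a proxy for
endodermal cell number), pooled percent-height position distributions,
the per-embryo leading-edge height (most animally positioned marker+
cells), and unpaired two-tailed t-test group comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .embryo_geometry import CellPosition, EmbryoGeometry

__all__ = [
    "EmbryoCellRecord",
    "PositionDistribution",
    "select_lateral_cells",
    "count_lateral_cells",
    "position_distribution",
    "leading_edge_height",
    "compare_groups",
]

DEFAULT_HALF_WIDTH_FRAC = 0.10  # lateral window: |offset| <= 10% embryo width
DEFAULT_BIN_WIDTH_PERCENT = 5.0


@dataclass
class EmbryoCellRecord:
    """Marker-positive cells of one embryo, sharing one geometry."""

    embryo_id: str
    genotype: str
    marker: str  # e.g. "sox17" (endoderm) or "fn1a" (mesoderm)
    cells: list[CellPosition]
    geometry: EmbryoGeometry | None = None

    def __len__(self) -> int:
        return len(self.cells)


@dataclass(frozen=True)
class PositionDistribution:
    """Proportion of cells per percent-embryo-height bin, pooled."""

    bin_edges: np.ndarray  # over [0, 100]
    frequencies: np.ndarray  # proportions summing to 1
    n_cells: int


def select_lateral_cells(
    rec: EmbryoCellRecord, half_width_frac: float = DEFAULT_HALF_WIDTH_FRAC
) -> list[CellPosition]:
    """Cells on or within ``half_width_frac`` of width from the lateral center.

    The boundary is closed: an offset of exactly the threshold is kept.
    """
    return [c for c in rec.cells if abs(c.lateral_offset) <= half_width_frac]


def count_lateral_cells(
    rec: EmbryoCellRecord, half_width_frac: float = DEFAULT_HALF_WIDTH_FRAC
) -> int:
    """Number of cells in the lateral window (cell-number proxy)."""
    return len(select_lateral_cells(rec, half_width_frac))


def position_distribution(
    recs: list[EmbryoCellRecord],
    bin_width_percent: float = DEFAULT_BIN_WIDTH_PERCENT,
    *,
    half_width_frac: float = DEFAULT_HALF_WIDTH_FRAC,
    lateral_only: bool = True,
) -> PositionDistribution:
    """Histogram of percent-height positions pooled across embryos.

    Each embryo contributes its (laterally selected) cells, not an
    embryo-average, and the pooled histogram is normalized to proportions.
    """
    heights = []
    for rec in recs:
        cells = select_lateral_cells(rec, half_width_frac) if lateral_only else rec.cells
        heights.extend(c.relative_height for c in cells)
    if not heights:
        raise ValueError("no cells after lateral selection")
    n_bins = int(np.ceil(100.0 / bin_width_percent))
    edges = np.linspace(0.0, n_bins * bin_width_percent, n_bins + 1)
    counts, _ = np.histogram(heights, bins=edges)
    # np.histogram treats the last bin as closed, so height 100 is included
    return PositionDistribution(
        bin_edges=edges,
        frequencies=counts / counts.sum(),
        n_cells=len(heights),
    )


def leading_edge_height(
    rec: EmbryoCellRecord,
    k: int = 1,
    *,
    half_width_frac: float = DEFAULT_HALF_WIDTH_FRAC,
    lateral_only: bool = False,
) -> float:
    """Mean percent height of the k most animally positioned cells.

    With the default k = 1 this is the height of the single front cell —
    the per-embryo migration readout that enters group comparisons.
    Mesoderm leading-edge measurements use all recorded cells
    (``lateral_only=False``); pass ``lateral_only=True`` to restrict to
    the lateral window first.
    """
    cells = select_lateral_cells(rec, half_width_frac) if lateral_only else rec.cells
    if len(cells) < k:
        raise ValueError(
            f"embryo {rec.embryo_id}: {len(cells)} cells available, k={k} requested"
        )
    heights = sorted((c.relative_height for c in cells), reverse=True)
    return float(np.mean(heights[:k]))


def compare_groups(
    values_a, values_b, *, welch: bool = False
) -> tuple[float, float]:
    """Unpaired two-tailed t-test between two per-embryo value lists.

    Student's equal-variance test by default; ``welch=True`` switches to
    the Welch unequal-variance form.  Returns ``(t, p)``.
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if np.var(a, ddof=1) + np.var(b, ddof=1) == 0:
        if np.all(a == b[0]) and np.all(b == a[0]):
            # identical constant groups: no difference by construction
            return 0.0, 1.0
        raise ValueError("degenerate (zero) variance in both groups")
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p)


def comparison_table(groups: dict[str, np.ndarray], *, welch: bool = False) -> pd.DataFrame:
    """All pairwise group comparisons as a tidy table."""
    names = list(groups)
    rows = []
    for i, ga in enumerate(names):
        for gb in names[i + 1 :]:
            t, p = compare_groups(groups[ga], groups[gb], welch=welch)
            rows.append(
                {
                    "group_a": ga,
                    "group_b": gb,
                    "n_a": len(groups[ga]),
                    "n_b": len(groups[gb]),
                    "t": t,
                    "p": p,
                }
            )
    return pd.DataFrame(rows, columns=["group_a", "group_b", "n_a", "n_b", "t", "p"])
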