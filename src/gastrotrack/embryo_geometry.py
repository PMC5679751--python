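"""Embryo coordinate frame and conversions between image and anatomical axes.

The early zebrafish embryo is described by two anatomical axes: the
animal–vegetal (AV) axis running between the two poles, and the
dorsal–ventral axis perpendicular to it.  Positions measured on lateral-view
micrographs are normalized onto these axes:

* *percent embryo height* — linear position along the AV axis, with the
  vegetal pole at 0% and the animal pole at 100%;
* *lateral offset* — signed perpendicular distance from the AV axis,
  expressed as a fraction of embryo width (positive toward dorsal).

The lateral view is treated as a flat 2D plane, matching what measurements
on maximum-intensity projections deliver; no spherical correction is
applied.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "EmbryoGeometry",
    "CellPosition",
    "DirectionConvention",
    "OutOfEmbryoError",
    "relative_height",
    "lateral_offset",
    "movement_angle",
    "read_landmarks",
]


class OutOfEmbryoError(ValueError):
    """A position projects outside the embryo beyond tolerance."""


CARDINAL_LABELS = ("dorsal", "animal", "ventral", "vegetal")


@dataclass(frozen=True)
class DirectionConvention:
    """Mapping from anatomical directions to plot angles.

    Defaults place dorsal at 0° and animal at 90°, increasing
    counter-clockwise, so the four cardinal anatomical directions sit at
    90° spacing: dorsal 0°, animal 90°, ventral 180°, vegetal 270°.
    """

    zero_axis: str = "dorsal"
    orientation: str = "ccw"  # "ccw" or "cw"
    labels: tuple[str, str, str, str] = CARDINAL_LABELS

    def __post_init__(self) -> None:
        if set(self.labels) != set(CARDINAL_LABELS):
            raise ValueError(
                f"labels must be the four cardinal directions {CARDINAL_LABELS}"
            )
        if self.zero_axis not in self.labels:
            raise ValueError(f"zero_axis {self.zero_axis!r} not among labels")
        if self.orientation not in ("ccw", "cw"):
            raise ValueError("orientation must be 'ccw' or 'cw'")

    def angle_of(self, direction: str) -> float:
        """Plot angle in degrees of a cardinal anatomical direction."""
        # canonical ccw order starting from dorsal
        order = ("dorsal", "animal", "ventral", "vegetal")
        base = {d: 90.0 * i for i, d in enumerate(order)}
        raw = base[direction] - base[self.zero_axis]
        if self.orientation == "cw":
            raw = -raw
        return raw % 360.0


@dataclass(frozen=True)
class EmbryoGeometry:
    """Landmark frame of one embryo on a lateral-view image.

    All coordinates share one unit (canonically µm).  ``height`` is the
    animal→vegetal distance along the AV axis and ``width`` the lateral
    extent perpendicular to it.  ``lateral_center``, the center of the
    lateral side 90° from dorsal, defaults to the midpoint of the AV
    segment (the projection of that point into the lateral view).
    """

    animal_pole: np.ndarray
    vegetal_pole: np.ndarray
    dorsal_ref: np.ndarray
    height: float
    width: float
    lateral_center: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        for name in ("animal_pole", "vegetal_pole", "dorsal_ref"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), float))
        if self.height <= 0 or self.width <= 0:
            raise ValueError("height and width must be positive")
        if np.allclose(self.animal_pole, self.vegetal_pole):
            raise ValueError("animal and vegetal poles coincide")
        if abs(self._dorsal_side_sign()) < 1e-12:
            raise ValueError("dorsal_ref lies on the AV axis; dorsal unresolvable")
        if self.lateral_center is None:
            mid = 0.5 * (self.animal_pole + self.vegetal_pole)
            object.__setattr__(self, "lateral_center", mid)
        else:
            object.__setattr__(
                self, "lateral_center", np.asarray(self.lateral_center, float)
            )

    # -- anatomical unit vectors -------------------------------------------
    @property
    def animal_axis(self) -> np.ndarray:
        """Unit vector pointing from the vegetal toward the animal pole."""
        v = self.animal_pole - self.vegetal_pole
        return v / np.linalg.norm(v)

    @property
    def dorsal_axis(self) -> np.ndarray:
        """Unit vector perpendicular to the AV axis, pointing dorsally."""
        a = self.animal_axis
        perp = np.array([-a[1], a[0]])
        return perp * self._dorsal_side_sign(perp)

    def _dorsal_side_sign(self, perp: np.ndarray | None = None) -> float:
        a = self.animal_pole - self.vegetal_pole
        a = a / np.linalg.norm(a)
        if perp is None:
            perp = np.array([-a[1], a[0]])
        s = float(np.dot(self.dorsal_ref - self.vegetal_pole, perp))
        return np.sign(s) if s != 0 else 0.0

    @property
    def axis_length(self) -> float:
        """Measured animal–vegetal pole distance (should equal ``height``)."""
        return float(np.linalg.norm(self.animal_pole - self.vegetal_pole))


def relative_height(
    pos, geom: EmbryoGeometry, *, tol_percent: float = 1.0
) -> float:
    """Position along the AV axis as percent embryo height.

    The point is projected linearly onto the animal–vegetal segment and
    scaled so the vegetal pole maps to 0 and the animal pole to 100.
    Projections outside ``[-tol, 100 + tol]`` (``tol`` in percent of
    height, default 1) raise :class:`OutOfEmbryoError`; projections inside
    the tolerance band are clipped to [0, 100].
    """
    pos = np.asarray(pos, float)
    frac = (
        np.dot(pos - geom.vegetal_pole, geom.animal_axis) / geom.axis_length
    )
    pct = 100.0 * frac
    if pct < -tol_percent or pct > 100.0 + tol_percent:
        raise OutOfEmbryoError(
            f"position projects to {pct:.2f}% embryo height, outside "
            f"[-{tol_percent}, {100 + tol_percent}]"
        )
    return float(np.clip(pct, 0.0, 100.0))


def lateral_offset(pos, geom: EmbryoGeometry) -> float:
    """Signed perpendicular distance from the AV axis, as fraction of width.

    Positive values lie on the dorsal side.  A cell exactly on the axis
    (through ``lateral_center``) has offset 0.
    """
    pos = np.asarray(pos, float)
    return float(np.dot(pos - geom.lateral_center, geom.dorsal_axis) / geom.width)


def movement_angle(
    step,
    conv: DirectionConvention | None = None,
    geom: EmbryoGeometry | None = None,
) -> float:
    """Angle of a displacement step in the anatomical compass frame.

    With default convention: dorsal = 0°, animal = 90°, ventral = 180°,
    vegetal = 270° (counter-clockwise).  If ``geom`` is given the step is
    first expressed in its anatomical basis; otherwise the image +x axis
    is taken as dorsal and +y as animal.  Zero-length steps have no
    direction and raise ``ValueError``.
    """
    conv = conv or DirectionConvention()
    step = np.asarray(step, float)
    if np.linalg.norm(step) == 0:
        raise ValueError("zero-length step has undefined movement angle")
    if geom is not None:
        comp_dorsal = float(np.dot(step, geom.dorsal_axis))
        comp_animal = float(np.dot(step, geom.animal_axis))
    else:
        comp_dorsal, comp_animal = float(step[0]), float(step[1])
    # angle measured ccw from dorsal in the anatomical plane
    ang = np.degrees(np.arctan2(comp_animal, comp_dorsal))
    if conv.orientation == "cw":
        ang = -ang
    return float((ang + conv.angle_of("dorsal")) % 360.0)


@dataclass(frozen=True)
class CellPosition:
    """One cell on one embryo, with derived normalized coordinates."""

    xy: np.ndarray
    relative_height: float
    lateral_offset: float

    @classmethod
    def from_xy(
        cls, xy, geom: EmbryoGeometry, *, tol_percent: float = 1.0
    ) -> "CellPosition":
        xy = np.asarray(xy, float)
        return cls(
            xy=xy,
            relative_height=relative_height(xy, geom, tol_percent=tol_percent),
            lateral_offset=lateral_offset(xy, geom),
        )


# -- landmark sidecar -------------------------------------------------------

_LANDMARK_COLS = [
    "embryo_id",
    "genotype",
    "animal_x",
    "animal_y",
    "vegetal_x",
    "vegetal_y",
    "dorsal_x",
    "dorsal_y",
    "height",
    "width",
]

_UNIT_SCALE = {"um": 1.0, "µm": 1.0, "micron": 1.0, "mm": 1000.0, "px": 1.0}


def read_landmarks(path) -> dict[str, tuple[EmbryoGeometry, str]]:
    """Read a landmark sidecar (CSV or JSON) into per-embryo geometries.

    Returns a mapping ``embryo_id -> (EmbryoGeometry, genotype)``.  The
    canonical internal unit is µm; a ``units`` field ('um', 'mm', 'px')
    rescales coordinates on read.  Pixel units are accepted verbatim
    (downstream metrics are then in pixels).
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        units = payload.get("units", "um")
        rows = payload["embryos"]
        df = pd.DataFrame(rows)
    else:
        df = pd.read_csv(path, comment="#")
        units = "um"
        first = path.read_text().splitlines()[0]
        if first.startswith("#"):
            for tok in first[1:].replace(",", " ").split():
                if tok.startswith("units="):
                    units = tok.split("=", 1)[1]
    missing = [c for c in _LANDMARK_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"landmark sidecar missing columns: {missing}")
    scale = _UNIT_SCALE.get(units, 1.0)
    out: dict[str, tuple[EmbryoGeometry, str]] = {}
    for _, r in df.iterrows():
        geom = EmbryoGeometry(
            animal_pole=np.array([r.animal_x, r.animal_y], float) * scale,
            vegetal_pole=np.array([r.vegetal_x, r.vegetal_y], float) * scale,
            dorsal_ref=np.array([r.dorsal_x, r.dorsal_y], float) * scale,
            height=float(r.height) * scale,
            width=float(r.width) * scale,
        )
        out[str(r.embryo_id)] = (geom, str(r.genotype))
    return out
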