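"""Defect coordinate sets and their descriptive statistics.

A *defect* is a membrane-spanning pore observed in an AFM topography image of a
tethered bilayer lipid membrane (tBLM).  For detection purposes every defect is
represented by its center coordinates (nm) and a square bounding box of
half-width ``r_box`` (25 nm by default, i.e. a 50 nm x 50 nm box).  A
:class:`DefectSet` collects the defects found on one rectangular field together
with the field dimensions.

Two descriptive statistics characterise a set:

* the defect density ``N_def`` in defects per square micrometer, and
* the clustering statistic ``sigma`` -- the standard deviation of the
  field-clipped Voronoi cell areas normalised by the mean cell area
  (equivalently, multiplied by the defect density).  ``sigma = 0`` for a
  perfect lattice and grows with the strength of clustering; a homogeneous
  Poisson pattern sits near 0.53.

Coordinates use the image convention: origin at the top-left corner of the
field, x to the right, y downward, units of nanometers.  The default AFM pixel
pitch is 2000 nm / 512 px.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.spatial import Voronoi

from .exceptions import (
    DegenerateTessellationError,
    GeometryError,
    InsufficientPointsError,
    ValidationError,
)

#: nm per pixel of the source AFM scans (2 um imaged at 512 x 512).
PIXEL_SIZE_NM = 2000.0 / 512.0

#: half-width of the equalised detection bounding box (50 nm box -> 25 nm).
DEFAULT_R_BOX_NM = 25.0

NM2_PER_UM2 = 1.0e6


@dataclasses.dataclass(frozen=True)
class Defect:
    """A single membrane defect: center (nm) plus bounding-box half-width."""

    x: float
    y: float
    r_box: float = DEFAULT_R_BOX_NM

    def __post_init__(self) -> None:
        if not self.r_box > 0:
            raise ValidationError(f"r_box must be positive, got {self.r_box}")

    @property
    def bounding_box(self) -> "BoundingBox":
        return BoundingBox(
            self.x - self.r_box,
            self.y - self.r_box,
            self.x + self.r_box,
            self.y + self.r_box,
        )


@dataclasses.dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned rectangle in nm."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self) -> None:
        if not (self.x_max > self.x_min and self.y_max > self.y_min):
            raise ValidationError(f"degenerate bounding box {self}")

    @property
    def area(self) -> float:
        return (self.x_max - self.x_min) * (self.y_max - self.y_min)


class DefectSet:
    """An ordered collection of defects on a rectangular field.

    Parameters
    ----------
    defects
        Iterable of :class:`Defect`; all centers must lie inside
        ``[0, field_width] x [0, field_height]``.
    field_width, field_height
        Field dimensions in nm (must be positive).
    label
        Free-text tag carried through outputs.
    """

    def __init__(
        self,
        defects: Iterable[Defect],
        field_width: float,
        field_height: float,
        label: str = "",
    ) -> None:
        if not (field_width > 0 and field_height > 0):
            raise GeometryError(
                f"field must have positive area, got {field_width} x {field_height}"
            )
        self.defects: tuple[Defect, ...] = tuple(defects)
        self.field_width = float(field_width)
        self.field_height = float(field_height)
        self.label = label
        for i, d in enumerate(self.defects):
            if not (0.0 <= d.x <= field_width and 0.0 <= d.y <= field_height):
                raise ValidationError(
                    f"defect {i} at ({d.x}, {d.y}) outside "
                    f"[0, {field_width}] x [0, {field_height}]"
                )

    def __len__(self) -> int:
        return len(self.defects)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"DefectSet(N={len(self)}, field={self.field_width:g} x "
            f"{self.field_height:g} nm, label={self.label!r})"
        )

    @property
    def coordinates(self) -> np.ndarray:
        """(N, 2) array of center coordinates in nm."""
        if not self.defects:
            return np.empty((0, 2))
        return np.array([(d.x, d.y) for d in self.defects])

    @property
    def field_area_um2(self) -> float:
        return self.field_width * self.field_height / NM2_PER_UM2

    def with_defects(self, defects: Iterable[Defect], label: str | None = None) -> "DefectSet":
        """Copy of this set with the defects replaced."""
        return DefectSet(
            defects,
            self.field_width,
            self.field_height,
            self.label if label is None else label,
        )

    @classmethod
    def from_coordinates(
        cls,
        xy: np.ndarray,
        field_width: float,
        field_height: float,
        r_box: float = DEFAULT_R_BOX_NM,
        label: str = "",
    ) -> "DefectSet":
        xy = np.asarray(xy, dtype=float).reshape(-1, 2)
        return cls(
            (Defect(float(x), float(y), r_box) for x, y in xy),
            field_width,
            field_height,
            label,
        )


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def defect_density(defect_set: DefectSet) -> float:
    """Defect density ``N_def`` in defects per square micrometer."""
    return len(defect_set) / defect_set.field_area_um2


def clipped_voronoi_areas(defect_set: DefectSet) -> np.ndarray:
    """Areas (nm^2) of the Voronoi cells of the defect centers, clipped to the field.

    Clipping is exact: the point set is reflected across all four field edges
    before tessellating, so every original cell is bounded by the field
    rectangle and the areas sum to the field area to machine precision.
    """
    pts = defect_set.coordinates
    n = len(pts)
    if n < 3:
        raise InsufficientPointsError(
            f"Voronoi tessellation requires at least 3 defects, got {n}"
        )
    uniq = np.unique(pts, axis=0)
    if len(uniq) < n:
        raise DegenerateTessellationError(
            "duplicate defect coordinates break the tessellation"
        )
    w, h = defect_set.field_width, defect_set.field_height
    mirrored = np.vstack(
        [
            pts,
            pts * (-1.0, 1.0),
            pts * (1.0, -1.0),
            np.column_stack([2.0 * w - pts[:, 0], pts[:, 1]]),
            np.column_stack([pts[:, 0], 2.0 * h - pts[:, 1]]),
        ]
    )
    vor = Voronoi(mirrored)
    areas = np.empty(n)
    for i in range(n):
        region = vor.regions[vor.point_region[i]]
        poly = vor.vertices[region]
        x, y = poly[:, 0], poly[:, 1]
        areas[i] = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    return areas


def voronoi_sigma(defect_set: DefectSet) -> float:
    """Clustering statistic sigma: SD of normalised Voronoi cell areas.

    Each field-clipped cell area is multiplied by the defect density (i.e.
    divided by the mean cell area), so the normalised areas average to one and
    their standard deviation is scale-free.  Higher values indicate stronger
    clustering; a square lattice gives exactly 0.
    """
    areas = clipped_voronoi_areas(defect_set)
    normalized = areas * len(defect_set) / (defect_set.field_width * defect_set.field_height)
    return float(np.std(normalized, ddof=1))


# ---------------------------------------------------------------------------
# CSV + sidecar I/O
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".yaml")


def write_defects(defect_set: DefectSet, path: str | Path) -> None:
    """Write a defect CSV (header ``x_nm,y_nm,r_nm``) plus a YAML geometry sidecar."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "x_nm": [d.x for d in defect_set.defects],
            "y_nm": [d.y for d in defect_set.defects],
            "r_nm": [d.r_box for d in defect_set.defects],
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")
    sidecar = {
        "field_width_nm": defect_set.field_width,
        "field_height_nm": defect_set.field_height,
        "label": defect_set.label,
    }
    _sidecar_path(path).write_text(yaml.safe_dump(sidecar, sort_keys=False))


def read_defects(
    path: str | Path,
    field_width: float | None = None,
    field_height: float | None = None,
    label: str | None = None,
) -> DefectSet:
    """Read a defect CSV; field geometry comes from the YAML sidecar unless given."""
    path = Path(path)
    if field_width is None or field_height is None:
        sidecar_path = _sidecar_path(path)
        if not sidecar_path.exists():
            raise ValidationError(
                f"no field geometry: sidecar {sidecar_path} missing and no "
                "explicit dimensions given"
            )
        sidecar = yaml.safe_load(sidecar_path.read_text())
        field_width = float(sidecar["field_width_nm"])
        field_height = float(sidecar["field_height_nm"])
        if label is None:
            label = str(sidecar.get("label", ""))
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"x_nm", "y_nm"}
    if not required.issubset(df.columns):
        raise ValidationError(
            f"{path}: missing required columns {sorted(required - set(df.columns))}"
        )
    if "r_nm" not in df.columns:
        df["r_nm"] = DEFAULT_R_BOX_NM
    for col in ("x_nm", "y_nm", "r_nm"):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any() or numeric.isna().any():
            row = int(np.flatnonzero(numeric.isna())[0])
            raise ValidationError(f"{path}: non-numeric value in column {col}, row {row}")
        df[col] = numeric
    defects = []
    for i, row in enumerate(df.itertuples(index=False)):
        x, y, r = float(row.x_nm), float(row.y_nm), float(row.r_nm)
        if not (0.0 <= x <= field_width and 0.0 <= y <= field_height):
            raise ValidationError(
                f"{path}: row {i} at ({x}, {y}) outside field "
                f"[0, {field_width}] x [0, {field_height}]"
            )
        defects.append(Defect(x, y, r))
    return DefectSet(defects, field_width, field_height, label or "")
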