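"""Cell filtering and manual group selection.

Filters are conjunctions of predicates over the cell table (categorical
level sets, inclusive numeric ranges) and over embeddings (boxes and lasso
polygons). Boundary points count as selected. Group assignments feed the
differential expression; cells caught by more than one selection are
excluded from every group so results cannot depend on selection order.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .dataset import CellDataset
from .errors import SpecificationError

__all__ = [
    "Categorical",
    "Range",
    "Region",
    "FilterSpec",
    "GroupAssignment",
    "apply_filter",
    "points_in_polygon",
    "region_to_cells",
    "assign_groups",
]


@dataclass(frozen=True)
class Categorical:
    """Keep cells whose value in ``column`` is one of ``levels``."""

    column: str
    levels: frozenset

    def __init__(self, column: str, levels):
        object.__setattr__(self, "column", column)
        object.__setattr__(self, "levels", frozenset(str(v) for v in levels))


@dataclass(frozen=True)
class Range:
    """Keep cells with ``low <= value <= high`` (either bound optional)."""

    column: str
    low: Optional[float] = None
    high: Optional[float] = None


@dataclass(frozen=True)
class Region:
    """Keep cells inside a box or polygon on a named embedding.

    ``box`` is ``(xmin, xmax, ymin, ymax)``; ``polygon`` is an ordered list
    of at least three 2-D vertices, implicitly closed.
    """

    embedding: str
    box: Optional[tuple[float, float, float, float]] = None
    polygon: Optional[tuple[tuple[float, float], ...]] = None

    def __post_init__(self):
        if (self.box is None) == (self.polygon is None):
            raise SpecificationError("Region needs exactly one of box or polygon")
        if self.box is not None:
            xmin, xmax, ymin, ymax = self.box
            if xmin > xmax or ymin > ymax:
                raise SpecificationError("box must satisfy xmin<=xmax and ymin<=ymax")
        if self.polygon is not None:
            if len(self.polygon) < 3:
                raise SpecificationError("polygon needs at least 3 vertices")
            object.__setattr__(
                self, "polygon", tuple((float(x), float(y)) for x, y in self.polygon)
            )


@dataclass
class FilterSpec:
    """Conjunctive set of predicates selecting cells."""

    predicates: list = field(default_factory=list)

    # -- JSON serialization (the web service's wire form) ---------------
    def to_json(self) -> str:
        out = []
        for p in self.predicates:
            if isinstance(p, Categorical):
                out.append(
                    {"type": "categorical", "column": p.column,
                     "levels": sorted(p.levels)}
                )
            elif isinstance(p, Range):
                out.append(
                    {"type": "range", "column": p.column, "low": p.low, "high": p.high}
                )
            elif isinstance(p, Region):
                entry = {"type": "region", "embedding": p.embedding}
                if p.box is not None:
                    entry["box"] = list(p.box)
                else:
                    entry["polygon"] = [list(v) for v in p.polygon]
                out.append(entry)
            else:
                raise SpecificationError(f"unknown predicate {p!r}")
        return json.dumps(out)

    @classmethod
    def from_json(cls, text: str) -> "FilterSpec":
        preds = []
        for entry in json.loads(text):
            kind = entry.get("type")
            if kind == "categorical":
                preds.append(Categorical(entry["column"], entry["levels"]))
            elif kind == "range":
                preds.append(
                    Range(entry["column"], entry.get("low"), entry.get("high"))
                )
            elif kind == "region":
                preds.append(
                    Region(
                        entry["embedding"],
                        box=tuple(entry["box"]) if "box" in entry else None,
                        polygon=tuple(map(tuple, entry["polygon"]))
                        if "polygon" in entry
                        else None,
                    )
                )
            else:
                raise SpecificationError(f"unknown predicate type {kind!r}")
        return cls(predicates=preds)


@dataclass
class GroupAssignment:
    """Disjoint labeled cell index sets (e.g. 'A' and 'B')."""

    groups: dict[str, set[int]]
    warnings: list[str] = field(default_factory=list)


# ----------------------------------------------------------------------
# geometry


def points_in_polygon(points, polygon) -> np.ndarray:
    """Even-odd (ray casting) point-in-polygon test, boundary inclusive.

    The polygon is implicitly closed; points exactly on an edge or vertex
    are inside. Returns a boolean flag per point.
    """
    poly = np.asarray(polygon, dtype=np.float64)
    if poly.ndim != 2 or poly.shape[0] < 3 or poly.shape[1] != 2:
        raise SpecificationError("polygon needs at least 3 two-dimensional vertices")
    pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
    px, py = pts[:, 0], pts[:, 1]
    inside = np.zeros(len(pts), dtype=bool)
    boundary = np.zeros(len(pts), dtype=bool)

    n = len(poly)
    for i in range(n):
        x1, y1 = poly[i]
        x2, y2 = poly[(i + 1) % n]
        # on-segment check: zero cross product and within the bounding box
        cross = (x2 - x1) * (py - y1) - (y2 - y1) * (px - x1)
        on_line = np.abs(cross) <= 1e-12 * max(
            1.0, abs(x2 - x1) + abs(y2 - y1), np.abs(px).max(initial=1.0),
            np.abs(py).max(initial=1.0),
        )
        within = (
            (px >= min(x1, x2) - 1e-12)
            & (px <= max(x1, x2) + 1e-12)
            & (py >= min(y1, y2) - 1e-12)
            & (py <= max(y1, y2) + 1e-12)
        )
        boundary |= on_line & within
        # ray casting toward +x: does the edge straddle the horizontal line?
        straddles = (y1 > py) != (y2 > py)
        with np.errstate(divide="ignore", invalid="ignore"):
            x_at = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
        inside ^= straddles & (px < x_at)
    return inside | boundary


def _box_polygon(box) -> tuple:
    xmin, xmax, ymin, ymax = box
    return ((xmin, ymin), (xmax, ymin), (xmax, ymax), (xmin, ymax))


def region_to_cells(ds: CellDataset, embedding: str, region) -> set[int]:
    """Cells whose embedding coordinates fall inside a box or polygon."""
    if embedding not in ds.embeddings:
        raise SpecificationError(f"unknown embedding {embedding!r}")
    coords = np.asarray(ds.embeddings[embedding])
    if isinstance(region, Region):
        poly = region.polygon if region.polygon is not None else _box_polygon(region.box)
    elif isinstance(region, (tuple, list)) and len(region) == 4 and np.isscalar(region[0]):
        poly = _box_polygon(region)
    else:
        poly = tuple(region)
    flags = points_in_polygon(coords, poly)
    return set(np.flatnonzero(flags).tolist())


# ----------------------------------------------------------------------
# filtering


def _eval_predicate(ds: CellDataset, pred) -> np.ndarray:
    if isinstance(pred, Categorical):
        if pred.column not in ds.cell_table.columns:
            raise SpecificationError(f"unknown column {pred.column!r}")
        col = ds.cell_table[pred.column]
        known = set(
            col.cat.categories.astype(str)
            if isinstance(col.dtype, pd.CategoricalDtype)
            else col.astype(str).unique()
        )
        unknown = pred.levels - known
        if unknown:
            warnings.warn(
                f"filter on {pred.column!r}: levels {sorted(unknown)} not present",
                stacklevel=3,
            )
        return col.astype(str).isin(pred.levels).to_numpy()
    if isinstance(pred, Range):
        if pred.column not in ds.cell_table.columns:
            raise SpecificationError(f"unknown column {pred.column!r}")
        values = ds.cell_table[pred.column].to_numpy(dtype=float)
        mask = np.ones(len(values), dtype=bool)
        if pred.low is not None:
            mask &= values >= pred.low
        if pred.high is not None:
            mask &= values <= pred.high
        return mask
    if isinstance(pred, Region):
        region_cells = region_to_cells(ds, pred.embedding, pred)
        mask = np.zeros(ds.n_cells, dtype=bool)
        mask[sorted(region_cells)] = True
        return mask
    raise SpecificationError(f"unknown predicate {pred!r}")


def apply_filter(ds: CellDataset, spec: FilterSpec) -> set[int]:
    """Cells satisfying every predicate; the empty spec selects all cells."""
    mask = np.ones(ds.n_cells, dtype=bool)
    for pred in spec.predicates:
        mask &= _eval_predicate(ds, pred)
    return set(np.flatnonzero(mask).tolist())


def assign_groups(selections: dict[str, Sequence[int]]) -> GroupAssignment:
    """Turn labeled selections into disjoint groups.

    Cells present in more than one selection are removed from every group
    (with a warning carrying the overlap count) so downstream comparisons
    do not depend on the order selections were made.
    """
    sets = {label: set(int(i) for i in cells) for label, cells in selections.items()}
    counts: dict[int, int] = {}
    for cells in sets.values():
        for c in cells:
            counts[c] = counts.get(c, 0) + 1
    overlap = {c for c, k in counts.items() if k > 1}
    notes = []
    if overlap:
        notes.append(
            f"{len(overlap)} overlapping cell(s) removed from all groups"
        )
    return GroupAssignment(
        groups={label: cells - overlap for label, cells in sets.items()},
        warnings=notes,
    )
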