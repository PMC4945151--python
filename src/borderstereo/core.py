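"""Core planar domain types shared across the package.

All coordinates are micrometres in a planar frame: x to the right,
y up, origin at the lower-left corner of the field extent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import shapely
from shapely.geometry import Polygon

__all__ = [
    "Region",
    "RegionMap",
    "CurveSet",
    "MeasurementLine",
    "BACKGROUND",
]

BACKGROUND = "background"


@dataclass(frozen=True)
class Region:
    """A labeled planar region: polygon geometry, class label, unique id."""

    polygon: Polygon
    class_label: str
    region_id: str


class RegionMap:
    """Labeled planar partition of a rectangular extent.

    Regions of distinct ids are interior-disjoint; any point of the
    extent not covered by a region belongs to the background class.
    """

    def __init__(self, regions: Sequence[Region], extent: tuple[float, float, float, float]):
        xmin, ymin, xmax, ymax = extent
        if not (xmax > xmin and ymax > ymin):
            raise ValueError(f"degenerate extent {extent!r}")
        self.regions: list[Region] = list(regions)
        self.extent = (float(xmin), float(ymin), float(xmax), float(ymax))
        ids = [r.region_id for r in self.regions]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate region ids")
        self._prep: list[Polygon] | None = None

    @property
    def width(self) -> float:
        return self.extent[2] - self.extent[0]

    @property
    def height(self) -> float:
        return self.extent[3] - self.extent[1]

    @property
    def area(self) -> float:
        return self.width * self.height

    def class_labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.regions:
            seen.setdefault(r.class_label, None)
        return list(seen)

    def regions_of_class(self, class_label: str) -> list[Region]:
        return [r for r in self.regions if r.class_label == class_label]

    def class_area(self, class_label: str) -> float:
        if class_label == BACKGROUND:
            return self.area - sum(r.polygon.area for r in self.regions)
        return sum(r.polygon.area for r in self.regions_of_class(class_label))

    def _prepared(self) -> list[Polygon]:
        if self._prep is None:
            self._prep = [r.polygon for r in self.regions]
            for g in self._prep:
                shapely.prepare(g)
        return self._prep

    def class_at(self, points: np.ndarray) -> np.ndarray:
        """Class label for each (n, 2) point; background where uncovered.

        Points exactly on a shared border resolve to the lowest-index
        covering region (deterministic tie-break).
        """
        idx = self.region_index_at(points)
        labels = np.full(len(idx), BACKGROUND, dtype=object)
        for ri in np.unique(idx):
            if ri >= 0:
                labels[idx == ri] = self.regions[ri].class_label
        return labels

    def region_index_at(self, points: np.ndarray) -> np.ndarray:
        """Index into ``self.regions`` per point, -1 for background."""
        pts = np.asarray(points, dtype=float)
        if pts.ndim == 1:
            pts = pts[None, :]
        out = np.full(len(pts), -1, dtype=int)
        if not self.regions:
            return out
        todo = np.ones(len(pts), dtype=bool)
        for ri, poly in enumerate(self._prepared()):
            if not todo.any():
                break
            sel = np.flatnonzero(todo)
            hit = shapely.intersects_xy(poly, pts[sel, 0], pts[sel, 1])
            out[sel[hit]] = ri
            todo[sel[hit]] = False
        return out


@dataclass
class Curve:
    """One polyline fiber: (n, 2) vertex array plus a parent-structure tag."""

    vertices: np.ndarray
    structure_id: str

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 2:
            raise ValueError("curve needs an (n>=2, 2) vertex array")
        self.vertices = v

    @property
    def length(self) -> float:
        d = np.diff(self.vertices, axis=0)
        return float(np.hypot(d[:, 0], d[:, 1]).sum())


class CurveSet:
    """A collection of polylines tagged with parent-structure ids.

    Generators may build a CurveSet from one packed vertex array (via
    `_from_packed`); individual `Curve` objects are then materialized
    lazily, while segment-level consumers read the packed cache.
    """

    def __init__(self, curves: Sequence[Curve] = ()):
        self._curves: list[Curve] | None = list(curves)
        self._packed: tuple[np.ndarray, np.ndarray, list[str]] | None = None
        self._segcache: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None

    @classmethod
    def _from_packed(cls, flat: np.ndarray, spans: np.ndarray,
                     structure_ids: list[str],
                     segcache: tuple[np.ndarray, np.ndarray, np.ndarray] | None
                     ) -> "CurveSet":
        """Packed layout: ``spans[i] = (start, stop)`` rows of ``flat``."""
        obj = cls.__new__(cls)
        obj._curves = None
        obj._packed = (flat, spans, structure_ids)
        obj._segcache = segcache
        return obj

    @property
    def curves(self) -> list[Curve]:
        if self._curves is None:
            flat, spans, ids = self._packed
            self._curves = [Curve(flat[a:b], sid)
                            for (a, b), sid in zip(spans, ids)]
        return self._curves

    def segments(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """All polyline steps as flat (P0, P1, structure index) arrays.

        Cached; generators that build curves from packed arrays may
        pre-populate the cache.
        """
        if self._segcache is None:
            p0s, p1s, sids = [], [], []
            struct_index: dict[str, int] = {}
            for c in self.curves:
                v = c.vertices
                if len(v) < 2:
                    continue
                si = struct_index.setdefault(c.structure_id, len(struct_index))
                p0s.append(v[:-1])
                p1s.append(v[1:])
                sids.append(np.full(len(v) - 1, si))
            if not p0s:
                z = np.zeros((0, 2))
                self._segcache = (z, z.copy(), np.zeros(0, dtype=int))
            else:
                self._segcache = (np.vstack(p0s), np.vstack(p1s),
                                  np.concatenate(sids))
        return self._segcache

    def __len__(self) -> int:
        if self._curves is None:
            return len(self._packed[1])
        return len(self.curves)

    def __iter__(self) -> Iterator[Curve]:
        return iter(self.curves)

    def total_length(self) -> float:
        if self._segcache is not None:
            p0, p1, _ = self._segcache
            d = p1 - p0
            return float(np.hypot(d[:, 0], d[:, 1]).sum())
        return float(sum(c.length for c in self.curves))

    def structure_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.curves:
            seen.setdefault(c.structure_id, None)
        return list(seen)

    def extend(self, other: "CurveSet") -> None:
        self.curves.extend(other.curves)
        self._segcache = None


@dataclass(frozen=True)
class MeasurementLine:
    """A straight open test segment with its placement metadata.

    ``placement`` is one of: septal, core, offset, blob-center,
    interblob-center, interblob-margin.  ``pair_key`` links a line to
    its matched counterpart (septal<->core); ``side`` and ``offset``
    apply to offset lines only.
    """

    start: tuple[float, float]
    end: tuple[float, float]
    placement: str
    line_id: str
    pair_key: str | None = None
    side: str | None = None
    offset: float | None = None
    meta: Mapping[str, object] = field(default_factory=dict)

    @property
    def length(self) -> float:
        return float(np.hypot(self.end[0] - self.start[0], self.end[1] - self.start[1]))

    @property
    def orientation(self) -> float:
        """Direction angle in radians, wrapped to [0, pi)."""
        ang = float(np.arctan2(self.end[1] - self.start[1], self.end[0] - self.start[0]))
        return ang % np.pi

    @property
    def midpoint(self) -> tuple[float, float]:
        return (
            0.5 * (self.start[0] + self.end[0]),
            0.5 * (self.start[1] + self.end[1]),
        )

    def as_array(self) -> np.ndarray:
        return np.array([self.start, self.end], dtype=float)
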