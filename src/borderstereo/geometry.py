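"""Border extraction and placement of measurement constructs.

Everything here is deterministic given a `RegionMap`: border polylines
with local tangents, septal/core line matrices, offset lines, blob
lines, perpendicular density bands, and landmark-based rigid alignment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from shapely.geometry import LineString, MultiLineString
from shapely.ops import linemerge

from .core import BACKGROUND, Curve, CurveSet, MeasurementLine, RegionMap

__all__ = [
    "BorderPolyline",
    "DensityBand",
    "RigidTransform",
    "extract_borders",
    "place_septal_and_core_lines",
    "place_offset_lines",
    "place_blob_lines",
    "place_density_bands",
    "estimate_landmark_transform",
    "apply_transform",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# borders


@dataclass
class BorderPolyline:
    """An ordered border polyline between two region classes.

    ``side_classes`` is (class on the +normal side, class on the
    -normal side), where the +normal is the tangent rotated by +90°.
    """

    vertices: np.ndarray
    side_classes: tuple[str, str]
    border_id: str

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or len(v) < 2:
            raise ValueError("border needs an (n>=2, 2) vertex array")
        self.vertices = v
        d = np.diff(v, axis=0)
        seg = np.hypot(d[:, 0], d[:, 1])
        if np.any(seg == 0):
            keep = np.concatenate([[True], seg > 0])
            self.vertices = v[keep]
            d = np.diff(self.vertices, axis=0)
            seg = np.hypot(d[:, 0], d[:, 1])
        self._seg_len = seg
        self._cum = np.concatenate([[0.0], np.cumsum(seg)])

    @property
    def length(self) -> float:
        return float(self._cum[-1])

    @property
    def is_closed(self) -> bool:
        return bool(np.allclose(self.vertices[0], self.vertices[-1]))

    def _locate(self, s: float) -> tuple[int, float]:
        s = float(np.clip(s, 0.0, self.length))
        i = int(np.searchsorted(self._cum, s, side="right") - 1)
        i = min(i, len(self._seg_len) - 1)
        t = (s - self._cum[i]) / self._seg_len[i]
        return i, t

    def point_at(self, s: float) -> np.ndarray:
        i, t = self._locate(s)
        return self.vertices[i] + t * (self.vertices[i + 1] - self.vertices[i])

    def tangent_at(self, s: float, window: float = 0.0) -> np.ndarray:
        """Unit tangent at arclength ``s``; averaged over ±window/2 if given."""
        if window <= 0:
            i, _ = self._locate(s)
            d = self.vertices[i + 1] - self.vertices[i]
            return d / np.hypot(*d)
        p0 = self.point_at(s - window / 2.0)
        p1 = self.point_at(s + window / 2.0)
        d = p1 - p0
        n = np.hypot(*d)
        if n == 0:
            return self.tangent_at(s)
        return d / n

    def normal_at(self, s: float, window: float = 0.0) -> np.ndarray:
        t = self.tangent_at(s, window)
        return np.array([-t[1], t[0]])


def _probe_side_classes(region_map: RegionMap, line: LineString,
                        eps: float = 0.5) -> tuple[str, str]:
    s = line.length / 2.0
    mid = np.asarray(line.interpolate(s).coords[0])
    ahead = np.asarray(line.interpolate(min(line.length, s + 1.0)).coords[0])
    behind = np.asarray(line.interpolate(max(0.0, s - 1.0)).coords[0])
    t = ahead - behind
    norm = np.hypot(*t)
    t = t / norm if norm else np.array([1.0, 0.0])
    n = np.array([-t[1], t[0]])
    plus, minus = region_map.class_at(np.vstack([mid + eps * n, mid - eps * n]))
    return str(plus), str(minus)


def extract_borders(region_map: RegionMap) -> list[BorderPolyline]:
    """Shared borders between adjacent classes, each emitted exactly once.

    Region/region borders come from pairwise boundary intersections;
    the remaining pieces of each region's boundary (not shared with any
    other region and not on the extent frame) border the background.
    """
    regions = [r for r in region_map.regions]
    valid = []
    for r in regions:
        if r.polygon.is_empty or r.polygon.area <= 0:
            log.warning("skipping degenerate region %s", r.region_id)
            continue
        valid.append(r)

    borders: list[BorderPolyline] = []

    def emit(geom, id_base: str) -> list[LineString]:
        if geom.is_empty:
            return []
        merged = linemerge(geom) if isinstance(geom, (MultiLineString,)) else geom
        if isinstance(merged, LineString):
            parts = [merged]
        else:
            parts = [g for g in getattr(merged, "geoms", []) if isinstance(g, LineString)]
        return [g for g in parts if g.length > 1e-9]

    shared_by_region: dict[int, list] = {i: [] for i in range(len(valid))}
    for i in range(len(valid)):
        for j in range(i + 1, len(valid)):
            inter = valid[i].polygon.boundary.intersection(valid[j].polygon.boundary)
            pieces = emit(inter, "")
            if not pieces:
                continue
            shared_by_region[i].extend(pieces)
            shared_by_region[j].extend(pieces)
            for k, ls in enumerate(pieces):
                v = np.asarray(ls.coords, dtype=float)
                plus, minus = _probe_side_classes(region_map, ls)
                bid = f"{valid[i].region_id}|{valid[j].region_id}|{k}"
                borders.append(BorderPolyline(v, (plus, minus), bid))

    # background borders: boundary pieces not shared and not on the frame
    xmin, ymin, xmax, ymax = region_map.extent
    from shapely.geometry import box

    frame = box(xmin, ymin, xmax, ymax).boundary
    for i, reg in enumerate(valid):
        rest = reg.polygon.boundary
        for piece in shared_by_region[i]:
            rest = rest.difference(piece)
        rest = rest.difference(frame.buffer(1e-6))
        for k, ls in enumerate(emit(rest, "")):
            v = np.asarray(ls.coords, dtype=float)
            plus, minus = _probe_side_classes(region_map, ls)
            bid = f"{reg.region_id}|{BACKGROUND}|{k}"
            borders.append(BorderPolyline(v, (plus, minus), bid))
    return borders


# ---------------------------------------------------------------------------
# septal / core line matrices


def _bbox(poly) -> tuple[float, float, float, float]:
    return poly.bounds


def place_septal_and_core_lines(
    region_map: RegionMap,
    line_length: float = 375.0,
    core_span_window: tuple[float, float] = (350.0, 450.0),
) -> list[MeasurementLine]:
    """Line matrix for a barrel-style map.

    One septal line per qualifying inter-core border, centered on the
    septum midline and oriented along the border; one core line per
    qualifying core at its centroid, carrying the orientation of its
    paired septal line (pair_key = the septal line's id).
    """
    cores = region_map.regions_of_class("core")
    if not cores:
        return []
    lo, hi = core_span_window
    boxes = {c.region_id: _bbox(c.polygon) for c in cores}

    # septum width = smallest positive gap between core bboxes
    gaps: list[float] = []
    ids = sorted(boxes)
    for a in range(len(ids)):
        for b in range(a + 1, len(ids)):
            x0a, y0a, x1a, y1a = boxes[ids[a]]
            x0b, y0b, x1b, y1b = boxes[ids[b]]
            gx = max(x0a, x0b) - min(x1a, x1b)
            gy = max(y0a, y0b) - min(y1a, y1b)
            if gx > 0 and gy < 0:
                gaps.append(gx)
            elif gy > 0 and gx < 0:
                gaps.append(gy)
    if not gaps:
        return []
    septum_w = min(gaps)

    def qualifies(rid: str) -> bool:
        # "large barrels only": both extents inside the selection window
        x0, y0, x1, y1 = boxes[rid]
        return lo <= x1 - x0 <= hi and lo <= y1 - y0 <= hi

    septal: list[MeasurementLine] = []
    septal_for_core: dict[str, list[str]] = {rid: [] for rid in ids}
    for a in range(len(ids)):
        for b in range(a + 1, len(ids)):
            x0a, y0a, x1a, y1a = boxes[ids[a]]
            x0b, y0b, x1b, y1b = boxes[ids[b]]
            gx = max(x0a, x0b) - min(x1a, x1b)
            gy = max(y0a, y0b) - min(y1a, y1b)
            if gx > 0 and gy < 0 and gx <= 1.5 * septum_w:
                cx = (min(x1a, x1b) + max(x0a, x0b)) / 2.0
                ov0, ov1 = max(y0a, y0b), min(y1a, y1b)
                center = np.array([cx, (ov0 + ov1) / 2.0])
                direction = np.array([0.0, 1.0])
                corridor = (ov1 - ov0) + 2.0 * septum_w
            elif gy > 0 and gx < 0 and gy <= 1.5 * septum_w:
                cy = (min(y1a, y1b) + max(y0a, y0b)) / 2.0
                ov0, ov1 = max(x0a, x0b), min(x1a, x1b)
                center = np.array([(ov0 + ov1) / 2.0, cy])
                direction = np.array([1.0, 0.0])
                corridor = (ov1 - ov0) + 2.0 * septum_w
            else:
                continue
            if not (qualifies(ids[a]) and qualifies(ids[b])):
                continue
            if corridor < line_length:
                log.warning("septum %s-%s shorter than the line; skipped",
                            ids[a], ids[b])
                continue
            half = 0.5 * line_length * direction
            lid = f"sep-{ids[a]}-{ids[b]}"
            septal.append(MeasurementLine(
                start=tuple(center - half), end=tuple(center + half),
                placement="septal", line_id=lid, pair_key=lid,
                meta={"cores": (ids[a], ids[b])}))
            septal_for_core[ids[a]].append(lid)
            septal_for_core[ids[b]].append(lid)

    lines: list[MeasurementLine] = list(septal)
    septal_by_id = {l.line_id: l for l in septal}
    for core in sorted(cores, key=lambda c: c.region_id):
        partners = sorted(septal_for_core[core.region_id])
        if not partners:
            continue
        partner = septal_by_id[partners[0]]
        d = np.asarray(partner.end) - np.asarray(partner.start)
        d = d / np.hypot(*d)
        c = core.polygon.centroid
        center = np.array([c.x, c.y])
        half = 0.5 * line_length * d
        lines.append(MeasurementLine(
            start=tuple(center - half), end=tuple(center + half),
            placement="core", line_id=f"core-{core.region_id}",
            pair_key=partner.line_id))
    return lines


# ---------------------------------------------------------------------------
# offset lines


def place_offset_lines(
    border: BorderPolyline,
    offsets: Sequence[float] = (50.0, 200.0),
    line_length: float = 50.0,
    spacing: float | None = None,
    extent: tuple[float, float, float, float] | None = None,
    tangent_window: float | None = None,
) -> list[MeasurementLine]:
    """Lines parallel to the border at fixed offsets on both sides.

    Stations sit at arclength ``(i + 0.5) * spacing`` (one mid-border
    station when ``spacing`` is None).  Side labels come from the
    border's adjacent classes; offset 0 puts the line on the border
    itself (testing only).  Lines leaving ``extent`` are dropped.
    """
    if line_length <= 0:
        raise ValueError("line_length must be > 0")
    if spacing is None:
        stations = [border.length / 2.0]
    else:
        if spacing <= 0:
            raise ValueError("spacing must be > 0")
        n = int(np.floor(border.length / spacing))
        stations = [(i + 0.5) * spacing for i in range(n)]
    win = line_length if tangent_window is None else tangent_window

    lines: list[MeasurementLine] = []
    plus_cls, minus_cls = border.side_classes
    for si, s in enumerate(stations):
        p = border.point_at(s)
        t = border.tangent_at(s, window=win)
        nvec = np.array([-t[1], t[0]])
        for off in offsets:
            if off < 0:
                raise ValueError("offsets must be >= 0")
            sides = ((+1, plus_cls), (-1, minus_cls)) if off > 0 else ((+1, plus_cls),)
            for sign, cls in sides:
                center = p + sign * off * nvec
                half = 0.5 * line_length * t
                a, b = center - half, center + half
                if extent is not None:
                    xmin, ymin, xmax, ymax = extent
                    pts = np.vstack([a, b])
                    if (pts[:, 0].min() < xmin or pts[:, 0].max() > xmax
                            or pts[:, 1].min() < ymin or pts[:, 1].max() > ymax):
                        log.warning("offset line at s=%.1f off=%g leaves extent; dropped",
                                    s, off)
                        continue
                lines.append(MeasurementLine(
                    start=tuple(a), end=tuple(b), placement="offset",
                    line_id=f"off-{border.border_id}-{si}-{cls}-{off:g}",
                    pair_key=f"{border.border_id}-{si}",
                    side=cls, offset=float(off)))
    return lines


# ---------------------------------------------------------------------------
# blob lines


def place_blob_lines(blob_map: RegionMap, line_length: float = 500.0,
                     margin_gap: float = 25.0) -> list[MeasurementLine]:
    """Vertical lines at blob centers, inter-blob centers and margins.

    The inter-blob margin line sits ``margin_gap`` to the right of the
    preceding blob's right edge (the left margin of the inter-blob).
    """
    if line_length <= 0:
        raise ValueError("line_length must be > 0")
    blobs = sorted(blob_map.regions_of_class("blob"),
                   key=lambda r: r.polygon.centroid.x)
    if not blobs:
        return []
    xmin, ymin, xmax, ymax = blob_map.extent
    yc = (ymin + ymax) / 2.0
    y0, y1 = yc - line_length / 2.0, yc + line_length / 2.0
    if y0 < ymin or y1 > ymax:
        raise ValueError("line_length exceeds the extent height")

    lines: list[MeasurementLine] = []

    def add(x: float, placement: str, lid: str) -> None:
        if not xmin <= x <= xmax:
            log.warning("%s line at x=%.1f outside extent; skipped", placement, x)
            return
        lines.append(MeasurementLine(
            start=(x, y0), end=(x, y1), placement=placement, line_id=lid))

    for b in blobs:
        add(b.polygon.centroid.x, "blob-center", f"blobc-{b.region_id}")
    for k in range(len(blobs) - 1):
        left, right = blobs[k], blobs[k + 1]
        mid = (left.polygon.centroid.x + right.polygon.centroid.x) / 2.0
        add(mid, "interblob-center", f"ibc-{k}")
        add(left.polygon.bounds[2] + margin_gap, "interblob-margin", f"ibm-{k}")
    return lines


# ---------------------------------------------------------------------------
# density bands


@dataclass
class DensityBand:
    """Rectangle centered on a border, long axis perpendicular to it.

    ``axis`` is the unit vector of the long axis and points toward
    ``side_classes[0]`` (positive profile positions); the border is at
    position 0.
    """

    center: np.ndarray
    axis: np.ndarray
    width: float
    length: float
    band_id: str
    side_classes: tuple[str, str] = ("", "")

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        a = np.asarray(self.axis, dtype=float)
        n = np.hypot(*a)
        if n == 0:
            raise ValueError("band axis must be nonzero")
        self.axis = a / n
        if self.width <= 0 or self.length <= 0:
            raise ValueError("band width and length must be > 0")

    @property
    def across(self) -> np.ndarray:
        return np.array([-self.axis[1], self.axis[0]])

    def corners(self) -> np.ndarray:
        ha = 0.5 * self.length * self.axis
        hw = 0.5 * self.width * self.across
        c = self.center
        return np.vstack([c - ha - hw, c + ha - hw, c + ha + hw, c - ha + hw])

    def oriented(self, inner_class: str) -> "DensityBand":
        """Flip so ``inner_class`` lies at negative profile positions."""
        if self.side_classes[0] != inner_class:
            return self
        return DensityBand(self.center, -self.axis, self.width, self.length,
                           self.band_id, (self.side_classes[1], self.side_classes[0]))


def place_density_bands(border: BorderPolyline, width: float = 25.0,
                        length: float = 100.0, count: int = 10,
                        tangent_window: float | None = None) -> list[DensityBand]:
    """Evenly spaced bands centered on the border, axes perpendicular."""
    if count < 1:
        raise ValueError("count must be >= 1")
    max_fit = int(np.floor(border.length / width))
    if max_fit < count:
        log.warning("border fits only %d of %d bands", max_fit, count)
        count = max_fit
    if count == 0:
        return []
    spacing = border.length / count
    win = width if tangent_window is None else tangent_window
    bands = []
    for i in range(count):
        s = (i + 0.5) * spacing
        p = border.point_at(s)
        nvec = border.normal_at(s, window=win)
        bands.append(DensityBand(p, nvec, width, length, f"band-{border.border_id}-{i}",
                                 border.side_classes))
    return bands


# ---------------------------------------------------------------------------
# landmark alignment


@dataclass(frozen=True)
class RigidTransform:
    """Rotation + translation (+ optional uniform scale) in the plane."""

    rotation: float
    translation: tuple[float, float]
    scale: float = 1.0
    rms_residual: float = 0.0

    def matrix(self) -> np.ndarray:
        c, s = np.cos(self.rotation), np.sin(self.rotation)
        return self.scale * np.array([[c, -s], [s, c]])

    def apply_points(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.matrix().T + np.asarray(self.translation)

    def inverse(self) -> "RigidTransform":
        inv_scale = 1.0 / self.scale
        c, s = np.cos(-self.rotation), np.sin(-self.rotation)
        r_inv = inv_scale * np.array([[c, -s], [s, c]])
        t_inv = -(r_inv @ np.asarray(self.translation))
        return RigidTransform(-self.rotation, tuple(t_inv), inv_scale)


def estimate_landmark_transform(source_points: np.ndarray,
                                target_points: np.ndarray,
                                allow_scale: bool = False) -> RigidTransform:
    """Least-squares rigid (or similarity) alignment of paired landmarks.

    Standard Procrustes/Umeyama solution via SVD of the cross-covariance.
    """
    src = np.asarray(source_points, dtype=float)
    dst = np.asarray(target_points, dtype=float)
    if src.shape != dst.shape or src.ndim != 2 or src.shape[1] != 2:
        raise ValueError("point sets must be matching (n, 2) arrays")
    n = len(src)
    if n < 2:
        raise ValueError("at least 2 point pairs are required")
    mu_s, mu_d = src.mean(axis=0), dst.mean(axis=0)
    xs, xd = src - mu_s, dst - mu_d
    var_s = (xs ** 2).sum() / n
    if var_s < 1e-12 or (xd ** 2).sum() / n < 1e-12:
        raise ValueError("degenerate landmark configuration (coincident points)")
    cov = xd.T @ xs / n
    u, sv, vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(u @ vt))
    s_mat = np.diag([1.0, d])
    rot = u @ s_mat @ vt
    scale = float((sv * np.diag(s_mat)).sum() / var_s) if allow_scale else 1.0
    angle = float(np.arctan2(rot[1, 0], rot[0, 0]))
    trans = mu_d - scale * (rot @ mu_s)
    tf = RigidTransform(angle, (float(trans[0]), float(trans[1])), scale)
    resid = tf.apply_points(src) - dst
    rms = float(np.sqrt((resid ** 2).sum(axis=1).mean()))
    return RigidTransform(angle, (float(trans[0]), float(trans[1])), scale, rms)


def apply_transform(transform: RigidTransform, obj):
    """Map curves/lines/bands/points through a transform, preserving type."""
    if isinstance(obj, np.ndarray):
        return transform.apply_points(obj)
    if isinstance(obj, CurveSet):
        return CurveSet([Curve(transform.apply_points(c.vertices), c.structure_id)
                         for c in obj])
    if isinstance(obj, Curve):
        return Curve(transform.apply_points(obj.vertices), obj.structure_id)
    if isinstance(obj, MeasurementLine):
        a, b = transform.apply_points(np.vstack([obj.start, obj.end]))
        return MeasurementLine(tuple(a), tuple(b), obj.placement, obj.line_id,
                               obj.pair_key, obj.side, obj.offset, obj.meta)
    if isinstance(obj, BorderPolyline):
        return BorderPolyline(transform.apply_points(obj.vertices),
                              obj.side_classes, obj.border_id)
    if isinstance(obj, DensityBand):
        c = transform.apply_points(obj.center[None, :])[0]
        a = transform.matrix() @ obj.axis
        return DensityBand(c, a, obj.width * transform.scale,
                           obj.length * transform.scale, obj.band_id,
                           obj.side_classes)
    if isinstance(obj, (list, tuple)):
        mapped = [apply_transform(transform, o) for o in obj]
        return type(obj)(mapped)
    raise TypeError(f"cannot transform object of type {type(obj).__name__}")
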