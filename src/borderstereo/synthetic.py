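"""Synthetic scenes: region layouts, boundary-confined arbors, capillaries.

The generator produces planar scenes with the statistical structure the
measurement chain assumes: labeled region mosaics, astrocyte-like
branching arbors whose growth is confined at region borders with a
tunable crossing probability, border-indifferent capillary segment
processes, shared landmark points, and section-thickness thinning.

The stereological bridge between fiber length density ``rho`` (µm/µm²)
and test-line crossings is the isotropic line-intercept relation::

    E[crossings of a line of length L] = 2 * L * rho / pi

which `calibrate_densities` inverts to match target per-line means.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from shapely.geometry import LineString, box
from shapely.ops import unary_union

from ._rng import stream
from .core import BACKGROUND, Curve, CurveSet, Region, RegionMap

__all__ = [
    "GeneratorConfig",
    "SyntheticScene",
    "sample_barrel_map",
    "sample_area_map",
    "grow_astrocyte_arbors",
    "sample_capillary_network",
    "sample_landmarks",
    "thin_by_section",
    "expected_crossings",
    "density_for_target_mean",
    "calibrate_densities",
    "solve_confinement",
    "rasterize_scene",
    "RasterScene",
]

_CIRCLE_SEGMENTS = 64  # quad_segs for disc regions; perimeter error < 1e-4


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class GeneratorConfig:
    """Generative parameters for one scene.

    Fiber placement is driven either by explicit per-class soma
    intensities (count/µm²) or, more commonly, by per-class fiber
    length densities ``fiber_density`` (µm/µm²) from which the soma
    intensity is derived as ``rho / (branch_count_mean *
    branch_length_mean)``.
    """

    fiber_density: Mapping[str, float] = field(default_factory=dict)
    soma_intensity: Mapping[str, float] = field(default_factory=dict)
    branch_count_mean: float = 5.0
    step_length: float = 5.0
    turning_sigma: float = 0.3
    branch_length_mean: float = 60.0
    p_cross: float | Mapping[tuple[str, str], float] = 1.0
    capillary_density: float | Mapping[str, float] = 0.0
    capillary_segment_length: float = 150.0
    retention: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        for name, mapping in (("fiber_density", self.fiber_density),
                              ("soma_intensity", self.soma_intensity)):
            for k, v in mapping.items():
                if v < 0:
                    raise ValueError(f"{name}[{k!r}] must be >= 0, got {v}")
        if self.step_length <= 0:
            raise ValueError(f"step_length must be > 0, got {self.step_length}")
        if self.branch_length_mean <= 0 or self.branch_count_mean < 0:
            raise ValueError("branch parameters must be positive")
        if self.turning_sigma < 0:
            raise ValueError("turning_sigma must be >= 0")
        for p in (self.p_cross.values() if isinstance(self.p_cross, Mapping)
                  else [self.p_cross]):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"p_cross values must lie in [0, 1], got {p}")
        caps = (self.capillary_density.values()
                if isinstance(self.capillary_density, Mapping)
                else [self.capillary_density])
        for v in caps:
            if v < 0:
                raise ValueError("capillary_density must be >= 0")
        if not 0.0 < self.retention <= 1.0:
            raise ValueError(f"retention must lie in (0, 1], got {self.retention}")

    def border_p(self, class_a: str, class_b: str) -> float:
        if isinstance(self.p_cross, Mapping):
            key = tuple(sorted((class_a, class_b)))
            if key in self.p_cross:
                return float(self.p_cross[key])
            return float(self.p_cross.get(("default", "default"), 1.0))
        return float(self.p_cross)


@dataclass
class SyntheticScene:
    """A generated scene plus the ground truth that produced it."""

    region_map: RegionMap
    astrocytes: CurveSet
    capillaries: CurveSet
    landmarks: np.ndarray
    config: GeneratorConfig


# ---------------------------------------------------------------------------
# region layouts


def _row_letters(n: int) -> list[str]:
    letters = string.ascii_uppercase
    if n > len(letters):
        raise ValueError(f"at most {len(letters)} rows supported")
    return list(letters[:n])


def sample_barrel_map(
    rows: int = 5,
    arcs: int = 5,
    core_span: tuple[float, float] = (350.0, 450.0),
    septum_width: float = 60.0,
    seed: int = 0,
    margin: float = 0.0,
) -> RegionMap:
    """Grid of rectangular barrel cores separated by a septal frame.

    Row heights and arc widths are drawn uniformly from ``core_span``;
    every core is surrounded by septum of ``septum_width``.  Cores are
    labeled row-letter + arc-number (``A1`` .. ``E5`` for 5x5).
    """
    if rows < 1 or arcs < 1:
        raise ValueError("rows and arcs must be >= 1")
    if septum_width <= 0:
        raise ValueError(f"septum_width must be > 0, got {septum_width}")
    lo, hi = (core_span, core_span) if np.isscalar(core_span) else core_span
    if lo <= 0 or hi < lo:
        raise ValueError(f"invalid core_span window {core_span!r}")
    if margin < 0:
        raise ValueError("margin must be >= 0")

    rng = stream(seed, "layout")
    heights = rng.uniform(lo, hi, rows)
    widths = rng.uniform(lo, hi, arcs)

    # left/bottom edges of each core; the septal frame wraps all cores
    x_left = margin + septum_width + np.concatenate(
        [[0.0], np.cumsum(widths + septum_width)])[:-1]
    y_bot = margin + septum_width + np.concatenate(
        [[0.0], np.cumsum(heights + septum_width)])[:-1]
    frame_x1 = float(x_left[-1] + widths[-1] + septum_width)
    frame_y1 = float(y_bot[-1] + heights[-1] + septum_width)
    frame = box(margin, margin, frame_x1, frame_y1)

    letters = _row_letters(rows)
    cores: list[Region] = []
    for r in range(rows):
        for a in range(arcs):
            poly = box(x_left[a], y_bot[r],
                       x_left[a] + widths[a], y_bot[r] + heights[r])
            cores.append(Region(poly, "core", f"{letters[r]}{a + 1}"))

    septum_poly = frame.difference(unary_union([c.polygon for c in cores]))
    regions = cores + [Region(septum_poly, "septum", "septum")]
    extent = (0.0, 0.0, frame_x1 + margin, frame_y1 + margin)
    return RegionMap(regions, extent)


def sample_area_map(layout: str, params: Mapping[str, float] | None = None,
                    seed: int = 0) -> RegionMap:
    """Two-class layouts with a single border, or a periodic blob mosaic.

    Layouts:

    ``A1_in_A2``
        disc of class ``A1`` (radius ``disc_radius``, default 750)
        inside an ``A2`` square; ``ring_width`` (default 350) of A2
        around the disc.
    ``laminar_IIIa_IIIb``
        horizontal border at ``border_y`` (default 0); ``IIIa`` above,
        ``IIIb`` below; ``width`` x 2*``half_height`` extent.
    ``blob_interblob``
        ``n_blobs`` discs of diameter ``blob_diameter`` (default 500)
        at period ``period`` (default 1000) in an ``interblob`` band.
    """
    p = dict(params or {})
    if layout == "A1_in_A2":
        radius = float(p.get("disc_radius", 750.0))
        ring = float(p.get("ring_width", 350.0))
        if radius <= 0 or ring <= 0:
            raise ValueError("disc_radius and ring_width must be > 0")
        half = radius + ring
        cx = cy = half
        extent = (0.0, 0.0, 2 * half, 2 * half)
        from shapely.geometry import Point
        disc = Point(cx, cy).buffer(radius, quad_segs=_CIRCLE_SEGMENTS)
        a2 = box(*extent).difference(disc)
        return RegionMap([Region(disc, "A1", "A1"), Region(a2, "A2", "A2")], extent)

    if layout == "laminar_IIIa_IIIb":
        width = float(p.get("width", 2000.0))
        hh = float(p.get("half_height", 600.0))
        y0 = float(p.get("border_y", 0.0))
        if width <= 0 or hh <= 0:
            raise ValueError("width and half_height must be > 0")
        extent = (0.0, y0 - hh, width, y0 + hh)
        upper = box(0.0, y0, width, y0 + hh)
        lower = box(0.0, y0 - hh, width, y0)
        return RegionMap(
            [Region(upper, "IIIa", "IIIa"), Region(lower, "IIIb", "IIIb")], extent)

    if layout == "blob_interblob":
        period = float(p.get("period", 1000.0))
        diameter = float(p.get("blob_diameter", 500.0))
        n_blobs = int(p.get("n_blobs", 5))
        height = float(p.get("height", 1000.0))
        if period <= 0 or diameter <= 0 or n_blobs < 1 or height <= 0:
            raise ValueError("blob layout parameters must be positive")
        if diameter >= period:
            raise ValueError(
                f"blob diameter {diameter} must be smaller than the period {period}")
        extent = (0.0, 0.0, n_blobs * period, height)
        from shapely.geometry import Point
        yc = height / 2.0
        blobs = [
            Region(Point((k + 0.5) * period, yc).buffer(diameter / 2.0,
                                                        quad_segs=_CIRCLE_SEGMENTS),
                   "blob", f"blob-{k}")
            for k in range(n_blobs)
        ]
        inter = box(*extent).difference(unary_union([b.polygon for b in blobs]))
        return RegionMap(blobs + [Region(inter, "interblob", "interblob")], extent)

    raise ValueError(f"unknown layout {layout!r}")


# ---------------------------------------------------------------------------
# fiber growth


def _bulk_random_walks(origins: np.ndarray, lengths: np.ndarray, step: float,
                       sigma: float, rng: np.random.Generator
                       ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Persistent random-walk step endpoints for all branches at once.

    Each branch walks in steps of ``step`` with a fractional final step,
    so its polyline arclength equals ``lengths[b]`` exactly (no
    discretization bias in the realized length density).  Returns
    (flat_vertices (total, 2), branch start offsets (B+1,), n_steps).
    """
    n_steps = np.maximum(1, np.ceil(lengths / step).astype(int))
    total = int(n_steps.sum())
    offsets = np.concatenate([[0], np.cumsum(n_steps)])
    starts = offsets[:-1]
    dl = np.full(total, step)
    dl[offsets[1:] - 1] = lengths - (n_steps - 1) * step
    inc = rng.normal(0.0, sigma, total)
    theta0 = rng.uniform(0.0, 2.0 * np.pi, len(n_steps))
    cs = np.cumsum(inc)
    base = np.repeat(cs[starts] - inc[starts], n_steps)
    theta = cs - base + np.repeat(theta0, n_steps)
    dx = dl * np.cos(theta)
    dy = dl * np.sin(theta)
    cx, cy = np.cumsum(dx), np.cumsum(dy)
    bx = np.repeat(cx[starts] - dx[starts], n_steps)
    by = np.repeat(cy[starts] - dy[starts], n_steps)
    vx = np.repeat(origins[:, 0], n_steps) + (cx - bx)
    vy = np.repeat(origins[:, 1], n_steps) + (cy - by)
    return np.column_stack([vx, vy]), offsets, n_steps


def _clip_to_extent(p0: np.ndarray, p1: np.ndarray,
                    extent: tuple[float, float, float, float]) -> np.ndarray:
    """Exit points of segments p0->p1 leaving the extent box (p0 inside).

    Vectorized over (n, 2) arrays.
    """
    xmin, ymin, xmax, ymax = extent
    d = p1 - p0
    t = np.ones(len(p0))
    for axis, lo, hi in ((0, xmin, xmax), (1, ymin, ymax)):
        with np.errstate(divide="ignore", invalid="ignore"):
            t_hi = (hi - p0[:, axis]) / d[:, axis]
            t_lo = (lo - p0[:, axis]) / d[:, axis]
        t = np.where((d[:, axis] > 0) & (p1[:, axis] > hi), np.minimum(t, t_hi), t)
        t = np.where((d[:, axis] < 0) & (p1[:, axis] < lo), np.minimum(t, t_lo), t)
    return p0 + np.clip(t, 0.0, 1.0)[:, None] * d


def _border_points(region_map: RegionMap, p0: np.ndarray, p1: np.ndarray,
                   n_iter: int = 20) -> np.ndarray:
    """First departure point from the start region along each segment.

    Vectorized bisection against the start point's region polygon (the
    step is short, so leaving the region coincides with the class
    change that triggered the event).
    """
    import shapely

    start_region = region_map.region_index_at(p0)
    lo = np.zeros(len(p0))
    hi = np.ones(len(p0))
    d = p1 - p0
    prepared = region_map._prepared()
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        pts = p0 + mid[:, None] * d
        same = np.empty(len(p0), dtype=bool)
        for r in np.unique(start_region):
            m = start_region == r
            if r < 0:
                same[m] = region_map.region_index_at(pts[m]) < 0
            else:
                same[m] = shapely.intersects_xy(prepared[r], pts[m, 0], pts[m, 1])
        lo = np.where(same, mid, lo)
        hi = np.where(same, hi, mid)
    return p0 + hi[:, None] * d


def grow_astrocyte_arbors(region_map: RegionMap, config: GeneratorConfig,
                          seed: int | None = None) -> CurveSet:
    """Grow boundary-confined branching arbors.

    Somata follow a homogeneous Poisson process per class; each soma
    emits Poisson-many branches grown as persistent random walks.  A
    step that changes region class is accepted with the border's
    ``p_cross``; on rejection the branch terminates exactly at the
    border.  Steps leaving the extent always terminate at the extent
    edge so every curve stays inside the field.
    """
    config.validate()
    root = config.seed if seed is None else seed
    rng_somata = stream(root, "somata")
    rng_branches = stream(root, "branches")

    mean_len_per_soma = config.branch_count_mean * config.branch_length_mean
    classes = sorted(set(config.fiber_density) | set(config.soma_intensity))

    somata_xy: list[np.ndarray] = []
    somata_label: list[str] = []
    xmin, ymin, xmax, ymax = region_map.extent
    for cls in classes:
        if cls in config.soma_intensity:
            intensity = config.soma_intensity[cls]
        else:
            if mean_len_per_soma <= 0:
                raise ValueError("cannot derive soma intensity: zero branch budget")
            intensity = config.fiber_density[cls] / mean_len_per_soma
        area = region_map.class_area(cls)
        n = rng_somata.poisson(intensity * area) if intensity * area > 0 else 0
        placed = 0
        while placed < n:
            batch = max(64, 4 * (n - placed))
            cand = np.column_stack([
                rng_somata.uniform(xmin, xmax, batch),
                rng_somata.uniform(ymin, ymax, batch),
            ])
            keep = region_map.class_at(cand) == cls
            pts = cand[keep][: n - placed]
            somata_xy.extend(pts)
            somata_label.extend([cls] * len(pts))
            placed += len(pts)
    somata_ids = [f"astro-{lab}-{i}" for i, lab in enumerate(somata_label)]

    if not somata_xy:
        return CurveSet()
    somata = np.asarray(somata_xy)

    n_branches = rng_branches.poisson(config.branch_count_mean, len(somata))
    branch_soma = np.repeat(np.arange(len(somata)), n_branches)
    B = len(branch_soma)
    if B == 0:
        return CurveSet()
    lengths = rng_branches.exponential(config.branch_length_mean, B)
    verts, offsets, n_steps = _bulk_random_walks(
        somata[branch_soma], lengths, config.step_length,
        config.turning_sigma, rng_branches)

    labels = region_map.class_at(verts)
    inside = ((verts[:, 0] >= xmin) & (verts[:, 0] <= xmax)
              & (verts[:, 1] >= ymin) & (verts[:, 1] <= ymax))

    # per-step start labels: previous vertex within the branch, soma label first
    start_labels = np.empty(len(verts), dtype=object)
    start_labels[1:] = labels[:-1]
    start_labels[offsets[:-1]] = np.asarray(somata_label, dtype=object)[branch_soma]
    change = (labels != start_labels) | ~inside

    # resolve crossing events in vectorized rounds: each round handles the
    # next unresolved event of every still-active branch
    ext = region_map.extent
    step_branch = np.repeat(np.arange(B), n_steps)
    ev_flat = np.flatnonzero(change)  # global step indices, grouped by branch
    ev_owner = step_branch[ev_flat]
    ptr = np.searchsorted(ev_owner, np.arange(B), side="left")
    ev_end = np.searchsorted(ev_owner, np.arange(B), side="right")
    trunc_flat = np.full(B, -1, dtype=np.int64)  # global step index of truncation

    p_lut: dict[tuple[str, str], float] = {}

    def lookup_p(a: str, b_: str) -> float:
        key = (a, b_)
        if key not in p_lut:
            p_lut[key] = config.border_p(a, b_)
        return p_lut[key]

    active = np.flatnonzero(ptr < ev_end)
    while len(active):
        k = ev_flat[ptr[active]]
        exit_mask = ~inside[k]
        ps = np.fromiter(
            (0.0 if ex else lookup_p(a, b_)
             for ex, a, b_ in zip(exit_mask, start_labels[k], labels[k])),
            dtype=float, count=len(k))
        draws = rng_branches.random(len(k))
        reject = draws >= ps
        trunc_flat[active[reject]] = k[reject]
        ptr[active[~reject]] += 1
        still = active[~reject]
        active = still[ptr[still] < ev_end[still]]

    # truncation points: extent exits clip analytically, class changes bisect
    trunc_pt = np.full((B, 2), np.nan)
    tb = np.flatnonzero(trunc_flat >= 0)
    if len(tb):
        k = trunc_flat[tb]
        at_start = k == offsets[:-1][tb]
        prev = np.where(at_start[:, None], somata[branch_soma[tb]], verts[k - 1])
        cur = verts[k]
        is_exit = ~inside[k]
        if is_exit.any():
            trunc_pt[tb[is_exit]] = _clip_to_extent(prev[is_exit], cur[is_exit], ext)
        if (~is_exit).any():
            trunc_pt[tb[~is_exit]] = _border_points(
                region_map, prev[~is_exit], cur[~is_exit])
    trunc_at = np.where(trunc_flat >= 0, trunc_flat - offsets[:-1], -1)

    # assemble output polylines in one flat array: per branch the soma
    # vertex, the kept step vertices, and (if truncated) the border point
    has_trunc = trunc_at >= 0
    n_keep = np.where(has_trunc, trunc_at, n_steps)
    n_out = 1 + n_keep + has_trunc.astype(int)
    out_starts = np.concatenate([[0], np.cumsum(n_out)])
    flat = np.empty((out_starts[-1], 2))
    flat[out_starts[:-1]] = somata[branch_soma]
    local = np.arange(len(verts)) - np.repeat(offsets[:-1], n_steps)
    keep_mask = local < n_keep[step_branch]
    dest = (np.repeat(out_starts[:-1], n_steps) + 1 + local)[keep_mask]
    flat[dest] = verts[keep_mask]
    flat[out_starts[1:][has_trunc] - 1] = trunc_pt[has_trunc]

    # drop branches truncated on their very first step at a border point
    # coincident with the soma (degenerate zero-length polylines)
    ok = np.ones(B, dtype=bool)
    deg = has_trunc & (n_keep == 0)
    if deg.any():
        d0 = np.linalg.norm(trunc_pt[deg] - somata[branch_soma[deg]], axis=1)
        ok[np.flatnonzero(deg)[d0 <= 1e-9]] = False

    ok_idx = np.flatnonzero(ok)
    spans = np.column_stack([out_starts[:-1][ok_idx], out_starts[1:][ok_idx]])
    ids = [somata_ids[branch_soma[b]] for b in ok_idx]

    # segment cache straight from the packed layout
    seg_keep = np.ones(out_starts[-1], dtype=bool)
    seg_keep[out_starts[1:] - 1] = False  # last vertex of a branch starts no step
    seg_keep &= np.repeat(ok, n_out)
    p0 = flat[seg_keep]
    p1 = flat[np.flatnonzero(seg_keep) + 1]
    seg_sid = np.repeat(branch_soma, n_out)[seg_keep]  # soma index as structure
    return CurveSet._from_packed(flat, spans, ids, (p0, p1, seg_sid))


# ---------------------------------------------------------------------------
# capillaries


def _segment_pieces(p0: np.ndarray, p1: np.ndarray, geom) -> list[np.ndarray]:
    seg = LineString([p0, p1])
    inter = seg.intersection(geom)
    if inter.is_empty:
        return []
    parts = getattr(inter, "geoms", [inter])
    out = []
    for g in parts:
        if isinstance(g, LineString) and g.length > 0:
            out.append(np.asarray(g.coords, dtype=float))
    return out


def sample_capillary_network(region_map: RegionMap,
                             length_density: float | Mapping[str, float],
                             seed: int = 0,
                             segment_length: float = 150.0) -> CurveSet:
    """Isotropic line-segment process with no border interaction.

    With a scalar density the process is stationary and isotropic over
    the whole extent (segments may originate outside and are clipped to
    the field), so its tangential distribution is homogeneous across
    region classes.  With a per-class mapping, the stationary process
    is generated per class and restricted to that class's region,
    yielding exactly the requested length density inside each class
    while remaining isotropic there.
    """
    if segment_length <= 0:
        raise ValueError("segment_length must be > 0")
    rng = stream(seed, "capillaries")
    xmin, ymin, xmax, ymax = region_map.extent
    pad = segment_length / 2.0
    bx0, by0 = xmin - pad, ymin - pad
    bx1, by1 = xmax + pad, ymax + pad
    buf_area = (bx1 - bx0) * (by1 - by0)

    targets: list[tuple[object, float]]
    if isinstance(length_density, Mapping):
        for v in length_density.values():
            if v < 0:
                raise ValueError("length_density must be >= 0")
        targets = [
            (unary_union([r.polygon for r in region_map.regions_of_class(c)]),
             length_density[c])
            for c in sorted(length_density)
        ]
    else:
        if length_density < 0:
            raise ValueError("length_density must be >= 0")
        targets = [(box(xmin, ymin, xmax, ymax), float(length_density))]

    curves: list[Curve] = []
    idx = 0
    for geom, rho in targets:
        if rho == 0 or geom.is_empty:
            continue
        n = rng.poisson(rho * buf_area / segment_length)
        if n == 0:
            continue
        centers = np.column_stack([
            rng.uniform(bx0, bx1, n), rng.uniform(by0, by1, n)])
        angles = rng.uniform(0.0, np.pi, n)
        d = 0.5 * segment_length * np.column_stack([np.cos(angles), np.sin(angles)])
        p0s, p1s = centers - d, centers + d
        for i in range(n):
            for piece in _segment_pieces(p0s[i], p1s[i], geom):
                curves.append(Curve(piece, f"cap-{idx}"))
                idx += 1
    return CurveSet(curves)


def sample_landmarks(region_map: RegionMap, n: int = 6, seed: int = 0) -> np.ndarray:
    """Shared alignment points ('penetrating arterioles') in the extent."""
    if n < 4:
        raise ValueError("at least 4 landmarks are required")
    rng = stream(seed, "landmarks")
    xmin, ymin, xmax, ymax = region_map.extent
    return np.column_stack([
        rng.uniform(xmin, xmax, n), rng.uniform(ymin, ymax, n)])


# ---------------------------------------------------------------------------
# section thinning


def thin_by_section(curves: CurveSet, retention: float, seed: int = 0) -> CurveSet:
    """Model thinner physical sections as i.i.d. polyline retention."""
    if not 0.0 < retention <= 1.0:
        raise ValueError(f"retention must lie in (0, 1], got {retention}")
    if retention == 1.0:
        return CurveSet(list(curves.curves))
    rng = stream(seed, "thinning")
    keep = rng.random(len(curves)) < retention
    return CurveSet([c for c, k in zip(curves.curves, keep) if k])


# ---------------------------------------------------------------------------
# calibration


def expected_crossings(line_length: float, density: float) -> float:
    """Isotropic line-intercept expectation 2*L*rho/pi."""
    return 2.0 * line_length * density / np.pi


def density_for_target_mean(target_mean: float, line_length: float) -> float:
    """Invert 2*L*rho/pi for the length density hitting a per-line mean."""
    if target_mean < 0:
        raise ValueError(f"target mean must be >= 0, got {target_mean}")
    if line_length <= 0:
        raise ValueError(f"line length must be > 0, got {line_length}")
    return np.pi * target_mean / (2.0 * line_length)


def calibrate_densities(target_means: Mapping[str, float],
                        line_length: float) -> dict[str, float]:
    """Per-class fiber length densities matching target per-line means."""
    return {cls: density_for_target_mean(m, line_length)
            for cls, m in target_means.items()}


def solve_confinement(simulated_mean: Callable[[float], float], target: float,
                      n_iter: int = 10, lo: float = 0.0, hi: float = 1.0) -> float:
    """Bisect for the p_cross whose simulated mean hits ``target``.

    ``simulated_mean`` must be (stochastically) non-decreasing in p.
    """
    f_lo, f_hi = simulated_mean(lo), simulated_mean(hi)
    if target <= f_lo:
        return lo
    if target >= f_hi:
        return hi
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        if simulated_mean(mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# rasterization


@dataclass
class RasterScene:
    """Raster export: region label channel plus fiber masks."""

    region_labels: np.ndarray  # (H, W) uint8 class index, 0 = background
    astrocyte_mask: np.ndarray  # (H, W) uint8
    capillary_mask: np.ndarray  # (H, W) uint8
    class_names: list[str]  # index 0 is background
    landmarks_px: np.ndarray  # (n, 2) pixel coordinates (col, row)
    pixel_size: float
    origin: tuple[float, float]

    def landmark_to_um(self, landmark_px: Sequence[float]) -> tuple[float, float]:
        col, row = landmark_px
        return (self.origin[0] + (col + 0.5) * self.pixel_size,
                self.origin[1] + (row + 0.5) * self.pixel_size)

    def write_tiff(self, path: str) -> None:
        import tifffile

        tifffile.imwrite(
            path,
            np.stack([self.region_labels, self.astrocyte_mask,
                      self.capillary_mask]),
            photometric="minisblack")


def _burn_curves(mask: np.ndarray, curves: CurveSet, origin: tuple[float, float],
                 pixel_size: float, stroke_width: float | None = None) -> None:
    """Mark pixels whose center lies within stroke_width/2 of any segment.

    Center-in-band marking makes the expected foreground pixel count
    equal (stroke area) / (pixel area) independently of orientation.
    """
    h, w = mask.shape
    half = 0.5 * (pixel_size if stroke_width is None else stroke_width)
    p0, p1, _ = curves.segments()
    for a, b in zip(p0, p1):
        lo = np.minimum(a, b) - half
        hi = np.maximum(a, b) + half
        c0 = max(0, int(np.floor((lo[0] - origin[0]) / pixel_size - 0.5)))
        c1 = min(w - 1, int(np.ceil((hi[0] - origin[0]) / pixel_size - 0.5)))
        r0 = max(0, int(np.floor((lo[1] - origin[1]) / pixel_size - 0.5)))
        r1 = min(h - 1, int(np.ceil((hi[1] - origin[1]) / pixel_size - 0.5)))
        if c1 < c0 or r1 < r0:
            continue
        cx = origin[0] + (np.arange(c0, c1 + 1) + 0.5) * pixel_size
        cy = origin[1] + (np.arange(r0, r1 + 1) + 0.5) * pixel_size
        gx, gy = np.meshgrid(cx, cy)
        d = b - a
        ll = d @ d
        if ll == 0:
            continue
        # perpendicular band only (no end caps): marked area = length * width
        t = ((gx - a[0]) * d[0] + (gy - a[1]) * d[1]) / ll
        dist2 = (gx - a[0] - t * d[0]) ** 2 + (gy - a[1] - t * d[1]) ** 2
        sub = mask[r0:r1 + 1, c0:c1 + 1]
        sub[(t >= 0.0) & (t <= 1.0) & (dist2 <= half * half)] = 1


def rasterize_scene(scene: SyntheticScene, pixel_size: float) -> RasterScene:
    """Optional raster bridge: label channel + fiber masks + px landmarks."""
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")
    rm = scene.region_map
    if pixel_size > min(rm.width, rm.height):
        raise ValueError("pixel_size exceeds the scene extent")
    xmin, ymin, _, _ = rm.extent
    w = int(np.ceil(rm.width / pixel_size))
    h = int(np.ceil(rm.height / pixel_size))
    xs = xmin + (np.arange(w) + 0.5) * pixel_size
    ys = ymin + (np.arange(h) + 0.5) * pixel_size
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    labels = rm.class_at(pts)
    class_names = [BACKGROUND] + [c for c in rm.class_labels() if c != BACKGROUND]
    lut = {name: i for i, name in enumerate(class_names)}
    region_idx = np.fromiter((lut[l] for l in labels), dtype=np.uint8,
                             count=len(labels)).reshape(h, w)
    astro = np.zeros((h, w), dtype=np.uint8)
    caps = np.zeros((h, w), dtype=np.uint8)
    _burn_curves(astro, scene.astrocytes, (xmin, ymin), pixel_size)
    _burn_curves(caps, scene.capillaries, (xmin, ymin), pixel_size)
    lm = np.asarray(scene.landmarks, dtype=float)
    lm_px = np.column_stack([(lm[:, 0] - xmin) / pixel_size - 0.5,
                             (lm[:, 1] - ymin) / pixel_size - 0.5]) if len(lm) else lm
    return RasterScene(region_idx, astro, caps, class_names, lm_px,
                       pixel_size, (xmin, ymin))
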