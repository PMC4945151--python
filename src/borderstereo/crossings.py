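"""Crossing counts, band density profiles and derived summary measures.

A crossing is a transversal intersection of a fiber polyline with the
open test segment.  Tangential touches are resolved by the side-change
rule: a polyline step counts iff its endpoints lie on different sides
of the line's carrier, with points exactly on the carrier assigned to
the positive half-plane.  A fiber crossing a line twice counts twice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core import CurveSet, MeasurementLine
from .geometry import DensityBand

__all__ = [
    "CROSSING_COLUMNS",
    "DensityProfile",
    "PairedSeries",
    "RatioStats",
    "count_line_crossings",
    "band_density_profile",
    "aggregate_profiles",
    "percent_drop",
    "septa_core_ratio",
    "co_density_series",
]

log = logging.getLogger(__name__)

#: frozen column order of a crossing table
CROSSING_COLUMNS = ["line_id", "placement", "side", "offset", "pair_key",
                    "scene_id", "count"]


def _flatten_segments(curves: CurveSet) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All polyline steps as (P0, P1, structure index) flat arrays."""
    return curves.segments()


def count_line_crossings(lines: Sequence[MeasurementLine], curves: CurveSet,
                         scene_id: str = "scene-0",
                         dedupe_structures: bool = False) -> pd.DataFrame:
    """Crossings of every line by every fiber step (side-change rule).

    Returns a table with columns `CROSSING_COLUMNS`.  With
    ``dedupe_structures`` each parent structure contributes at most one
    crossing per line (off by default: crossings, not processes, are
    counted).
    """
    p0, p1, sid = _flatten_segments(curves)
    rows = []
    for line in lines:
        a = np.asarray(line.start, dtype=float)
        b = np.asarray(line.end, dtype=float)
        d = b - a
        length = float(np.hypot(*d))
        if length == 0:
            raise ValueError(f"zero-length measurement line {line.line_id}")
        u = d / length
        nvec = np.array([-u[1], u[0]])
        if len(p0):
            s0 = (p0 - a) @ nvec
            s1 = (p1 - a) @ nvec
            side0 = np.where(s0 >= 0.0, 1, -1)
            side1 = np.where(s1 >= 0.0, 1, -1)
            change = side0 != side1
            if change.any():
                alpha = s0[change] / (s0[change] - s1[change])
                t0 = (p0[change] - a) @ u
                t1 = (p1[change] - a) @ u
                t = t0 + alpha * (t1 - t0)
                hit = (t > 0.0) & (t < length)
                if dedupe_structures:
                    n = int(len(np.unique(sid[change][hit])))
                else:
                    n = int(hit.sum())
            else:
                n = 0
        else:
            n = 0
        rows.append((line.line_id, line.placement, line.side, line.offset,
                     line.pair_key, scene_id, n))
    return pd.DataFrame(rows, columns=CROSSING_COLUMNS)


# ---------------------------------------------------------------------------
# density profiles


@dataclass
class DensityProfile:
    """Fiber length density along a band axis; border at position 0."""

    positions: np.ndarray
    density: np.ndarray
    band_id: str
    aggregate: bool = False

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if self.positions.shape != self.density.shape:
            raise ValueError("positions and density must match")
        if len(self.positions) > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")
        if np.any(self.density < -1e-12):
            raise ValueError("densities must be >= 0")


def _clip_segments_to_box(a0: np.ndarray, a1: np.ndarray,
                          lo: np.ndarray, hi: np.ndarray
                          ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Liang-Barsky clip of segments a0->a1 to the box [lo, hi] (vectorized)."""
    d = a1 - a0
    t0 = np.zeros(len(a0))
    t1 = np.ones(len(a0))
    keep = np.ones(len(a0), dtype=bool)
    for axis in (0, 1):
        for p, q in ((-d[:, axis], a0[:, axis] - lo[axis]),
                     (d[:, axis], hi[axis] - a0[:, axis])):
            with np.errstate(divide="ignore", invalid="ignore"):
                r = q / p
            par = p == 0
            keep &= ~(par & (q < 0))
            enter = (~par) & (p < 0)
            leave = (~par) & (p > 0)
            t0 = np.where(enter, np.maximum(t0, r), t0)
            t1 = np.where(leave, np.minimum(t1, r), t1)
    keep &= t0 <= t1
    c0 = a0 + t0[:, None] * d
    c1 = a0 + t1[:, None] * d
    return c0[keep], c1[keep], keep


def band_density_profile(band: DensityBand, curves: CurveSet,
                         step: float = 1.0) -> DensityProfile:
    """Length density per axial slab [s, s+step) across the band width."""
    if step <= 0:
        raise ValueError(f"step must be > 0, got {step}")
    half_l, half_w = band.length / 2.0, band.width / 2.0
    n_slabs = max(1, int(round(band.length / step)))
    edges = -half_l + step * np.arange(n_slabs + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    dens = np.zeros(n_slabs)

    p0, p1, _ = _flatten_segments(curves)
    if len(p0):
        rel0 = p0 - band.center
        rel1 = p1 - band.center
        f0 = np.column_stack([rel0 @ band.axis, rel0 @ band.across])
        f1 = np.column_stack([rel1 @ band.axis, rel1 @ band.across])
        lo = np.array([-half_l, -half_w])
        hi = np.array([half_l, half_w])
        c0, c1, _ = _clip_segments_to_box(f0, f1, lo, hi)
        for s0, s1 in zip(c0, c1):
            seg = s1 - s0
            seg_len = float(np.hypot(*seg))
            if seg_len == 0:
                continue
            a_lo, a_hi = sorted((s0[0], s1[0]))
            if a_hi == a_lo:
                i = int(np.clip(np.floor((s0[0] + half_l) / step), 0, n_slabs - 1))
                dens[i] += seg_len
                continue
            i0 = int(np.clip(np.floor((a_lo + half_l) / step), 0, n_slabs - 1))
            i1 = int(np.clip(np.floor((a_hi + half_l - 1e-12) / step), 0, n_slabs - 1))
            for i in range(i0, i1 + 1):
                ov = min(a_hi, edges[i + 1]) - max(a_lo, edges[i])
                if ov > 0:
                    dens[i] += seg_len * ov / (a_hi - a_lo)
    slab_area = step * band.width
    return DensityProfile(centers, dens / slab_area, band.band_id)


def aggregate_profiles(profiles: Sequence[DensityProfile]) -> DensityProfile:
    """Pointwise mean over profiles sharing one station grid."""
    if not profiles:
        raise ValueError("no profiles to aggregate")
    ref = profiles[0].positions
    for p in profiles[1:]:
        if p.positions.shape != ref.shape or not np.allclose(p.positions, ref):
            raise ValueError("profiles are on mismatched station grids")
    mean = np.mean([p.density for p in profiles], axis=0)
    return DensityProfile(ref.copy(), mean, "aggregate", aggregate=True)


def percent_drop(profile: DensityProfile,
                 inner_window: tuple[float, float] = (-50.0, -10.0),
                 outer_window: tuple[float, float] = (10.0, 50.0)) -> float:
    """100 * (1 - mean(outer) / mean(inner)) across the border at 0."""
    if not (inner_window[1] <= 0 <= outer_window[0]
            or outer_window[1] <= 0 <= inner_window[0]):
        raise ValueError("windows must lie on opposite sides of the border")
    pos = profile.positions

    def window_mean(w: tuple[float, float]) -> float:
        m = (pos >= w[0]) & (pos <= w[1])
        if not m.any():
            raise ValueError(f"no stations inside window {w}")
        return float(profile.density[m].mean())

    inner = window_mean(inner_window)
    outer = window_mean(outer_window)
    if inner == 0:
        raise ZeroDivisionError("inner-window mean density is zero; drop undefined")
    return 100.0 * (1.0 - outer / inner)


# ---------------------------------------------------------------------------
# septa / core ratio


@dataclass
class RatioStats:
    """Per-scene (or per-pair) septa/core crossing ratios with summaries."""

    ratios: np.ndarray
    method: str
    n_excluded: int = 0

    @property
    def n(self) -> int:
        return len(self.ratios)

    @property
    def mean(self) -> float:
        return float(np.mean(self.ratios)) if self.n else float("nan")

    @property
    def sem(self) -> float:
        if self.n < 2:
            return float("nan")
        return float(np.std(self.ratios, ddof=1) / np.sqrt(self.n))


def septa_core_ratio(table: pd.DataFrame,
                     method: str = "ratio_of_means") -> RatioStats:
    """Septa/core crossing ratio per scene (primary) or per pair.

    ``ratio_of_means``: one ratio per scene_id, (mean septal count) /
    (mean core count).  ``mean_of_ratios``: one ratio per pairing key,
    zero-denominator pairs excluded and logged.
    """
    sep = table[table["placement"] == "septal"]
    cor = table[table["placement"] == "core"]
    if sep.empty or cor.empty:
        raise ValueError("table contains no septal/core pairs")
    excluded = 0
    ratios: list[float] = []
    if method == "ratio_of_means":
        for scene, sub in table.groupby("scene_id"):
            s = sub[sub["placement"] == "septal"]["count"]
            c = sub[sub["placement"] == "core"]["count"]
            if s.empty or c.empty:
                continue
            if c.mean() == 0:
                excluded += 1
                continue
            ratios.append(float(s.mean() / c.mean()))
        if excluded:
            log.warning("excluded %d scenes with zero core mean", excluded)
    elif method == "mean_of_ratios":
        merged = pd.merge(
            sep.groupby(["scene_id", "pair_key"])["count"].mean().rename("septal"),
            cor.groupby(["scene_id", "pair_key"])["count"].mean().rename("core"),
            left_index=True, right_index=True, how="inner")
        zero = merged["core"] == 0
        excluded = int(zero.sum())
        if excluded:
            log.warning("excluded %d zero-denominator pairs", excluded)
        merged = merged[~zero]
        ratios = list(merged["septal"] / merged["core"])
    else:
        raise ValueError(f"unknown ratio method {method!r}")
    if not ratios:
        raise ValueError("no computable septa/core ratios")
    return RatioStats(np.asarray(ratios, dtype=float), method, excluded)


# ---------------------------------------------------------------------------
# CO / astrocyte paired series


@dataclass
class PairedSeries:
    """Two series aligned on one horizontal grid, ready for correlation."""

    positions: np.ndarray
    series_a: np.ndarray
    series_b: np.ndarray
    constant: bool = False


def co_density_series(co_profile: DensityProfile,
                      astro_profile: DensityProfile) -> PairedSeries:
    """Align a transmission profile with a density profile by position.

    Both series are linearly interpolated onto the overlap of their
    supports (the finer grid of the two); constant inputs are flagged
    because the downstream correlation is undefined for them.
    """
    lo = max(co_profile.positions.min(), astro_profile.positions.min())
    hi = min(co_profile.positions.max(), astro_profile.positions.max())
    if hi <= lo:
        raise ValueError("profiles have non-overlapping supports")
    steps = [np.diff(p.positions).min() for p in (co_profile, astro_profile)
             if len(p.positions) > 1]
    step = min(steps) if steps else (hi - lo)
    grid = np.arange(lo, hi + 0.5 * step, step)
    a = np.interp(grid, co_profile.positions, co_profile.density)
    b = np.interp(grid, astro_profile.positions, astro_profile.density)
    constant = bool(np.ptp(a) == 0 or np.ptp(b) == 0)
    if constant:
        log.warning("constant series: correlation will be undefined")
    return PairedSeries(grid, a, b, constant)
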