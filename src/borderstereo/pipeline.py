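"""Experiment presets and end-to-end orchestration.

Each preset fully determines the scene layout, the calibrated fiber
densities (via the Buffon inversion of its target per-line means), the
measurement-line placement, and the statistics that run on the pooled
crossing tables.  Presets:

``barrel_layer4``
    septal/core 375 µm line matrix on a barrel map; astrocytes fully
    confined, capillaries border-indifferent; pooled t-tests and
    septa/core ratios.
``barrel_layer3_5``
    the layer-IV line matrix re-used on independently drawn fiber sets
    for the layers above/below, after landmark-based rigid alignment;
    log-ratio ANOVA across the three layers.
``auditory_A1A2``
    disc border; 50 µm lines at 50/200 µm offsets on both sides plus
    ten 25x100 µm perpendicular density bands and the percent drop.
``human_IIIaIIIb``
    straight laminar border; 375 µm offset lines, 30 µm bands.
``human_blobs``
    periodic blob mosaic; 500 µm vertical lines at blob centers,
    inter-blob centers and inter-blob margins; CO-vs-density Pearson r.
``thickness_4v8``
    the layer-IV experiment at full retention vs 0.65, comparing mean
    counts and the septa/core ratio.
"""

from __future__ import annotations

import importlib.resources
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._rng import scene_seed, stream
from .core import CurveSet, MeasurementLine, RegionMap
from .crossings import (aggregate_profiles, band_density_profile,
                        co_density_series, count_line_crossings, percent_drop,
                        septa_core_ratio)
from .geometry import (apply_transform, estimate_landmark_transform,
                       extract_borders, place_blob_lines, place_density_bands,
                       place_offset_lines, place_septal_and_core_lines)
from .stats import anova_log_ratios, group_summary, pearson_r, students_t_pooled
from .synthetic import (GeneratorConfig, SyntheticScene, calibrate_densities,
                        grow_astrocyte_arbors, sample_area_map,
                        sample_barrel_map, sample_capillary_network,
                        sample_landmarks, thin_by_section)

__all__ = ["ExperimentPreset", "PRESET_NAMES", "get_preset", "simulate_scene",
           "run_experiment", "sweep_confinement"]

log = logging.getLogger(__name__)

#: arbor morphology used by the calibrated presets: small arbors keep the
#: per-line count distribution close to Poisson (low clumping variance)
#: and the border absorption layer thin, so the Buffon inversion holds at
#: the line positions without an empirical correction factor.
CALIBRATION_MORPHOLOGY = {"branch_count_mean": 3.0, "branch_length_mean": 10.0}

PRESET_NAMES = ("barrel_layer4", "barrel_layer3_5", "auditory_A1A2",
                "human_IIIaIIIb", "human_blobs", "thickness_4v8")


def _load_calibration() -> dict:
    ref = importlib.resources.files("borderstereo") / "calibration.yaml"
    return yaml.safe_load(ref.read_text())


@dataclass(frozen=True)
class ExperimentPreset:
    """Fully resolved parameters of one experiment."""

    name: str
    line_length: float
    astro_targets: Mapping[str, float]
    cap_targets: Mapping[str, float] | None
    layout: Mapping[str, object]
    placement: Mapping[str, object]
    morphology: Mapping[str, float]
    n_scenes: int
    extras: Mapping[str, object] = field(default_factory=dict)


_DEFAULT_SCENES = {"barrel_layer4": 60, "barrel_layer3_5": 30,
                   "auditory_A1A2": 12, "human_IIIaIIIb": 25,
                   "human_blobs": 40, "thickness_4v8": 60}


def get_preset(name: str) -> ExperimentPreset:
    cal = _load_calibration()["presets"]
    if name not in PRESET_NAMES:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    c = cal[name]
    line_length = float(c["line_length"])
    if name in ("barrel_layer4", "thickness_4v8"):
        targets = {"septum": c["astrocyte"]["septal"], "core": c["astrocyte"]["core"]}
        cap = c.get("capillary")
        cap_targets = ({"septum": cap["septal"], "core": cap["core"]}
                       if cap else None)
        extras = {}
        if name == "thickness_4v8":
            extras["thin_retention"] = float(c["thin_retention"])
        return ExperimentPreset(
            name, line_length, targets, cap_targets,
            layout={"kind": "barrel", "rows": 3, "arcs": 3, "septum_width": 100.0},
            placement={"core_span_window": (350.0, 450.0)},
            morphology=CALIBRATION_MORPHOLOGY, n_scenes=_DEFAULT_SCENES[name],
            extras=extras)
    if name == "barrel_layer3_5":
        extras = {
            "layer4": {"septum": cal["barrel_layer4"]["astrocyte"]["septal"],
                       "core": cal["barrel_layer4"]["astrocyte"]["core"]},
            "layer3": {"septum": c["astrocyte_layer3"]["septal"],
                       "core": c["astrocyte_layer3"]["core"]},
            "layer5": {"septum": c["astrocyte_layer5"]["septal"],
                       "core": c["astrocyte_layer5"]["core"]},
            "cap_layer4": {"septum": cal["barrel_layer4"]["capillary"]["septal"],
                           "core": cal["barrel_layer4"]["capillary"]["core"]},
            "cap_layer3": {"septum": c["capillary_layer3"]["septal"],
                           "core": c["capillary_layer3"]["core"]},
            "cap_layer5": {"septum": c["capillary_layer5"]["septal"],
                           "core": c["capillary_layer5"]["core"]},
        }
        return ExperimentPreset(
            name, line_length, extras["layer4"], extras["cap_layer4"],
            layout={"kind": "barrel", "rows": 3, "arcs": 3, "septum_width": 100.0},
            placement={"core_span_window": (350.0, 450.0)},
            morphology=CALIBRATION_MORPHOLOGY, n_scenes=_DEFAULT_SCENES[name],
            extras=extras)
    if name == "auditory_A1A2":
        return ExperimentPreset(
            name, line_length, dict(c["astrocyte"]), None,
            layout={"kind": "A1_in_A2", "disc_radius": 750.0, "ring_width": 300.0},
            placement={"offsets": (50.0, 200.0), "spacing": 235.0,
                       "band_width": 25.0, "band_length": 100.0, "band_count": 10,
                       "inner_class": "A1"},
            morphology=CALIBRATION_MORPHOLOGY, n_scenes=_DEFAULT_SCENES[name],
            extras={"reference_200um": dict(c["reference_200um"])})
    if name == "human_IIIaIIIb":
        return ExperimentPreset(
            name, line_length, dict(c["astrocyte"]), None,
            layout={"kind": "laminar_IIIa_IIIb", "width": 3000.0,
                    "half_height": 450.0},
            placement={"offsets": (50.0, 200.0), "spacing": 420.0,
                       "band_width": 30.0, "band_length": 100.0, "band_count": 10,
                       "inner_class": "IIIa"},
            morphology=CALIBRATION_MORPHOLOGY, n_scenes=_DEFAULT_SCENES[name],
            extras={"reference_200um": dict(c["reference_200um"])})
    if name == "human_blobs":
        return ExperimentPreset(
            name, line_length, dict(c["astrocyte"]), None,
            layout={"kind": "blob_interblob", "period": 1000.0,
                    "blob_diameter": 600.0, "n_blobs": 5, "height": 1000.0},
            placement={"margin_gap": 25.0},
            morphology=CALIBRATION_MORPHOLOGY, n_scenes=_DEFAULT_SCENES[name],
            extras={"reference_margin": dict(c["reference_margin"])})
    raise AssertionError("unreachable")


# ---------------------------------------------------------------------------
# scene construction per preset


def _astro_config(preset: ExperimentPreset,
                  targets: Mapping[str, float] | None = None) -> GeneratorConfig:
    dens = calibrate_densities(dict(targets or preset.astro_targets),
                               preset.line_length)
    return GeneratorConfig(fiber_density=dens, p_cross=0.0, **preset.morphology)


def _make_region_map(preset: ExperimentPreset, seed: int) -> RegionMap:
    layout = dict(preset.layout)
    kind = layout.pop("kind")
    if kind == "barrel":
        return sample_barrel_map(seed=seed, **layout)
    return sample_area_map(kind, layout, seed=seed)


def _place_lines(preset: ExperimentPreset, region_map: RegionMap
                 ) -> list[MeasurementLine]:
    if preset.layout["kind"] == "barrel":
        return place_septal_and_core_lines(
            region_map, preset.line_length,
            preset.placement["core_span_window"])
    if preset.layout["kind"] == "blob_interblob":
        return place_blob_lines(region_map, preset.line_length,
                                preset.placement["margin_gap"])
    border = extract_borders(region_map)[0]
    return place_offset_lines(border, preset.placement["offsets"],
                              preset.line_length,
                              spacing=preset.placement["spacing"],
                              extent=region_map.extent)


def generate_scene(preset: ExperimentPreset, index: int, seed: int
                   ) -> SyntheticScene:
    """One serializable scene for this preset (region map, fibers, landmarks)."""
    sseed = scene_seed(seed, index)
    rm = _make_region_map(preset, sseed)
    cfg = _astro_config(preset)
    if preset.cap_targets:
        cap_dens = calibrate_densities(dict(preset.cap_targets),
                                       preset.line_length)
        cfg = GeneratorConfig(**{**cfg.__dict__, "capillary_density": cap_dens})
    astro = grow_astrocyte_arbors(rm, cfg, seed=sseed)
    caps = (sample_capillary_network(rm, cfg.capillary_density, seed=sseed)
            if preset.cap_targets else CurveSet())
    landmarks = sample_landmarks(rm, n=6, seed=sseed)
    return SyntheticScene(rm, astro, caps, landmarks, cfg)


def simulate_scene(preset: ExperimentPreset, index: int, seed: int) -> dict:
    """Generate, measure and (optionally) profile one scene.

    Returns a dict with the crossing table(s) and any band profiles.
    """
    sseed = scene_seed(seed, index)
    rm = _make_region_map(preset, sseed)
    lines = _place_lines(preset, rm)
    sid = f"scene-{index}"
    out: dict = {"scene_id": sid, "region_map": rm, "lines": lines}

    if preset.name in ("barrel_layer4", "thickness_4v8"):
        astro = grow_astrocyte_arbors(rm, _astro_config(preset), seed=sseed)
        tab_a = count_line_crossings(lines, astro, scene_id=sid)
        tab_a["structure"] = "astrocyte"
        tables = [tab_a]
        if preset.cap_targets:
            caps = sample_capillary_network(
                rm, calibrate_densities(dict(preset.cap_targets),
                                        preset.line_length), seed=sseed)
            tab_c = count_line_crossings(lines, caps, scene_id=sid)
            tab_c["structure"] = "capillary"
            tables.append(tab_c)
        out["table"] = pd.concat(tables, ignore_index=True)
        if preset.name == "thickness_4v8":
            thin = thin_by_section(astro, preset.extras["thin_retention"],
                                   seed=sseed)
            tab_t = count_line_crossings(lines, thin, scene_id=sid)
            tab_t["structure"] = "astrocyte_thin"
            out["table"] = pd.concat([out["table"], tab_t], ignore_index=True)
        out["astrocytes"] = astro
        return out

    if preset.name == "barrel_layer3_5":
        landmarks = sample_landmarks(rm, n=6, seed=sseed)
        tables = []
        rng_align = stream(sseed, "alignment")
        for li, (layer, key) in enumerate(
                (("IV", "layer4"), ("III", "layer3"), ("V", "layer5"))):
            cfg = _astro_config(preset, preset.extras[key])
            astro = grow_astrocyte_arbors(rm, cfg, seed=scene_seed(sseed, li))
            caps = sample_capillary_network(
                rm, calibrate_densities(dict(preset.extras[f"cap_{key}"]),
                                        preset.line_length),
                seed=scene_seed(sseed, 500 + li))
            if layer == "IV":
                lines_layer = lines
            else:
                # the drawn image of this layer lives in its own frame:
                # displace it rigidly, then recover the alignment from the
                # shared landmark pattern and carry the lines across
                true_tf = _random_misalignment(rng_align)
                astro = apply_transform(true_tf, astro)
                caps = apply_transform(true_tf, caps)
                lm_img = true_tf.apply_points(landmarks)
                est = estimate_landmark_transform(landmarks, lm_img)
                lines_layer = [apply_transform(est, l) for l in lines]
            for struct, cs in (("astrocyte", astro), ("capillary", caps)):
                t = count_line_crossings(lines_layer, cs, scene_id=sid)
                t["structure"] = struct
                t["layer"] = layer
                tables.append(t)
        out["table"] = pd.concat(tables, ignore_index=True)
        return out

    if preset.name in ("auditory_A1A2", "human_IIIaIIIb"):
        astro = grow_astrocyte_arbors(rm, _astro_config(preset), seed=sseed)
        tab = count_line_crossings(lines, astro, scene_id=sid)
        tab["structure"] = "astrocyte"
        out["table"] = tab
        border = extract_borders(rm)[0]
        bands = place_density_bands(border, preset.placement["band_width"],
                                    preset.placement["band_length"],
                                    preset.placement["band_count"])
        inner = preset.placement["inner_class"]
        bands = [b.oriented(inner) for b in bands]
        out["profiles"] = [band_density_profile(b, astro) for b in bands]
        out["astrocytes"] = astro
        return out

    if preset.name == "human_blobs":
        astro = grow_astrocyte_arbors(rm, _astro_config(preset), seed=sseed)
        tab = count_line_crossings(lines, astro, scene_id=sid)
        tab["structure"] = "astrocyte"
        out["table"] = tab
        out["astrocytes"] = astro
        out["co_series"] = _co_correlation_inputs(preset, rm, astro)
        return out

    raise AssertionError("unreachable")


def _random_misalignment(rng: np.random.Generator):
    from .geometry import RigidTransform

    angle = rng.normal(0.0, 0.05)
    shift = rng.normal(0.0, 40.0, 2)
    return RigidTransform(float(angle), (float(shift[0]), float(shift[1])))


def _co_correlation_inputs(preset: ExperimentPreset, rm: RegionMap,
                           astro: CurveSet):
    """CO transmission vs astrocyte density along a horizontal traverse.

    The synthetic CO transmission dips inside blobs (dense staining
    absorbs light); the astrocyte density profile is measured along the
    same traverse with a wide horizontal band.
    """
    from .crossings import DensityProfile
    from .geometry import DensityBand

    xmin, ymin, xmax, ymax = rm.extent
    cx, cy = (xmin + xmax) / 2.0, (ymin + ymax) / 2.0
    band = DensityBand(np.array([cx, cy]), np.array([1.0, 0.0]),
                       width=float(preset.line_length),
                       length=float(xmax - xmin), band_id="co-traverse")
    astro_profile = band_density_profile(band, astro, step=10.0)
    xs = astro_profile.positions + cx
    sigma = preset.layout["blob_diameter"] / 3.0
    trans = np.ones_like(xs)
    for blob in rm.regions_of_class("blob"):
        c = blob.polygon.centroid.x
        trans -= 0.5 * np.exp(-0.5 * ((xs - c) / sigma) ** 2)
    co_profile = DensityProfile(astro_profile.positions, trans, "co-transmission")
    return co_density_series(co_profile, astro_profile)


# ---------------------------------------------------------------------------
# experiment driver


def _group_values(table: pd.DataFrame, **filters) -> np.ndarray:
    sub = table
    for col, val in filters.items():
        sub = sub[sub[col] == val]
    return sub["count"].to_numpy(dtype=float)


def _summ(x: np.ndarray) -> dict:
    return group_summary(x).as_dict()


def run_experiment(name: str, seed: int = 0, n_scenes: int | None = None,
                   out_dir: str | None = None) -> dict:
    """Run a preset end-to-end and return (and optionally write) a report."""
    preset = get_preset(name)
    n = n_scenes or preset.n_scenes
    log.info("preset=%s seed=%d scenes=%d", name, seed, n)
    results = [simulate_scene(preset, i, seed) for i in range(n)]
    table = pd.concat([r["table"] for r in results], ignore_index=True)
    log.info("pooled crossing table: %d rows", len(table))

    report: dict = {
        "preset": name, "seed": seed, "n_scenes": n,
        "version": __version__,
        "groups": {}, "tests": {},
    }

    if name in ("barrel_layer4", "thickness_4v8"):
        for struct in table["structure"].unique():
            sep = _group_values(table, structure=struct, placement="septal")
            cor = _group_values(table, structure=struct, placement="core")
            report["groups"][f"{struct}_septal"] = _summ(sep)
            report["groups"][f"{struct}_core"] = _summ(cor)
            report["tests"][f"{struct}_septal_vs_core"] = \
                students_t_pooled(sep, cor).as_dict()
            sub = table[table["structure"] == struct]
            ratio = septa_core_ratio(sub)
            report["groups"][f"{struct}_septa_core_ratio"] = {
                "n": ratio.n, "mean": ratio.mean, "sem": ratio.sem}
        if name == "thickness_4v8":
            thick = _group_values(table, structure="astrocyte")
            thin = _group_values(table, structure="astrocyte_thin")
            report["tests"]["thin_count_reduction_pct"] = float(
                100.0 * (1.0 - thin.mean() / thick.mean()))
    elif name == "barrel_layer3_5":
        ratio_sets = {}
        for struct in ("astrocyte", "capillary"):
            for layer in ("III", "IV", "V"):
                sub = table[(table["structure"] == struct)
                            & (table["layer"] == layer)]
                sep = _group_values(sub, placement="septal")
                cor = _group_values(sub, placement="core")
                report["groups"][f"{struct}_L{layer}_septal"] = _summ(sep)
                report["groups"][f"{struct}_L{layer}_core"] = _summ(cor)
                report["tests"][f"{struct}_L{layer}_septal_vs_core"] = \
                    students_t_pooled(sep, cor).as_dict()
                ratios = septa_core_ratio(sub)
                ratio_sets[(struct, layer)] = ratios.ratios
                report["groups"][f"{struct}_L{layer}_ratio"] = {
                    "n": ratios.n, "mean": ratios.mean, "sem": ratios.sem}
            anova = anova_log_ratios(ratio_sets[(struct, "III")],
                                     ratio_sets[(struct, "IV")],
                                     ratio_sets[(struct, "V")])
            report["tests"][f"{struct}_ratio_anova_layers"] = anova.as_dict()
    elif name in ("auditory_A1A2", "human_IIIaIIIb"):
        sides = sorted(table["side"].unique())
        for side in sides:
            for off in (50.0, 200.0):
                vals = _group_values(table, side=side, offset=off)
                report["groups"][f"{side}@{off:g}"] = _summ(vals)
        inner, outer = (("A1", "A2") if name == "auditory_A1A2"
                        else ("IIIa", "IIIb"))
        for off in (50.0, 200.0):
            a = _group_values(table, side=inner, offset=off)
            b = _group_values(table, side=outer, offset=off)
            report["tests"][f"{inner}_vs_{outer}@{off:g}"] = \
                students_t_pooled(a, b).as_dict()
        for side in (inner, outer):
            a = _group_values(table, side=side, offset=50.0)
            b = _group_values(table, side=side, offset=200.0)
            report["tests"][f"{side}_50_vs_200"] = students_t_pooled(a, b).as_dict()
        profiles = [p for r in results for p in r.get("profiles", [])]
        agg = aggregate_profiles(profiles)
        report["density_drop_pct"] = percent_drop(agg)
        report["profile"] = {"positions": agg.positions.tolist(),
                             "density": agg.density.tolist()}
    elif name == "human_blobs":
        for pl in ("blob-center", "interblob-center", "interblob-margin"):
            report["groups"][pl] = _summ(_group_values(table, placement=pl))
        ibc = _group_values(table, placement="interblob-center")
        ibm = _group_values(table, placement="interblob-margin")
        bc = _group_values(table, placement="blob-center")
        report["tests"]["interblob_center_vs_blob"] = \
            students_t_pooled(ibc, bc).as_dict()
        report["tests"]["interblob_margin_vs_blob"] = \
            students_t_pooled(ibm, bc).as_dict()
        report["tests"]["interblob_center_vs_margin"] = \
            students_t_pooled(ibc, ibm).as_dict()
        rs, ps = [], []
        for r in results:
            series = r["co_series"]
            if not series.constant:
                rr, pp = pearson_r(series.series_a, series.series_b)
                rs.append(rr)
                ps.append(pp)
        report["tests"]["co_astro_pearson"] = {
            "mean_r": float(np.mean(rs)), "n": len(rs),
            "r_values": [float(v) for v in rs[:10]]}

    if out_dir is not None:
        from .io import write_scene

        os.makedirs(out_dir, exist_ok=True)
        table.to_csv(os.path.join(out_dir, f"{name}_crossings.csv"), index=False)
        with open(os.path.join(out_dir, f"{name}_report.json"), "w") as fh:
            json.dump(report, fh, indent=2)
        write_scene(generate_scene(preset, 0, seed),
                    os.path.join(out_dir, f"{name}_scene0.geojson"))
        log.info("wrote outputs to %s", out_dir)
    return report


# ---------------------------------------------------------------------------
# confinement sweep


def sweep_confinement(p_grid: Sequence[float], replicates: int = 50,
                      seed: int = 0, target_mean: float = 8.0) -> pd.DataFrame:
    """Septa/core ratio as a function of the border crossing probability.

    Somata live only in the cores of a thin-septum barrel map, with
    long branches, so the septal compartment fills purely through
    border crossings: the ratio runs from ~0 (full confinement) to ~1
    (border-indifferent null).
    """
    for p in p_grid:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p_cross grid value {p} outside [0, 1]")
    dens = {"core": calibrate_densities({"core": target_mean}, 375.0)["core"]}
    rows = []
    for gi, p in enumerate(p_grid):
        cfg = GeneratorConfig(fiber_density=dens, p_cross=float(p),
                              branch_count_mean=5.0, branch_length_mean=100.0)
        ratios = []
        for i in range(replicates):
            sseed = scene_seed(seed, gi * 100003 + i)
            rm = sample_barrel_map(2, 2, core_span=(400.0, 450.0),
                                   septum_width=10.0, seed=sseed)
            lines = place_septal_and_core_lines(rm)
            astro = grow_astrocyte_arbors(rm, cfg, seed=sseed)
            tab = count_line_crossings(lines, astro, scene_id=f"s{i}")
            ratios.append(septa_core_ratio(tab).mean)
        arr = np.asarray(ratios)
        rows.append({"p_cross": float(p), "ratio_mean": float(arr.mean()),
                     "ratio_se": float(arr.std(ddof=1) / np.sqrt(len(arr))),
                     "replicates": len(arr)})
    return pd.DataFrame(rows)
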