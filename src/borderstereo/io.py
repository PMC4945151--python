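"""Serialization: GeoJSON scenes, YAML configs, JSON transforms/reports.

Scenes round-trip through a single GeoJSON FeatureCollection: regions
as Polygons with a ``class`` property, fibers as LineStrings with a
``structure_id``, landmarks as Points.  Ground-truth generator
parameters travel in a JSON sidecar (or the collection's ``config``
member).
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np
import yaml
from shapely.geometry import Polygon, mapping, shape

from .core import Curve, CurveSet, Region, RegionMap
from .geometry import RigidTransform
from .synthetic import GeneratorConfig, SyntheticScene

__all__ = [
    "scene_to_geojson",
    "scene_from_geojson",
    "write_scene",
    "read_scene",
    "lines_to_geojson",
    "config_to_yaml",
    "config_from_yaml",
    "transform_to_json",
    "transform_from_json",
]


def _config_to_dict(config: GeneratorConfig) -> dict:
    d = dataclasses.asdict(config)
    if isinstance(d.get("p_cross"), dict):
        d["p_cross"] = {"|".join(k): v for k, v in d["p_cross"].items()}
    return d


def _config_from_dict(d: dict) -> GeneratorConfig:
    d = dict(d)
    p = d.get("p_cross")
    if isinstance(p, dict):
        d["p_cross"] = {tuple(k.split("|")): float(v) for k, v in p.items()}
    return GeneratorConfig(**d)


def scene_to_geojson(scene: SyntheticScene) -> dict:
    features: list[dict] = []
    for r in scene.region_map.regions:
        features.append({
            "type": "Feature",
            "geometry": mapping(r.polygon),
            "properties": {"kind": "region", "class": r.class_label,
                           "region_id": r.region_id},
        })
    for name, cs in (("astrocyte", scene.astrocytes),
                     ("capillary", scene.capillaries)):
        for i, c in enumerate(cs):
            features.append({
                "type": "Feature",
                "geometry": {"type": "LineString",
                             "coordinates": c.vertices.tolist()},
                "properties": {"kind": name, "structure_id": c.structure_id},
            })
    for i, (x, y) in enumerate(np.asarray(scene.landmarks, dtype=float)):
        features.append({
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [float(x), float(y)]},
            "properties": {"kind": "landmark", "landmark_id": i},
        })
    return {
        "type": "FeatureCollection",
        "features": features,
        "extent": list(scene.region_map.extent),
        "config": _config_to_dict(scene.config),
    }


def scene_from_geojson(doc: dict) -> SyntheticScene:
    regions: list[Region] = []
    astro: list[Curve] = []
    caps: list[Curve] = []
    landmarks: list[list[float]] = []
    for feat in doc["features"]:
        props = feat.get("properties", {})
        kind = props.get("kind")
        if kind == "region":
            poly = shape(feat["geometry"])
            if not isinstance(poly, Polygon):
                poly = poly.geoms[0]
            regions.append(Region(poly, props["class"], props["region_id"]))
        elif kind in ("astrocyte", "capillary"):
            curve = Curve(np.asarray(feat["geometry"]["coordinates"], dtype=float),
                          props["structure_id"])
            (astro if kind == "astrocyte" else caps).append(curve)
        elif kind == "landmark":
            landmarks.append(feat["geometry"]["coordinates"])
    region_map = RegionMap(regions, tuple(doc["extent"]))
    config = _config_from_dict(doc.get("config", {}))
    return SyntheticScene(region_map, CurveSet(astro), CurveSet(caps),
                          np.asarray(landmarks, dtype=float), config)


def write_scene(scene: SyntheticScene, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(scene_to_geojson(scene), fh)


def read_scene(path: str) -> SyntheticScene:
    with open(path) as fh:
        return scene_from_geojson(json.load(fh))


def lines_to_geojson(lines) -> dict:
    features = []
    for line in lines:
        features.append({
            "type": "Feature",
            "geometry": {"type": "LineString",
                         "coordinates": [list(line.start), list(line.end)]},
            "properties": {"kind": "measurement_line", "line_id": line.line_id,
                           "placement": line.placement, "pair_key": line.pair_key,
                           "side": line.side, "offset": line.offset},
        })
    return {"type": "FeatureCollection", "features": features}


def config_to_yaml(config: GeneratorConfig, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_config_to_dict(config), fh, sort_keys=False)


def config_from_yaml(path: str) -> GeneratorConfig:
    with open(path) as fh:
        return _config_from_dict(yaml.safe_load(fh))


def transform_to_json(tf: RigidTransform) -> str:
    return json.dumps({"rotation": tf.rotation, "translation": list(tf.translation),
                       "scale": tf.scale, "rms_residual": tf.rms_residual})


def transform_from_json(text: str) -> RigidTransform:
    d = json.loads(text)
    return RigidTransform(d["rotation"], tuple(d["translation"]),
                          d.get("scale", 1.0), d.get("rms_residual", 0.0))
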