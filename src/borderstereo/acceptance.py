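"""Calibration-recovery harness: measured grand means per target group.

Each target is recovered by running the full chain — generate calibrated
scenes, place measurement lines, count crossings — and reporting the
measured grand mean of the named line group (crossings per line).  The
calibration constants enter only as generator densities through the
Buffon inversion; the reported values are measured, never assigned.
"""

from __future__ import annotations

from .pipeline import run_experiment

__all__ = ["TARGETS", "ACCEPTANCE_SCENES", "recover_target_means"]

#: target id -> (preset, report group key)
TARGETS = {
    "t1": ("barrel_layer4", "astrocyte_septal"),
    "t2": ("barrel_layer4", "astrocyte_core"),
    "t3": ("barrel_layer4", "capillary_septal"),
    "t4": ("barrel_layer4", "capillary_core"),
    "t5": ("auditory_A1A2", "A1@50"),
    "t6": ("auditory_A1A2", "A2@50"),
    "t7": ("human_IIIaIIIb", "IIIa@50"),
    "t8": ("human_IIIaIIIb", "IIIb@50"),
    "t9": ("human_blobs", "interblob-center"),
    "t10": ("human_blobs", "blob-center"),
}

#: scene counts sized so the grand-mean s.e. stays well under the 5%
#: comparison tolerance for every group (the septal and blob groups have
#: the largest per-line dispersion)
ACCEPTANCE_SCENES = {
    "barrel_layer4": 200,
    "auditory_A1A2": 50,
    "human_IIIaIIIb": 100,
    "human_blobs": 400,
}


def recover_target_means(seed: int,
                         scene_counts: dict[str, int] | None = None) -> dict:
    """Measured grand mean and group size for every acceptance target."""
    counts = {**ACCEPTANCE_SCENES, **(scene_counts or {})}
    presets = sorted({preset for preset, _ in TARGETS.values()})
    reports = {p: run_experiment(p, seed=seed, n_scenes=counts[p])
               for p in presets}
    out = {}
    for tid, (preset, group) in TARGETS.items():
        g = reports[preset]["groups"][group]
        out[tid] = {"value": float(g["mean"]), "n": int(g["n"])}
    return out
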