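"""Named, independent random streams derived from one root seed.

Each component (somata, branches, capillaries, thinning, landmarks, ...)
draws from its own child stream so adding or reordering components never
perturbs the draws of the others.
"""

from __future__ import annotations

import numpy as np

# fixed registry: stream key -> spawn index (append-only)
_STREAMS = {
    "somata": 0,
    "branches": 1,
    "capillaries": 2,
    "thinning": 3,
    "landmarks": 4,
    "layout": 5,
    "calibration": 6,
    "scene": 7,
    "alignment": 8,
}


def scene_seed(root_seed: int, index: int) -> int:
    """Deterministic per-scene integer seed derived from the root seed."""
    return int(stream(root_seed, "scene", index).integers(2 ** 62))


def stream(seed: int, name: str, index: int = 0) -> np.random.Generator:
    """Generator for the named component under the given root seed.

    ``index`` sub-keys a stream (e.g. per-scene replicates).
    """
    try:
        key = _STREAMS[name]
    except KeyError:
        raise KeyError(f"unknown RNG stream {name!r}; known: {sorted(_STREAMS)}") from None
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(key, int(index)))
    return np.random.Generator(np.random.PCG64(ss))
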