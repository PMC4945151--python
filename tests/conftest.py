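import numpy as np
import pytest
from shapely.geometry import box

from borderstereo.core import Curve, CurveSet, MeasurementLine, Region, RegionMap
from borderstereo.synthetic import sample_area_map, sample_barrel_map


@pytest.fixture
def barrel_map():
    return sample_barrel_map(rows=3, arcs=3, septum_width=100.0, seed=1)


@pytest.fixture
def disc_map():
    return sample_area_map("A1_in_A2", {"ring_width": 300.0}, seed=1)


@pytest.fixture
def laminar_map():
    return sample_area_map("laminar_IIIa_IIIb", seed=1)


@pytest.fixture
def blob_map():
    return sample_area_map("blob_interblob", {"blob_diameter": 600.0}, seed=1)


@pytest.fixture
def two_region_map():
    """Two abutting unit-labeled rectangles inside a 200x100 extent."""
    left = Region(box(0, 0, 100, 100), "left", "L")
    right = Region(box(100, 0, 200, 100), "right", "R")
    return RegionMap([left, right], (0, 0, 200, 100))


@pytest.fixture
def horizontal_line():
    return MeasurementLine(start=(10.0, 50.0), end=(90.0, 50.0),
                           placement="test", line_id="hline")


def make_curves(*vertex_lists, structure_id="s0"):
    return CurveSet([Curve(np.asarray(v, dtype=float), structure_id)
                     for v in vertex_lists])
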