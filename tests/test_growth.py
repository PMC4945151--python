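import json

import numpy as np
import pytest
from shapely.geometry import LineString

from borderstereo.core import CurveSet
from borderstereo.crossings import count_line_crossings
from borderstereo.geometry import extract_borders, place_septal_and_core_lines
from borderstereo.io import scene_to_geojson
from borderstereo.synthetic import (GeneratorConfig, SyntheticScene,
                                    calibrate_densities, density_for_target_mean,
                                    expected_crossings, grow_astrocyte_arbors,
                                    rasterize_scene, sample_area_map,
                                    sample_barrel_map, sample_capillary_network,
                                    sample_landmarks, solve_confinement,
                                    thin_by_section)

MORPH = {"branch_count_mean": 3.0, "branch_length_mean": 20.0}


class TestConfig:
    def test_validates_p_cross_range(self):
        with pytest.raises(ValueError, match="p_cross"):
            GeneratorConfig(p_cross=1.5).validate()

    def test_validates_retention(self):
        with pytest.raises(ValueError, match="retention"):
            GeneratorConfig(retention=0.0).validate()

    def test_validates_negative_density(self):
        with pytest.raises(ValueError):
            GeneratorConfig(fiber_density={"a": -1.0}).validate()

    def test_negative_step_rejected(self):
        with pytest.raises(ValueError, match="step"):
            GeneratorConfig(step_length=-5.0).validate()

    def test_border_p_lookup(self):
        cfg = GeneratorConfig(p_cross={("a", "b"): 0.25})
        assert cfg.border_p("b", "a") == 0.25
        assert cfg.border_p("a", "c") == 1.0  # unlisted pairs default open


class TestArborGrowth:
    def test_full_confinement_never_crosses_borders(self, barrel_map):
        dens = calibrate_densities({"septum": 4.0, "core": 8.0}, 375.0)
        cfg = GeneratorConfig(fiber_density=dens, p_cross=0.0, **MORPH)
        astro = grow_astrocyte_arbors(barrel_map, cfg, seed=11)
        assert len(astro) > 100
        borders = [LineString(b.vertices) for b in extract_borders(barrel_map)]
        crossings = 0
        p0, p1, _ = astro.segments()
        for b in borders:
            for i in range(0, len(p0), 997):  # sample segments for speed
                seg = LineString([p0[i], p1[i]])
                if seg.crosses(b):
                    crossings += 1
        assert crossings == 0

    def test_full_confinement_keeps_class_pure(self, barrel_map):
        cfg = GeneratorConfig(fiber_density={"core": 0.01}, p_cross=0.0, **MORPH)
        astro = grow_astrocyte_arbors(barrel_map, cfg, seed=3)
        p0, p1, _ = astro.segments()
        mids = 0.5 * (p0 + p1)
        labels = barrel_map.class_at(mids)
        assert (labels == "core").mean() > 0.999

    def test_curves_stay_inside_extent(self, disc_map):
        cfg = GeneratorConfig(fiber_density={"A2": 0.01}, p_cross=1.0, **MORPH)
        astro = grow_astrocyte_arbors(disc_map, cfg, seed=5)
        xmin, ymin, xmax, ymax = disc_map.extent
        for c in astro:
            v = c.vertices
            assert v[:, 0].min() >= xmin - 1e-9 and v[:, 0].max() <= xmax + 1e-9
            assert v[:, 1].min() >= ymin - 1e-9 and v[:, 1].max() <= ymax + 1e-9

    def test_zero_density_gives_empty_set(self, barrel_map):
        cfg = GeneratorConfig(fiber_density={"core": 0.0})
        assert len(grow_astrocyte_arbors(barrel_map, cfg, seed=0)) == 0

    def test_tagged_with_soma_ids(self, barrel_map):
        cfg = GeneratorConfig(fiber_density={"core": 0.002}, **MORPH)
        astro = grow_astrocyte_arbors(barrel_map, cfg, seed=0)
        assert all(c.structure_id.startswith("astro-core-") for c in astro)

    def test_interior_line_matches_buffon(self):
        """Mean crossings of an interior line ~= 2*L*rho/pi (3 s.e.)."""
        from borderstereo.core import MeasurementLine, Region, RegionMap
        from shapely.geometry import box

        rho, L = 0.015, 300.0
        rm = RegionMap([Region(box(0, 0, 1000, 1000), "a", "a")],
                       (0, 0, 1000, 1000))
        line = MeasurementLine((350.0, 500.0), (650.0, 500.0), "test", "l")
        cfg = GeneratorConfig(fiber_density={"a": rho}, p_cross=0.0, **MORPH)
        counts = [
            count_line_crossings([line], grow_astrocyte_arbors(rm, cfg, seed=s)
                                 )["count"].iloc[0]
            for s in range(120)
        ]
        counts = np.asarray(counts, float)
        se = counts.std(ddof=1) / np.sqrt(len(counts))
        assert abs(counts.mean() - expected_crossings(L, rho)) < 3 * se

    def test_no_confinement_null_matches_interior(self, barrel_map):
        """p_cross=1 with equal densities: septal ~= core means (3 s.e.)."""
        dens = {"septum": 0.02, "core": 0.02}
        cfg = GeneratorConfig(fiber_density=dens, p_cross=1.0, **MORPH)
        sep, cor = [], []
        for s in range(50):
            rm = sample_barrel_map(3, 3, septum_width=100.0, seed=s)
            lines = place_septal_and_core_lines(rm)
            tab = count_line_crossings(lines, grow_astrocyte_arbors(rm, cfg, seed=s))
            sep.extend(tab[tab.placement == "septal"]["count"])
            cor.extend(tab[tab.placement == "core"]["count"])
        sep, cor = np.asarray(sep, float), np.asarray(cor, float)
        se = np.sqrt(sep.var(ddof=1) / len(sep) + cor.var(ddof=1) / len(cor))
        assert abs(sep.mean() - cor.mean()) < 3 * se

    def test_deterministic_given_seed(self, barrel_map):
        cfg = GeneratorConfig(fiber_density={"core": 0.005}, p_cross=0.0, **MORPH)
        a = grow_astrocyte_arbors(barrel_map, cfg, seed=42)
        b = grow_astrocyte_arbors(barrel_map, cfg, seed=42)
        assert len(a) == len(b)
        for ca, cb in zip(a, b):
            assert np.array_equal(ca.vertices, cb.vertices)
            assert ca.structure_id == cb.structure_id


class TestCapillaries:
    def test_zero_density_empty(self, barrel_map):
        assert len(sample_capillary_network(barrel_map, 0.0, seed=0)) == 0

    def test_negative_density_rejected(self, barrel_map):
        with pytest.raises(ValueError):
            sample_capillary_network(barrel_map, -0.1, seed=0)

    def test_homogeneous_across_classes(self):
        """Septal vs core mean crossings ratio -> 1 within 3 s.e."""
        sep, cor = [], []
        for s in range(60):
            rm = sample_barrel_map(3, 3, septum_width=100.0, seed=s)
            caps = sample_capillary_network(rm, 0.02, seed=s)
            lines = place_septal_and_core_lines(rm)
            tab = count_line_crossings(lines, caps)
            sep.extend(tab[tab.placement == "septal"]["count"])
            cor.extend(tab[tab.placement == "core"]["count"])
        sep, cor = np.asarray(sep, float), np.asarray(cor, float)
        ratio = sep.mean() / cor.mean()
        rel_se = np.sqrt(sep.var(ddof=1) / len(sep) / sep.mean() ** 2
                         + cor.var(ddof=1) / len(cor) / cor.mean() ** 2)
        assert abs(ratio - 1.0) < 3 * rel_se

    def test_matches_buffon(self):
        rho, L = 0.02, 375.0
        counts = []
        for s in range(60):
            rm = sample_barrel_map(2, 2, septum_width=100.0, seed=s)
            caps = sample_capillary_network(rm, rho, seed=s)
            lines = place_septal_and_core_lines(rm)
            counts.extend(count_line_crossings(lines, caps)["count"])
        counts = np.asarray(counts, float)
        se = counts.std(ddof=1) / np.sqrt(len(counts))
        assert abs(counts.mean() - expected_crossings(L, rho)) < 3 * se

    def test_per_class_restriction_density(self, barrel_map):
        caps = sample_capillary_network(barrel_map, {"core": 0.02}, seed=1)
        p0, p1, _ = caps.segments()
        mids = 0.5 * (p0 + p1)
        assert (barrel_map.class_at(mids) == "core").mean() > 0.999
        realized = caps.total_length() / barrel_map.class_area("core")
        assert realized == pytest.approx(0.02, rel=0.1)


class TestThinning:
    def test_retention_one_is_identity(self, barrel_map):
        cfg = GeneratorConfig(fiber_density={"core": 0.005}, **MORPH)
        astro = grow_astrocyte_arbors(barrel_map, cfg, seed=0)
        thin = thin_by_section(astro, 1.0, seed=0)
        assert len(thin) == len(astro)

    def test_retention_out_of_range(self, barrel_map):
        astro = CurveSet()
        for bad in (0.0, -0.2, 1.5):
            with pytest.raises(ValueError, match="retention"):
                thin_by_section(astro, bad, seed=0)

    def test_binomial_retained_count(self):
        from borderstereo.core import Curve

        curves = CurveSet([Curve(np.array([[0, 0], [1, 0]], float), f"c{i}")
                           for i in range(4000)])
        kept = len(thin_by_section(curves, 0.65, seed=1))
        # 3 sigma binomial window around 0.65 * 4000
        sigma = np.sqrt(4000 * 0.65 * 0.35)
        assert abs(kept - 0.65 * 4000) < 3 * sigma

    def test_tags_preserved(self, barrel_map):
        cfg = GeneratorConfig(fiber_density={"core": 0.005}, **MORPH)
        astro = grow_astrocyte_arbors(barrel_map, cfg, seed=0)
        thin = thin_by_section(astro, 0.5, seed=2)
        originals = {id(c) for c in astro}
        assert all(id(c) in originals for c in thin.curves)


class TestCalibration:
    def test_zero_target_zero_density(self):
        assert density_for_target_mean(0.0, 375.0) == 0.0

    def test_negative_target_rejected(self):
        with pytest.raises(ValueError):
            density_for_target_mean(-1.0, 375.0)

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ValueError):
            density_for_target_mean(1.0, 0.0)

    def test_linearity(self):
        d1 = density_for_target_mean(3.0, 375.0)
        d2 = density_for_target_mean(6.0, 375.0)
        assert d2 == pytest.approx(2.0 * d1)

    def test_buffon_inversion_formula(self):
        m, L = 7.5, 375.0
        rho = density_for_target_mean(m, L)
        assert rho == pytest.approx(np.pi * m / (2 * L))
        assert expected_crossings(L, rho) == pytest.approx(m)

    def test_inversion_recovered_by_simulation(self):
        """Calibrated density reproduces the target mean within 3 s.e."""
        target, L = 5.0, 375.0
        dens = calibrate_densities({"core": target, "septum": target}, L)
        cfg = GeneratorConfig(fiber_density=dens, p_cross=0.0, **MORPH)
        counts = []
        for s in range(100):
            rm = sample_barrel_map(2, 2, septum_width=100.0, seed=s)
            lines = place_septal_and_core_lines(rm)
            tab = count_line_crossings(lines, grow_astrocyte_arbors(rm, cfg, seed=s))
            counts.extend(tab["count"])
        counts = np.asarray(counts, float)
        se = counts.std(ddof=1) / np.sqrt(len(counts))
        assert abs(counts.mean() - target) < 3 * se

    def test_solve_confinement_bisects_monotone(self):
        f = lambda p: 10.0 * p ** 2  # deterministic monotone stand-in
        p = solve_confinement(f, 2.5, n_iter=20)
        assert p == pytest.approx(0.5, abs=1e-3)
        assert solve_confinement(f, -1.0) == 0.0
        assert solve_confinement(f, 99.0) == 1.0


class TestLandmarks:
    def test_landmarks_inside_extent(self, barrel_map):
        lm = sample_landmarks(barrel_map, n=6, seed=0)
        xmin, ymin, xmax, ymax = barrel_map.extent
        assert len(lm) == 6
        assert (lm[:, 0] >= xmin).all() and (lm[:, 0] <= xmax).all()
        assert (lm[:, 1] >= ymin).all() and (lm[:, 1] <= ymax).all()

    def test_minimum_count(self, barrel_map):
        with pytest.raises(ValueError):
            sample_landmarks(barrel_map, n=3, seed=0)


class TestRasterize:
    def _scene(self, barrel_map, with_fibers=True):
        cfg = GeneratorConfig(fiber_density={"core": 0.002} if with_fibers else {},
                              **MORPH)
        astro = grow_astrocyte_arbors(barrel_map, cfg, seed=0)
        lm = sample_landmarks(barrel_map, n=4, seed=0)
        return SyntheticScene(barrel_map, astro, CurveSet(), lm, cfg)

    def test_empty_scene_all_background_fibers(self, barrel_map):
        scene = self._scene(barrel_map, with_fibers=False)
        raster = rasterize_scene(scene, pixel_size=20.0)
        assert raster.astrocyte_mask.sum() == 0
        assert raster.capillary_mask.sum() == 0

    def test_pixel_size_validation(self, barrel_map):
        scene = self._scene(barrel_map)
        with pytest.raises(ValueError):
            rasterize_scene(scene, pixel_size=0.0)
        with pytest.raises(ValueError, match="extent"):
            rasterize_scene(scene, pixel_size=1e6)

    def test_foreground_pixels_track_fiber_length(self, barrel_map):
        # default morphology (long branches) so stroke-joint overlap stays
        # small relative to total stroke area
        cfg = GeneratorConfig(fiber_density={"core": 0.002})
        astro = grow_astrocyte_arbors(barrel_map, cfg, seed=0)
        lm = sample_landmarks(barrel_map, n=4, seed=0)
        scene = SyntheticScene(barrel_map, astro, CurveSet(), lm, cfg)
        px = 3.0
        raster = rasterize_scene(scene, pixel_size=px)
        total_len = scene.astrocytes.total_length()
        expected_px = total_len * px / px ** 2  # 1-px stroke
        assert raster.astrocyte_mask.sum() == pytest.approx(expected_px, rel=0.10)

    def test_multipage_tiff_export(self, barrel_map, tmp_path):
        import tifffile

        scene = self._scene(barrel_map)
        raster = rasterize_scene(scene, pixel_size=20.0)
        path = tmp_path / "scene.tiff"
        raster.write_tiff(str(path))
        pages = tifffile.imread(str(path))
        assert pages.shape[0] == 3
        assert np.array_equal(pages[0], raster.region_labels)

    def test_landmark_roundtrip_within_one_pixel(self, barrel_map):
        scene = self._scene(barrel_map)
        px = 4.0
        raster = rasterize_scene(scene, pixel_size=px)
        for orig, lp in zip(scene.landmarks, raster.landmarks_px):
            back = raster.landmark_to_um(lp)
            assert np.hypot(back[0] - orig[0], back[1] - orig[1]) <= px


class TestDeterminism:
    def test_serialized_scene_identical_across_runs(self, barrel_map):
        from borderstereo.pipeline import generate_scene, get_preset

        preset = get_preset("barrel_layer4")
        a = json.dumps(scene_to_geojson(generate_scene(preset, 0, seed=9)))
        b = json.dumps(scene_to_geojson(generate_scene(preset, 0, seed=9)))
        assert a == b
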