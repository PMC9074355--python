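import math

import numpy as np
import pytest

import ki67flow as kf
from ki67flow.detect import DetectionParams, NucleusDetection
from ki67flow.synthetic import (DEFAULT_CLASS_PARAMS, GroundTruthNucleus,
                                _ellipse_polygon)
from shapely.geometry import Point


def _render_od(nuclei, profile, w, h, px=0.23):
    rgb = kf.render_scene(nuclei, profile, w, h, px)
    return kf.rgb_to_od(rgb, pixel_size_um=px)


@pytest.fixture(scope="module")
def separated_scene(default_profile):
    """50 well-separated tumour nuclei, noise-free."""
    params = {k: dict(v) for k, v in DEFAULT_CLASS_PARAMS.items()}
    params["tumour"]["min_spacing_um"] = 30.0
    cfg = kf.SceneConfig(width_um=300, height_um=300, n_tumour=50,
                         n_stroma=0, n_lymph=0, nucleus_size_params=params,
                         seed=4, noise_sd=0.0, base_positivity=0.3)
    rgb, truth = kf.simulate_scene(cfg, default_profile)
    od = kf.rgb_to_od(rgb, pixel_size_um=cfg.pixel_size_um)
    return rgb, truth, od


class TestDetectNuclei:
    def test_counts_and_centroids_on_separated_scene(self, separated_scene):
        rgb, truth, od = separated_scene
        dets = kf.detect_nuclei(od)
        assert len(dets) == len(truth) == 50
        pairs, metrics = kf.match_to_truth(dets, truth)
        assert metrics["f1"] == 1.0
        for di, ti in pairs.items():
            err = math.dist(dets[di].centroid_um, truth[ti].centroid_um)
            assert err < 1.0

    def test_subminimal_area_nucleus_rejected(self, default_profile):
        a = math.sqrt(5 / math.pi)  # 5 um^2 circle
        nuc = GroundTruthNucleus(0, "tumour",
                                 _ellipse_polygon(30, 30, a, a, 0.0),
                                 False, 0.0, 0.7)
        od = _render_od([nuc], default_profile, 60, 60)
        assert kf.detect_nuclei(od) == []

    def test_touching_pair_split_in_two(self, default_profile):
        a = math.sqrt(80 / math.pi)
        d = 0.8 * 2 * a  # centres at 0.8x diameter: clearly overlapping
        nuclei = [
            GroundTruthNucleus(0, "tumour",
                               _ellipse_polygon(60, 60, a, a, 0.0),
                               False, 0.0, 0.7),
            GroundTruthNucleus(1, "tumour",
                               _ellipse_polygon(60 + d, 60, a, a, 0.0),
                               False, 0.0, 0.7)]
        od = _render_od(nuclei, default_profile, 120, 120)
        dets = kf.detect_nuclei(od)
        assert len(dets) == 2

    def test_empty_image_gives_empty_list(self):
        od = kf.rgb_to_od(np.full((64, 64, 3), 255.0), pixel_size_um=0.4)
        assert kf.detect_nuclei(od) == []

    def test_all_areas_within_configured_bounds(self, detected_scene):
        cfg, truth, od, dets = detected_scene
        p = DetectionParams()
        for det in dets:
            assert p.min_area_um2 <= det.features["area_um2"] \
                <= p.max_area_um2 + 1.0  # polygon tracing tolerance

    def test_f1_against_ground_truth(self, detected_scene):
        cfg, truth, od, dets = detected_scene
        _, metrics = kf.match_to_truth(dets, truth, match_radius_um=3.0)
        assert metrics["f1"] >= 0.90

    def test_rotation_invariance(self, separated_scene):
        rgb, truth, od = separated_scene
        n0 = len(kf.detect_nuclei(od))
        od90 = kf.rgb_to_od(np.rot90(rgb).copy(), pixel_size_um=0.23)
        n90 = len(kf.detect_nuclei(od90))
        assert abs(n0 - n90) <= 1

    def test_invalid_pixel_size_raises(self):
        od = kf.ODImage(np.zeros((8, 8, 3)))
        od.pixel_size_um = 0.0
        with pytest.raises(ValueError, match="pixel size"):
            kf.detect_nuclei(od)


class TestExpandCells:
    def _single(self):
        poly = _ellipse_polygon(30, 30, 5, 4, 0.3)
        det = NucleusDetection(id=0, nucleus_polygon=poly,
                               centroid_um=(30, 30))
        return det

    def test_zero_expansion_is_identity(self):
        det = self._single()
        kf.expand_cells([det], 0.0)
        assert det.cell_polygon is det.nucleus_polygon

    def test_isolated_nucleus_dilated_area(self):
        """Cell area of an isolated nucleus matches the Minkowski dilation
        A + P*e + pi*e^2 of the nucleus polygon."""
        det = self._single()
        e = 5.0
        a0 = det.nucleus_polygon.area
        p0 = det.nucleus_polygon.length
        kf.expand_cells([det], e)
        expected = a0 + p0 * e + math.pi * e**2
        assert det.cell_polygon.area == pytest.approx(expected, rel=0.05)

    def test_neighbouring_cells_split_on_equidistant_line(self):
        gap = 4.0
        p1 = _ellipse_polygon(30, 30, 4, 4, 0.0)
        p2 = _ellipse_polygon(30 + 8 + gap, 30, 4, 4, 0.0)
        d1 = NucleusDetection(id=0, nucleus_polygon=p1, centroid_um=(30, 30))
        d2 = NucleusDetection(id=1, nucleus_polygon=p2,
                              centroid_um=(42, 30))
        kf.expand_cells([d1, d2], 5.0)
        # cells never overlap and meet near the midline x = 36
        inter = d1.cell_polygon.intersection(d2.cell_polygon)
        assert inter.area < 1.0
        mid = Point(36.0, 30.0)
        assert d1.cell_polygon.distance(mid) < 0.5
        assert d2.cell_polygon.distance(mid) < 0.5

    def test_cells_pairwise_disjoint_on_scene(self, detected_scene):
        cfg, truth, od, dets = detected_scene
        from shapely.strtree import STRtree
        polys = [d.cell_polygon for d in dets]
        tree = STRtree(polys)
        for i, poly in enumerate(polys):
            for j in tree.query(poly):
                if j <= i:
                    continue
                assert poly.intersection(polys[j]).area < 1.0


class TestMeasureFeatures:
    def test_circle_circularity_near_one(self, default_profile):
        nuc = GroundTruthNucleus(0, "tumour",
                                 _ellipse_polygon(30, 30, 5, 5, 0.0, 64),
                                 False, 0.0, 0.7)
        od = _render_od([nuc], default_profile, 60, 60)
        dets = kf.detect_nuclei(od)
        kf.measure_features(dets, od)
        assert dets[0].features["circularity"] > 0.95

    def test_uniform_dab_recovered_in_nucleus_mean(self, default_profile):
        c = 0.5
        nuc = GroundTruthNucleus(0, "tumour",
                                 _ellipse_polygon(30, 30, 6, 6, 0.0),
                                 True, c, 0.6)
        od = _render_od([nuc], default_profile, 60, 60)
        dets = kf.detect_nuclei(od)
        kf.measure_features(dets, od)
        assert dets[0].features["nucleus_dab_od_mean"] == pytest.approx(
            c, rel=0.02)

    def test_zero_dab_nucleus_near_zero_mean(self, default_profile):
        nuc = GroundTruthNucleus(0, "tumour",
                                 _ellipse_polygon(30, 30, 6, 6, 0.0),
                                 False, 0.0, 0.7)
        od = _render_od([nuc], default_profile, 60, 60)
        dets = kf.detect_nuclei(od)
        kf.measure_features(dets, od)
        assert abs(dets[0].features["nucleus_dab_od_mean"]) < 0.01

    def test_degenerate_polygon_flagged_invalid(self, default_profile):
        od = _render_od([], default_profile, 20, 20)
        from shapely.geometry import Polygon
        bad = NucleusDetection(
            id=0, nucleus_polygon=Polygon([(5, 5), (5.001, 5), (5, 5.001)]),
            centroid_um=(5, 5))
        kf.measure_features([bad], od)
        assert bad.features["valid"] == 0.0


class TestSmoothFeatures:
    def _make(self, positions, values):
        dets = []
        for i, ((x, y), v) in enumerate(zip(positions, values)):
            d = NucleusDetection(id=i,
                                 nucleus_polygon=_ellipse_polygon(x, y, 3, 3,
                                                                  0),
                                 centroid_um=(x, y))
            d.features = {"area_um2": v}
            dets.append(d)
        return dets

    def test_single_detection_smooths_to_itself(self):
        dets = self._make([(10, 10)], [7.5])
        kf.smooth_features(dets, feature_names=["area_um2"])
        for r in (25.0, 50.0, 100.0):
            assert dets[0].smoothed[("area_um2", r)] == pytest.approx(7.5)

    def test_constant_feature_invariant(self):
        pos = [(10 * i, 5 * (i % 3)) for i in range(12)]
        dets = self._make(pos, [3.0] * 12)
        kf.smooth_features(dets, feature_names=["area_um2"])
        for d in dets:
            assert d.smoothed[("area_um2", 50.0)] == pytest.approx(3.0)

    def test_distant_clusters_do_not_mix(self):
        pos = [(i * 5.0, 0.0) for i in range(5)] + \
              [(500 + i * 5.0, 0.0) for i in range(5)]
        dets = self._make(pos, [1.0] * 5 + [0.0] * 5)
        kf.smooth_features(dets, radii_um=[50.0],
                           feature_names=["area_um2"])
        for d in dets[:5]:
            assert abs(d.smoothed[("area_um2", 50.0)] - 1.0) < 0.01
        for d in dets[5:]:
            assert abs(d.smoothed[("area_um2", 50.0)]) < 0.01

    def test_smoothed_is_convex_combination(self, detected_scene):
        cfg, truth, od, dets = detected_scene
        raw = [d.features["area_um2"] for d in dets]
        lo, hi = min(raw), max(raw)
        for d in dets:
            v = d.smoothed[("area_um2", 50.0)]
            assert lo - 1e-9 <= v <= hi + 1e-9
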