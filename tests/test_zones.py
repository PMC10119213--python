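import math

import numpy as np
import pytest

from spheroidquant.calibration import ImageStack, PixelCalibration
from spheroidquant.image_io import BoundaryPolygon
from spheroidquant.segmentation import NucleusRecord
from spheroidquant.synthetic import preset, simulate_spheroid
from spheroidquant.zones import (Ellipse, EstimationError, GeometryError,
                                 QuadrantSelection, assign_zones,
                                 build_zone_map, estimate_boundaries,
                                 fit_boundary_ellipse, radial_distance,
                                 select_quadrant)


def ngon(center, radius, n=64, label="core_rim"):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    verts = np.column_stack([center[0] + radius * np.sin(t),
                             center[1] + radius * np.cos(t)])
    return BoundaryPolygon(verts, label)


class TestFitEllipse:
    def test_disc_recovers_radius_and_area(self):
        e = fit_boundary_ellipse(ngon((100, 120), 50))
        assert e.semi_major == pytest.approx(50, abs=1.0)
        assert e.semi_minor == pytest.approx(50, abs=1.0)
        assert e.area == pytest.approx(math.pi * 50**2, rel=0.01)
        assert e.center[0] == pytest.approx(100, abs=0.5)
        assert e.center[1] == pytest.approx(120, abs=0.5)

    def test_rectangle_axis_ratio_and_orientation(self):
        w, h = 60.0, 20.0  # w along columns
        verts = np.array([[0, 0], [0, w], [h, w], [h, 0]], dtype=float)
        e = fit_boundary_ellipse(verts)
        assert e.semi_major / e.semi_minor == pytest.approx(w / h, rel=0.02)
        assert abs(e.orientation) < math.radians(1)
        assert e.area == pytest.approx(w * h, rel=1e-6)

    def test_rotation_equivariance(self):
        w, h = 60.0, 20.0
        base = np.array([[-h / 2, -w / 2], [-h / 2, w / 2],
                         [h / 2, w / 2], [h / 2, -w / 2]])
        theta = math.radians(30)
        # rotate in (x=col, y=row) by +30°
        c, s = math.cos(theta), math.sin(theta)
        rot = np.column_stack([base[:, 1] * s + base[:, 0] * c,
                               base[:, 1] * c - base[:, 0] * s])  # (row, col)
        e = fit_boundary_ellipse(rot)
        assert abs(abs(e.orientation) - theta) < math.radians(1)

    def test_degenerate_polygon_rejected(self):
        with pytest.raises(GeometryError):
            fit_boundary_ellipse(np.array([[0, 0], [1, 1], [2, 2]], dtype=float))


class TestZoneMap:
    def test_concentric_circles_match_analytic_ring_areas(self):
        core = Ellipse((127.5, 127.5), 30, 30, 0.0)
        rim = Ellipse((127.5, 127.5), 60, 60, 0.0)
        zm = build_zone_map(core, rim, (256, 256))
        counts = zm.pixel_counts()
        assert counts["core"] == pytest.approx(math.pi * 30**2, rel=0.02)
        assert counts["rim"] == pytest.approx(math.pi * (60**2 - 30**2), rel=0.02)
        assert counts["invasion"] == pytest.approx(256**2 - math.pi * 60**2,
                                                   rel=0.02)
        assert counts["outside"] == 0

    def test_every_pixel_has_exactly_one_zone(self):
        zm = build_zone_map(Ellipse((50, 50), 20, 15, 0.3),
                            Ellipse((50, 50), 40, 35, 0.3), (100, 100))
        total = sum(zm.pixel_counts().values())
        assert total == 100 * 100

    def test_identical_boundaries_accepted_with_warning(self, caplog):
        e = Ellipse((50, 50), 20, 20, 0.0)
        with caplog.at_level("WARNING", logger="spheroidquant"):
            zm = build_zone_map(e, e, (100, 100))
        assert zm.pixel_counts()["rim"] == 0
        assert "rim has 0 pixels" in caplog.text

    def test_crossing_boundaries_rejected_with_overlap_fraction(self):
        core = Ellipse((50, 70), 30, 30, 0.0)  # sticks out of the rim ellipse
        rim = Ellipse((50, 50), 40, 40, 0.0)
        with pytest.raises(GeometryError, match="%"):
            build_zone_map(core, rim, (100, 100))


class TestEstimateBoundaries:
    def test_recovers_simulated_radii_within_ten_percent(self):
        params = preset("control", seed=3)
        stack, _ = simulate_spheroid(params)
        core_poly, rim_poly = estimate_boundaries(stack, central_slice=1)
        core_r = fit_boundary_ellipse(core_poly).semi_major
        rim_r = fit_boundary_ellipse(rim_poly).semi_major
        assert core_r == pytest.approx(params.core_radius, rel=0.10)
        assert rim_r == pytest.approx(params.rim_outer_radius, rel=0.10)

    def test_blank_noise_slice_is_an_estimation_error(self, cal, rng):
        stack = ImageStack(rng.normal(10, 2, (1, 128, 128)).clip(0), cal)
        with pytest.raises(EstimationError):
            estimate_boundaries(stack, central_slice=0)

    def test_user_rois_take_precedence_over_auto_mode(self, tmp_path):
        # pipeline contract: when an ROI file is configured the estimator
        # is never invoked, even on a stack it could not handle
        import json

        from spheroidquant.pipeline import RunConfig, _zone_boundaries

        roi = {"core_rim": ngon((127.5, 127.5), 40).vertices.tolist(),
               "rim_invasion": ngon((127.5, 127.5), 80).vertices.tolist()}
        roi_path = tmp_path / "zones.json"
        roi_path.write_text(json.dumps(roi))
        config = RunConfig(out_dir=tmp_path / "out", simulate_preset="control",
                           roi_path=roi_path)
        blank = ImageStack(np.zeros((1, 256, 256)),
                           PixelCalibration(1.0, 10.0))
        core, rim = _zone_boundaries(config, blank, None)
        assert core.semi_major == pytest.approx(40, abs=1)
        assert rim.semi_major == pytest.approx(80, abs=1)


class TestQuadrant:
    @staticmethod
    def _zone_map():
        return build_zone_map(Ellipse((50, 50), 10, 10, 0.0),
                              Ellipse((50, 50), 20, 20, 0.0), (101, 101))

    def test_same_seed_same_quadrant(self):
        zm = self._zone_map()
        assert select_quadrant(zm, 7).index == select_quadrant(zm, 7).index

    def test_uniform_over_seeds(self):
        zm = self._zone_map()
        n = 40_000
        draws = np.array([select_quadrant(zm, s).index for s in range(n)])
        freqs = np.bincount(draws, minlength=4) / n
        np.testing.assert_allclose(freqs, 0.25, atol=0.02)

    def test_masks_partition_slice_minus_centroid_axes(self):
        zm = self._zone_map()
        masks = [QuadrantSelection(i, zm.centroid, 0).mask((101, 101))
                 for i in range(4)]
        union = np.zeros((101, 101), dtype=int)
        for m in masks:
            union += m
        assert union.max() == 1  # disjoint
        rows, cols = np.mgrid[0:101, 0:101]
        on_axes = (rows == 50) | (cols == 50)
        np.testing.assert_array_equal(union == 1, ~on_axes)


class TestRadialDistance:
    @staticmethod
    def _record(row, col):
        return NucleusRecord(id=1, slice_index=0, centroid=(row, col),
                             area_um2=100.0, mean_intensity=1.0)

    def test_zero_at_centroid(self, cal):
        assert radial_distance(self._record(10, 10), (10, 10), cal) == 0.0

    def test_three_four_five_triangle_with_calibration(self):
        cal = PixelCalibration(xy_size=2.0, z_step=10.0)
        rec = self._record(13, 14)
        assert radial_distance(rec, (10, 10), cal) == pytest.approx(10.0)
        assert rec.radial_distance_um == pytest.approx(10.0)

    def test_invariant_under_rotation_about_centroid(self, cal):
        centroid = (50.0, 50.0)
        rec = self._record(62.0, 55.0)
        d0 = radial_distance(rec, centroid, cal)
        for theta in (0.5, 1.3, 2.9):
            dr, dc = 12.0, 5.0
            rot = self._record(
                centroid[0] + dr * math.cos(theta) - dc * math.sin(theta),
                centroid[1] + dr * math.sin(theta) + dc * math.cos(theta))
            assert radial_distance(rot, centroid, cal) == pytest.approx(d0)


class TestAssignZones:
    @staticmethod
    def _setup():
        zm = build_zone_map(Ellipse((50, 50), 10, 10, 0.0),
                            Ellipse((50, 50), 20, 20, 0.0), (100, 100))
        quad = QuadrantSelection(0, zm.centroid, 0)  # (+row, +col)
        return zm, quad

    @staticmethod
    def _record(row, col):
        return NucleusRecord(id=1, slice_index=0, centroid=(row, col),
                             area_um2=100.0, mean_intensity=1.0)

    def test_core_pixel_gets_core_zone(self, cal):
        zm, quad = self._setup()
        rec, = assign_zones([self._record(52, 52)], zm, quad,
                            calibration=cal)
        assert rec.zone == "core"

    def test_invasion_record_outside_quadrant_unassigned_when_restricted(self, cal):
        zm, quad = self._setup()
        rec, = assign_zones([self._record(20, 20)], zm, quad,
                            restrict_invasion_to_quadrant=True,
                            calibration=cal)
        assert rec.zone == "unassigned"

    def test_flag_unset_keeps_all_invasion_records(self, cal):
        zm, quad = self._setup()
        rec, = assign_zones([self._record(20, 20)], zm, quad,
                            restrict_invasion_to_quadrant=False,
                            calibration=cal)
        assert rec.zone == "invasion"

    def test_core_and_rim_never_quadrant_restricted(self, cal):
        zm, quad = self._setup()
        recs = [self._record(45, 45), self._record(50 - 15, 50)]
        assign_zones(recs, zm, quad, restrict_invasion_to_quadrant=True,
                     calibration=cal)
        assert recs[0].zone == "core"
        assert recs[1].zone == "rim"

    def test_centroid_outside_image_marked_unassigned(self, cal, caplog):
        zm, quad = self._setup()
        with caplog.at_level("WARNING", logger="spheroidquant"):
            rec, = assign_zones([self._record(-5, 20)], zm, quad,
                                calibration=cal)
        assert rec.zone == "unassigned"

    def test_zone_assignment_matches_ground_truth_on_simulation(self):
        from spheroidquant.evaluate import score_recovery
        from spheroidquant.pipeline import _circle_ellipse
        from spheroidquant.segmentation import SegmentationParams, segment_stack
        from spheroidquant.synthetic import preset, simulate_spheroid

        params = preset("control", seed=6)
        stack, truth = simulate_spheroid(params)
        nuclei, _ = segment_stack(stack, SegmentationParams())
        zm = build_zone_map(_circle_ellipse(stack, params.core_radius),
                            _circle_ellipse(stack, params.rim_outer_radius),
                            stack.shape)
        assign_zones(nuclei, zm, None, calibration=params.calibration)
        # match each detection to its nearest truth cell that is actually
        # near the detection's slice plane (a deep cell cannot be the true
        # source of a detection); measured zone must agree with the truth
        # zone for >= 95% of matches (boundary-adjacent cells may flip)
        from scipy.spatial import cKDTree
        z_planes = params.slice_z_positions()
        cells = truth.cells[truth.cells["state"] != "apoptotic"]
        agree = total = 0
        for s in range(stack.n_slices):
            near = cells[np.abs(cells["z_um"] - z_planes[s]) <= 12.0]
            tree = cKDTree(np.column_stack([near["row_px"], near["col_px"]]))
            for rec in (n for n in nuclei if n.slice_index == s):
                dist, idx = tree.query(rec.centroid)
                if dist > 10:
                    continue
                total += 1
                agree += rec.zone == near["zone"].iloc[idx]
        assert total > 100
        assert agree / total >= 0.95
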