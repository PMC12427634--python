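import json
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cspine import (
    ComponentMask,
    MeasureConfig,
    OracleDetector,
    PhantomSpec,
    directional_extrema,
    enhance_roi,
    euclidean_distance,
    generate_phantom,
    largest_component,
    measure_intervertebral,
    measure_vertebra_foramen,
    reference_points,
    run_pipeline,
)
from tests.conftest import rect_mask


def flood_fill_components(binary):
    """Independent 8-connectivity labeling by explicit stack-based flood fill."""
    fg = binary > 0
    seen = np.zeros_like(fg, dtype=bool)
    comps = []
    h, w = fg.shape
    for y0 in range(h):
        for x0 in range(w):
            if not fg[y0, x0] or seen[y0, x0]:
                continue
            stack, pixels = [(y0, x0)], []
            seen[y0, x0] = True
            while stack:
                y, x = stack.pop()
                pixels.append((y, x))
                for dy in (-1, 0, 1):
                    for dx in (-1, 0, 1):
                        ny, nx = y + dy, x + dx
                        if 0 <= ny < h and 0 <= nx < w and fg[ny, nx] and not seen[ny, nx]:
                            seen[ny, nx] = True
                            stack.append((ny, nx))
            comps.append(pixels)
    return comps


class TestLargestComponent:
    def test_bigger_blob_wins(self):
        img = rect_mask((30, 30), (2, 12), (2, 7))  # area 50
        img[20:21, 20:27] = 255  # area 7
        comp = largest_component(img)
        assert comp.component_area == 50
        assert comp.pixels[5, 4] and not comp.pixels[20, 22]

    def test_single_blob_identity(self):
        img = rect_mask((10, 10), (3, 7), (3, 7))
        comp = largest_component(img)
        assert np.array_equal(comp.pixels, img > 0)

    def test_all_black_rejected(self):
        with pytest.raises(ValueError, match="no component"):
            largest_component(np.zeros((5, 5), np.uint8))

    def test_area_tie_prefers_first_in_row_major_order(self):
        img = np.zeros((10, 10), np.uint8)
        img[6:8, 1:3] = 255  # area 4, first pixel later in raster order
        img[1:3, 6:8] = 255  # area 4, first pixel earlier
        comp = largest_component(img)
        assert comp.pixels[1, 6] and not comp.pixels[6, 1]

    def test_matches_flood_fill_oracle(self, rng):
        for _ in range(30):
            img = (rng.random((20, 20)) < 0.35).astype(np.uint8) * 255
            if not img.any():
                continue
            comps = flood_fill_components(img)
            best = max(comps, key=lambda c: (len(c), [-p[0] for p in sorted(c)]))
            sizes = sorted(len(c) for c in comps)
            comp = largest_component(img)
            assert comp.component_area == sizes[-1]
            if sizes.count(sizes[-1]) == 1:  # unique winner: compare pixel sets
                assert sorted(zip(*np.nonzero(comp.pixels))) == sorted(best)


class TestDirectionalExtrema:
    def test_rectangle_corners(self):
        comp = largest_component(rect_mask((60, 60), (30, 40), (10, 20)))
        bl, br, tl, tr = directional_extrema(comp)
        assert (bl, br, tl, tr) == ((10, 39), (19, 39), (10, 30), (19, 30))

    def test_single_pixel_degenerate(self):
        img = np.zeros((10, 10), np.uint8)
        img[5, 5] = 255
        assert directional_extrema(largest_component(img)) == ((5, 5),) * 4

    def test_matches_exhaustive_scan(self, rng):
        for _ in range(30):
            img = (rng.random((15, 15)) < 0.5).astype(np.uint8) * 255
            if not img.any():
                continue
            comp = largest_component(img)
            pts = sorted(zip(*np.nonzero(comp.pixels)))  # (y, x) ascending

            def opt(key, maximize):
                vals = [key(x, y) for y, x in pts]
                target = max(vals) if maximize else min(vals)
                return next((float(x), float(y)) for (y, x), v in zip(pts, vals) if v == target)

            bl, br, tl, tr = directional_extrema(comp)
            assert bl == opt(lambda x, y: y - x, True)
            assert br == opt(lambda x, y: y + x, True)
            assert tl == opt(lambda x, y: y + x, False)
            assert tr == opt(lambda x, y: y - x, False)


class TestReferencePoints:
    def test_rectangle_edge_midpoints(self):
        comp = largest_component(rect_mask((60, 60), (30, 40), (10, 20)))
        rp = reference_points(comp)
        assert rp.lower_ref == (14.0, 39.0)  # round(14.5) -> 14, half-to-even
        assert rp.upper_ref == (14.0, 30.0)
        assert not rp.fallback_used

    def test_single_pixel(self):
        img = np.zeros((10, 10), np.uint8)
        img[5, 5] = 255
        rp = reference_points(largest_component(img))
        assert rp.lower_ref == rp.upper_ref == (5.0, 5.0)

    def test_empty_mid_column_falls_back_to_nearest_column(self):
        # a connected component occupies every column between its extremes,
        # so construct the degenerate two-tower mask directly to exercise the
        # nearest-foreground-column fallback
        pixels = np.zeros((20, 21), dtype=bool)
        pixels[2:16, 2:5] = True
        pixels[2:16, 16:19] = True
        rp = reference_points(ComponentMask(pixels, int(pixels.sum())))
        assert rp.fallback_used
        assert rp.lower_ref == (4.0, 15.0)  # cols 4 and 16 tie; lower index wins

    def test_translation_equivariance(self, rng):
        img = (rng.random((25, 25)) < 0.4).astype(np.uint8) * 255
        img[10:15, 10:15] = 255
        comp = largest_component(img)
        rp = reference_points(comp)
        shifted = ComponentMask(comp.pixels, comp.component_area, offset=(7, 11))
        rp2 = reference_points(shifted)
        for name in ("bottom_left", "bottom_right", "top_left", "top_right", "lower_ref", "upper_ref"):
            a, b = getattr(rp, name), getattr(rp2, name)
            assert (a[0] + 7, a[1] + 11) == b


class TestEuclideanDistance:
    @pytest.mark.parametrize(
        "p1, p2, expected",
        [((0, 0), (3, 4), 5.0), ((7, 2), (7, 2), 0.0), ((1, 1), (7, 9), 10.0)],
    )
    def test_pythagorean_triples(self, p1, p2, expected):
        assert euclidean_distance(p1, p2) == expected

    def test_matches_hypot_oracle(self, rng):
        for _ in range(100):
            p1, p2 = rng.uniform(-50, 50, (2, 2))
            expect = math.sqrt(((p2 - p1) ** 2).sum())
            assert abs(euclidean_distance(tuple(p1), tuple(p2)) - expect) < 1e-9

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=6, max_size=6))
    def test_metric_axioms(self, coords):
        p, q, r = (coords[0], coords[1]), (coords[2], coords[3]), (coords[4], coords[5])
        assert euclidean_distance(p, q) >= 0
        assert euclidean_distance(p, p) == 0
        assert euclidean_distance(p, q) == euclidean_distance(q, p)
        assert euclidean_distance(p, r) <= euclidean_distance(p, q) + euclidean_distance(q, r) + 1e-6


class TestEnhanceRoi:
    def test_band_blob_recovered_exactly(self):
        roi = np.full((40, 40), 40, np.uint8)
        roi[10:30, :] = 200  # straight-edged blob spanning the ROI
        mask = enhance_roi(roi)
        assert np.array_equal(mask > 0, roi == 200)

    def test_square_blob_recovered_almost_exactly(self):
        # blur rounds the four corner pixels of a sharp square at most
        roi = np.full((40, 40), 40, np.uint8)
        roi[10:30, 8:28] = 200
        mask = enhance_roi(roi) > 0
        blob = roi == 200
        assert np.sum(mask ^ blob) <= 4
        assert mask[15, 15] and not mask[5, 5]

    def test_constant_roi_rejected(self):
        with pytest.raises(ValueError, match="degenerate ROI"):
            enhance_roi(np.full((20, 20), 90, np.uint8))

    def test_tiny_roi_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            enhance_roi(np.full((4, 20), 90, np.uint8))

    def test_salt_specks_removed_by_opening(self, rng):
        roi = np.full((40, 40), 40, np.uint8)
        roi[12:28, 12:28] = 210
        specks = [(3, 5), (35, 30), (5, 33)]
        for y, x in specks:
            roi[y, x] = 255
        mask = enhance_roi(roi)
        comps = flood_fill_components(mask)
        assert all(len(c) >= 5 for c in comps)  # no tiny white component survives


class TestMeasurements:
    def test_aligned_rectangles_vertical_gap(self):
        upper = largest_component(rect_mask((60, 40), (0, 10), (10, 19)))
        lower = largest_component(rect_mask((60, 40), (23, 33), (10, 19)))
        m = measure_intervertebral(upper, lower, ("C2", "C3"))
        assert m.distance == 14.0
        assert m.kind == "intervertebral" and (m.from_label, m.to_label) == ("C2", "C3")

    def test_offset_rectangles_three_four_five(self):
        upper = largest_component(rect_mask((60, 40), (0, 10), (10, 19)))  # lower ref (14, 9)
        lower = largest_component(rect_mask((60, 40), (13, 23), (13, 22)))  # upper ref (17, 13)
        m = measure_intervertebral(upper, lower)
        assert m.distance == 5.0

    def test_vertebra_foramen_horizontal_separation(self):
        vert = largest_component(rect_mask((30, 60), (0, 9), (0, 10)))  # right mid (9, 4)
        fora = largest_component(rect_mask((30, 60), (0, 9), (39, 49)))  # left mid (39, 4)
        m = measure_vertebra_foramen(vert, fora, ("C2", "FORAMEN"))
        assert m.distance == 30.0 and m.kind == "vertebra_foramen"

    def test_vertebra_foramen_six_eight_ten(self):
        vert = largest_component(rect_mask((30, 60), (0, 9), (0, 10)))  # right mid (9, 4)
        fora = largest_component(rect_mask((30, 60), (8, 17), (15, 25)))  # left mid (15, 12)
        m = measure_vertebra_foramen(vert, fora)
        assert m.distance == 10.0

    def test_foramen_on_the_left_mirrors_sides(self):
        vert = largest_component(rect_mask((30, 60), (0, 9), (40, 50)))  # left mid (40, 4)
        fora = largest_component(rect_mask((30, 60), (0, 9), (10, 20)))  # right mid (19, 4)
        assert measure_vertebra_foramen(vert, fora).distance == 21.0


class TestPhantomLandmarks:
    def test_tilted_vertebra_reference_points_near_analytic(self):
        """On a noise-free phantom, measured edge midpoints stay within
        1.5 px of the analytic tilted-rectangle geometry."""
        img, truth = generate_phantom(
            PhantomSpec(seed=11, gaussian_noise_sigma=0.0, salt_pepper_fraction=0.0)
        )
        for lab, (x0, y0, x1, y1) in truth.boxes.items():
            roi = img[max(y0 - 5, 0) : y1 + 5, max(x0 - 5, 0) : x1 + 5]
            comp = largest_component(
                enhance_roi(roi), offset=(max(x0 - 5, 0), max(y0 - 5, 0))
            )
            rp = reference_points(comp)
            for measured, name in ((rp.lower_ref, "lower"), (rp.upper_ref, "upper")):
                exact = truth.reference_points[lab][name]
                assert euclidean_distance(measured, exact) <= 1.5


class TestRunPipeline:
    def test_phantom_end_to_end(self, default_phantom):
        img, truth = default_phantom
        report = run_pipeline(img, OracleDetector(truth), image_id="p42")
        iv = [m for m in report.measurements if m.kind == "intervertebral"]
        vf = [m for m in report.measurements if m.kind == "vertebra_foramen"]
        assert len(iv) == 5 and len(vf) == 6
        assert report.missing_levels == []
        for m in iv:
            truth_d = truth.intervertebral_distances[f"{m.from_label}-{m.to_label}"]
            assert abs(m.distance - truth_d) <= 3.0

    def test_empty_detector_reports_all_levels_missing(self, default_phantom):
        img, _ = default_phantom

        class Empty:
            def detect(self, image, frame=None):
                return []

        report = run_pipeline(img, Empty())
        assert report.measurements == []
        assert report.missing_levels == ["C2", "C3", "C4", "C5", "C6", "C7"]

    def test_rerun_byte_identical(self, default_phantom):
        img, truth = default_phantom
        a = run_pipeline(img, OracleDetector(truth), image_id="x")
        b = run_pipeline(img, OracleDetector(truth), image_id="x")
        assert json.dumps(a.to_dict(), sort_keys=True) == json.dumps(b.to_dict(), sort_keys=True)
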