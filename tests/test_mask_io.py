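import numpy as np
import pandas as pd
import pytest
from PIL import Image
from shapely.geometry import Polygon, Point

from ovimorph.errors import EmptyMaskError, ValidationError
from ovimorph.mask_io import (BinaryMask, Contour, FrameSequence,
                              MEASUREMENT_COLUMNS, extract_contour,
                              largest_component, load_mask,
                              rasterize_polygons, write_measurements)

from conftest import solid_mask


def _png(tmp_path, arr, name="m.png", mode="L"):
    path = tmp_path / name
    Image.fromarray(arr, mode=mode).save(path)
    return path


class TestLoadMask:
    def test_saturated_image_all_true(self, tmp_path):
        p = _png(tmp_path, np.full((48, 64), 255, np.uint8))
        assert load_mask(p).pixel_count == 64 * 48

    def test_black_image_empty_but_valid(self, tmp_path):
        p = _png(tmp_path, np.zeros((10, 10), np.uint8))
        assert load_mask(p).pixel_count == 0

    def test_checkerboard_matches_parity_oracle(self, tmp_path):
        ys, xs = np.mgrid[0:8, 0:8]
        arr = (((xs + ys) % 2) * 255).astype(np.uint8)
        mask = load_mask(_png(tmp_path, arr))
        assert mask.pixel_count == 32
        # per-pixel oracle: true iff (x + y) odd
        for y in range(8):
            for x in range(8):
                assert mask.at(x, y) == ((x + y) % 2 == 1)

    def test_rgb_converted_by_luma(self, tmp_path):
        arr = np.zeros((4, 4, 3), np.uint8)
        arr[:2] = (255, 255, 255)
        mask = load_mask(_png(tmp_path, arr, mode="RGB"))
        assert mask.pixel_count == 8

    @pytest.mark.parametrize("thr", [0, 256])
    def test_threshold_out_of_range(self, tmp_path, thr):
        p = _png(tmp_path, np.zeros((4, 4), np.uint8))
        with pytest.raises(ValidationError):
            load_mask(p, threshold=thr)

    def test_count_nonincreasing_in_threshold(self, tmp_path, rng):
        arr = rng.integers(0, 256, (16, 16)).astype(np.uint8)
        p = _png(tmp_path, arr)
        counts = [load_mask(p, t).pixel_count for t in (1, 64, 128, 200, 255)]
        assert counts == sorted(counts, reverse=True)


class TestRasterizePolygons:
    def test_axis_aligned_square_pixel_centers(self):
        ann = {"imageWidth": 32, "imageHeight": 32,
               "shapes": [{"points": [[10, 10], [20, 10], [20, 20], [10, 20]]}]}
        mask = rasterize_polygons(ann)
        assert mask.pixel_count == 100
        # point-in-polygon oracle over every pixel center
        poly = Polygon([(10, 10), (20, 10), (20, 20), (10, 20)])
        for y in range(32):
            for x in range(32):
                assert mask.at(x, y) == poly.contains(Point(x + 0.5, y + 0.5))

    def test_empty_shapes_empty_mask(self):
        assert rasterize_polygons({"imageWidth": 8, "imageHeight": 8,
                                   "shapes": []}).pixel_count == 0

    def test_disjoint_squares_union_additive(self):
        sq1 = [[1, 1], [5, 1], [5, 5], [1, 5]]
        sq2 = [[10, 10], [14, 10], [14, 14], [10, 14]]
        both = rasterize_polygons(
            {"imageWidth": 20, "imageHeight": 20,
             "shapes": [{"points": sq1}, {"points": sq2}]})
        one = rasterize_polygons(
            {"imageWidth": 20, "imageHeight": 20, "shapes": [{"points": sq1}]})
        two = rasterize_polygons(
            {"imageWidth": 20, "imageHeight": 20, "shapes": [{"points": sq2}]})
        assert both.pixel_count == one.pixel_count + two.pixel_count

    def test_degenerate_polygon_rejected(self):
        with pytest.raises(ValidationError):
            rasterize_polygons({"imageWidth": 8, "imageHeight": 8,
                                "shapes": [{"points": [[1, 1], [1, 1], [2, 2]]}]})


class TestLargestComponent:
    def test_keeps_biggest_blob(self):
        g = np.zeros((20, 20), bool)
        g[1:6, 1:11] = True   # 50 px
        g[12:16, 12:17] = True  # 20 px
        out = largest_component(BinaryMask(g))
        assert out.pixel_count == 50
        assert out.grid[2, 2] and not out.grid[13, 13]

    def test_idempotent_and_never_grows(self, rng):
        g = rng.random((15, 15)) < 0.4
        g[0, 0] = True
        once = largest_component(BinaryMask(g))
        twice = largest_component(once)
        assert np.array_equal(once.grid, twice.grid)
        assert once.pixel_count <= int(g.sum())

    def test_tie_broken_by_row_major_first_pixel(self):
        g = np.zeros((10, 30), bool)
        g[0:2, 0:5] = True    # 10 px, starts at (0, 0)
        g[5:7, 20:25] = True  # 10 px, later in row-major order
        out = largest_component(BinaryMask(g))
        assert out.grid[0, 0] and not out.grid[5, 20]

    def test_empty_mask_rejected(self):
        with pytest.raises(EmptyMaskError):
            largest_component(BinaryMask(np.zeros((4, 4), bool)))


def _boundary_oracle(grid):
    """Set of boundary pixels by the 4-neighbour test (independent of the
    tracer)."""
    h, w = grid.shape
    out = set()
    for y in range(h):
        for x in range(w):
            if not grid[y, x]:
                continue
            for dx, dy in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                nx, ny = x + dx, y + dy
                if not (0 <= nx < w and 0 <= ny < h) or not grid[ny, nx]:
                    out.add((x, y))
                    break
    return out


class TestExtractContour:
    def test_solid_square_boundary_count(self):
        mask = solid_mask(8, 8, 1, 1, 6, 6)
        contour = extract_contour(mask)
        oracle = _boundary_oracle(mask.grid)
        assert len(oracle) == 16
        assert set(map(tuple, contour.points)) == oracle

    def test_single_pixel_too_small(self):
        with pytest.raises(ValidationError):
            extract_contour(solid_mask(4, 4, 1, 1, 2, 2))

    def test_thin_bar_all_three_pixels(self):
        mask = solid_mask(6, 4, 1, 1, 4, 2)
        contour = extract_contour(mask)
        assert set(map(tuple, contour.points)) == {(1, 1), (2, 1), (3, 1)}

    def test_starts_top_left_and_clockwise(self):
        mask = solid_mask(8, 8, 2, 1, 7, 6)
        pts = extract_contour(mask).points
        assert tuple(pts[0]) == (2, 1)
        assert tuple(pts[1]) == (3, 1)  # east first = clockwise on screen

    def test_multi_component_rejected(self):
        g = np.zeros((8, 8), bool)
        g[0:2, 0:2] = True
        g[5:8, 5:8] = True
        with pytest.raises(ValidationError):
            extract_contour(BinaryMask(g))

    def test_rasterize_contour_round_trip_hausdorff(self, rng):
        # convex polygons >= 5x5 px: contour within 1 px of the polygon
        for _ in range(5):
            c = rng.uniform(12, 20, 2)
            r = rng.uniform(5, 9)
            ang = np.sort(rng.uniform(0, 2 * np.pi, 7))
            verts = np.stack([c[0] + r * np.cos(ang), c[1] + r * np.sin(ang)], 1)
            poly = Polygon(verts).convex_hull
            ann = {"imageWidth": 32, "imageHeight": 32,
                   "shapes": [{"points": np.asarray(poly.exterior.coords)[:-1].tolist()}]}
            mask = largest_component(rasterize_polygons(ann))
            contour = extract_contour(mask)
            # pixel (x, y) represents its center (x+0.5, y+0.5)
            d = [poly.exterior.distance(Point(p[0] + 0.5, p[1] + 0.5))
                 for p in contour.points]
            assert max(d) <= 1.0 + 1e-9


class TestWriteMeasurements:
    def test_empty_header_only(self, tmp_path):
        path = tmp_path / "out.csv"
        write_measurements([], path)
        lines = path.read_text().strip().splitlines()
        assert lines == [",".join(MEASUREMENT_COLUMNS)]

    def test_round_trip_two_decimals(self, tmp_path):
        rec = {c: "" for c in MEASUREMENT_COLUMNS}
        rec.update(ear_tag="t1", frame=3, posture="head_down",
                   angle_deg=1.2345, bsl_px=222.2222, wh_px=210.005,
                   hh_px=215.0, cd_px=100.4999, flags="")
        path = tmp_path / "out.csv"
        write_measurements([rec], path)
        df = pd.read_csv(path)
        assert len(df) == 1 and len(df.columns) == 13
        assert df.loc[0, "bsl_px"] == pytest.approx(222.22, abs=5e-3)
        assert df.loc[0, "angle_deg"] == pytest.approx(1.23, abs=5e-3)
        assert np.isnan(df.loc[0, "bsl_cm"])


class TestFrameSequence:
    def test_indices_strictly_increasing(self):
        m = solid_mask(4, 4, 0, 0, 2, 2)
        with pytest.raises(ValidationError):
            FrameSequence("t", "side", [(1, m), (1, m)])

    def test_mixed_resolution_rejected(self):
        with pytest.raises(ValidationError):
            FrameSequence("t", "side", [(0, solid_mask(4, 4, 0, 0, 2, 2)),
                                        (1, solid_mask(5, 4, 0, 0, 2, 2))])
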