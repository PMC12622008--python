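"""Tests of TLS polygon construction, distance axes, and the radial partition."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Point, Polygon

from tlsniche.geometry import (
    TLSPolygon,
    build_tls_polygons,
    distance_to_tls,
    distance_to_zone_cells,
    radial_partition,
)

from .oracles import distance_to_polygons, mean_knn_distance


def _cells(xy, types=None):
    idx = pd.Index([f"c{i}" for i in range(len(xy))], name="cell_id")
    return pd.DataFrame(
        {
            "cell_id": idx,
            "x_um": [p[0] for p in xy],
            "y_um": [p[1] for p in xy],
            "cell_type": types if types is not None else ["T"] * len(xy),
        },
        index=idx,
    )


def _square_polygon(tls_id=0, lo=0.0, hi=100.0):
    poly = Polygon([(lo, lo), (hi, lo), (hi, hi), (lo, hi)])
    return TLSPolygon(tls_id, poly, poly.area, (poly.centroid.x, poly.centroid.y))


class TestBuildPolygons:
    def test_convex_hull_of_square(self):
        cells = _cells([(0, 0), (100, 0), (100, 100), (0, 100)])
        polys = build_tls_polygons(
            cells, group_eps=200.0, concavity=np.inf, min_area=1000.0
        )
        assert len(polys) == 1
        assert polys[0].area == pytest.approx(10000.0)

    def test_min_area_filter_empties_output(self):
        cells = _cells([(0, 0), (100, 0), (100, 100), (0, 100)])
        with pytest.warns(UserWarning, match="minimum-area"):
            polys = build_tls_polygons(
                cells, group_eps=200.0, concavity=np.inf, min_area=20000.0
            )
        assert polys == []

    def test_two_discs_give_two_hulls_containing_their_cells(self):
        rng = np.random.default_rng(5)
        n = 100
        a = rng.normal(0, 1, (n, 2)) * 60
        b = rng.normal(0, 1, (n, 2)) * 60 + np.array([1000.0, 0.0])
        cells = _cells(np.vstack([a, b]))
        polys = build_tls_polygons(cells, group_eps=80.0, concavity=200.0,
                                   min_area=1000.0)
        assert len(polys) == 2
        for pts, poly in zip((a, b), polys):
            covered = np.mean(
                [poly.polygon.covers(Point(x, y)) for x, y in pts]
            )
            assert covered >= 0.95

    def test_enlarging_min_area_never_adds_polygons(self, small_tissue):
        _, (cells, _, _) = small_tissue
        tls = cells[cells["true_zone"] == "TLS"]
        import warnings

        counts = []
        for min_area in (1000.0, 10000.0, 40000.0, 200000.0):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                polys = build_tls_polygons(tls, 50.0, 150.0, min_area)
            counts.append(len(polys))
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestDistanceToTLS:
    def test_inside_cell_distance_zero(self):
        cells = _cells([(50, 50), (0, 0)])  # interior and boundary corner
        d = distance_to_tls(cells, [_square_polygon()])
        assert d["d_tls"].tolist() == [0.0, 0.0]

    def test_axis_aligned_offset(self):
        cells = _cells([(150, 50)])
        d = distance_to_tls(cells, [_square_polygon()])
        assert d.loc["c0", "d_tls"] == pytest.approx(50.0)

    def test_no_polygons_flagged_undefined(self):
        d = distance_to_tls(_cells([(0, 0)]), [])
        assert np.isnan(d.loc["c0", "d_tls"])
        assert d.loc["c0", "tls_id"] == -1

    def test_matches_segment_distance_oracle(self, random_cells):
        rng = np.random.default_rng(8)
        polys = []
        for i, (cx, cy) in enumerate([(200, 200), (700, 300), (400, 800)]):
            ang = np.sort(rng.uniform(0, 2 * np.pi, 6))
            ring = [
                (cx + 80 * np.cos(t), cy + 80 * np.sin(t)) for t in ang
            ]
            poly = Polygon(ring)
            polys.append(TLSPolygon(i, poly, poly.area,
                                    (poly.centroid.x, poly.centroid.y)))
        cells = random_cells(100, seed=31)
        d = distance_to_tls(cells, polys)
        rings = [list(p.polygon.exterior.coords) for p in polys]
        for cid, row in cells.iterrows():
            expected = distance_to_polygons(row["x_um"], row["y_um"], rings)
            assert d.loc[cid, "d_tls"] == pytest.approx(expected, abs=1e-8)


class TestDistanceToZoneCells:
    def test_arithmetic_mean_of_ten_nearest(self):
        # bronchi-zone cells at 10, 20, ..., 100 μm from the query cell
        xy = [(0.0, 0.0)] + [(10.0 * k, 0.0) for k in range(1, 11)]
        cells = _cells(xy)
        zones = pd.Series(
            ["parenchyma"] + ["bronchi"] * 10, index=cells.index
        )
        d = distance_to_zone_cells(cells, zones, zone="bronchi", k=10)
        assert d.loc["c0"] == pytest.approx(55.0)

    def test_zone_member_distance_zero(self):
        cells = _cells([(0, 0), (5, 0), (10, 0)])
        zones = pd.Series(["bronchi", "bronchi", "parenchyma"], index=cells.index)
        d = distance_to_zone_cells(cells, zones, zone="bronchi", k=2)
        assert d.loc["c0"] == 0.0 and d.loc["c1"] == 0.0

    def test_matches_sort_and_average_oracle(self, random_cells):
        cells = random_cells(300, seed=32, types=("bronchi_cell", "other"))
        zones = pd.Series(
            np.where(cells["cell_type"] == "bronchi_cell", "bronchi", "parenchyma"),
            index=cells.index,
        )
        d = distance_to_zone_cells(cells, zones, zone="bronchi", k=10)
        zone_xy = cells.loc[zones == "bronchi", ["x_um", "y_um"]].to_numpy()
        for cid, row in cells[zones != "bronchi"].iterrows():
            expected = mean_knn_distance(row["x_um"], row["y_um"], zone_xy, 10)
            assert d.loc[cid] == pytest.approx(expected, abs=1e-8)

    def test_zone_smaller_than_k_fails(self):
        cells = _cells([(0, 0), (1, 0), (2, 0)])
        zones = pd.Series(["bronchi", "parenchyma", "parenchyma"],
                          index=cells.index)
        with pytest.raises(ValueError, match="k = 10"):
            distance_to_zone_cells(cells, zones, zone="bronchi", k=10)


class TestRadialPartition:
    def test_centroid_and_extreme_cells(self):
        poly = _square_polygon()
        # centroid is (50, 50); corner cell is the farthest inside cell
        cells = _cells([(50, 50), (1, 1), (50, 60)])
        rad = radial_partition(cells, [poly])
        assert rad.loc["c0", "r_scaled"] == pytest.approx(0.0)
        assert rad.loc["c0", "category"] == "core"
        assert rad.loc["c1", "r_scaled"] == pytest.approx(1.0)
        assert rad.loc["c1", "category"] == "outer"

    def test_ring_membership_boundaries(self):
        poly = _square_polygon()
        cells = _cells([(130, 50), (160, 50), (150, 50)])
        rad = radial_partition(cells, [poly], ring_width=50.0)
        assert rad.loc["c0", "category"] == "surrounding"  # 30 μm outside
        assert rad.loc["c1", "category"] == "none"  # 60 μm outside
        assert rad.loc["c2", "category"] == "surrounding"  # exactly 50 μm
        assert rad.loc["c0", "ring_dist"] == pytest.approx(30.0)

    def test_single_inside_cell_is_core(self):
        poly = _square_polygon()
        cells = _cells([(20, 30), (500, 500)])
        rad = radial_partition(cells, [poly])
        assert rad.loc["c0", "r_scaled"] == 0.0
        assert rad.loc["c0", "category"] == "core"

    def test_core_outer_partition_inside_cells(self, small_tissue):
        _, (cells, _, _) = small_tissue
        tls = cells[cells["true_zone"] == "TLS"]
        polys = build_tls_polygons(tls, 50.0, 150.0, 5000.0)
        rad = radial_partition(cells, polys)
        inside = rad["category"].isin(["core", "outer"])
        # every inside-TLS cell is core or outer and has a scaled radius
        assert rad.loc[inside, "r_scaled"].between(0, 1).all()
        ring = rad["category"] == "surrounding"
        assert rad.loc[ring, "ring_dist"].gt(0).all()
        assert rad.loc[ring, "ring_dist"].le(50.0).all()
        # surrounding is disjoint from core/outer by construction
        assert not (inside & ring).any()

    def test_count_split_mode_balances_halves(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(5, 95, size=(200, 2))
        cells = _cells(pts)
        rad = radial_partition(cells, [_square_polygon()], split_mode="count")
        frac_core = (rad["category"] == "core").mean()
        assert 0.4 <= frac_core <= 0.6


class TestLipschitz:
    def test_distance_axes_are_1_lipschitz(self, random_cells):
        rng = np.random.default_rng(40)
        cells = random_cells(120, seed=41)
        poly = _square_polygon(lo=300.0, hi=500.0)
        d0 = distance_to_tls(cells, [poly])["d_tls"]
        delta = 7.0
        moved = cells.copy()
        angles = rng.uniform(0, 2 * np.pi, len(cells))
        moved["x_um"] += delta * np.cos(angles)
        moved["y_um"] += delta * np.sin(angles)
        d1 = distance_to_tls(moved, [poly])["d_tls"]
        assert (d1 - d0).abs().max() <= delta + 1e-9
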