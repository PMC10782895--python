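"""Geometry representation, rasterization and morphometrics."""

import json

import numpy as np
import pytest

import isletvmo as vmo
from isletvmo.geometry import (
    GEL,
    ISLET,
    LUMEN,
    WALL,
    GeometryError,
    IsletSet,
    ParseError,
    ResolutionError,
    VesselEdge,
    VesselGraph,
)


def shell(w=1000.0, h=600.0):
    return vmo.default_shell(chamber_width=w, chamber_height=h)


def straight_graph(p0, p1, diameter=40.0):
    nodes = np.array([p0, p1], dtype=float)
    return VesselGraph(
        nodes=nodes, edges=[VesselEdge(nodes=(0, 1), polyline=nodes.copy(), diameter_um=diameter)]
    )


class TestRasterize:
    def test_empty_chamber_is_all_gel(self):
        g = shell()
        grid = vmo.rasterize(g, 10.0)
        cx0, cy0, cx1, cy1 = g.chamber_rect
        xs, ys = grid.cell_centers()
        inside = (
            (xs[:, None] > cx0) & (xs[:, None] < cx1) & (ys[None, :] > cy0) & (ys[None, :] < cy1)
        )
        assert np.all(grid.labels[inside] == GEL)

    def test_channels_are_lumen_and_outside_is_wall(self):
        g = shell()
        grid = vmo.rasterize(g, 10.0)
        assert grid.label_at(500.0, -100.0) == LUMEN  # C1
        assert grid.label_at(500.0, 700.0) == LUMEN  # C2
        # nothing outside the chamber+channels
        assert (grid.labels == WALL).sum() == 0  # bbox == domain for the default shell

    def test_straight_vessel_strip_width(self):
        # 40 µm vessel at 5 µm spacing → ~8-cell-wide lumen strip
        g = shell()
        import dataclasses

        g = dataclasses.replace(g, vessels=straight_graph((200.0, 300.0), (800.0, 300.0)))
        grid = vmo.rasterize(g, 5.0)
        # count lumen cells in a column through the strip, away from ends
        ix = grid.cell_of(500.0, 300.0)[0]
        col = grid.labels[ix, :]
        ys = grid.cell_centers()[1]
        strip = (col == LUMEN) & (ys > 0) & (ys < 600.0)
        assert abs(int(strip.sum()) - 8) <= 1
        # painted area matches the analytic strip area within one cell layer/edge
        area = int((grid.labels == LUMEN).sum() * 25) - 2 * int(1000 / 5 * 200 / 5) * 25
        analytic = 600.0 * 40.0
        assert abs(area - analytic) < (600.0 / 5 + 8) * 2 * 25

    def test_islet_disc_area(self):
        import dataclasses

        g = dataclasses.replace(
            shell(),
            islets=IsletSet(centers=np.array([[500.0, 300.0]]), diameters=np.array([90.0])),
        )
        grid = vmo.rasterize(g, 5.0)
        n = int((grid.labels == ISLET).sum())
        assert n == pytest.approx(np.pi * 45.0**2 / 25.0, rel=0.05)
        assert np.all(grid.islet_id[grid.labels == ISLET] == 0)

    def test_spacing_too_coarse_raises(self):
        import dataclasses

        g = dataclasses.replace(shell(), vessels=straight_graph((200, 300), (800, 300), 30.0))
        with pytest.raises(ResolutionError):
            vmo.rasterize(g, 20.0)

    def test_islet_outside_chamber_rejected(self):
        import dataclasses

        g = dataclasses.replace(
            shell(),
            islets=IsletSet(centers=np.array([[5000.0, 300.0]]), diameters=np.array([90.0])),
        )
        with pytest.raises(GeometryError):
            vmo.rasterize(g, 10.0)

    def test_lumen_takes_precedence_over_islet_boundary(self):
        import dataclasses

        g = dataclasses.replace(
            shell(),
            vessels=straight_graph((200.0, 300.0), (800.0, 300.0)),
            islets=IsletSet(centers=np.array([[500.0, 340.0]]), diameters=np.array([90.0])),
        )
        grid = vmo.rasterize(g, 5.0)
        # cells on the vessel midline stay lumen even where the islet disc clips it
        assert grid.label_at(500.0, 300.0) == LUMEN

    def test_area_converges_with_refinement(self):
        g = shell()
        analytic = 1000.0 * 600.0 + 2 * 1000.0 * 200.0
        errs = []
        for h in (10.0, 5.0, 2.5):
            grid = vmo.rasterize(g, h)
            painted = (grid.labels != WALL).sum() * h * h
            errs.append(abs(painted - analytic) / analytic)
        assert errs[2] <= errs[0] + 1e-12


class TestMorphometrics:
    def test_total_length_single_edge(self):
        assert vmo.total_vessel_length(straight_graph((0, 0), (1000, 0))) == pytest.approx(1000.0)

    def test_total_length_additive(self):
        nodes = np.array([[0, 0], [300, 0], [300, 700]], dtype=float)
        g = VesselGraph(
            nodes=nodes,
            edges=[
                VesselEdge((0, 1), nodes[[0, 1]], 40.0),
                VesselEdge((1, 2), nodes[[1, 2]], 40.0),
            ],
        )
        assert vmo.total_vessel_length(g) == pytest.approx(1000.0)

    def test_total_length_polyline_matches_bruteforce(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(0, 1000, size=(30, 2))
        g = VesselGraph(
            nodes=pts[[0, -1]],
            edges=[VesselEdge((0, 1), pts, 30.0)],
        )
        brute = sum(
            float(np.hypot(*(pts[i + 1] - pts[i]))) for i in range(len(pts) - 1)
        )
        assert vmo.total_vessel_length(g) == pytest.approx(brute, rel=1e-12)

    def test_total_length_rigid_motion_invariant(self):
        rng = np.random.default_rng(4)
        pts = rng.uniform(0, 1000, size=(12, 2))
        g = VesselGraph(nodes=pts[[0, -1]], edges=[VesselEdge((0, 1), pts, 30.0)])
        th = 0.73
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        pts2 = pts @ R.T + np.array([123.0, -456.0])
        g2 = VesselGraph(nodes=pts2[[0, -1]], edges=[VesselEdge((0, 1), pts2, 30.0)])
        assert vmo.total_vessel_length(g2) == pytest.approx(vmo.total_vessel_length(g))

    def test_branch_points(self):
        # single edge: none
        assert vmo.count_branch_points(straight_graph((0, 0), (100, 0))) == 0
        # Y shape: one
        nodes = np.array([[0, 0], [100, 0], [200, 100], [200, -100]], dtype=float)
        g = VesselGraph(
            nodes=nodes,
            edges=[
                VesselEdge((0, 1), nodes[[0, 1]], 30.0),
                VesselEdge((1, 2), nodes[[1, 2]], 30.0),
                VesselEdge((1, 3), nodes[[1, 3]], 30.0),
            ],
        )
        assert vmo.count_branch_points(g) == 1

    def test_branch_points_random_tree(self):
        # binary tree with k internal degree-3 nodes
        rng = np.random.default_rng(5)
        nodes = [np.array([0.0, 0.0])]
        edges = []
        leaves = [0]
        internal = 0
        for _ in range(5):
            new_leaves = []
            for leaf in leaves:
                for _ in range(2 if rng.uniform() < 0.5 else 1):
                    nodes.append(nodes[leaf] + rng.uniform(50, 200, 2))
                    edges.append((leaf, len(nodes) - 1))
                new_leaves.extend(
                    j for (i, j) in edges if i == leaf and j not in new_leaves
                )
            leaves = new_leaves
        deg = {}
        for i, j in edges:
            deg[i] = deg.get(i, 0) + 1
            deg[j] = deg.get(j, 0) + 1
        expected = sum(1 for d in deg.values() if d >= 3)
        arr = np.array(nodes)
        g = VesselGraph(
            nodes=arr,
            edges=[VesselEdge((i, j), arr[[i, j]], 30.0) for i, j in edges],
        )
        assert vmo.count_branch_points(g) == expected

    def test_branch_count_invariant_under_subdivision(self):
        nodes = np.array([[0, 0], [100, 0], [200, 100], [200, -100]], dtype=float)
        g = VesselGraph(
            nodes=nodes,
            edges=[
                VesselEdge((0, 1), nodes[[0, 1]], 30.0),
                VesselEdge((1, 2), nodes[[1, 2]], 30.0),
                VesselEdge((1, 3), nodes[[1, 3]], 30.0),
            ],
        )
        # subdivide edge (0,1) with a degree-2 node at (50, 0)
        nodes2 = np.vstack([nodes, [[50.0, 0.0]]])
        g2 = VesselGraph(
            nodes=nodes2,
            edges=[
                VesselEdge((0, 4), nodes2[[0, 4]], 30.0),
                VesselEdge((4, 1), nodes2[[4, 1]], 30.0),
                VesselEdge((1, 2), nodes2[[1, 2]], 30.0),
                VesselEdge((1, 3), nodes2[[1, 3]], 30.0),
            ],
        )
        assert vmo.count_branch_points(g2) == vmo.count_branch_points(g) == 1

    def test_nearby_junctions_merge(self):
        # two degree-3 "nodes" 5 µm apart merge into one branch point at
        # the default 10 µm tolerance (degree 4 after merge)
        nodes = np.array(
            [[0, 0], [100, 0], [105, 0], [200, 80], [200, -80], [205, 80], [205, -80]],
            dtype=float,
        )
        g = VesselGraph(
            nodes=nodes,
            edges=[
                VesselEdge((0, 1), nodes[[0, 1]], 30.0),
                VesselEdge((1, 3), nodes[[1, 3]], 30.0),
                VesselEdge((1, 4), nodes[[1, 4]], 30.0),
                VesselEdge((2, 5), nodes[[2, 5]], 30.0),
                VesselEdge((2, 6), nodes[[2, 6]], 30.0),
            ],
        )
        assert vmo.count_branch_points(g, merge_tol=10.0) == 1
        assert vmo.count_branch_points(g, merge_tol=1.0) == 1  # only node 1 has deg 3

    @pytest.mark.parametrize(
        "length,interval,expected",
        [(120.0, 50.0, 3), (30.0, 50.0, 1), (100.0, 50.0, 2), (1000.0, 50.0, 20)],
    )
    def test_diameter_sample_counts(self, length, interval, expected):
        g = straight_graph((0, 0), (length, 0), diameter=42.0)
        pooled, per_edge = vmo.sample_diameters(g, interval)
        assert len(pooled) == expected
        assert np.all(pooled == 42.0)

    def test_pooled_count_formula(self):
        rng = np.random.default_rng(8)
        edges = []
        nodes = []
        for k in range(6):
            p0 = rng.uniform(0, 2000, 2)
            p1 = p0 + rng.uniform(20, 800, 2)
            nodes.extend([p0, p1])
            arr = np.array([p0, p1])
            edges.append(VesselEdge((2 * k, 2 * k + 1), arr, 30.0))
        g = VesselGraph(nodes=np.array(nodes), edges=edges)
        pooled, _ = vmo.sample_diameters(g, 50.0)
        expected = sum(int(np.floor(e.length / 50.0)) + 1 for e in g.edges)
        assert len(pooled) == expected


class TestIO:
    def test_round_trip(self, tmp_path, small_device):
        path = tmp_path / "g.json"
        vmo.write_geometry(small_device, path)
        g2 = vmo.read_geometry(path)
        assert np.array_equal(g2.islets.centers, small_device.islets.centers)
        assert np.array_equal(g2.islets.diameters, small_device.islets.diameters)
        assert g2.vessels.n_edges == small_device.vessels.n_edges
        for e1, e2 in zip(small_device.vessels.edges, g2.vessels.edges):
            assert e1.diameter_um == e2.diameter_um  # bit-exact
            assert np.array_equal(e1.polyline, e2.polyline)
        assert [p.name for p in g2.ports] == [p.name for p in small_device.ports]

    def test_missing_vessels_key_names_field(self, tmp_path):
        doc = vmo.geometry_to_dict(shell())
        del doc["vessels"]
        path = tmp_path / "bad.json"
        path.write_text(json.dumps(doc))
        with pytest.raises(ParseError, match="vessels"):
            vmo.read_geometry(path)

    def test_swc_import(self, tmp_path):
        path = tmp_path / "skel.swc"
        path.write_text(
            "# test skeleton\n"
            "1 2 0 0 0 20 -1\n"
            "2 2 100 0 0 20 1\n"
            "3 2 200 80 0 15 2\n"
            "4 2 200 -80 0 15 2\n"
        )
        g = vmo.read_swc_skeleton(path)
        assert g.n_edges == 3
        assert vmo.count_branch_points(g) == 1
        assert g.edges[0].diameter_um == pytest.approx(40.0)
        assert g.edges[1].diameter_um == pytest.approx(35.0)  # mean radius × 2


class TestValidation:
    def test_overlapping_islets_rejected(self):
        with pytest.raises(GeometryError, match="overlap"):
            IsletSet(
                centers=np.array([[500.0, 300.0], [540.0, 300.0]]),
                diameters=np.array([90.0, 90.0]),
            ).validate()

    def test_oversized_islet_rejected(self):
        with pytest.raises(GeometryError):
            IsletSet(centers=np.array([[500.0, 300.0]]), diameters=np.array([250.0])).validate()

    def test_port_head_nonnegative(self):
        from isletvmo.geometry import PortSpec

        with pytest.raises(GeometryError):
            PortSpec("V_A", (0, 0, 0, 100), head_mm=-1.0)
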