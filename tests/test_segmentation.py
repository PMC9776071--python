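"""Active-contour lumen and polar-DP outer-wall segmentation."""
from itertools import product

import numpy as np
import pytest

from plaquestruct.segmentation import (
    Contour,
    SnakeParams,
    WallTraceParams,
    evolve_active_contour,
    init_contours_from_centerline,
    minimal_cyclic_path,
    trace_outer_wall,
)

from conftest import PX, annulus_image, circle_vertices, disk_image


class TestInitContours:
    def test_circle_area_matches_analytic(self):
        c = Contour(circle_vertices((5.0, 5.0), 1.5, n=64), 0)
        assert c.area == pytest.approx(np.pi * 1.5**2, rel=0.01)

    def test_straight_centerline_gives_identical_circles(self, default_phantom):
        from plaquestruct.centerline import Centerline

        pts = np.array([[5.0, 5.0, z * 0.25] for z in range(10)])
        vox = np.round(pts / 0.25).astype(int)
        arc = np.linalg.norm(np.diff(pts, axis=0), axis=1).cumsum()
        cl = Centerline(pts, vox, np.concatenate([[0], arc]), "CCA-ICA", 1.0)
        contours = init_contours_from_centerline(
            cl, default_phantom["stack"], r0=1.5
        )
        assert len(contours) == 10
        areas = {round(c.area, 9) for c in contours}
        assert len(areas) == 1

    def test_nonpositive_radius_rejected(self, default_phantom):
        from plaquestruct.centerline import Centerline

        pts = np.array([[5.0, 5.0, 0.0], [5.0, 5.0, 0.25]])
        cl = Centerline(pts, np.round(pts / 0.25).astype(int),
                        np.array([0.0, 0.25]), "CCA-ICA", 1.0)
        with pytest.raises(ValueError):
            init_contours_from_centerline(cl, default_phantom["stack"], r0=0.0)


class TestSnake:
    def test_disk_radius_recovered_within_five_percent(self):
        img, c = disk_image(2.0, noise=0.0)
        out = evolve_active_contour(
            img, PX, Contour(circle_vertices(c, 0.8 * 2.0), 0)
        )
        r = np.linalg.norm(out.vertices - np.asarray(out.centroid), axis=1)
        assert r.mean() == pytest.approx(2.0, rel=0.05)
        assert out.area == pytest.approx(np.pi * 4.0, rel=0.05)

    def test_convergence_from_inside_and_outside_agree(self):
        img, c = disk_image(2.0, noise=0.05)
        a = evolve_active_contour(img, PX, Contour(circle_vertices(c, 1.2), 0))
        b = evolve_active_contour(img, PX, Contour(circle_vertices(c, 2.8), 0))
        assert a.area == pytest.approx(b.area, rel=0.03)

    def test_init_on_edge_barely_moves(self):
        img, c = disk_image(2.0, noise=0.0)
        init = Contour(circle_vertices(c, 2.0), 0)
        out = evolve_active_contour(img, PX, init)
        disp = np.linalg.norm(
            out.vertices - init.vertices[: len(out.vertices)], axis=1
        ).max()
        assert disp < 0.5 * PX

    def test_flat_image_perimeter_shrinks_monotonically(self):
        img = np.zeros((80, 80))
        p = SnakeParams(iters=1, refine=False)
        cur = Contour(circle_vertices((10.0, 10.0), 5.0), 0)
        peris = [cur.perimeter]
        for _ in range(50):
            cur = evolve_active_contour(img, PX, cur, p)
            peris.append(cur.perimeter)
        diffs = np.diff(peris)
        assert np.all(diffs <= 1e-9)
        assert peris[-1] < 0.5 * peris[0]

    def test_collapse_raises_with_advice(self):
        # tiny contour in the dark corner, far from the bright disk: the
        # region pressure deflates it below one voxel of area
        img, _ = disk_image(2.0)
        init = Contour(circle_vertices((1.5, 1.5), 0.3), 0)
        with pytest.raises(ValueError, match="r0"):
            evolve_active_contour(img, PX, init, SnakeParams(iters=2000))

    def test_output_contour_is_simple(self):
        img, c = disk_image(1.5, noise=0.08, seed=3)
        out = evolve_active_contour(img, PX, Contour(circle_vertices(c, 1.0), 0))
        assert out.is_simple()


class TestOuterWall:
    def test_annulus_outer_radius_within_one_radial_sample(self):
        img, c = annulus_image(r_in=2.0, r_out=3.0)
        lum = Contour(circle_vertices(c, 2.0), 0, kind="lumen")
        p = WallTraceParams()
        out = trace_outer_wall(img, PX, lum, p)
        r = np.linalg.norm(out.vertices - c, axis=1)
        dr = p.r_max_offset / (p.n_r - 1)
        assert np.all(np.abs(r - 3.0) <= dr + 1e-9)

    def test_infinite_smoothness_gives_circle(self):
        img, c = annulus_image()
        lum = Contour(circle_vertices(c, 2.0), 0, kind="lumen")
        out = trace_outer_wall(img, PX, lum, WallTraceParams(smoothness=1e9))
        r = np.linalg.norm(out.vertices - c, axis=1)
        assert np.ptp(r) < 1e-9

    def test_outer_contour_encloses_lumen(self):
        img, c = annulus_image(noise=0.08, seed=5)
        lum = Contour(circle_vertices(c, 2.0), 0, kind="lumen")
        out = trace_outer_wall(img, PX, lum)
        assert out.polygon().buffer(1e-6).contains(lum.polygon())

    def test_saturated_search_range_warns(self):
        # intensity falls ever faster with radius, so the strongest outward
        # edge always sits at the far end of the (too short) search range
        shape = (96, 96)
        c = (np.array(shape) - 1) / 2 * PX
        yy, xx = np.meshgrid(
            np.arange(shape[0]) * PX, np.arange(shape[1]) * PX, indexing="ij"
        )
        d = np.hypot(xx - c[1], yy - c[0])
        img = 1.0 - (d / 12.0) ** 2
        lum = Contour(circle_vertices(c, 2.0), 0, kind="lumen")
        with pytest.warns(UserWarning, match="search range"):
            trace_outer_wall(img, PX, lum, WallTraceParams(r_max_offset=2.0))


class TestCyclicDP:
    def _brute(self, cost, radii, lam, max_jump):
        nt, nr = cost.shape
        best = np.inf
        best_path = None
        for path in product(range(nr), repeat=nt):
            if any(
                abs(path[(i + 1) % nt] - path[i]) > max_jump for i in range(nt)
            ):
                continue
            tot = sum(cost[i, path[i]] for i in range(nt)) + sum(
                lam * abs(radii[(i + 1) % nt, path[(i + 1) % nt]] - radii[i, path[i]])
                for i in range(nt)
            )
            if tot < best:
                best, best_path = tot, path
        return best, best_path

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_dp_equals_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        nt, nr = 6, 4
        cost = rng.normal(size=(nt, nr))
        radii = np.cumsum(rng.uniform(0.1, 0.5, size=(nt, nr)), axis=1)
        ref, ref_path = self._brute(cost, radii, 0.35, 2)
        path, total = minimal_cyclic_path(cost, radii, 0.35, 2)
        assert total == pytest.approx(ref, abs=1e-10)
        assert tuple(path) == ref_path

    @pytest.mark.parametrize("seed", [0, 1])
    def test_dp_equals_layered_graph_shortest_path_at_study_size(self, seed):
        """Exact optimality at N_theta=12, N_r=8 via an independent
        layered-graph Dijkstra (networkx) over every admissible cycle."""
        import networkx as nx

        rng = np.random.default_rng(seed + 10)
        nt, nr, lam, mj = 12, 8, 0.35, 2
        cost = rng.normal(size=(nt, nr))
        radii = np.cumsum(rng.uniform(0.1, 0.5, size=(nt, nr)), axis=1)
        shift = 10.0  # keep every edge weight positive for Dijkstra
        best_ref = np.inf
        for r0 in range(nr):
            G = nx.DiGraph()
            G.add_edge("s", (0, r0), weight=cost[0, r0] + shift)
            for i in range(1, nt):
                for j in range(nr):
                    for k in range(max(0, j - mj), min(nr, j + mj + 1)):
                        G.add_edge(
                            (i - 1, k), (i, j),
                            weight=cost[i, j] + shift
                            + lam * abs(radii[i, j] - radii[i - 1, k]),
                        )
            for k in range(nr):
                if abs(r0 - k) <= mj:
                    G.add_edge(
                        (nt - 1, k), "t", weight=lam * abs(radii[0, r0] - radii[nt - 1, k])
                    )
            try:
                best_ref = min(
                    best_ref, nx.dijkstra_path_length(G, "s", "t") - shift * nt
                )
            except nx.NetworkXNoPath:
                pass
        _, total = minimal_cyclic_path(cost, radii, lam, mj)
        assert total == pytest.approx(best_ref, abs=1e-10)


class TestWallBandOnPhantom:
    def test_wall_band_dice_and_lumen_area_on_noise_free_annulus(self):
        """Per-slice lumen area error <= 5% and wall-band Dice >= 0.9."""
        img_t, c = annulus_image(noise=0.0)
        img_l, _ = disk_image(2.0, shape=(96, 96), noise=0.0)
        lum = evolve_active_contour(
            img_l, PX, Contour(circle_vertices(c, 1.2), 0)
        )
        assert lum.area == pytest.approx(np.pi * 4.0, rel=0.05)
        outer = trace_outer_wall(img_t, PX, lum)
        # Dice of the traced annulus band vs the true 2..3 mm band
        from shapely.geometry import Point

        truth = Point(c).buffer(3.0).difference(Point(c).buffer(2.0))
        got = outer.polygon().difference(lum.polygon())
        inter = truth.intersection(got).area
        dice = 2 * inter / (truth.area + got.area)
        assert dice >= 0.9
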