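import numpy as np
import pytest

from spinetrack.errors import ParameterError
from spinetrack.fastmarching import solve_eikonal
from spinetrack.imgio import VoxelGeometry, ZStack
from spinetrack.neckpath import (NeckPath, build_speed_map,
                                 candidate_base_points, distance_map_3d,
                                 path_terms, select_neck_path, trace_path,
                                 trim_path)

ISO = VoxelGeometry(dx=0.1, dy=0.1, dz=0.1, bit_depth=16)


class TestSpeedMap:
    def test_zero_erosion_is_normalized_intensity(self):
        data = np.random.default_rng(0).uniform(0, 500, (12, 12, 4))
        sm = build_speed_map(ZStack(data, ISO), erosion_radius=0)
        np.testing.assert_allclose(sm.values.max(), 1.0)
        np.testing.assert_allclose(sm.values,
                                   np.maximum(data / data.max(), 1e-3))

    def test_thin_line_collapsed_by_erosion(self):
        data = np.full((21, 21, 3), 10.0)
        data[9:12, :, :] = 1000.0  # 3-px-wide bright line
        sm = build_speed_map(ZStack(data, ISO), erosion_radius=2)
        line_speed = sm.values[10, 10, 1]
        assert line_speed < 0.5  # line intensity no longer dominates

    def test_constant_bright_cube_interior_speed_one(self):
        sm = build_speed_map(ZStack(np.full((9, 9, 3), 800.0), ISO),
                             erosion_radius=0)
        assert sm.values[4, 4, 1] == 1.0


class TestDistanceMap:
    def test_uniform_speed_matches_euclidean(self):
        sm = build_speed_map(ZStack(np.full((21, 21, 21), 100.0), ISO),
                             erosion_radius=0)
        T = distance_map_3d(sm, (10, 10, 10))
        idx = np.indices((21, 21, 21)).astype(float)
        d = 0.1 * np.sqrt(((idx - 10) ** 2).sum(axis=0))
        far = d > 0.25
        rel = np.abs(T[far] - d[far]) / d[far]
        assert rel.max() <= 0.02

    def test_source_time_zero_and_monotone_nonnegative(self):
        sm = build_speed_map(ZStack(np.full((9, 9, 5), 10.0), ISO),
                             erosion_radius=0)
        T = distance_map_3d(sm, (4, 4, 2))
        assert T[4, 4, 2] == 0.0
        assert (T >= 0).all()

    def test_doubling_speed_halves_arrival_times(self):
        speed = np.random.default_rng(1).uniform(0.2, 1.0, (11, 11, 5))
        T1 = solve_eikonal(speed, (5, 5, 2))
        T2 = solve_eikonal(2.0 * speed, (5, 5, 2))
        np.testing.assert_allclose(T2, T1 / 2.0, rtol=1e-10)

    def test_dijkstra_oracle_agreement(self):
        # independent oracle: Dijkstra on the 26-neighbor graph.  The graph
        # metric overestimates the continuum by up to 8.24% in-plane and
        # 12.81% in 3D (chamfer discretization bounds), which bounds the
        # admissible deviation.
        from scipy.sparse import coo_matrix
        from scipy.sparse.csgraph import dijkstra

        def graph_distances(shape, src):
            n = int(np.prod(shape))
            index = np.arange(n).reshape(shape)
            coords = np.argwhere(np.ones(shape, bool))
            rows, cols, w = [], [], []
            for off in np.ndindex(3, 3, 3):
                off = np.array(off) - 1
                if not off.any():
                    continue
                ok = np.all((coords + off >= 0) & (coords + off < shape), axis=1)
                a = coords[ok]
                b = a + off
                rows.extend(index[tuple(a.T)])
                cols.extend(index[tuple(b.T)])
                w.extend([np.linalg.norm(off)] * len(a))
            g = coo_matrix((w, (rows, cols)), shape=(n, n)).tocsr()
            return dijkstra(g, indices=index[src]).reshape(shape)

        T = solve_eikonal(np.ones((7, 7, 7)), (3, 3, 3))
        D = graph_distances((7, 7, 7), (3, 3, 3))
        nz = D > 0
        assert (np.abs(T[nz] - D[nz]) / D[nz]).max() <= 0.1282

        T2 = solve_eikonal(np.ones((7, 7, 1)), (3, 3, 0))
        D2 = graph_distances((7, 7, 1), (3, 3, 0))
        nz2 = D2 > 0
        assert (np.abs(T2[nz2] - D2[nz2]) / D2[nz2]).max() <= 0.0825


class TestTracePath:
    def test_straight_line_in_uniform_medium(self):
        T = solve_eikonal(np.ones((9, 31, 9)), (4, 4, 4))
        path = trace_path(T, (4.0, 28.0, 4.0))
        # geodesic is the straight row=4, z=4 line
        dev = np.abs(path[:, [0, 2]] - 4.0).max()
        assert dev <= 0.5
        assert np.linalg.norm(path[-1] - (4, 4, 4)) <= 1.0

    def test_start_at_source_single_point(self):
        T = solve_eikonal(np.ones((9, 9, 9)), (4, 4, 4))
        path = trace_path(T, (4.0, 4.0, 4.0))
        assert len(path) <= 2

    def test_path_stays_in_high_speed_channel(self):
        speed = np.full((25, 25, 5), 1e-3)
        speed[12, 2:23, 2] = 1.0          # horizontal arm
        speed[2:13, 22, 2] = 1.0          # vertical arm (L shape)
        T = solve_eikonal(speed, (12, 2, 2))
        path = trace_path(T, (2.0, 22.0, 2.0))
        in_channel = 0
        for p in path:
            r, c, z = (int(round(v)) for v in p)
            in_channel += speed[min(r, 24), min(c, 24), min(z, 4)] > 0.5
        assert in_channel / len(path) >= 0.95

    def test_monotone_arrival_times(self):
        T = solve_eikonal(np.ones((9, 21, 9)), (4, 3, 4))
        path = trace_path(T, (4.0, 18.0, 4.0))
        from scipy import ndimage
        vals = ndimage.map_coordinates(T, path.T, order=1)
        assert (np.diff(vals) <= 1e-6).all()


class TestCandidateBasePoints:
    def test_nearest_single_point(self):
        mask = np.zeros((11, 11, 3), bool)
        mask[8, :, 1] = True
        pts = candidate_base_points((2, 5, 1), mask, N=1)
        assert len(pts) == 1
        # perimeter of a 1-voxel-thick line is the line itself
        assert pts[0][0] == 8 and pts[0][1] == 5

    def test_tie_break_lower_row(self):
        mask = np.zeros((9, 9, 1), bool)
        mask[1, 4, 0] = True
        mask[7, 4, 0] = True
        pts = candidate_base_points((4, 4, 0), mask, N=1)
        assert tuple(pts[0][:2]) == (1, 4)

    def test_perpendicular_foot_neighborhood_on_tube(self):
        mask = np.zeros((21, 41, 5), bool)
        rr, cc, zz = np.mgrid[0:21, 0:41, 0:5]
        mask[(rr - 16) ** 2 + (zz - 2) ** 2 <= 9] = True
        pts = candidate_base_points((4, 20, 2), mask, N=6)
        # all within a short arc around the perpendicular foot (col 20)
        assert np.abs(pts[:, 1] - 20).max() <= 6

    def test_small_perimeter_returns_all(self):
        mask = np.zeros((5, 5, 1), bool)
        mask[2, 2, 0] = True
        pts = candidate_base_points((0, 0, 0), mask, N=10)
        assert len(pts) == 1

    def test_empty_mask_rejected(self):
        with pytest.raises(ParameterError):
            candidate_base_points((0, 0, 0), np.zeros((3, 3, 3), bool), 1)


class TestPathTerms:
    def test_axis_aligned_hand_geometry(self):
        stack = ZStack(np.full((3, 15, 3), 50.0), ISO)
        path = np.array([[1.0, 2.0, 1.0], [1.0, 12.0, 1.0]])
        L, C, S = path_terms(path, stack, ISO)
        assert L == pytest.approx(1.0)      # 10 voxels at 0.1 μm
        assert C == pytest.approx(10.0)
        assert S == pytest.approx(0.0)      # constant intensity

    def test_hand_made_path_over_hand_made_volume(self):
        vol = np.arange(27, dtype=float).reshape(3, 3, 3)
        stack = ZStack(vol, ISO)
        path = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [2, 1, 1]], dtype=float)
        # L: segments (1,0,0), (0,1,0), (1,0,1) → 0.1·(1 + 1 + sqrt(2))
        L, C, S = path_terms(path, stack, ISO, resample_step=1e-3)
        assert L == pytest.approx(0.1 * (2 + np.sqrt(2)))
        # C telescopes along monotone segments: 1 + 1 + (1+0+1) = 4
        assert C == pytest.approx(4.0, rel=1e-3)
        # intensity field is linear (9r+3c+z), so TV = 22 − 0 (monotone)
        assert S == pytest.approx(22.0, rel=1e-3)

    def test_point_outside_volume_rejected(self):
        stack = ZStack(np.zeros((3, 3, 3)), ISO)
        with pytest.raises(ParameterError):
            path_terms(np.array([[0, 0, 0], [5, 0, 0]], float), stack, ISO)


class TestSelection:
    def test_dominating_candidate_selected(self):
        p = np.zeros((2, 3))
        cands = [(p, 1.0, 1.0, 1.0), (p, 2.0, 3.0, 4.0)]
        assert select_neck_path(cands).L == 1.0

    def test_hand_arithmetic_max_normalized_sum(self):
        p = np.zeros((2, 3))
        first = (p, 1.0, 1.0, 2.0)   # cost 0.5 + 0.5 + 1.0 = 2.0
        second = (p, 2.0, 2.0, 1.0)  # cost 1.0 + 1.0 + 0.5 = 2.5
        best = select_neck_path([first, second])
        assert best.L == 1.0 and best.cost == pytest.approx(2.0)

    def test_all_equal_tie_breaks_to_first(self):
        paths = [np.full((2, 3), i, dtype=float) for i in range(3)]
        cands = [(p, 1.0, 1.0, 1.0) for p in paths]
        np.testing.assert_array_equal(select_neck_path(cands).points, paths[0])

    def test_single_candidate_cost_counts_nondegenerate_terms(self):
        p = np.zeros((2, 3))
        assert select_neck_path([(p, 1.0, 2.0, 0.0)]).cost == pytest.approx(2.0)

    def test_rescaling_one_term_preserves_choice(self):
        p = np.zeros((2, 3))
        base = [(p, 1.0, 1.0, 2.0), (p, 2.0, 2.0, 1.0)]
        scaled = [(p, 10.0, 1.0, 2.0), (p, 20.0, 2.0, 1.0)]
        assert select_neck_path(base).cost == pytest.approx(
            select_neck_path(scaled).cost)


class TestTrim:
    def _straight_path(self, n=10):
        return NeckPath(points=np.array([[5.0, float(c), 1.0] for c in range(n)]),
                        L=0.9, C=9.0, S=0.0, cost=1.0)

    def test_outside_both_masks_unchanged(self):
        stack = ZStack(np.full((11, 11, 3), 10.0), ISO)
        path = self._straight_path()
        out = trim_path(path, np.zeros((11, 11), bool), np.zeros((11, 11), bool),
                        stack, ISO)
        assert out.trimmed
        assert "untrimmed-endpoints" in out.flags
        np.testing.assert_array_equal(out.points, path.points)

    def test_hand_masking_keeps_interior(self):
        stack = ZStack(np.full((11, 11, 3), 10.0), ISO)
        head = np.zeros((11, 11), bool)
        head[5, 0:3] = True      # first 3 voxels
        dend = np.zeros((11, 11), bool)
        dend[5, 8:10] = True     # last 2 voxels
        out = trim_path(self._straight_path(), head, dend, stack, ISO)
        assert len(out.points) == 5
        assert out.points[0][1] == 3.0 and out.points[-1][1] == 7.0

    def test_stubby_spine_zero_length(self):
        stack = ZStack(np.full((11, 11, 3), 10.0), ISO)
        head = np.zeros((11, 11), bool)
        head[5, :5] = True
        dend = np.zeros((11, 11), bool)
        dend[5, 4:] = True
        out = trim_path(self._straight_path(), head, dend, stack, ISO)
        assert out.L == 0.0
        assert "zero-length" in out.flags


class TestPhantomNeckExtraction:
    def test_length_recovered_and_base_on_parent(self):
        from spinetrack.neckpath import extract_neck
        from spinetrack.simulator import make_phantom_zstack

        stack, truth = make_phantom_zstack(neck_length_um=1.0,
                                           distractor_gap_um=0.4, seed=1)
        neck = extract_neck(stack, truth["head_center_vox"],
                            truth["head_mask"], truth["dendrite_mask"])
        ell = truth["neck_length_um"]
        assert 0.85 * ell <= neck.L <= 1.15 * ell
        # base point attaches to the parent dendrite, not the Euclidean-nearer
        # distractor on the other side of the head
        assert neck.points[0][0] > truth["head_center_vox"][0]
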