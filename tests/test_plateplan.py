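import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plateforge import synthetic
from plateforge.meshcore import concatenate, surface_distances
from plateforge.plateplan import (PathParams, PathProjectionError, SurfacePath,
                                  arc_length, build_path, load_anchors_json,
                                  match_length, point_at_arc_length,
                                  project_anchors, save_anchors_json,
                                  wrap_path)


def straight_path(length, spacing=0.5):
    n = max(int(np.ceil(length / spacing)), 1)
    xs = np.linspace(0.0, length, n + 1)
    pts = np.stack([xs, np.zeros_like(xs), np.zeros_like(xs)], axis=1)
    return SurfacePath.from_samples(pts, anchor_indices=[0, n])


def oracle_unit_count(S, L):
    """Nearest-integer brute force, ties rounded up, floor 1."""
    lo = int(np.floor(S / L))
    hi = lo + 1
    best = lo if abs(S - lo * L) < abs(S - hi * L) else hi
    if abs(S - lo * L) == abs(S - hi * L):
        best = hi
    return max(best, 1)


class TestPathParams:
    def test_defaults(self):
        p = PathParams()
        assert p.sample_spacing == 0.5
        assert p.wrap_distance == 5.0

    def test_invalid(self):
        with pytest.raises(ValueError):
            PathParams(sample_spacing=0)
        with pytest.raises(ValueError):
            PathParams(wrap_distance=0.05, projection_tolerance=0.1)
        with pytest.raises(ValueError):
            PathParams(smoothing_lambda=1.5)


class TestSurfacePath:
    def test_cumulative_length_consistency(self, rng):
        pts = rng.normal(size=(30, 3)) * 10
        path = SurfacePath.from_samples(pts)
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        assert np.allclose(np.diff(path.cumulative_length), seg, atol=1e-9)

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            SurfacePath.from_samples([[0, 0, 0]])


class TestProjectAnchors:
    def test_points_on_mesh_unchanged(self, flat100):
        pts = np.array([[-10.0, 3.0, 0.0], [15.0, -7.0, 0.0]])
        out = project_anchors(flat100, pts)
        assert np.allclose(out, pts, atol=1e-9)

    def test_vertical_foot_point(self, flat100):
        out = project_anchors(flat100, [[5.0, 5.0, 5.0], [20.0, 0.0, 3.0]])
        assert np.allclose(out[0], [5.0, 5.0, 0.0], atol=1e-9)

    def test_sphere_projection_radius(self, icosphere10, rng):
        raw = []
        for _ in range(10):
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            raw.append(d * (10 + rng.uniform(-2, 2)))
        out = project_anchors(icosphere10, raw)
        radii = np.linalg.norm(out, axis=1)
        assert np.all(np.abs(radii - 10) < 0.15)  # facet chord error

    def test_duplicates_collapsed(self, flat100):
        pts = [[0, 0, 1], [0, 0, 2], [10, 0, 1]]  # same foot point twice
        out = project_anchors(flat100, pts)
        assert len(out) == 2

    def test_all_duplicates_error(self, flat100):
        with pytest.raises(ValueError, match="distinct"):
            project_anchors(flat100, [[0, 0, 1], [0, 0, 5]])

    def test_single_point_error(self, flat100):
        with pytest.raises(ValueError):
            project_anchors(flat100, [[0, 0, 1]])


class TestBuildPath:
    def test_flat_straight_segment(self, flat100):
        anchors = np.array([[-20.0, 0, 0], [20.0, 0, 0]])
        path = build_path(flat100, anchors)
        assert arc_length(path) == pytest.approx(40.0, abs=1e-6)
        assert np.allclose(path.samples[:, 2], 0, atol=1e-9)

    def test_great_circle_arc_length(self):
        sphere = synthetic.icosphere(100.0, 5)
        angles = np.radians(np.arange(0, 121, 30))
        anchors = np.stack([100 * np.cos(angles), 100 * np.sin(angles),
                            np.zeros_like(angles)], axis=1)
        path = build_path(sphere, project_anchors(sphere, anchors))
        want = 100 * np.radians(120)
        assert arc_length(path) == pytest.approx(want, rel=0.01)

    def test_lambda_zero_is_identity(self, flat100):
        anchors = np.array([[-20.0, 0, 0], [0.0, 10.0, 0], [20.0, 0, 0]])
        p0 = build_path(flat100, anchors,
                        PathParams(smoothing_lambda=0.0))
        p1 = build_path(flat100, anchors,
                        PathParams(smoothing_lambda=0.0, smoothing_iterations=50))
        assert np.array_equal(p0.samples, p1.samples)

    def test_on_surface_samples_near_mesh(self, flat100):
        anchors = np.array([[-20.0, 0, 2.0], [0.0, 15.0, 3.0], [20.0, 0, 2.0]])
        params = PathParams()
        path = build_path(flat100, project_anchors(flat100, anchors), params)
        d = surface_distances(flat100, path.samples[path.on_surface_flags])
        assert d.max() <= params.projection_tolerance

    def test_deterministic(self, flat100):
        anchors = np.array([[-20.0, 0, 0], [0.0, 10.0, 0], [20.0, 0, 0]])
        a = build_path(flat100, anchors)
        b = build_path(flat100, anchors)
        assert np.array_equal(a.samples, b.samples)

    def test_gap_error_directs_to_wrap(self):
        left = synthetic.flat_grid(30, 30, 2, center=(-25, 0, 0))
        right = synthetic.flat_grid(30, 30, 2, center=(25, 0, 0))
        both = concatenate([left, right])
        anchors = np.array([[-25.0, 0, 0], [25.0, 0, 0]])
        with pytest.raises(PathProjectionError, match="wrap_path"):
            build_path(both, anchors)

    def test_anchor_order_in_path(self, flat100):
        anchors = np.array([[-20.0, 0, 0], [0.0, 10.0, 0], [20.0, 0, 0]])
        path = build_path(flat100, anchors)
        idx = path.source_anchor_indices
        assert np.all(np.diff(idx) > 0)
        assert idx[0] == 0 and idx[-1] == len(path.samples) - 1


class TestWrapPath:
    def test_fully_on_surface_unchanged(self, flat100):
        anchors = np.array([[-20.0, 0, 0], [20.0, 0, 0]])
        path = build_path(flat100, anchors)
        assert wrap_path(path, flat100) is path

    def test_two_grids_single_bridge(self):
        gap = 20.0
        left = synthetic.flat_grid(30, 30, 1.0, center=(-15 - gap / 2, 0, 0))
        right = synthetic.flat_grid(30, 30, 1.0, center=(15 + gap / 2, 0, 0))
        both = concatenate([left, right])
        anchors = np.array([[-20.0, 0, 0], [20.0, 0, 0]])
        params = PathParams(wrap_distance=2.0)
        path = build_path(both, anchors, params, gap_policy="flag")
        wrapped = wrap_path(path, both, params)
        off = ~wrapped.on_surface_flags
        assert off.any()
        # bridge spans the gap: off-surface run length ~ gap width
        bridge_pts = wrapped.samples[off]
        runs = np.nonzero(np.diff(off.astype(int)))[0]
        first_on_after = wrapped.samples[~off]
        lo = bridge_pts[:, 0].min()
        hi = bridge_pts[:, 0].max()
        assert hi - lo <= gap
        # bounding on-surface samples sit at the two rims
        i_off = np.nonzero(off)[0]
        a = wrapped.samples[i_off[0] - 1]
        b = wrapped.samples[i_off[-1] + 1]
        assert np.linalg.norm(b - a) == pytest.approx(gap, abs=1.0)

    def test_slot_bridge_length(self):
        # trench phantom: sheet with a deep slot; the path must bridge it
        slot_lo, slot_hi = -6.0, 6.0

        def h(gx, gy):
            return np.where((gx > slot_lo) & (gx < slot_hi), -50.0, 0.0)

        sheet = synthetic.flat_grid(80, 40, 1.0, height_fn=h)
        anchors = np.array([[-30.0, 0, 0], [30.0, 0, 0]])
        params = PathParams(wrap_distance=3.0, smoothing_iterations=0)
        path = build_path(sheet, anchors, params, gap_policy="flag")
        wrapped = wrap_path(path, sheet, params)
        off = ~wrapped.on_surface_flags
        assert off.any()
        i_off = np.nonzero(off)[0]
        a = wrapped.samples[i_off[0] - 1]
        b = wrapped.samples[i_off[-1] + 1]
        width = slot_hi - slot_lo
        # rim-to-rim chord matches the slot width (within a mesh cell + step)
        assert np.linalg.norm(b - a) == pytest.approx(width, abs=2.0)

    def test_endpoint_off_surface_errors(self):
        samples = np.stack([np.linspace(0, 10, 21), np.zeros(21),
                            np.zeros(21)], axis=1)
        pd = np.zeros(21)
        pd[0] = 99.0
        path = SurfacePath.from_samples(samples, projection_distances=pd)
        grid = synthetic.flat_grid(30, 30, 2)
        with pytest.raises(PathProjectionError, match="start and end"):
            wrap_path(path, grid)


class TestMatchLength:
    def test_exact_multiple_unchanged(self):
        n, adj = match_length(straight_path(50.0), 10.0)
        assert n == 5
        assert arc_length(adj) == pytest.approx(50.0, abs=1e-6)

    def test_crop_when_residual_short(self):
        n, adj = match_length(straight_path(54.0), 10.0)
        assert n == 5
        assert arc_length(adj) == pytest.approx(50.0, abs=1e-6)

    def test_lengthen_when_residual_long(self):
        n, adj = match_length(straight_path(56.0), 10.0)
        assert n == 6
        assert arc_length(adj) == pytest.approx(60.0, abs=1e-6)

    def test_tie_rounds_up(self):
        n, adj = match_length(straight_path(55.0), 10.0)
        assert n == 6
        assert arc_length(adj) == pytest.approx(60.0, abs=1e-6)

    def test_short_path_still_one_unit(self):
        n, adj = match_length(straight_path(3.0), 10.0)
        assert n == 1
        assert arc_length(adj) == pytest.approx(10.0, abs=1e-6)

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            match_length(straight_path(10.0), 0.0)

    def test_extension_follows_tangent(self):
        n, adj = match_length(straight_path(56.0), 10.0)
        # straight path along +x: extension continues along +x
        assert np.allclose(adj.samples[-1], [60.0, 0.0, 0.0], atol=1e-9)

    def test_extension_reprojects_to_mesh(self, flat100):
        anchors = np.array([[-20.0, 0, 0], [23.0, 0, 0]])  # S = 43
        path = build_path(flat100, anchors)
        n, adj = match_length(path, 12.0, mesh=flat100)
        assert n == 4
        assert arc_length(adj) == pytest.approx(48.0, abs=1e-6)
        assert adj.on_surface_flags.all()
        assert np.allclose(adj.samples[:, 2], 0, atol=1e-9)

    def test_exhaustive_oracle(self):
        L = 7.0
        for S in np.arange(0.1, 100.05, 0.1):
            S = round(float(S), 10)
            n, adj = match_length(straight_path(S, spacing=0.25), L)
            assert n == oracle_unit_count(arc_length(straight_path(S, 0.25)), L)
            assert arc_length(adj) == pytest.approx(n * L, abs=1e-6)


class TestArcLength:
    def test_two_sample_straight(self):
        p = SurfacePath.from_samples([[0, 0, 0], [10, 0, 0]])
        assert arc_length(p) == 10.0

    def test_square_polyline(self):
        sq = [[0, 0, 0], [5, 0, 0], [5, 5, 0], [0, 5, 0], [0, 0, 0]]
        assert arc_length(SurfacePath.from_samples(sq)) == pytest.approx(20.0)

    def test_equals_segment_sum(self, rng):
        pts = rng.normal(size=(50, 3)) * 20
        p = SurfacePath.from_samples(pts)
        want = np.linalg.norm(np.diff(pts, axis=0), axis=1).sum()
        assert arc_length(p) == pytest.approx(want, abs=1e-9)


class TestAnchorsIO:
    def test_json_roundtrip(self, tmp_path, rng):
        pts = rng.normal(size=(6, 3)) * 30
        p = tmp_path / "anchors.json"
        save_anchors_json(pts, p)
        back = load_anchors_json(p)
        assert np.allclose(back, pts, atol=1e-12)


@settings(max_examples=60, deadline=None)
@given(st.floats(0.2, 150.0), st.floats(1.0, 20.0))
def test_property_match_length_rule(S, L):
    path = straight_path(S, spacing=0.5)
    S_actual = arc_length(path)
    n, adj = match_length(path, L)
    assert n == oracle_unit_count(S_actual, L)
    assert arc_length(adj) == pytest.approx(n * L, abs=1e-6)
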