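import numpy as np
import pytest

from wormneurite import (
    MainBranchGeometry,
    MorphConfig,
    NeuronSpec,
    bend_density,
    detect_beads,
    detect_bends,
    local_thickness_residual,
    make_neuron,
    node_angles,
    spline_curvature,
    threshold_sweep,
)
from wormneurite.synthetic import match_events

from conftest import corner_polyline, random_rotation


def geometry(points, radii=None):
    points = np.asarray(points, float)
    radii = (
        np.full(len(points), 0.5) if radii is None else np.asarray(radii)
    )
    return MainBranchGeometry(
        points=points, radii=radii, node_ids=np.arange(len(points))
    )


def straight_line(length=20.0, spacing=0.2):
    n = int(length / spacing) + 1
    pts = np.zeros((n, 3))
    pts[:, 0] = np.arange(n) * spacing
    return pts


def nms_oracle(values, arclengths, nms, sharpest_first=True):
    """Exhaustive greedy selection, recomputed from scratch at every step."""
    remaining = list(range(len(values)))
    selected = []
    while remaining:
        best = min(
            remaining,
            key=lambda i: (values[i], i) if sharpest_first else (-values[i], i),
        )
        selected.append(best)
        s0 = arclengths[best]
        remaining = [i for i in remaining if abs(arclengths[i] - s0) > nms]
    return sorted(selected, key=lambda i: arclengths[i])


class TestNodeAngles:
    def test_straight_polyline_all_180(self):
        a = node_angles(straight_line(), window=2.0)
        defined = a[~np.isnan(a)]
        assert len(defined) > 50
        assert np.allclose(defined, 180.0, atol=1e-6)

    @pytest.mark.parametrize("angle", [60.0, 90.0, 120.0, 150.0])
    def test_corner_apex_angle(self, angle):
        pts = corner_polyline(angle)
        a = node_angles(pts, window=2.0)
        apex = len(pts) // 2
        assert a[apex] == pytest.approx(angle, abs=1.0)

    def test_rotation_invariance(self, rng):
        pts = corner_polyline(120.0)
        rot = random_rotation(rng)
        a = node_angles(pts, window=2.0)
        b = node_angles(pts @ rot.T, window=2.0)
        assert np.allclose(a, b, atol=1e-6, equal_nan=True)

    def test_boundary_nodes_undefined(self):
        a = node_angles(straight_line(length=10.0), window=2.0)
        assert np.isnan(a[0]) and np.isnan(a[-1])
        assert np.isnan(a[2])  # within 2 um of the start


class TestDetectBends:
    def test_straight_line_no_bends(self):
        assert detect_bends(straight_line()) == []

    def test_threshold_logic_on_single_corner(self):
        pts = corner_polyline(150.0)
        assert len(detect_bends(pts, MorphConfig(bend_threshold=155.0))) == 1
        assert len(detect_bends(pts, MorphConfig(bend_threshold=145.0))) == 0

    def _two_corners(self, separation):
        """Two 120-degree corners a given arclength apart (3D zig-zag)."""
        spec = NeuronSpec(
            main_length=20.0 + separation,
            bend_list=((10.0, 120.0), (10.0 + separation, 120.0)),
            rng_seed=1,
        )
        tree, _ = make_neuron(spec)
        pts = np.array(
            [tree.nodes[i].position for i in sorted(tree.nodes)]
        )
        return pts

    def test_nms_suppresses_close_pair(self):
        assert len(detect_bends(self._two_corners(3.0))) == 1

    def test_distant_pair_both_detected(self):
        assert len(detect_bends(self._two_corners(6.0))) == 2

    def test_events_sorted_and_separated(self):
        tree, _ = make_neuron(
            NeuronSpec(
                main_length=100.0,
                bend_list=tuple((15.0 + 10 * k, 110.0) for k in range(8)),
                rng_seed=2,
            )
        )
        pts = np.array([tree.nodes[i].position for i in sorted(tree.nodes)])
        ev = detect_bends(pts)
        s = [e.arclength for e in ev]
        assert s == sorted(s)
        assert np.min(np.diff(s)) > 4.0

    def test_sequential_selection_matches_exhaustive_greedy(self):
        cfg = MorphConfig()
        for seed in range(10):
            tree, _ = make_neuron(
                NeuronSpec(
                    main_length=60.0,
                    bend_list=tuple(
                        (8.0 + 6.5 * k, float(100 + 7 * k)) for k in range(7)
                    ),
                    coordinate_noise_sd=0.05,
                    rng_seed=seed,
                )
            )
            pts = np.array(
                [tree.nodes[i].position for i in sorted(tree.nodes)]
            )
            geom = geometry(pts)
            angles = node_angles(geom, cfg.bend_window)
            s = geom.arclengths
            cand = np.nonzero(angles < cfg.bend_threshold)[0]
            oracle = nms_oracle(
                angles[cand], s[cand], cfg.bend_nms, sharpest_first=True
            )
            expected = sorted(s[cand][oracle])
            got = [e.arclength for e in detect_bends(geom, cfg)]
            assert np.allclose(got, expected)

    def test_reversal_invariance(self):
        pts = self._two_corners(8.0)
        fwd = detect_bends(pts)
        rev = detect_bends(pts[::-1])
        L = geometry(pts).length
        assert len(fwd) == len(rev) == 2
        assert np.allclose(
            sorted(e.arclength for e in fwd),
            sorted(L - e.arclength for e in rev),
            atol=1e-9,
        )


class TestBendDensity:
    def test_count_over_length(self):
        assert bend_density([1] * 5, 100.0) == pytest.approx(0.05)
        assert bend_density([], 100.0) == 0.0

    def test_zero_length_errors(self):
        with pytest.raises(ValueError):
            bend_density([], 0.0)

    def test_counts_invariant_under_scaling_with_scaled_windows(self):
        pts = corner_polyline(120.0, arm_length=8.0)
        cfg = MorphConfig()
        scaled_cfg = MorphConfig(
            bend_window=2 * cfg.bend_window, bend_nms=2 * cfg.bend_nms
        )
        a = detect_bends(pts, cfg)
        b = detect_bends(pts * 2.0, scaled_cfg)
        assert len(a) == len(b) == 1
        La, Lb = geometry(pts).length, geometry(pts * 2.0).length
        assert bend_density(a, La) == pytest.approx(2 * bend_density(b, Lb))


class TestThresholdSweep:
    def test_monotone_in_threshold(self):
        tree, _ = make_neuron(
            NeuronSpec(
                main_length=100.0,
                bend_list=tuple(
                    (10.0 + 11 * k, float(115 + 10 * k)) for k in range(8)
                ),
                coordinate_noise_sd=0.05,
                rng_seed=3,
            )
        )
        pts = np.array([tree.nodes[i].position for i in sorted(tree.nodes)])
        dens = threshold_sweep(pts, thresholds=np.arange(135.0, 166.0, 5.0))
        vals = [dens[t] for t in sorted(dens)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_corner_angle_brackets_detection(self):
        pts = corner_polyline(150.0, arm_length=6.0)
        dens = threshold_sweep(
            pts, thresholds=(135.0, 145.0, 149.0, 151.0, 155.0, 165.0)
        )
        assert dens[135.0] == 0.0 and dens[149.0] == 0.0
        assert dens[151.0] > 0 and dens[165.0] > 0

    def test_straight_branch_zero_everywhere(self):
        dens = threshold_sweep(straight_line())
        assert all(v == 0.0 for v in dens.values())


class TestLocalThickness:
    def test_constant_radius_zero_excess(self):
        g = geometry(straight_line(), radii=None)
        assert np.allclose(local_thickness_residual(g), 0.0, atol=1e-12)

    def test_single_bump_matches_windowed_mean_oracle(self):
        pts = straight_line(length=30.0)
        radii = np.full(len(pts), 0.5)
        radii[75] = 1.5
        g = geometry(pts, radii)
        excess = local_thickness_residual(g, window=8.0)
        s = g.arclengths
        # brute-force windowed mean
        for i in (70, 75, 80):
            m = np.abs(s - s[i]) <= 4.0
            assert excess[i] == pytest.approx(radii[i] - radii[m].mean())
        assert excess[75] == pytest.approx(1.0, abs=0.1)

    def test_linear_taper_cancels_in_interior(self):
        pts = straight_line(length=40.0)
        radii = 0.3 + 0.01 * geometry(pts).arclengths
        excess = local_thickness_residual(geometry(pts, radii), window=8.0)
        interior = excess[40:-40]
        # symmetric window cancels the trend up to one node falling on the
        # discrete window edge: slope * spacing = 2e-3
        assert np.max(np.abs(interior)) <= 0.01 * 0.2 + 1e-12


class TestDetectBeads:
    def test_constant_radius_no_beads(self):
        assert detect_beads(geometry(straight_line())) == []

    def test_planted_bumps_recovered_over_seeds(self):
        for seed in range(10):
            tree, gt = make_neuron(
                NeuronSpec(
                    main_length=100.0,
                    bead_list=(
                        (25.0, 0.5, 0.5),
                        (45.0, 0.5, 0.5),
                        (65.0, 0.5, 0.5),
                    ),
                    radius_noise_sd=0.03,
                    rng_seed=seed,
                )
            )
            pts = np.array(
                [tree.nodes[i].position for i in sorted(tree.nodes)]
            )
            radii = np.array(
                [tree.nodes[i].radius for i in sorted(tree.nodes)]
            )
            ev = detect_beads(geometry(pts, radii))
            matched, missed, _ = match_events(
                gt.beads, [e.arclength for e in ev], tol=1.0
            )
            assert missed == 0

    def test_close_pair_suppressed_to_one(self):
        tree, _ = make_neuron(
            NeuronSpec(
                main_length=60.0,
                bead_list=((30.0, 0.6, 0.4), (32.0, 0.5, 0.4)),
                rng_seed=1,
            )
        )
        pts = np.array([tree.nodes[i].position for i in sorted(tree.nodes)])
        radii = np.array([tree.nodes[i].radius for i in sorted(tree.nodes)])
        ev = detect_beads(geometry(pts, radii))
        assert len(ev) == 1

    def test_too_few_nodes_errors(self):
        with pytest.raises(ValueError):
            detect_beads(geometry([[0, 0, 0], [1, 0, 0]]))


class TestSplineCurvature:
    def test_straight_line_zero_curvature(self):
        _, k = spline_curvature(straight_line(), smoothing=0.0)
        assert np.max(k) < 1e-6

    def test_circle_curvature_matches_radius(self):
        th = np.linspace(0, 1.5 * np.pi, 400)
        pts = np.c_[10 * np.cos(th), 10 * np.sin(th), np.zeros_like(th)]
        s, k = spline_curvature(pts, smoothing=0.0)
        interior = k[20:-20]
        assert np.median(interior) == pytest.approx(0.1, rel=0.05)

    def test_smoothing_never_raises_curvature_max(self):
        tree, _ = make_neuron(
            NeuronSpec(
                main_length=50.0,
                bend_list=((25.0, 120.0),),
                coordinate_noise_sd=0.05,
                rng_seed=6,
            )
        )
        pts = np.array([tree.nodes[i].position for i in sorted(tree.nodes)])
        maxima = []
        for s in (0.0, 0.5, 2.0, 10.0):
            _, k = spline_curvature(pts, smoothing=s)
            maxima.append(np.max(k))
        assert all(b <= a * 1.001 for a, b in zip(maxima, maxima[1:]))
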