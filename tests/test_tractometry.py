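"""Centerlines, node projection, profile alignment and tract volume."""

import numpy as np
import pytest

from microtract.synthetic_cohort import generate_bundle
from microtract.tractometry import (
    Centerline,
    align_profiles,
    centerline_qc_ratio,
    compute_centerline,
    orient_and_resample,
    project_to_nodes,
    read_streamlines,
    tract_volume,
    write_streamlines,
)


class TestOrientAndResample:
    def test_constant_spacing_per_streamline(self):
        # chord spacing equals arc spacing exactly on straight streamlines
        ph = generate_bundle("straight", n_streamlines=10, radius=0.0, seed=1)
        mat = orient_and_resample(ph.streamlines, n_points=50)
        for r in mat:
            steps = np.linalg.norm(np.diff(r, axis=0), axis=1)
            assert steps.max() - steps.min() < 1e-9 * steps.mean()
        # on a constant-curvature arc the chords stay equal too
        pha = generate_bundle("arc", n_streamlines=5, radius=0.0, seed=1)
        mata = orient_and_resample(pha.streamlines, n_points=50)
        steps = np.linalg.norm(np.diff(mata[0], axis=0), axis=1)
        assert (steps.max() - steps.min()) / steps.mean() < 1e-3

    def test_reversed_streamlines_get_flipped(self):
        line = np.stack([np.linspace(0, 10, 11), np.zeros(11), np.zeros(11)], axis=1)
        mat = orient_and_resample([line, line[::-1], line], n_points=11)
        starts = mat[:, 0, :]
        assert np.allclose(starts, starts[0], atol=1e-9)

    def test_zero_length_streamline_skipped_with_warning(self):
        line = np.stack([np.linspace(0, 10, 5), np.zeros(5), np.zeros(5)], axis=1)
        degenerate = np.zeros((3, 3))
        with pytest.warns(UserWarning, match="zero-length"):
            mat = orient_and_resample([line, degenerate], n_points=5)
        assert mat.shape[0] == 1

    def test_mean_curve_approaches_generating_curve(self):
        # CLT: pointwise mean of N jittered copies converges to the centerline
        ph = generate_bundle("straight", n_streamlines=400, length=50.0,
                             radius=2.0, seed=3)
        mat = orient_and_resample(ph.streamlines, n_points=30)
        mean_curve = mat.mean(axis=0)
        sd = 1.0  # radius/2
        assert np.max(np.abs(mean_curve[:, 1:])) < 4 * sd / np.sqrt(400) + 0.15


class TestCenterline:
    def test_straight_bundle_recovery(self):
        ph = generate_bundle("straight", n_streamlines=300, length=80.0,
                             radius=2.0, seed=1, voxel_size=2.0)
        cl = compute_centerline(ph.streamlines)
        # collinear with the generating x-axis line: off-axis deviation small
        assert np.max(np.abs(cl.nodes[:, 1:])) < 0.1 * ph.voxel_size

    def test_arc_recovery_within_jitter_sd(self):
        length, radius = 80.0, 1.5
        ph = generate_bundle("arc", n_streamlines=300, length=length,
                             radius=radius, seed=2)
        cl = compute_centerline(ph.streamlines)
        R = length / (np.pi / 2)
        dist = np.abs(np.sqrt(cl.nodes[:, 0] ** 2 + (R - cl.nodes[:, 1]) ** 2) - R)
        assert np.max(dist) < radius / 2.0  # jitter SD

    def test_twenty_equidistant_nodes(self):
        # nodes are placed at equal arc-length steps; on constant-curvature
        # centerlines (straight, circular arc) chord spacing is then equal too
        for geometry, tol in (("straight", 1e-6), ("arc", 5e-4)):
            ph = generate_bundle(geometry, n_streamlines=50, seed=5)
            cl = compute_centerline(ph.streamlines)
            spacing = np.linalg.norm(np.diff(cl.nodes, axis=0), axis=1)
            assert cl.nodes.shape == (20, 3)
            assert (spacing.max() - spacing.min()) / spacing.mean() < tol

    def test_rigid_motion_invariance(self):
        from scipy.spatial.transform import Rotation

        ph = generate_bundle("arc", n_streamlines=80, seed=7)
        R = Rotation.from_rotvec([0.4, 0.3, -0.2]).as_matrix()
        t = np.array([10.0, -5.0, 3.0])
        moved = [s @ R.T + t for s in ph.streamlines]
        a = compute_centerline(ph.streamlines)
        b = compute_centerline(moved)
        assert a.arc_length == pytest.approx(b.arc_length, rel=1e-6)
        assert np.allclose(a.nodes @ R.T + t, b.nodes, atol=1e-6)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            compute_centerline([np.zeros((2, 3)) + 0.0][:0] or
                               [np.array([[1.0, 1, 1], [1, 1, 1], [1, 1, 1]])])

    def test_qc_ratio_flags_folded_centerline(self):
        straight = generate_bundle("straight", n_streamlines=20, seed=0)
        helix = generate_bundle("helix", n_streamlines=20, seed=0)
        r_s = centerline_qc_ratio(compute_centerline(straight.streamlines))
        r_h = centerline_qc_ratio(compute_centerline(helix.streamlines))
        assert r_s < 1.05 < r_h


class TestNodeProjection:
    @pytest.fixture()
    def straight_centerline(self):
        ph = generate_bundle("straight", n_streamlines=100, length=40.0,
                             radius=1.0, seed=3)
        return compute_centerline(ph.streamlines)

    def test_constant_field(self, straight_centerline, rng):
        coords = np.column_stack(
            [rng.uniform(0, 40, 200), rng.uniform(-2, 2, 200), rng.uniform(-2, 2, 200)]
        )
        vals, counts = project_to_nodes(np.full(200, 3.3), coords, straight_centerline)
        filled = ~np.isnan(vals)
        assert np.allclose(vals[filled], 3.3)
        assert counts.sum() == 200

    def test_linear_gradient_gives_monotone_profile(self, straight_centerline, rng):
        x = rng.uniform(0, 40, 500)
        coords = np.column_stack([x, rng.uniform(-1, 1, 500), rng.uniform(-1, 1, 500)])
        vals, _ = project_to_nodes(0.5 + 0.01 * x, coords, straight_centerline)
        filled = vals[~np.isnan(vals)]
        assert np.all(np.diff(filled) > 0)

    def test_equidistant_voxel_goes_to_lower_index_node(self):
        nodes = np.stack([np.arange(20.0), np.zeros(20), np.zeros(20)], axis=1)
        cl = Centerline(points=nodes, arc_length=19.0, nodes=nodes)
        vals, counts = project_to_nodes(
            np.array([7.0]), np.array([[0.5, 0.0, 0.0]]), cl
        )
        assert counts[0] == 1 and counts[1] == 0

    def test_empty_voxel_set_rejected(self, straight_centerline):
        with pytest.raises(ValueError):
            project_to_nodes(np.array([]), np.zeros((0, 3)), straight_centerline)


class TestAlignProfiles:
    def test_identical_profiles_identity_map(self):
        x = np.arange(20.0)
        prof = np.sin(x / 3.0)
        aligned, params = align_profiles(np.tile(prof, (4, 1)))
        assert np.allclose(aligned, prof, atol=1e-6)
        assert np.allclose(params[:, 0], 0.0, atol=0.02)
        assert np.allclose(params[:, 1], 1.0, atol=0.01)

    def test_one_node_shift_recovered(self):
        x = np.arange(20.0)
        base = np.exp(-0.5 * ((x - 10) / 3.0) ** 2)
        shifted = np.exp(-0.5 * ((x - 11) / 3.0) ** 2)
        _, params = align_profiles(np.stack([base, shifted]))
        relative_shift = params[1, 0] - params[0, 0]
        assert relative_shift == pytest.approx(1.0, abs=0.15)

    def test_alignment_preserves_profile_mean(self):
        x = np.arange(20.0)
        profs = np.stack([np.sin(x / 4 + p) for p in (0.0, 0.15, -0.1)])
        aligned, _ = align_profiles(profs)
        assert np.allclose(aligned.mean(axis=1), profs.mean(axis=1), atol=0.08)

    def test_degenerate_profile_flagged(self):
        x = np.arange(20.0)
        profs = np.stack([np.sin(x / 4), np.full(20, 2.0)])
        aligned, params = align_profiles(profs)
        assert params[1, 2] == 1.0
        assert np.allclose(aligned[1], profs[1])


class TestTractVolume:
    def test_axis_aligned_line_with_endpoints_at_voxel_centers(self):
        line = np.stack(
            [np.linspace(0.5, 10.5, 101), np.full(101, 0.5), np.full(101, 0.5)],
            axis=1,
        )
        count, _ = tract_volume([line], voxel_size=1.0, brain_volume=1e6)
        assert count == 11

    def test_duplicated_streamlines_do_not_change_count(self):
        ph = generate_bundle("straight", n_streamlines=30, seed=2)
        c1, _ = tract_volume(ph.streamlines, 2.0, 1e6)
        c2, _ = tract_volume(ph.streamlines * 2, 2.0, 1e6)
        assert c1 == c2

    def test_volume_fraction_halves_with_double_brain(self):
        ph = generate_bundle("straight", n_streamlines=30, seed=2)
        _, f1 = tract_volume(ph.streamlines, 2.0, 1e6)
        _, f2 = tract_volume(ph.streamlines, 2.0, 2e6)
        assert f2 == pytest.approx(f1 / 2.0)

    def test_cylinder_phantom_volume_within_twenty_percent(self):
        ph = generate_bundle(
            "straight", n_streamlines=4000, length=40.0, radius=5.0, seed=3,
            voxel_size=0.5, jitter="disk", n_points=100,
        )
        count, _ = tract_volume(ph.streamlines, 0.5, 1e6)
        est = count * 0.5**3
        analytic = np.pi * 5.0**2 * 40.0
        assert abs(est - analytic) / analytic < 0.20


class TestStreamlineIO:
    @pytest.mark.parametrize("ext", ["tck", "trk"])
    def test_roundtrip(self, tmp_path, ext):
        ph = generate_bundle("arc", n_streamlines=5, seed=1)
        path = tmp_path / f"bundle.{ext}"
        write_streamlines(ph.streamlines, path)
        back = read_streamlines(path)
        assert len(back) == 5
        for a, b in zip(ph.streamlines, back):
            assert np.allclose(a, b, atol=1e-4)
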