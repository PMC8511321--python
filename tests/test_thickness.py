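import numpy as np
import pytest

import petromap as pm
from petromap.thickness import (
    CLTParams,
    GridSpec,
    compute_clt,
    compute_ddvs,
    project_grid,
    project_grid_local,
    samples_to_map,
)

from .oracles import brute_clt, brute_nearest


class TestProjectGrid:
    def test_flat_slab_nine_samples(self, slab_mesh):
        grid = GridSpec(spacing=1.0, extent=(0, 2, 0, 2))
        samples = project_grid_local(slab_mesh, grid)
        assert len(samples) == 9
        assert all(s.valid for s in samples)
        for s in samples:
            assert s.position[2] == pytest.approx(0.0, abs=1e-12)
            assert s.inward_normal == pytest.approx([0, 0, -1.0])
            assert s.polar is not None

    def test_rays_outside_mesh_are_invalid(self, slab_mesh):
        grid = GridSpec(spacing=1.0, extent=(0, 10, 0, 10))
        samples = project_grid_local(slab_mesh, grid)
        valid = [s for s in samples if s.valid]
        # slab only covers [-1, 3]^2
        assert 0 < len(valid) < len(samples)
        assert all(s.position[0] <= 3.0 + 1e-9 for s in valid)

    def test_mesh_outside_extent_is_error(self, slab_mesh):
        grid = GridSpec(spacing=1.0, extent=(50, 60, 50, 60))
        with pytest.raises(ValueError, match="outside grid extent"):
            project_grid_local(slab_mesh, grid)

    def test_dome_apex_height(self, flat_phantom):
        _, (bone, _, truth) = flat_phantom
        grid = GridSpec(spacing=1.0, extent=(-1, 1, -1, 1))
        samples = project_grid_local(bone, grid)
        apex = next(s for s in samples if s.grid_index == (1, 1))
        assert apex.position[2] == pytest.approx(truth.dome_amplitude, abs=0.01)

    def test_positions_match_analytic_heightfield(self, flat_analysis):
        _, samples, truth = flat_analysis
        valid = [s for s in samples if s.valid]
        pos = np.array([s.position for s in valid])
        z_true = np.asarray(truth.surface_height(pos[:, 0], pos[:, 1]))
        # mesh chord tolerance on the gentle dome
        assert np.abs(pos[:, 2] - z_true).max() < 0.01

    def test_project_with_identity_frame_matches_local(self, flat_phantom):
        _, (bone, _, _) = flat_phantom
        grid = GridSpec(spacing=5.0, extent=(-10, 10, -10, 10))
        a = project_grid(bone, pm.AnatomyFrame(), grid)
        b = project_grid_local(bone, grid)
        for sa, sb in zip(a, b):
            assert sa.valid == sb.valid
            if sa.valid:
                assert sa.position == pytest.approx(sb.position, abs=1e-12)


class TestComputeCLT:
    def test_constant_phantom_recovers_thickness(self, flat_analysis):
        _, samples, _ = flat_analysis
        clt = np.array([s.clt for s in samples if s.valid])
        assert np.all(np.abs(clt - 2.0) <= 0.05)

    def test_air_cell_thins_the_layer(self):
        cfg = pm.PhantomConfig(
            grid_extent=20.0, mesh_resolution=1.0,
            base_thickness_field=pm.ScalarField2D(a=3.0),
            dura_depth_field=pm.ScalarField2D(a=6.0),
            explicit_cells=[(10.0, 10.0, 1.5, 1.0)],
        )
        bone, _, truth = pm.generate_phantom(cfg)
        grid = GridSpec(spacing=1.0, extent=(8, 12, 8, 12))
        samples = project_grid_local(bone, grid)
        compute_clt(samples, bone)
        above = next(s for s in samples if s.grid_index == (2, 2))  # (10, 10)
        assert above.clt == pytest.approx(0.5, abs=0.05)
        far_grid = GridSpec(spacing=1.0, extent=(-12, -8, -12, -8))
        far = project_grid_local(bone, far_grid)
        compute_clt(far, bone)
        assert np.array([s.clt for s in far]) == pytest.approx(np.full(25, 3.0), abs=0.05)

    def test_matches_bruteforce_oracle(self, tiny_phantom):
        _, (bone, _, _) = tiny_phantom
        assert len(bone.faces) <= 200
        grid = GridSpec(spacing=0.7, extent=(-2, 2, -2, 2))
        samples = project_grid_local(bone, grid)[:20]
        params = CLTParams()
        compute_clt(samples, bone, params)
        for s in samples:
            if not s.valid:
                continue
            probe = s.position + params.delta * s.inward_normal
            d = brute_clt(probe, s.position, s.inward_normal, params.delta,
                          bone.triangles)
            assert s.clt == pytest.approx(d + params.delta, abs=1e-9)

    def test_ray_mode_equals_nearest_on_slab_geometry(self, flat_phantom):
        _, (bone, _, _) = flat_phantom
        grid = GridSpec(spacing=2.0, extent=(-6, 6, -6, 6))
        a = project_grid_local(bone, grid)
        b = project_grid_local(bone, grid)
        compute_clt(a, bone, CLTParams(mode="nearest"))
        compute_clt(b, bone, CLTParams(mode="ray"))
        for sa, sb in zip(a, b):
            if sa.valid:
                assert sa.clt == pytest.approx(sb.clt, abs=0.02)

    def test_censoring_at_max_thickness(self, flat_phantom):
        _, (bone, _, _) = flat_phantom
        grid = GridSpec(spacing=2.0, extent=(-4, 4, -4, 4))
        samples = project_grid_local(bone, grid)
        compute_clt(samples, bone, CLTParams(max_thickness=1.0))
        for s in samples:
            if s.valid:
                assert s.clt == 1.0
                assert s.clt_censored

    def test_no_opposite_surface_gives_missing(self, slab_mesh):
        grid = GridSpec(spacing=1.0, extent=(0, 2, 0, 2))
        samples = project_grid_local(slab_mesh, grid)
        with pytest.warns(UserWarning, match="watertight"):
            compute_clt(samples, slab_mesh)
        assert all(np.isnan(s.clt) for s in samples if s.valid)

    def test_rigid_invariance(self, tiny_phantom):
        from scipy.spatial.transform import Rotation

        _, (bone, _, _) = tiny_phantom
        grid = GridSpec(spacing=1.0, extent=(-2, 2, -2, 2))
        base = project_grid_local(bone, grid)
        compute_clt(base, bone)

        R = Rotation.from_euler("xyz", [20, -35, 60], degrees=True).as_matrix()
        t = np.array([12.0, -7.0, 30.0])
        moved = bone.transformed(R, t)
        frame = pm.AnatomyFrame(origin=tuple(t), z_axis=tuple(R[:, 2]),
                                x_axis=tuple(R[:, 0]))
        samples = project_grid(moved, frame, grid)
        compute_clt(samples, moved.transformed(frame.rotation.T, -frame.rotation.T @ t))
        for sa, sb in zip(base, samples):
            if sa.valid:
                assert sb.valid
                assert sb.clt == pytest.approx(sa.clt, abs=1e-6)

    def test_clt_not_above_ddvs_on_clean_phantom(self, flat_analysis):
        _, samples, _ = flat_analysis
        for s in samples:
            if s.valid:
                assert s.clt <= s.ddvs + 1e-6


class TestComputeDDVS:
    def test_constant_dura_depth(self, flat_analysis):
        _, samples, _ = flat_analysis
        ddvs = np.array([s.ddvs for s in samples if s.valid])
        assert np.all(np.abs(ddvs - 5.0) <= 0.05)

    def test_sinus_ridge_reduces_distance(self):
        cfg = pm.PhantomConfig(
            grid_extent=25.0, mesh_resolution=1.0, dome_amplitude=0.0,
            base_thickness_field=pm.ScalarField2D(a=2.0),
            dura_depth_field=pm.ScalarField2D(a=8.0),
            sinus_tube=pm.SinusTube(p0=(0.0, -15.0), p1=(0.0, 15.0), depth=6.0, radius=2.0),
        )
        bone, dura, _ = pm.generate_phantom(cfg)
        grid = GridSpec(spacing=1.0, extent=(-1, 1, -1, 1))
        samples = project_grid_local(bone, grid)
        compute_ddvs(samples, dura)
        crest = next(s for s in samples if s.grid_index == (1, 1))
        assert crest.ddvs == pytest.approx(4.0, abs=0.1)

    def test_matches_bruteforce_oracle(self, tiny_phantom):
        _, (bone, dura, _) = tiny_phantom
        grid = GridSpec(spacing=0.7, extent=(-2, 2, -2, 2))
        samples = project_grid_local(bone, grid)[:20]
        compute_ddvs(samples, dura)
        for s in samples:
            if s.valid:
                d, _ = brute_nearest(s.position, dura.triangles)
                assert s.ddvs == pytest.approx(d, abs=1e-9)

    def test_empty_dura_is_error(self, flat_phantom):
        _, (bone, dura, _) = flat_phantom
        grid = GridSpec(spacing=5.0, extent=(-5, 5, -5, 5))
        samples = project_grid_local(bone, grid)
        bad = pm.TriangleMesh(dura.vertices, dura.faces)
        bad.faces = bad.faces[:0]
        with pytest.raises(Exception, match="empty mesh"):
            compute_ddvs(samples, bad)


class TestThicknessMap:
    def test_nine_slab_samples_to_3x3_map(self, slab_mesh):
        grid = GridSpec(spacing=1.0, extent=(0, 2, 0, 2))
        samples = project_grid_local(slab_mesh, grid)
        for s in samples:
            s.clt = 2.0
        m = samples_to_map(samples, "CLT", grid)
        assert m.grid.shape == (3, 3)
        assert m.grid == pytest.approx(np.full((3, 3), 2.0))

    def test_invalid_sample_leaves_missing_cell(self, slab_mesh):
        grid = GridSpec(spacing=1.0, extent=(0, 2, 0, 2))
        samples = project_grid_local(slab_mesh, grid)
        for s in samples:
            s.clt = 2.0
        samples[4].valid = False
        m = samples_to_map(samples, "CLT", grid)
        assert int(np.isnan(m.grid).sum()) == 1

    def test_csv_round_trip_lossless(self, tmp_path, flat_analysis):
        grid, samples, _ = flat_analysis
        m = samples_to_map(samples, "DDVS", grid, subject_id="phantom-1")
        m.save(tmp_path / "map")
        back = pm.ThicknessMap.load(tmp_path / "map")
        assert back.metric == "DDVS"
        assert back.subject_id == "phantom-1"
        assert np.allclose(back.grid, m.grid, atol=1e-7, equal_nan=True)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            pm.ThicknessMap("CLT", np.zeros((3, 4)), 1.0, (0, 2, 0, 2))

    def test_png_render(self, tmp_path, flat_analysis):
        grid, samples, _ = flat_analysis
        m = samples_to_map(samples, "CLT", grid)
        m.render_png(tmp_path / "map.png")
        assert (tmp_path / "map.png").stat().st_size > 0


class TestResolutionConvergence:
    def test_finer_mesh_reduces_median_clt_error(self):
        errors = {}
        for res in (2.5, 1.25):
            cfg = pm.PhantomConfig(
                grid_extent=25.0, mesh_resolution=res, seed=11,
                base_thickness_field=pm.ScalarField2D(kind="sinusoid", a=2.5, b=1.0),
                dura_depth_field=pm.ScalarField2D(a=6.0),
            )
            bone, _, truth = pm.generate_phantom(cfg)
            grid = GridSpec(spacing=1.5, extent=(-15, 15, -15, 15))
            samples = project_grid_local(bone, grid)
            compute_clt(samples, bone)
            pos = np.array([s.position[:2] for s in samples if s.valid])
            clt = np.array([s.clt for s in samples if s.valid])
            truth_clt, _, _ = pm.sample_truth(truth, pos)
            errors[res] = float(np.median(np.abs(clt - truth_clt)))
        assert errors[1.25] < errors[2.5]
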