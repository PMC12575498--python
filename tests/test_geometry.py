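"""Reference profiles, scan meshes and (T, R) shape summaries."""

import numpy as np
import pytest
import trimesh

from gelshell import (
    AxisymProfile,
    IMPLANT_SIZES,
    InfeasibleGeometryError,
    ScanMesh,
    build_reference_profile,
    generate_synthetic_scan,
    summarize_shape,
)


def voxel_volume(profile, h=0.25):
    """Independent volume oracle: voxel counting of the solid of revolution.

    Counts voxel centers inside the solid whose boundary radius at height z
    is the meridian polyline's outer radius r_max(z).
    """
    r, z = profile.r, profile.z
    z_top, r_max = z.max(), r.max()
    # outer radius per z by scanning the side branch (apex to base edge)
    i_edge = int(np.argmax(r))
    zs, rs = z[: i_edge + 1][::-1], r[: i_edge + 1][::-1]  # increasing z
    z_centers = np.arange(h / 2, z_top, h)
    r_of_z = np.interp(z_centers, zs, rs)
    xy = np.arange(h / 2, r_max + h, h)  # no voxel centers on the axes
    X, Y = np.meshgrid(xy, xy)
    rho2 = np.sort((X**2 + Y**2).ravel())  # one quadrant
    counts = np.searchsorted(rho2, r_of_z**2, side="right")
    return float(np.sum(4 * counts) * h**3)


class TestBuildReferenceProfile:
    @pytest.mark.parametrize("label", sorted(IMPLANT_SIZES))
    def test_printed_sizes(self, label):
        radius, height, volume = IMPLANT_SIZES[label]
        prof = build_reference_profile(radius, height, volume, 64, implant_id=label)
        assert prof.enclosed_volume() == pytest.approx(volume, rel=1e-3)
        s = summarize_shape(prof)
        assert s.T == pytest.approx(height, abs=1e-12)
        assert s.R == pytest.approx(radius, abs=1e-12)

    def test_hemisphere_request_gives_hemisphere(self):
        vol = (2.0 / 3.0) * np.pi * 10.0**3
        prof = build_reference_profile(10.0, 10.0, vol, 64)
        assert prof.enclosed_volume() == pytest.approx(2094.4, abs=0.1)
        side = prof.z > 1e-9
        dev = np.abs(np.hypot(prof.r[side], prof.z[side]) - 10.0)
        assert dev.max() < 0.01

    def test_infeasible_volume_names_achievable_range(self):
        with pytest.raises(InfeasibleGeometryError, match="achievable range"):
            build_reference_profile(10.0, 10.0, 10_000.0, 64)  # > cylinder volume
        with pytest.raises(InfeasibleGeometryError):
            build_reference_profile(10.0, 10.0, 1.0, 64)

    def test_preconditions(self):
        with pytest.raises(ValueError):
            build_reference_profile(10.0, 10.0, 2000.0, n_samples=8)
        with pytest.raises(ValueError):
            build_reference_profile(-1.0, 10.0, 2000.0)

    def test_volume_matches_voxel_oracle(self, rng):
        shapes = [(10.0, 10.0, (2 / 3) * np.pi * 1e3)]
        for _ in range(5):
            radius = rng.uniform(8.0, 14.0)
            height = rng.uniform(6.0, 14.0)
            fill = rng.uniform(0.45, 0.8)
            shapes.append((radius, height, fill * np.pi * radius**2 * height))
        for radius, height, volume in shapes:
            prof = build_reference_profile(radius, height, volume, 64)
            vox = voxel_volume(prof)
            assert vox == pytest.approx(prof.enclosed_volume(), rel=5e-3)

    def test_profile_csv_roundtrip(self, tmp_path):
        prof = build_reference_profile(10.0, 8.0, 1500.0, 32)
        path = tmp_path / "profile.csv"
        prof.to_csv(path)
        back = AxisymProfile.from_csv(path)
        np.testing.assert_allclose(back.r, prof.r, atol=1e-12)
        np.testing.assert_allclose(back.z, prof.z, atol=1e-12)
        assert back.nominal_volume == pytest.approx(prof.enclosed_volume(), rel=1e-9)


class TestAxisymProfileInvariants:
    def test_meridian_must_close_on_axis(self):
        with pytest.raises(ValueError, match="axis"):
            AxisymProfile(
                np.array([1.0, 5.0, 2.0, 0.0]),
                np.array([3.0, 2.0, 1.0, 0.0]),
                100.0,
            )

    def test_negative_radius_rejected(self):
        with pytest.raises(ValueError):
            AxisymProfile(
                np.array([0.0, -2.0, 1.0, 0.0]),
                np.array([3.0, 2.0, 1.0, 0.0]),
                100.0,
            )

    def test_duplicate_samples_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            AxisymProfile(
                np.array([0.0, 1.0, 1.0, 0.0]),
                np.array([2.0, 1.0, 1.0, 0.0]),
                100.0,
            )


class TestSummarizeShape:
    def test_upright_cylinder(self):
        mesh = trimesh.creation.cylinder(radius=10.0, height=5.0, sections=64)
        mesh.apply_translation([0, 0, 2.5])  # rest on z = 0
        s = summarize_shape(mesh)
        assert s.T == pytest.approx(5.0, abs=1e-9)
        assert s.R == pytest.approx(10.0, rel=1e-9)

    def test_sphere_resting_on_plane(self):
        mesh = trimesh.creation.icosphere(subdivisions=4, radius=30.0)
        mesh.apply_translation([0, 0, 30.0])
        s = summarize_shape(mesh)
        assert s.T == pytest.approx(60.0, rel=1e-6)
        assert s.R == pytest.approx(30.0, rel=1e-3)  # facet chord shortfall

    def test_matches_exhaustive_vertex_oracle(self, profile200):
        mesh = generate_synthetic_scan(profile200, noise_sd=0.3, seed=7)
        s = summarize_shape(mesh)
        v = mesh.vertices
        cx, cy = v[:, 0].mean(), v[:, 1].mean()
        assert s.T == max(p[2] for p in v)
        assert s.R == max(np.hypot(p[0] - cx, p[1] - cy) for p in v)

    def test_vertex_order_and_axis_rotation_invariance(self, profile200, rng):
        mesh = generate_synthetic_scan(profile200, noise_sd=0.1, seed=3)
        s0 = summarize_shape(mesh)
        perm = rng.permutation(mesh.vertices.shape[0])
        inv = np.empty_like(perm)
        inv[perm] = np.arange(perm.size)
        shuffled = ScanMesh(mesh.vertices[perm], inv[mesh.faces])
        s1 = summarize_shape(shuffled)
        assert s1.T == pytest.approx(s0.T, abs=1e-9)
        assert s1.R == pytest.approx(s0.R, abs=1e-9)
        th = 1.2345
        rot = np.array(
            [
                [np.cos(th), -np.sin(th), 0.0],
                [np.sin(th), np.cos(th), 0.0],
                [0.0, 0.0, 1.0],
            ]
        )
        s2 = summarize_shape(ScanMesh(mesh.vertices @ rot.T, mesh.faces))
        assert s2.T == pytest.approx(s0.T, abs=1e-9)
        assert s2.R == pytest.approx(s0.R, abs=1e-9)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            ScanMesh(np.empty((0, 3)), np.empty((0, 3), dtype=int))
        flat = ScanMesh(
            np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0]]),
            np.array([[0, 1, 2]]),
        )
        with pytest.raises(ValueError, match="coplanar"):
            summarize_shape(flat)
        with pytest.raises(TypeError):
            summarize_shape([[0, 0, 0]])


class TestSyntheticScan:
    def test_zero_noise_matches_profile_summary(self, profile200):
        mesh = generate_synthetic_scan(profile200, noise_sd=0.0)
        sm = summarize_shape(mesh)
        sp = summarize_shape(profile200)
        assert sm.T == pytest.approx(sp.T, abs=0.1)
        assert sm.R == pytest.approx(sp.R, abs=0.1)

    def test_fixed_seed_bit_identical(self, profile200):
        a = generate_synthetic_scan(profile200, 0.2, seed=11)
        b = generate_synthetic_scan(profile200, 0.2, seed=11)
        assert np.array_equal(a.vertices, b.vertices)
        assert np.array_equal(a.faces, b.faces)

    def test_noise_perturbs_but_summary_stays_close(self, profile200):
        base = summarize_shape(generate_synthetic_scan(profile200, 0.0))
        ref = generate_synthetic_scan(profile200, 0.2, seed=0)
        for seed in range(20):
            mesh = generate_synthetic_scan(profile200, 0.2, seed=seed)
            if seed > 0:
                assert not np.array_equal(mesh.vertices, ref.vertices)
            s = summarize_shape(mesh)
            assert abs(s.T - base.T) < 1.0

    def test_negative_noise_rejected(self, profile200):
        with pytest.raises(ValueError):
            generate_synthetic_scan(profile200, -0.1)

    def test_watertight_and_correct_volume(self, profile200):
        mesh = generate_synthetic_scan(profile200, 0.0, n_theta=128).to_trimesh()
        assert mesh.is_watertight
        assert abs(mesh.volume) == pytest.approx(200_000.0, rel=5e-3)

    @pytest.mark.parametrize("ext", ["stl", "ply"])
    def test_mesh_file_roundtrip(self, profile200, tmp_path, ext):
        # STL stores a float32 triangle soup, so compare geometry summaries;
        # PLY preserves the indexed vertex array
        mesh = generate_synthetic_scan(profile200, 0.1, seed=2)
        path = tmp_path / f"scan.{ext}"
        mesh.save(path)
        back = ScanMesh.load(path)
        s0, s1 = summarize_shape(mesh), summarize_shape(back)
        assert s1.T == pytest.approx(s0.T, abs=1e-4)
        assert s1.R == pytest.approx(s0.R, abs=1e-4)
        if ext == "ply":
            assert back.vertices.shape == mesh.vertices.shape
            np.testing.assert_allclose(back.vertices, mesh.vertices, atol=1e-4)
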