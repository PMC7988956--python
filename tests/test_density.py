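"""Trilinear sampling, reference grid, averaged model, zones and probes."""

import numpy as np
import pytest

import carposhape as cs
from carposhape.correspond import HomologousMeshSet
from carposhape.density import ZONE_NAMES, _grid_interpolator
from conftest import sphere_mesh


def _trilinear_oracle(vol, p):
    """Direct 8-corner formula, coded independently of the implementation."""
    g = (np.asarray(p) - vol.origin) / vol.voxel_size
    i0 = np.floor(g).astype(int)
    f = g - i0
    total = 0.0
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                w = ((f[0] if dx else 1 - f[0])
                     * (f[1] if dy else 1 - f[1])
                     * (f[2] if dz else 1 - f[2]))
                total += w * vol.values[i0[0] + dx, i0[1] + dy, i0[2] + dz]
    return total


@pytest.fixture(scope="module")
def random_volume():
    rng = np.random.default_rng(17)
    return cs.DensityVolume(rng.random((8, 8, 8)) * 1000, 0.7,
                            origin=np.array([-1.0, 0.5, 2.0]))


class TestTrilinear:
    def test_exact_at_voxel_centres(self, random_volume):
        vol = random_volume
        idx = np.array([[2, 3, 4], [0, 0, 0], [7, 7, 7], [5, 1, 6]])
        pts = vol.origin + vol.voxel_size * idx
        got = cs.trilinear_sample(vol, pts)
        assert np.array_equal(got, vol.values[tuple(idx.T)])

    def test_cell_centre_is_mean_of_eight_corners(self, random_volume):
        vol = random_volume
        p = vol.origin + vol.voxel_size * (np.array([3, 3, 3]) + 0.5)
        got = cs.trilinear_sample(vol, p)[0]
        want = vol.values[3:5, 3:5, 3:5].mean()
        assert abs(got - want) < 1e-12

    def test_fifty_random_queries_match_direct_formula(self, random_volume):
        vol = random_volume
        rng = np.random.default_rng(99)
        pts = vol.origin + vol.voxel_size * rng.uniform(0, 7, size=(50, 3))
        got = cs.trilinear_sample(vol, pts)
        want = [_trilinear_oracle(vol, p) for p in pts]
        assert np.abs(got - want).max() < 1e-12

    def test_linear_field_reproduced_exactly(self):
        idx = np.stack(np.meshgrid(*[np.arange(6)] * 3, indexing="ij"), axis=-1)
        vals = 2.0 * idx[..., 0] - 3.0 * idx[..., 1] + 0.5 * idx[..., 2] + 7.0
        vol = cs.DensityVolume(vals, 1.0)
        rng = np.random.default_rng(5)
        pts = rng.uniform(0, 5, size=(30, 3))
        want = 2.0 * pts[:, 0] - 3.0 * pts[:, 1] + 0.5 * pts[:, 2] + 7.0
        assert np.abs(cs.trilinear_sample(vol, pts) - want).max() < 1e-10

    def test_outside_queries_return_nan(self, random_volume):
        vol = random_volume
        out = cs.trilinear_sample(vol, vol.origin - 1.0)
        assert np.isnan(out).all()


class TestReferenceGrid:
    def test_ellipsoid_mask_matches_parity_oracle(self):
        # irrational semi-axes keep mesh facets off the node lattice, so the
        # inside test has no ambiguous on-surface nodes
        from test_mesh_kernels import _inside_brute
        mesh = sphere_mesh(1.0, subdivisions=2)
        scaled = cs.LabeledMesh(
            mesh.vertices * np.array([1.317, 0.9113, 0.7741]), mesh.triangles)
        grid = cs.build_reference_grid(scaled, 0.21, margin_nodes=2)
        nodes = grid.origin + grid.spacing * np.argwhere(
            np.ones(grid.shape, dtype=bool))
        want = _inside_brute(nodes, scaled.vertices, scaled.triangles,
                             np.array([0.357, 0.6143, 0.9231]))
        assert np.array_equal(grid.inside_mask.reshape(-1), want)

    def test_sphere_volume_recovered(self):
        mesh = sphere_mesh(6.0, subdivisions=4)
        grid = cs.build_reference_grid(mesh, 0.3)
        true = 4 / 3 * np.pi * 6 ** 3
        assert abs(grid.interior_volume - true) / true < 0.03

    def test_translation_equivariance(self):
        # radius chosen off the node lattice so no node sits on the surface;
        # the shift is a lattice multiple so both grids see identical offsets
        mesh = sphere_mesh(2.9371, subdivisions=2)
        g0 = cs.build_reference_grid(mesh, 0.5)
        shifted = cs.LabeledMesh(mesh.vertices + np.array([10.0, -5.0, 2.0]),
                                 mesh.triangles)
        g1 = cs.build_reference_grid(shifted, 0.5)
        assert np.array_equal(g0.inside_mask, g1.inside_mask)

    def test_bad_spacing_rejected(self, unit_sphere):
        with pytest.raises(ValueError, match="spacing"):
            cs.build_reference_grid(unit_sphere, 0.0)


def _constant_volume_for(mesh, value, voxel=0.6):
    lo = mesh.vertices.min(axis=0) - 3 * voxel
    hi = mesh.vertices.max(axis=0) + 3 * voxel
    shape = tuple(int(np.ceil((hi[a] - lo[a]) / voxel)) + 1 for a in range(3))
    return cs.DensityVolume(np.full(shape, float(value)), voxel, lo, "vBMD")


@pytest.fixture(scope="module")
def identical_homology():
    mesh, _, _ = cs.generate_phantom_mesh(cs.PhantomParams(bend_angle=0.0),
                                          n_subdiv=6)
    verts = np.stack([mesh.vertices] * 3)
    return mesh, HomologousMeshSet(verts, mesh.triangles, mesh.labels,
                                   ["a", "b", "c"], "a")


class TestAveragedModel:
    def test_constant_interiors_average_exactly(self, identical_homology):
        mesh, hom = identical_homology
        grid = cs.build_reference_grid(mesh, 0.8)
        vols = [_constant_volume_for(mesh, 300.0) for _ in range(3)]
        model = cs.build_averaged_model(grid, hom, vols, mesh.vertices,
                                        n_controls=120, control_layers=())
        inside_vals = model.mean_vbmd[grid.inside_mask]
        assert np.abs(inside_vals - 300.0).max() < 1e-9
        assert model.n_specimens == 3

    def test_linear_averaging_of_two_constants(self, identical_homology):
        mesh, hom = identical_homology
        hom2 = HomologousMeshSet(hom.vertices[:2], hom.triangles, hom.labels,
                                 ["a", "b"], "a")
        grid = cs.build_reference_grid(mesh, 0.8)
        vols = [_constant_volume_for(mesh, 100.0),
                _constant_volume_for(mesh, 500.0)]
        model = cs.build_averaged_model(grid, hom2, vols, mesh.vertices,
                                        n_controls=120, control_layers=())
        inside_vals = model.mean_vbmd[grid.inside_mask]
        assert np.abs(inside_vals - 300.0).max() < 1e-9

    def test_specimen_order_invariance(self, identical_homology):
        mesh, hom = identical_homology
        grid = cs.build_reference_grid(mesh, 0.9)
        vols = [_constant_volume_for(mesh, v) for v in (100.0, 300.0, 800.0)]
        m1 = cs.build_averaged_model(grid, hom, vols, mesh.vertices,
                                     n_controls=120, control_layers=())
        m2 = cs.build_averaged_model(grid, hom, vols[::-1], mesh.vertices,
                                     n_controls=120, control_layers=())
        assert np.allclose(m1.mean_vbmd[grid.inside_mask],
                           m2.mean_vbmd[grid.inside_mask], atol=1e-9,
                           equal_nan=True)

    def test_uncalibrated_volume_rejected(self, identical_homology):
        mesh, hom = identical_homology
        grid = cs.build_reference_grid(mesh, 1.0)
        vols = [_constant_volume_for(mesh, 1.0) for _ in range(3)]
        vols[1] = cs.DensityVolume(vols[1].values, vols[1].voxel_size,
                                   vols[1].origin, "HU")
        with pytest.raises(ValueError, match="vBMD"):
            cs.build_averaged_model(grid, hom, vols, mesh.vertices)


@pytest.fixture(scope="module")
def sphere_model():
    mesh = sphere_mesh(10.0, subdivisions=4)
    grid = cs.build_reference_grid(mesh, 0.4)
    mean_vbmd = np.where(grid.inside_mask, 100.0, np.nan)
    model = cs.AveragedDensityModel(grid, mean_vbmd,
                                    grid.inside_mask.astype(np.int32), 1)
    return mesh, cs.segment_zones(model, mesh, peripheral_depth=2.0,
                                  centre_start_depth=5.0)


class TestZones:
    def test_shell_volumes_match_closed_forms(self, sphere_model):
        _, model = sphere_model
        stats = cs.zone_stats(model)
        vol = lambda r: 4 / 3 * np.pi * r ** 3  # noqa: E731
        peripheral_true = vol(10) - vol(8)
        centre_true = vol(5)
        inter_true = vol(8) - vol(5)
        assert abs(stats.loc["peripheral", "volume_mm3"] - peripheral_true) \
            / peripheral_true < 0.05
        assert abs(stats.loc["centre", "volume_mm3"] - centre_true) \
            / centre_true < 0.05
        inter = stats.loc[[z for z in ZONE_NAMES if "intermediate" in z],
                          "volume_mm3"].sum()
        assert abs(inter - inter_true) / inter_true < 0.05

    def test_partition_is_exact(self, sphere_model):
        _, model = sphere_model
        inside = model.grid.inside_mask
        labelled = model.zone_labels >= 0
        assert np.array_equal(labelled, inside)
        counts = [(model.zone_labels == z).sum() for z in range(len(ZONE_NAMES))]
        assert sum(counts) == inside.sum()

    def test_zone_volumes_conserve_interior_volume(self, sphere_model):
        _, model = sphere_model
        stats = cs.zone_stats(model)
        assert abs(stats["volume_mm3"].sum() - model.grid.interior_volume) < 1e-9

    def test_constant_model_zone_stats(self, sphere_model):
        _, model = sphere_model
        stats = cs.zone_stats(model)
        occupied = stats[stats["n_nodes"] > 0]
        assert np.allclose(occupied["mean"], 100.0)
        assert np.allclose(occupied["sd"], 0.0)

    def test_invalid_depths_rejected(self, sphere_model):
        mesh, model = sphere_model
        with pytest.raises(ValueError, match="peripheral_depth"):
            cs.segment_zones(model, mesh, peripheral_depth=4.0,
                             centre_start_depth=2.0)

    def test_excessive_depths_warn_of_empty_centre(self):
        mesh = sphere_mesh(3.0, subdivisions=3)
        grid = cs.build_reference_grid(mesh, 0.4)
        model = cs.AveragedDensityModel(
            grid, np.where(grid.inside_mask, 1.0, np.nan),
            grid.inside_mask.astype(np.int32), 1)
        with pytest.warns(UserWarning, match="centre zone is empty"):
            cs.segment_zones(model, mesh, peripheral_depth=4.0,
                             centre_start_depth=5.0)

    def test_phantom_zone_ordering(self, zone_phantom_volume):
        mesh, zones, vol = zone_phantom_volume
        grid = cs.build_reference_grid(mesh, 0.4)
        model = cs.AveragedDensityModel(
            grid, np.where(grid.inside_mask,
                           cs.trilinear_sample(
                               vol, grid.node_coords(np.ones(grid.shape, bool))
                           ).reshape(grid.shape), np.nan),
            grid.inside_mask.astype(np.int32), 1)
        model = cs.segment_zones(model, mesh, zones.peripheral_thickness,
                                 zones.centre_start_depth)
        stats = cs.zone_stats(model)
        per = stats.loc["peripheral", "mean"]
        cen = stats.loc["centre", "mean"]
        inters = stats.loc[[z for z in ZONE_NAMES if "intermediate" in z], "mean"]
        assert (per > inters).all()
        assert (inters > cen).all()


class TestProbe:
    def test_constant_field_constant_profile(self, unit_sphere):
        vol = _constant_volume_for(unit_sphere, 42.0, voxel=0.2)
        prof = cs.probe_pathway(vol, np.array([-0.5, 0, 0]),
                                np.array([0.5, 0, 0]), diameter=0.4,
                                n_stations=20)
        assert np.allclose(prof.station_mean, 42.0, atol=1e-12)
        assert prof.summary["mean"] == pytest.approx(42.0)

    def test_line_mode_on_ramp_field_is_exact(self):
        idx = np.stack(np.meshgrid(*[np.arange(12)] * 3, indexing="ij"), axis=-1)
        vol = cs.DensityVolume(5.0 * idx[..., 0] + 3.0, 1.0)
        entry, exit_ = np.array([1.0, 5.0, 5.0]), np.array([10.0, 5.0, 5.0])
        prof = cs.probe_pathway(vol, entry, exit_, diameter=2.0,
                                n_stations=10, mode="line")
        want = 5.0 * prof.stations[:, 0] + 3.0
        assert np.abs(prof.station_mean - want).max() < 1e-9

    def test_station_mean_within_sample_range(self, zone_phantom_volume):
        mesh, _, vol = zone_phantom_volume
        c = mesh.vertices.mean(axis=0)
        prof = cs.probe_pathway(vol, c - np.array([8.0, 0, 0]),
                                c + np.array([8.0, 0, 0]), diameter=3.0)
        ok = np.isfinite(prof.station_mean)
        assert prof.summary["min"] <= prof.summary["mean"] <= prof.summary["max"]
        assert (prof.station_n[ok] > 0).all()

    def test_translation_invariance_of_profile(self):
        rng = np.random.default_rng(8)
        vals = rng.random((10, 10, 10)) * 100
        shift = np.array([3.0, -2.0, 5.0])
        v0 = cs.DensityVolume(vals, 0.5, origin=np.zeros(3))
        v1 = cs.DensityVolume(vals, 0.5, origin=shift)
        e1, e2 = np.array([1.0, 2.0, 2.0]), np.array([3.5, 2.5, 2.0])
        p0 = cs.probe_pathway(v0, e1, e2, diameter=1.0, n_stations=15)
        p1 = cs.probe_pathway(v1, e1 + shift, e2 + shift, diameter=1.0,
                              n_stations=15)
        assert np.allclose(p0.station_mean, p1.station_mean, atol=1e-10,
                           equal_nan=True)

    def test_degenerate_path_rejected(self, unit_sphere):
        vol = _constant_volume_for(unit_sphere, 1.0)
        with pytest.raises(ValueError, match="coincide"):
            cs.probe_pathway(vol, np.zeros(3), np.zeros(3))

    def test_outside_path_rejected(self, unit_sphere):
        vol = _constant_volume_for(unit_sphere, 1.0)
        with pytest.raises(ValueError, match="outside"):
            cs.probe_pathway(vol, np.array([50.0, 50, 50]),
                             np.array([60.0, 50, 50]))

    def test_peripheral_path_denser_than_central_and_matches_voxel_oracle(
            self, zone_phantom_volume):
        mesh, zones, vol = zone_phantom_volume
        p = cs.PhantomParams(bend_angle=0.0)
        L = p.length
        central = (np.array([0.08 * L, 0.0, 0.0]),
                   np.array([0.92 * L, 0.0, 0.0]))
        # medial chord inside the cortical shell at the waist
        zc = p.waist_radius - 0.5 * zones.peripheral_thickness - 1.5
        zc = p.waist_radius - 1.0  # 1 mm deep at the waist
        peripheral = (np.array([0.25 * L, 0.0, zc]),
                      np.array([0.75 * L, 0.0, zc]))
        prof_c = cs.probe_pathway(vol, *central, diameter=3.0)
        prof_p = cs.probe_pathway(vol, *peripheral, diameter=3.0)
        assert prof_p.summary["mean"] > prof_c.summary["mean"]

        # voxel-masking oracle: mean over voxel centres inside the cylinder
        for (entry, exit_), prof in ((central, prof_c), (peripheral, prof_p)):
            ijk = np.argwhere(np.ones(vol.shape, dtype=bool))
            pts = vol.origin + vol.voxel_size * ijk
            d = exit_ - entry
            t = (pts - entry) @ d / (d @ d)
            radial = np.linalg.norm(pts - (entry + t[:, None] * d), axis=1)
            sel = (t >= 0) & (t <= 1) & (radial <= 1.5)
            oracle = vol.values[tuple(ijk[sel].T)].mean()
            assert abs(prof.summary["mean"] - oracle) / oracle < 0.02
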