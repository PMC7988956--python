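"""Non-scaling GPA, the PCA form model, and morphometrics."""

import numpy as np
import pytest

import carposhape as cs
from carposhape.shape import _optimal_rotation


def _rot_z(deg):
    th = np.deg2rad(deg)
    return np.array([[np.cos(th), -np.sin(th), 0],
                     [np.sin(th), np.cos(th), 0], [0, 0, 1.0]])


class TestProcrustes:
    def test_rigid_motion_between_copies_removed(self, default_phantom):
        mesh, _, _ = default_phantom
        a = mesh.vertices
        b = a @ _rot_z(30).T + np.array([4.0, -1.0, 2.0])
        aligned, mean, _ = cs.procrustes_align(np.stack([a, b]))
        rmsd = np.sqrt(np.mean((aligned[0] - aligned[1]) ** 2))
        assert rmsd < 1e-6

    def test_centroid_sizes_preserved_exactly(self, population6):
        specimens, _ = population6
        shapes = np.stack([s.mesh.vertices for s in specimens])
        aligned, _, _ = cs.procrustes_align(shapes)
        before = [cs.centroid_size(s) for s in shapes]
        after = [cs.centroid_size(s) for s in aligned]
        assert np.abs(np.asarray(before) - after).max() < 1e-9

    def test_alignment_idempotent(self, population6):
        specimens, _ = population6
        shapes = np.stack([s.mesh.vertices for s in specimens])
        once, _, _ = cs.procrustes_align(shapes)
        twice, _, _ = cs.procrustes_align(once)
        assert np.abs(once - twice).max() < 1e-8

    def test_mean_of_identical_copies_is_the_centred_shape(self, default_phantom):
        mesh, _, _ = default_phantom
        v = mesh.vertices
        aligned, mean, _ = cs.procrustes_align(np.stack([v, v, v]))
        assert np.allclose(mean, v - v.mean(axis=0), atol=1e-9)
        assert np.allclose(mean.mean(axis=0), 0.0, atol=1e-9)

    def test_reflection_never_used(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(50, 3))
        b = a.copy()
        b[:, 0] = -b[:, 0]  # mirrored configuration
        r = _optimal_rotation(a - a.mean(0), b - b.mean(0))
        assert np.isclose(np.linalg.det(r), 1.0, atol=1e-9)

    def test_single_shape_rejected(self, default_phantom):
        mesh, _, _ = default_phantom
        with pytest.raises(ValueError, match="at least 2"):
            cs.GeneralizedProcrustes().fit(mesh.vertices[None])


@pytest.fixture(scope="module")
def length_only_model():
    sds = {k: 0.0 for k in cs.phantom.DEFAULT_PARAM_SDS}
    sds["length"] = 2.5
    specs, latent = cs.generate_population(25, mode_sds=sds, seed=21,
                                           n_subdiv=8)
    shapes = np.stack([s.mesh.vertices for s in specs])
    aligned, _, _ = cs.procrustes_align(shapes)
    pca = cs.ShapePCA().fit(aligned, triangles=specs[0].mesh.triangles,
                            labels=specs[0].mesh.labels)
    return pca, latent, aligned


class TestShapePCA:
    def test_single_latent_mode_recovered(self, length_only_model):
        pca, latent, _ = length_only_model
        assert pca.variance_fractions_[0] > 0.95
        r = np.corrcoef(pca.scores_[:, 0], latent["length"])[0, 1]
        assert abs(r) > 0.99

    def test_variance_fractions_sum_to_one(self, length_only_model):
        pca, _, _ = length_only_model
        assert abs(pca.variance_fractions_.sum() - 1.0) < 1e-9
        assert (pca.variance_fractions_ >= 0).all()

    def test_modes_orthonormal(self, length_only_model):
        pca, _, _ = length_only_model
        flat = pca.components_.reshape(len(pca.components_), -1)
        gram = flat @ flat.T
        assert np.abs(gram - np.eye(len(flat))).max() < 1e-8

    def test_full_reconstruction_of_training_shapes(self, length_only_model):
        pca, _, aligned = length_only_model
        rec = pca.reconstruct(pca.scores_)
        assert np.abs(rec - aligned).max() < 1e-6

    def test_synthesize_zero_sd_is_mean(self, length_only_model):
        pca, _, _ = length_only_model
        mesh = pca.synthesize(0, 0.0)
        assert np.array_equal(mesh.vertices, pca.mean_vertices_)

    def test_plus_minus_displacements_are_negatives(self, length_only_model):
        pca, _, _ = length_only_model
        plus = pca.synthesize(0, 2.0).vertices - pca.mean_vertices_
        minus = pca.synthesize(0, -2.0).vertices - pca.mean_vertices_
        assert np.allclose(plus, -minus, atol=1e-10)

    def test_synthesized_length_span_matches_latent_scale(self, length_only_model):
        pca, latent, _ = length_only_model
        len_plus = cs.measure(pca.synthesize(0, 2.0)).length
        len_minus = cs.measure(pca.synthesize(0, -2.0)).length
        span = len_plus - len_minus
        expected = 4.0 * latent["length"].std(ddof=1)
        # sign convention: +SD extends the long axis, so the span is positive
        assert span > 0
        assert abs(span - expected) / expected < 0.05

    def test_identical_shapes_give_degenerate_model(self, default_phantom):
        mesh, _, _ = default_phantom
        shapes = np.stack([mesh.vertices] * 4)
        with pytest.warns(UserWarning, match="degenerate"):
            pca = cs.ShapePCA().fit(shapes)
        assert pca.degenerate_
        assert len(pca.variance_fractions_) == 0

    def test_mode_truncation_warns(self, population6):
        specimens, _ = population6
        shapes = np.stack([s.mesh.vertices for s in specimens])
        aligned, _, _ = cs.procrustes_align(shapes)
        with pytest.warns(UserWarning, match="truncating"):
            pca = cs.ShapePCA(n_modes=50).fit(aligned)
        assert len(pca.components_) <= len(shapes) - 1

    def test_three_independent_modes_dominate(self):
        sds = {k: 0.0 for k in cs.phantom.DEFAULT_PARAM_SDS}
        sds.update(length=2.5, waist_radius=0.35, bend_angle=4.0)
        specs, latent = cs.generate_population(25, mode_sds=sds, seed=33,
                                               n_subdiv=8)
        aligned, _, _ = cs.procrustes_align(
            np.stack([s.mesh.vertices for s in specs]))
        pca = cs.ShapePCA().fit(aligned)
        assert pca.variance_fractions_[:3].sum() >= 0.90


class TestMorphometrics:
    def test_cosine_waisted_cylinder(self):
        # radius 5 necking to 4 at mid-length via a cosine bulge profile
        n_axial, n_ring = 120, 80
        x = np.linspace(0.0, 26.0, n_axial)
        r = 4.0 + 1.0 * np.cos(np.pi * (2 * x / 26.0 - 1.0)) ** 2
        th = 2 * np.pi * np.arange(n_ring) / n_ring
        rings = np.stack([
            np.repeat(x, n_ring),
            np.tile(np.sin(th), n_axial) * np.repeat(r, n_ring),
            np.tile(np.cos(th), n_axial) * np.repeat(r, n_ring)], axis=1)
        verts = np.vstack([[[0.0, 0, 0]], rings, [[26.0, 0, 0]]])
        idx = lambda i, j: 1 + i * n_ring + (j % n_ring)  # noqa: E731
        tris = [[0, idx(0, j + 1), idx(0, j)] for j in range(n_ring)]
        for i in range(n_axial - 1):
            for j in range(n_ring):
                a, b = idx(i, j), idx(i, j + 1)
                c, d = idx(i + 1, j), idx(i + 1, j + 1)
                tris += [[a, b, d], [a, d, c]]
        tris += [[len(verts) - 1, idx(n_axial - 1, j), idx(n_axial - 1, j + 1)]
                 for j in range(n_ring)]
        mesh = cs.LabeledMesh(verts, np.asarray(tris))
        m = cs.measure(mesh)
        assert abs(m.length - 26.0) < 0.02
        assert abs(m.waist_diameters[0] - 8.0) / 8.0 < 0.01
        assert abs(m.waist_diameters[1] - 8.0) / 8.0 < 0.01

    def test_unit_sphere_area_and_band_edge_waist(self, unit_sphere):
        m = cs.measure(unit_sphere)
        assert abs(m.total_area - 4 * np.pi) / (4 * np.pi) < 0.02
        # no interior necking: the minimal section over the central 60% band
        # sits at the band edge, diameter 2*sqrt(1 - 0.36) = 1.6
        assert abs(m.waist_diameters[0] - 1.6) < 0.03
        assert abs(m.waist_diameters[1] - 1.6) < 0.03

    def test_mirror_invariance_of_scalar_descriptors(self, default_phantom):
        mesh, _, _ = default_phantom
        mirrored = cs.mirror_to_right(mesh, "left")
        a, b = cs.measure(mesh), cs.measure(mirrored)
        assert np.isclose(a.length, b.length, atol=1e-9)
        assert np.allclose(a.waist_diameters, b.waist_diameters, atol=1e-9)
        assert np.isclose(a.total_area, b.total_area, atol=1e-9)
        for k in a.region_areas:
            assert np.isclose(a.region_areas[k], b.region_areas[k], atol=1e-9)

    def test_region_areas_sum_to_total(self, default_phantom):
        mesh, _, _ = default_phantom
        m = cs.measure(mesh)
        assert abs(sum(m.region_areas.values()) - m.total_area) < 1e-6

    def test_open_mesh_rejected(self, unit_sphere):
        open_mesh = cs.LabeledMesh(unit_sphere.vertices,
                                   unit_sphere.triangles[:-5])
        with pytest.raises(ValueError, match="closed"):
            cs.measure(open_mesh)

    def test_mean_model_descriptor_differs_from_descriptor_mean(self, corresponded6):
        # the mean shape's area is not the mean of per-specimen areas;
        # both paths must exist and generally disagree
        _, hom, areas = corresponded6
        aligned, mean, _ = cs.procrustes_align(hom)
        mean_mesh = cs.LabeledMesh(mean, hom.triangles, hom.labels)
        area_of_mean = cs.measure(mean_mesh).total_area
        mean_of_areas = areas["total"].mean()
        assert abs(area_of_mean - mean_of_areas) > 1e-6


class TestPopulationStats:
    def test_hand_computed_example(self):
        out = cs.population_stats({"v": [1.0, 2.0, 3.0]})
        row = out.loc["v"]
        assert row["mean"] == 2.0 and row["sd"] == 1.0
        assert row["min"] == 1.0 and row["max"] == 3.0
        assert "±" in row["formatted"]

    def test_constant_values_have_zero_sd(self):
        out = cs.population_stats({"v": [5.0] * 8})
        assert out.loc["v", "sd"] == 0.0

    def test_agreement_with_streaming_oracle(self):
        rng = np.random.default_rng(12)
        x = rng.normal(100.0, 15.0, size=1000)
        # Welford's online algorithm as the independent oracle
        n, mean, m2 = 0, 0.0, 0.0
        for v in x:
            n += 1
            d = v - mean
            mean += d / n
            m2 += d * (v - mean)
        sd = np.sqrt(m2 / (n - 1))
        out = cs.population_stats({"x": x})
        assert abs(out.loc["x", "mean"] - mean) < 1e-10
        assert abs(out.loc["x", "sd"] - sd) < 1e-10

    def test_single_specimen_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            cs.population_stats({"v": [1.0]})
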