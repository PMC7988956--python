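"""Shared fixtures: phantom specimens and meshes generated at test scale."""

import numpy as np
import pytest
import trimesh

import carposhape as cs


@pytest.fixture(scope="session")
def default_phantom():
    """One phantom at default parameters, moderate resolution."""
    mesh, lms, record = cs.generate_phantom_mesh(cs.PhantomParams(), n_subdiv=10)
    return mesh, lms, record


@pytest.fixture(scope="session")
def straight_phantom():
    """Unbent phantom: analytic geometry is easiest to reason about."""
    params = cs.PhantomParams(bend_angle=0.0)
    mesh, lms, record = cs.generate_phantom_mesh(params, n_subdiv=12)
    return params, mesh, lms, record


@pytest.fixture(scope="session")
def zone_phantom_volume(straight_phantom):
    """Noise-free concentric-zone volume of the unbent phantom."""
    _, mesh, _, _ = straight_phantom
    zones = cs.ZoneProfile(noise_sd=0.0)
    vol = cs.generate_phantom_volume(mesh, zones, voxel_size=0.3, seed=0)
    return mesh, zones, vol


@pytest.fixture(scope="session")
def population6():
    """Small phantom population with landmark sets (no volumes)."""
    specimens, latent = cs.generate_population(6, seed=11, n_subdiv=8)
    return specimens, latent


@pytest.fixture(scope="session")
def corresponded6(population6):
    specimens, _ = population6
    lsets = [cs.resample_segments(s.landmarks, 11, points_per_loop=24)
             for s in specimens]
    ridx = cs.choose_reference(lsets)
    hom = cs.establish_homology(
        (specimens[ridx].mesh, lsets[ridx]),
        [(s.mesh, l) for s, l in zip(specimens, lsets)],
        [s.specimen_id for s in specimens],
        reference_id=specimens[ridx].specimen_id)
    hom, areas = cs.transfer_cartilage_regions(specimens[ridx].mesh.labels, hom)
    return specimens, hom, areas


@pytest.fixture(scope="session")
def unit_sphere():
    m = trimesh.creation.icosphere(subdivisions=3, radius=1.0)
    return cs.LabeledMesh(np.asarray(m.vertices), np.asarray(m.faces))


def sphere_mesh(radius, subdivisions=3, center=(0.0, 0.0, 0.0)):
    m = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return cs.LabeledMesh(np.asarray(m.vertices) + np.asarray(center),
                          np.asarray(m.faces))
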