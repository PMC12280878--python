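"""Transport solver contracts on small fixtures.

The heavy reference-phantom checks live in test_acceptance; here the solver
is exercised on small meshes: feasibility, fold-freedom, the exact
uniform-density fixed point, map inversion and composition, and tensor
resampling.
"""

import numpy as np
import pytest

from omtapc.density import density_from_he, histogram_equalize, normalize_total_mass, vertex_wt_mask
from omtapc.mesh import BALL_VOLUME, CUBE_SIDE, ball_mesh, build_tet_mesh, cube_mesh, signed_tet_volumes
from omtapc.phantom import PhantomSpec, VoxelVolume, generate_phantom
from omtapc.transport import (
    _TetLocator,
    compose_to_cube,
    invert_piecewise_linear_map,
    resample_to_tensor,
    solve_mass_preserving_map,
    solve_volume_preserving_cube_map,
    voxel_tensor,
)

TOL = 0.075


@pytest.fixture(scope="module")
def tiny_volume():
    return generate_phantom(
        PhantomSpec(
            grid_shape=(16, 16, 16),
            brain_axes=(6.0, 5.5, 5.0),
            tumor_radius=2.5,
            class_label=1,
            effect_size=2.0,
            seed=77,
        )
    )


@pytest.fixture(scope="module")
def tiny_solution(tiny_volume):
    mesh = build_tet_mesh(tiny_volume, subdivision="center24")
    he = histogram_equalize(tiny_volume, mesh)
    wt_v = vertex_wt_mask(mesh, tiny_volume)
    field = normalize_total_mass(density_from_he(mesh, he, wt_v, 1.0), mesh)
    omt = solve_mass_preserving_map(
        mesh, field, tol=TOL, max_iter=10, inner_steps=2, target_factor=0.8
    )
    return mesh, field, omt


def test_solve_feasibility_contract(tiny_solution):
    mesh, field, omt = tiny_solution
    assert omt.converged
    assert omt.max_mass_residual <= TOL
    vols = signed_tet_volumes(omt.target_positions, mesh.tets)
    assert vols.min() > 0  # no folding
    assert omt.image_volume == pytest.approx(BALL_VOLUME, rel=1e-9)
    radii = np.linalg.norm(omt.target_positions, axis=1)
    assert radii.max() <= omt.ball_radius + 1e-9


def test_solve_objective_history_monotone(tiny_solution):
    _, _, omt = tiny_solution
    hist = omt.objective_history
    assert all(b <= a + 1e-12 for a, b in zip(hist, hist[1:]))
    assert omt.objective_value == hist[-1]


def test_solver_is_deterministic(tiny_volume):
    mesh = build_tet_mesh(tiny_volume, subdivision="center24")
    he = histogram_equalize(tiny_volume, mesh)
    wt_v = vertex_wt_mask(mesh, tiny_volume)
    field = normalize_total_mass(density_from_he(mesh, he, wt_v, 1.0), mesh)
    kw = dict(tol=TOL, max_iter=4, inner_steps=2, polish=False)
    a = solve_mass_preserving_map(mesh, field, **kw)
    b = solve_mass_preserving_map(mesh, field, **kw)
    assert np.array_equal(a.target_positions, b.target_positions)


def test_unnormalized_field_rejected(tiny_volume):
    mesh = build_tet_mesh(tiny_volume, subdivision="center24")
    he = histogram_equalize(tiny_volume, mesh)
    field = density_from_he(mesh, he, vertex_wt_mask(mesh, tiny_volume), 1.0)
    with pytest.raises(ValueError, match="normalized"):
        solve_mass_preserving_map(mesh, field)


def test_uniform_density_ball_is_fixed_point():
    """A discrete ball under uniform density: the identity map is feasible,
    so the solved map's transport cost must not exceed the identity's."""
    mesh = ball_mesh(8)
    zeros = np.zeros(mesh.n_vertices)
    field = normalize_total_mass(
        density_from_he(mesh, zeros, np.zeros(mesh.n_vertices, bool), 0.0), mesh
    )
    omt = solve_mass_preserving_map(mesh, field, tol=1e-2)
    identity_objective = 0.0
    assert omt.objective_value <= identity_objective + 1e-9
    assert omt.converged
    assert omt.max_mass_residual <= 1e-9
    assert np.allclose(omt.target_positions, mesh.vertices, atol=1e-9)


@pytest.fixture(scope="module")
def cube_map6():
    return solve_volume_preserving_cube_map(6, tol=TOL)


def test_cube_map_contracts(cube_map6):
    omt = cube_map6
    assert omt.converged
    assert omt.image_volume == pytest.approx(BALL_VOLUME, rel=1e-9)
    # the cube center is a mesh vertex and must stay near the ball center
    center_idx = int(np.argmin(np.linalg.norm(omt.source_mesh.vertices, axis=1)))
    assert np.linalg.norm(omt.source_mesh.vertices[center_idx]) < 1e-12
    assert np.linalg.norm(omt.target_positions[center_idx]) <= 0.05
    # cube corners map into the closed ball
    radii = np.linalg.norm(omt.target_positions, axis=1)
    assert radii.max() <= omt.ball_radius + 1e-9


def test_cube_map_cached(cube_map6):
    again = solve_volume_preserving_cube_map(6, tol=TOL)
    assert again is cube_map6


def test_inversion_roundtrips(cube_map6, rng):
    omt = cube_map6
    # vertex image -> indicator barycentrics
    v = 100
    tet_idx, bary, inside = invert_piecewise_linear_map(
        omt, omt.target_positions[[v]]
    )
    assert inside[0]
    verts = omt.source_mesh.tets[tet_idx[0]]
    weight_on_v = bary[0][verts == v].sum()
    assert weight_on_v == pytest.approx(1.0, abs=1e-9)

    # centroid of an image tet -> (1/4, 1/4, 1/4, 1/4)
    t = 42
    centroid = omt.target_positions[omt.source_mesh.tets[t]].mean(axis=0)
    tet_idx, bary, inside = invert_piecewise_linear_map(omt, centroid[None])
    assert inside[0]
    img = omt.target_positions[omt.source_mesh.tets[tet_idx[0]]]
    assert np.allclose(bary[0] @ img, centroid, atol=1e-9)

    # random interior points round-trip through the map
    queries = rng.uniform(-0.4, 0.4, size=(500, 3))
    tet_idx, bary, inside = invert_piecewise_linear_map(omt, queries)
    assert inside.all()
    img = omt.target_positions[omt.source_mesh.tets[tet_idx]]
    recon = np.einsum("qk,qkc->qc", bary, img)
    assert np.abs(recon - queries).max() <= 1e-9


def test_empty_query_inversion(cube_map6):
    tet_idx, bary, inside = invert_piecewise_linear_map(cube_map6, np.zeros((0, 3)))
    assert len(tet_idx) == 0 and bary.shape == (0, 4) and len(inside) == 0


def test_self_composition_is_identity(cube_map6):
    """Mapping the cube to the ball and back must reproduce the cube mesh."""
    composed = compose_to_cube(cube_map6, cube_map6)
    dev = np.abs(composed.positions - cube_map6.source_mesh.vertices).max()
    assert dev <= 1e-8
    # objective of the composed identity is at the discretization floor
    assert composed.clamped == 0


def test_resample_constant_intensity(cube_map6):
    mesh = cube_map6.source_mesh
    composed = compose_to_cube(cube_map6, cube_map6)
    shape = (8, 8, 8)
    mask = np.ones(shape, bool)
    wt = np.zeros(shape, bool)
    wt[4, 4, 4] = True
    volume = VoxelVolume(
        intensities=np.full((2, *shape), 0.7),
        brain_mask=mask,
        wt_mask=wt,
        spacing=tuple(mesh.spacing),
    )
    # the composed mesh spans the cube; interior voxels must read 0.7
    tensor = resample_to_tensor(composed, volume, 12)
    inside = tensor.intensities[0][tensor.intensities[0] != 0.0]
    assert len(inside) > 0.9 * tensor.labels.size
    assert np.allclose(inside, 0.7, atol=1e-9)


def test_resample_label_survival(tiny_solution, tiny_volume):
    mesh, field, omt = tiny_solution
    cube_map = solve_volume_preserving_cube_map(6, tol=TOL)
    composed = compose_to_cube(omt, cube_map, require_converged=False)
    tensor = resample_to_tensor(composed, tiny_volume, 16, gamma=1.0)
    assert tensor.labels.sum() > 0
    assert set(np.unique(tensor.labels)) <= {0, 1}
    assert np.all(np.isfinite(tensor.intensities))


def test_resample_rejects_tiny_grid(tiny_solution, tiny_volume):
    mesh, field, omt = tiny_solution
    cube_map = solve_volume_preserving_cube_map(6, tol=TOL)
    composed = compose_to_cube(omt, cube_map, require_converged=False)
    with pytest.raises(ValueError):
        resample_to_tensor(composed, tiny_volume, 4)


def test_voxel_tensor_wraps_grid(tiny_volume):
    t = voxel_tensor(tiny_volume, subject_id="s0")
    assert np.array_equal(t.labels.astype(bool), tiny_volume.wt_mask)
    assert np.array_equal(t.intensities, tiny_volume.intensities)
    assert t.provenance["tensorization"] == "identity"


def test_locator_handles_outside_points(cube_map6):
    loc = _TetLocator(cube_map6.target_positions, cube_map6.source_mesh.tets)
    far = np.array([[2.0, 2.0, 2.0]])
    tet_idx, bary, inside = loc.locate(far)
    assert not inside[0]
    assert bary[0].sum() == pytest.approx(1.0)
    assert bary[0].min() >= 0.0
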