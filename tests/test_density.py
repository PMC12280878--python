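"""Histogram equalization and the tumor-weighting density field."""

import numpy as np
import pytest
from scipy import stats

from omtapc.density import (
    density_from_he,
    density_gamma_rungs,
    histogram_equalize,
    intensity_cdf,
    normalize_total_mass,
    vertex_wt_mask,
)
from omtapc.mesh import BALL_VOLUME, build_tet_mesh
from omtapc.phantom import VoxelVolume


@pytest.fixture(scope="module")
def mesh_and_volume(small_volume):
    return build_tet_mesh(small_volume), small_volume


def _constant_volume(value, shape=(16, 16, 16)):
    mask = np.zeros(shape, bool)
    mask[4:12, 4:12, 4:12] = True
    wt = np.zeros(shape, bool)
    wt[7:9, 7:9, 7:9] = True
    return VoxelVolume(
        intensities=np.full((2, *shape), float(value)),
        brain_mask=mask,
        wt_mask=wt,
        spacing=(1.0, 1.0, 1.0),
    )


def test_constant_intensity_equalizes_to_one():
    vol = _constant_volume(7.0)
    mesh = build_tet_mesh(vol)
    he = histogram_equalize(vol, mesh)
    assert np.allclose(he, 1.0)


def test_two_level_equalization():
    vol = _constant_volume(0.0)
    intens = vol.intensities.copy()
    # half the masked voxels at 100, half at 900, no interpolation mixing
    idx = np.argwhere(vol.brain_mask)
    half = len(idx) // 2
    for r, (i, j, k) in enumerate(idx):
        intens[:, i, j, k] = 100.0 if r < half else 900.0
    cdf = intensity_cdf(intens[0][vol.brain_mask])
    assert cdf(np.array([100.0]))[0] == pytest.approx(0.5)
    assert cdf(np.array([900.0]))[0] == pytest.approx(1.0)


def test_equalization_property_uniformizes(rng):
    values = rng.uniform(0, 1000, size=20000)
    he = intensity_cdf(values)(values)
    d = stats.kstest(he, "uniform").statistic
    assert d < 0.05


def test_gamma_zero_density_is_unit(mesh_and_volume):
    mesh, vol = mesh_and_volume
    he = histogram_equalize(vol, mesh)
    wt_v = vertex_wt_mask(mesh, vol)
    field = density_from_he(mesh, he, wt_v, 0.0)
    assert np.allclose(field.rho_vertex, 1.0)
    expected_local = mesh.vertex_ring_sums(mesh.tet_volumes) / 4.0
    assert np.allclose(field.local_mass, expected_local)


def test_density_formula_and_bounds(mesh_and_volume):
    mesh, vol = mesh_and_volume
    he = histogram_equalize(vol, mesh)
    wt_v = vertex_wt_mask(mesh, vol)
    gamma = 1.75
    field = density_from_he(mesh, he, wt_v, gamma)
    assert np.allclose(field.rho_vertex[~wt_v], 1.0)
    assert np.allclose(field.rho_vertex[wt_v], np.exp(gamma * he[wt_v]))
    assert field.rho_vertex.min() >= 1.0
    assert field.rho_vertex.max() <= np.exp(gamma) + 1e-12
    # a vertex with He == 1 inside the tumor carries exactly e^gamma
    he1 = np.ones_like(he)
    f1 = density_from_he(mesh, he1, wt_v, gamma)
    assert f1.rho_vertex[wt_v][0] == pytest.approx(np.exp(1.75))


def test_tet_density_is_vertex_mean(mesh_and_volume, rng):
    mesh, vol = mesh_and_volume
    he = rng.uniform(size=mesh.n_vertices)
    wt_v = np.ones(mesh.n_vertices, bool)
    field = density_from_he(mesh, he, wt_v, 1.0)
    i = 37
    expected = field.rho_vertex[mesh.tets[i]].mean()
    assert field.rho_tet[i] == pytest.approx(expected)


def test_local_mass_sums_to_total(mesh_and_volume):
    mesh, vol = mesh_and_volume
    he = histogram_equalize(vol, mesh)
    field = density_from_he(mesh, he, vertex_wt_mask(mesh, vol), 1.5)
    assert field.local_mass.sum() == pytest.approx(field.total_mass, rel=1e-12)


def test_density_monotone_in_gamma(mesh_and_volume):
    mesh, vol = mesh_and_volume
    he = histogram_equalize(vol, mesh)
    wt_v = vertex_wt_mask(mesh, vol)
    prev = density_from_he(mesh, he, wt_v, 0.5).rho_vertex
    for g in (1.0, 1.5, 2.0):
        cur = density_from_he(mesh, he, wt_v, g).rho_vertex
        assert np.all(cur >= prev - 1e-15)
        prev = cur


def test_negative_gamma_rejected(mesh_and_volume):
    mesh, vol = mesh_and_volume
    with pytest.raises(ValueError):
        density_from_he(mesh, np.zeros(mesh.n_vertices), np.zeros(mesh.n_vertices, bool), -0.1)


def test_normalization_exact_and_ratio_preserving(mesh_and_volume, rng):
    mesh, vol = mesh_and_volume
    he = rng.uniform(size=mesh.n_vertices)
    wt_v = rng.uniform(size=mesh.n_vertices) > 0.7
    field = density_from_he(mesh, he, wt_v, 1.75)
    normed = normalize_total_mass(field, mesh)
    assert normed.total_mass == pytest.approx(BALL_VOLUME, rel=1e-12)
    assert normed.tet_mass.sum() == pytest.approx(BALL_VOLUME, rel=1e-12)
    ratio_before = field.rho_vertex[10] / field.rho_vertex[20]
    ratio_after = normed.rho_vertex[10] / normed.rho_vertex[20]
    assert ratio_after == pytest.approx(ratio_before, rel=1e-12)


def test_uniform_density_scale_factor():
    vol = _constant_volume(5.0)
    mesh = build_tet_mesh(vol)
    field = density_from_he(mesh, np.zeros(mesh.n_vertices), np.zeros(mesh.n_vertices, bool), 0.0)
    normed = normalize_total_mass(field, mesh)
    expected_scale = BALL_VOLUME / mesh.total_volume
    assert normed.rho_vertex[0] == pytest.approx(expected_scale, rel=1e-12)


def test_gamma_rungs_cover_targets():
    rungs = density_gamma_rungs([1.0, 1.5, 1.75, 2.0], step=0.5)
    assert rungs[0] == 0.0
    for g in (1.0, 1.5, 1.75, 2.0):
        assert g in rungs
    assert rungs == sorted(rungs)
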