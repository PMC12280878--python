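"""Histogram-equalized intensities and the tumor-weighting density.

The density at a mesh vertex is exp(γ·He(v)) inside the whole-tumor region
R_w and 1 elsewhere, where He ∈ [0,1] is the histogram-equalized intensity.
Per-tet density is the mean of the four vertex densities and the local mass
at a vertex is m(v) = (1/4) Σ_{τ ∈ N(v)} ρ(τ)|τ|, so Σ_v m(v) equals the
total mass Σ_τ ρ(τ)|τ|. Before the transport solve the density is globally
rescaled so the total mass equals |B³| = 4π/3, which makes the per-tet
mass-preservation constraints jointly satisfiable.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.ndimage import map_coordinates

from .mesh import BALL_VOLUME, TetMesh
from .phantom import VoxelVolume

__all__ = [
    "DensityField",
    "intensity_cdf",
    "histogram_equalize",
    "vertex_wt_mask",
    "density_from_he",
    "normalize_total_mass",
]

N_BINS = 256


@dataclasses.dataclass
class DensityField:
    gamma: float
    he: np.ndarray  # per-vertex, in [0, 1]
    rho_vertex: np.ndarray  # per-vertex density
    rho_tet: np.ndarray  # per-tet density (4-vertex mean)
    local_mass: np.ndarray  # per-vertex m_ρ(v)
    total_mass: float  # Σ_τ ρ(τ)|τ|
    normalized: bool = False

    @property
    def tet_mass(self) -> np.ndarray:
        """ρ(τ)|τ| per tet — the mass each image tet must carry."""
        return self._tet_mass

    def _attach(self, tet_mass: np.ndarray) -> "DensityField":
        self._tet_mass = tet_mass
        return self


def intensity_cdf(values: np.ndarray):
    """Right-continuous 256-bin empirical CDF of ``values``.

    Returns a callable mapping intensities to [0, 1]; a constant input maps
    everything to 1.0 (the CDF of a point mass).
    """
    values = np.asarray(values, float).ravel()
    lo, hi = float(values.min()), float(values.max())
    if hi <= lo:
        return lambda x: np.ones_like(np.asarray(x, float))
    edges = np.linspace(lo, hi, N_BINS + 1)
    counts, _ = np.histogram(values, bins=edges)
    cdf = np.cumsum(counts) / counts.sum()

    def apply(x):
        idx = np.clip(np.searchsorted(edges[1:], np.asarray(x, float), side="left"), 0, N_BINS - 1)
        return cdf[idx]

    return apply


def histogram_equalize(volume: VoxelVolume, mesh: TetMesh, modality: int = 0) -> np.ndarray:
    """Per-vertex He ∈ [0,1]: CDF rank of the vertex's interpolated intensity.

    The CDF is estimated from brain-mask voxels of the chosen modality only;
    vertex intensities are trilinear interpolations at the voxel corners.
    """
    if not 0 <= modality < volume.n_modalities:
        raise IndexError(f"modality {modality} out of range")
    channel = volume.intensities[modality]
    cdf = intensity_cdf(channel[volume.brain_mask])
    vertex_vals = map_coordinates(
        channel, mesh.corner_index.T, order=1, mode="nearest"
    )
    return cdf(vertex_vals)


def vertex_wt_mask(mesh: TetMesh, volume: VoxelVolume) -> np.ndarray:
    """Boolean per-vertex membership in R_w: any incident voxel is WT."""
    wt = np.asarray(volume.wt_mask, bool)
    padded = np.pad(wt, 1, constant_values=False)
    # a vertex touches every voxel whose closed cell [i-1/2, i+1/2]^3 contains
    # it; works for corner, face-center and cell-center vertices alike
    eps = 1e-9
    c = mesh.corner_index
    lo = np.ceil(c - 0.5 - eps).astype(np.int64) + 1  # +1 for padding offset
    hi = np.floor(c + 0.5 + eps).astype(np.int64) + 1
    member = np.zeros(mesh.n_vertices, bool)
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                ix = np.clip(lo[:, 0] if dx == 0 else hi[:, 0], 0, padded.shape[0] - 1)
                iy = np.clip(lo[:, 1] if dy == 0 else hi[:, 1], 0, padded.shape[1] - 1)
                iz = np.clip(lo[:, 2] if dz == 0 else hi[:, 2], 0, padded.shape[2] - 1)
                member |= padded[ix, iy, iz]
    return member


def density_from_he(
    mesh: TetMesh, he: np.ndarray, wt_vertices: np.ndarray, gamma: float
) -> DensityField:
    """Evaluate ρ_γ(v) = exp(γ·He(v)) on R_w, 1 elsewhere, plus derived masses."""
    if gamma < 0:
        raise ValueError("gamma must be nonnegative")
    he = np.asarray(he, float)
    rho_vertex = np.ones(mesh.n_vertices)
    rho_vertex[wt_vertices] = np.exp(gamma * he[wt_vertices])
    rho_tet = mesh.scatter_vertex_mean(rho_vertex)
    tet_mass = rho_tet * mesh.tet_volumes
    local_mass = mesh.vertex_ring_sums(tet_mass) / 4.0
    field = DensityField(
        gamma=float(gamma),
        he=he,
        rho_vertex=rho_vertex,
        rho_tet=rho_tet,
        local_mass=local_mass,
        total_mass=float(tet_mass.sum()),
    )
    return field._attach(tet_mass)


def density_gamma_rungs(requested: list[float], step: float = 0.5) -> list[float]:
    """Continuation ladder: 0 and evenly spaced rungs up to each target γ."""
    top = max(requested, default=0.0)
    rungs = {0.0}
    rungs.update(round(step * i, 10) for i in range(1, int(np.floor(top / step)) + 1))
    rungs.update(float(g) for g in requested)
    return sorted(rungs)


def normalize_total_mass(field: DensityField, mesh: TetMesh) -> DensityField:
    """Rescale the density so Σ_τ ρ(τ)|τ| = 4π/3 exactly.

    Relative densities (and hence the transport target) are unchanged.
    """
    if field.total_mass <= 0:
        raise ValueError("total mass must be positive")
    scale = BALL_VOLUME / field.total_mass
    out = DensityField(
        gamma=field.gamma,
        he=field.he,
        rho_vertex=field.rho_vertex * scale,
        rho_tet=field.rho_tet * scale,
        local_mass=field.local_mass * scale,
        total_mass=BALL_VOLUME,
        normalized=True,
    )
    return out._attach(field.tet_mass * scale)
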