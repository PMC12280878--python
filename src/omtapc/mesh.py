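"""Tetrahedral meshes over masked voxel grids.

Every masked voxel cell is split into six tetrahedra sharing the cell's main
diagonal (Kuhn subdivision). Because every cell uses the same diagonal
direction, faces of neighboring cells match and the mesh is conforming with
no Steiner points. Vertices sit on voxel *corners*: voxel (i,j,k) with
center-based index coordinate i spans [i-1/2, i+1/2], so corner c has index
coordinate c - 1/2 and mm position (c - 1/2) * spacing.

The module also builds the two reference domains of the transport stage: the
solid cube C of side (4π/3)^(1/3) (so |C| = |B³|) and a structured ball mesh
whose boundary vertices all sit at one radius, calibrated so the mesh volume
is exactly 4π/3.
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np
from scipy import ndimage

from .phantom import VoxelVolume

__all__ = [
    "TetMesh",
    "build_tet_mesh",
    "tet_volume",
    "signed_tet_volumes",
    "cube_mesh",
    "ball_mesh",
    "CUBE_SIDE",
    "BALL_VOLUME",
]

BALL_VOLUME = 4.0 * np.pi / 3.0
CUBE_SIDE = BALL_VOLUME ** (1.0 / 3.0)

_FACE_CONN = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


def _kuhn_local_tets() -> np.ndarray:
    """Six positively oriented tets on the unit cell, as corner offsets.

    Each tet is [origin, origin+e_a, origin+e_a+e_b, (1,1,1)] for a
    permutation (a, b, c) of the axes; odd permutations are swapped to keep
    the signed volume positive. Returns an array of shape (6, 4, 3).
    """
    tets = []
    for perm in itertools.permutations(range(3)):
        v0 = np.zeros(3, dtype=np.int64)
        v1 = v0.copy()
        v1[perm[0]] = 1
        v2 = v1.copy()
        v2[perm[1]] = 1
        v3 = np.ones(3, dtype=np.int64)
        quad = np.array([v0, v1, v2, v3])
        sign = np.linalg.det(np.asarray(quad[1:] - quad[0], dtype=float))
        if sign < 0:
            quad = quad[[0, 2, 1, 3]]
        tets.append(quad)
    return np.array(tets)


_LOCAL_TETS = _kuhn_local_tets()


def _center24_template():
    """24 tets per cell: cell center, face centers, corners.

    Each vertex is (kind, offset) with kind in {"corner", "xface", "yface",
    "zface", "center"}; offsets are integer shifts of the owning voxel index.
    Unlike Kuhn-6, every tet owns the (unshared) cell-center vertex, which
    leaves each cell enough local freedom to realize per-tet volume targets
    even where the prescribed density jumps between neighboring tets.
    """
    kinds = ["xface", "yface", "zface"]
    tets = []
    cyc = [(-0.5, -0.5), (0.5, -0.5), (0.5, 0.5), (-0.5, 0.5)]
    for axis in range(3):
        others = [a for a in range(3) if a != axis]
        for side in (0, 1):
            fpos = np.zeros(3)
            fpos[axis] = side - 0.5
            foffset = np.zeros(3, int)
            foffset[axis] = side
            for k in range(4):
                corners = []
                for (a, b) in (cyc[k], cyc[(k + 1) % 4]):
                    p = fpos.copy()
                    p[others[0]], p[others[1]] = a, b
                    corners.append(p)
                quad_pos = [np.zeros(3), fpos] + corners
                sign = np.linalg.det(np.array(quad_pos[1:]) - quad_pos[0])
                c_off = [tuple((np.asarray(c) + 0.5).astype(int)) for c in corners]
                verts = [
                    ("center", (0, 0, 0)),
                    (kinds[axis], tuple(foffset)),
                    ("corner", c_off[0]),
                    ("corner", c_off[1]),
                ]
                if sign < 0:
                    verts = [verts[0], verts[1], verts[3], verts[2]]
                tets.append(verts)
    return tets


_CENTER24_TETS = _center24_template()


@dataclasses.dataclass
class TetMesh:
    """Conforming tetrahedral mesh over masked voxels.

    ``vertices`` are mm positions; ``corner_index`` holds the center-based
    voxel-grid coordinate of each vertex (vertex position / spacing).
    """

    vertices: np.ndarray  # (n, 3) float, mm
    tets: np.ndarray  # (t, 4) int, positively oriented
    spacing: tuple[float, float, float]
    corner_index: np.ndarray  # (n, 3) float, index coords of each vertex
    subdivision: str = "kuhn6"

    def __post_init__(self) -> None:
        self._tet_volumes: np.ndarray | None = None
        self._boundary_vertices: np.ndarray | None = None

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_tets(self) -> int:
        return len(self.tets)

    @property
    def tet_volumes(self) -> np.ndarray:
        """Unsigned tet volumes |τ| in mm³ (signed volumes are all positive)."""
        if self._tet_volumes is None:
            vols = signed_tet_volumes(self.vertices, self.tets)
            if np.any(vols <= 0):
                raise ValueError("mesh contains non-positively oriented tetrahedra")
            self._tet_volumes = vols
        return self._tet_volumes

    @property
    def total_volume(self) -> float:
        return float(self.tet_volumes.sum())

    @property
    def boundary_vertices(self) -> np.ndarray:
        """Sorted indices of vertices on the mesh boundary surface."""
        if self._boundary_vertices is None:
            faces = self.tets[:, [[0, 1, 2], [0, 1, 3], [0, 2, 3], [1, 2, 3]]]
            faces = np.sort(faces.reshape(-1, 3), axis=1)
            uniq, counts = np.unique(faces, axis=0, return_counts=True)
            self._boundary_vertices = np.unique(uniq[counts == 1])
        return self._boundary_vertices

    def vertex_ring_sums(self, per_tet: np.ndarray) -> np.ndarray:
        """Σ over incident tets N(v) of a per-tet quantity, for every vertex."""
        out = np.zeros(self.n_vertices)
        for k in range(4):
            np.add.at(out, self.tets[:, k], per_tet)
        return out

    def scatter_vertex_mean(self, per_vertex: np.ndarray) -> np.ndarray:
        """Mean of the four vertex values on each tet."""
        return per_vertex[self.tets].mean(axis=1)


def signed_tet_volumes(positions: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Signed volumes det[p1-p0, p2-p0, p3-p0] / 6 for every tet."""
    p0 = positions[tets[:, 0]]
    d1 = positions[tets[:, 1]] - p0
    d2 = positions[tets[:, 2]] - p0
    d3 = positions[tets[:, 3]] - p0
    return np.einsum("ij,ij->i", d1, np.cross(d2, d3)) / 6.0


def tet_volume(p0, p1, p2, p3) -> float:
    """Unsigned volume of one tetrahedron, |det[p1-p0, p2-p0, p3-p0]| / 6."""
    e = np.array([p1, p2, p3], dtype=float) - np.asarray(p0, dtype=float)
    return abs(float(np.linalg.det(e))) / 6.0


def build_tet_mesh(
    volume: VoxelVolume,
    largest_component: bool = False,
    subdivision: str = "kuhn6",
) -> TetMesh:
    """Tetrahedralize every masked voxel of ``volume``.

    ``subdivision="kuhn6"`` (default) splits each voxel into six tets sharing
    the main diagonal; ``"center24"`` splits each voxel into 24 tets using the
    cell center and the six face centers (the subdivision the transport
    solver uses — see the module docstring). The brain mask must be nonempty
    and 6-connected; with ``largest_component=True`` smaller components are
    dropped instead of raising.
    """
    mask = np.asarray(volume.brain_mask, bool)
    if not mask.any():
        raise ValueError("brain mask is empty")
    labeled, n_comp = ndimage.label(mask, structure=_FACE_CONN)
    if n_comp > 1:
        if largest_component:
            sizes = ndimage.sum_labels(mask, labeled, index=np.arange(1, n_comp + 1))
            mask = labeled == (1 + int(np.argmax(sizes)))
        else:
            raise ValueError(
                f"brain mask has {n_comp} 6-connected components; expected 1 "
                "(pass largest_component=True to keep the largest)"
            )
    return _mesh_from_mask(mask, volume.spacing, subdivision)


def _mesh_from_mask(mask: np.ndarray, spacing, subdivision: str = "kuhn6") -> TetMesh:
    if subdivision == "kuhn6":
        return _mesh_from_mask_kuhn(mask, spacing)
    if subdivision == "center24":
        return _mesh_from_mask_center24(mask, spacing)
    raise ValueError(f"unknown subdivision {subdivision!r}")


def _mesh_from_mask_kuhn(mask: np.ndarray, spacing) -> TetMesh:
    nx, ny, nz = mask.shape
    vox = np.argwhere(mask)  # (Nv, 3)
    # global corner ids on the (nx+1, ny+1, nz+1) corner grid
    stride = np.array([(ny + 1) * (nz + 1), nz + 1, 1], dtype=np.int64)

    # (Nv, 6, 4) corner ids
    corners = vox[:, None, None, :] + _LOCAL_TETS[None]  # (Nv, 6, 4, 3)
    gids = (corners * stride).sum(axis=-1)
    flat = gids.reshape(-1, 4)
    used, inverse = np.unique(flat, return_inverse=True)
    tets = inverse.reshape(-1, 4).astype(np.int64)

    ci = np.stack(
        [used // stride[0], (used % stride[0]) // stride[1], used % stride[1]], axis=1
    ).astype(float)
    corner_index = ci - 0.5  # center-based index coordinate
    vertices = corner_index * np.asarray(spacing, float)
    return TetMesh(
        vertices=vertices,
        tets=tets,
        spacing=tuple(float(s) for s in spacing),
        corner_index=corner_index,
    )


def _mesh_from_mask_center24(mask: np.ndarray, spacing) -> TetMesh:
    nx, ny, nz = mask.shape
    vox = np.argwhere(mask)
    i, j, k = vox[:, 0], vox[:, 1], vox[:, 2]

    n_corner = (nx + 1) * (ny + 1) * (nz + 1)
    n_xf = (nx + 1) * ny * nz
    n_yf = nx * (ny + 1) * nz
    n_zf = nx * ny * (nz + 1)
    off = {
        "corner": 0,
        "xface": n_corner,
        "yface": n_corner + n_xf,
        "zface": n_corner + n_xf + n_yf,
        "center": n_corner + n_xf + n_yf + n_zf,
    }

    def gid(kind, o):
        ox, oy, oz = o
        if kind == "corner":
            return (i + ox) * (ny + 1) * (nz + 1) + (j + oy) * (nz + 1) + (k + oz)
        if kind == "xface":
            return off["xface"] + (i + ox) * ny * nz + j * nz + k
        if kind == "yface":
            return off["yface"] + i * (ny + 1) * nz + (j + oy) * nz + k
        if kind == "zface":
            return off["zface"] + i * ny * (nz + 1) + j * (nz + 1) + (k + oz)
        return off["center"] + i * ny * nz + j * nz + k

    all_tets = np.stack(
        [np.stack([gid(kind, o) for kind, o in tet], axis=1) for tet in _CENTER24_TETS],
        axis=1,
    ).reshape(-1, 4)
    used, inverse = np.unique(all_tets, return_inverse=True)
    tets = inverse.reshape(-1, 4).astype(np.int64)

    # decode center-based index coordinates per unique global id
    coords = np.empty((len(used), 3))
    kind_edges = [off["xface"], off["yface"], off["zface"], off["center"]]
    sel = used < kind_edges[0]
    u = used[sel]
    coords[sel] = (
        np.stack([u // ((ny + 1) * (nz + 1)), (u // (nz + 1)) % (ny + 1), u % (nz + 1)], 1)
        - 0.5
    )
    sel = (used >= kind_edges[0]) & (used < kind_edges[1])
    u = used[sel] - off["xface"]
    coords[sel] = np.stack([u // (ny * nz) - 0.5, (u // nz) % ny, u % nz], 1)
    sel = (used >= kind_edges[1]) & (used < kind_edges[2])
    u = used[sel] - off["yface"]
    coords[sel] = np.stack([u // ((ny + 1) * nz), (u // nz) % (ny + 1) - 0.5, u % nz], 1)
    sel = (used >= kind_edges[2]) & (used < kind_edges[3])
    u = used[sel] - off["zface"]
    coords[sel] = np.stack([u // (ny * (nz + 1)), (u // (nz + 1)) % ny, u % (nz + 1) - 0.5], 1)
    sel = used >= kind_edges[3]
    u = used[sel] - off["center"]
    coords[sel] = np.stack([u // (ny * nz), (u // nz) % ny, u % nz], 1).astype(float)

    vertices = coords * np.asarray(spacing, float)
    return TetMesh(
        vertices=vertices,
        tets=tets,
        spacing=tuple(float(s) for s in spacing),
        corner_index=coords,
        subdivision="center24",
    )


def _full_cube_mesh(resolution: int, side: float, subdivision: str) -> TetMesh:
    mask = np.ones((resolution,) * 3, bool)
    h = side / resolution
    mesh = _mesh_from_mask(mask, (h, h, h), subdivision)
    center = (mesh.vertices.min(axis=0) + mesh.vertices.max(axis=0)) / 2.0
    mesh.vertices = mesh.vertices - center
    return mesh


def cube_mesh(
    resolution: int, side: float = CUBE_SIDE, subdivision: str = "center24"
) -> TetMesh:
    """Tet mesh of the axis-aligned cube of the given side, centered at 0."""
    if resolution < 2:
        raise ValueError("cube resolution must be at least 2")
    return _full_cube_mesh(resolution, side, subdivision)


def ball_mesh(resolution: int) -> TetMesh:
    """Structured tet mesh of a ball of volume exactly 4π/3.

    Built by mapping the cube mesh shell-by-shell onto the ball (the cube
    shell of sup-radius t maps to the sphere of radius t, which preserves the
    volume enclosed by each shell), then uniformly rescaled so the total mesh
    volume is exactly 4π/3. All boundary vertices end at a single radius
    slightly above 1, the volume-calibrated discrete ball radius.
    """
    mesh = cube_mesh(resolution, side=2.0, subdivision="kuhn6")
    x = mesh.vertices
    sup = np.abs(x).max(axis=1)  # ∈ [0, 1]
    norm = np.linalg.norm(x, axis=1)
    scale = np.divide(sup, norm, out=np.zeros_like(sup), where=norm > 0)
    mesh.vertices = x * scale[:, None]
    vols = signed_tet_volumes(mesh.vertices, mesh.tets)
    if np.any(vols <= 0):
        raise ValueError("ball mesh construction produced inverted tets")
    factor = (BALL_VOLUME / vols.sum()) ** (1.0 / 3.0)
    mesh.vertices = mesh.vertices * factor
    mesh._tet_volumes = None
    return mesh
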