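"""HDF5 serialization for tensors, meshes and fitted APC models."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .apc import APCClassifier, MvOPLSModel
from .mesh import TetMesh
from .transport import OMTTensor

__all__ = [
    "save_tensors",
    "load_tensors",
    "save_model",
    "load_model",
    "save_mesh",
    "load_mesh",
    "export_mesh_vtk",
]


def save_tensors(path, tensors: list[OMTTensor], config: dict | None = None) -> None:
    """Write a cohort of OMT tensors, one group per subject."""
    with h5py.File(path, "w") as f:
        if config is not None:
            f.attrs["config"] = json.dumps(config, sort_keys=True)
        for i, t in enumerate(tensors):
            sid = t.provenance.get("subject_id") or f"sub-{i:03d}"
            g = f.create_group(sid)
            g.create_dataset("intensities", data=t.intensities, compression="gzip")
            g.create_dataset("labels", data=t.labels, compression="gzip")
            g.attrs["gamma"] = t.gamma
            g.attrs["provenance"] = json.dumps(t.provenance, sort_keys=True)


def load_tensors(path) -> list[OMTTensor]:
    out = []
    with h5py.File(path, "r") as f:
        for sid in sorted(f):
            g = f[sid]
            out.append(
                OMTTensor(
                    intensities=g["intensities"][()],
                    labels=g["labels"][()],
                    gamma=float(g.attrs["gamma"]),
                    provenance=json.loads(g.attrs["provenance"]),
                )
            )
    return out


def save_model(path, clf: APCClassifier, config: dict | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["j"] = clf.j
        f.attrs["k"] = clf.k
        f.attrs["gammas"] = list(clf.gammas)
        f.attrs["view_weights"] = json.dumps(
            {f"{m}_{s}": w for (m, s), w in clf.view_weights.items()}, sort_keys=True
        )
        refs = f.create_group("train_refs")
        for (m, s), arr in clf.train_refs.items():
            refs.create_dataset(f"{m}_{s}", data=arr)
        if config is not None:
            f.attrs["config"] = json.dumps(config, sort_keys=True)
        for mod, m in clf.models.items():
            g = f.create_group(f"modality_{mod}")
            g.create_dataset("P_star", data=m.P_star)
            g.create_dataset("W_star", data=m.W_star)
            g.create_dataset("eigenvalues", data=m.eigenvalues)
            g.attrs["k"] = m.k
            g.attrs["d"] = m.d
            g.attrs["gammas"] = list(m.gammas)
            g.attrs["class_counts"] = list(m.class_counts)
            g.attrs["objective"] = m.objective
            if m.view_centers is not None:
                g.create_dataset("view_centers", data=m.view_centers)


def load_model(path) -> APCClassifier:
    with h5py.File(path, "r") as f:
        clf = APCClassifier(
            j=int(f.attrs["j"]), k=int(f.attrs["k"]), gammas=tuple(f.attrs["gammas"])
        )
        weights = json.loads(f.attrs.get("view_weights", "{}"))
        clf.view_weights = {
            (int(k.split("_")[0]), int(k.split("_")[1])): float(v)
            for k, v in weights.items()
        }
        if "train_refs" in f:
            clf.train_refs = {
                (int(k.split("_")[0]), int(k.split("_")[1])): f["train_refs"][k][()]
                for k in f["train_refs"]
            }
        for name in f:
            if not name.startswith("modality_"):
                continue
            mod = int(name.split("_")[1])
            g = f[name]
            clf.models[mod] = MvOPLSModel(
                P_star=g["P_star"][()],
                W_star=g["W_star"][()],
                k=int(g.attrs["k"]),
                d=int(g.attrs["d"]),
                gammas=tuple(g.attrs["gammas"]),
                eigenvalues=g["eigenvalues"][()],
                class_counts=tuple(int(c) for c in g.attrs["class_counts"]),
                objective=float(g.attrs["objective"]),
                view_centers=g["view_centers"][()] if "view_centers" in g else None,
            )
    return clf


def save_mesh(path, mesh: TetMesh, extra: dict | None = None) -> None:
    """Documented mesh layout: vertices (mm), tets, index coords, spacing."""
    with h5py.File(path, "w") as f:
        f.create_dataset("vertices", data=mesh.vertices)
        f.create_dataset("tets", data=mesh.tets)
        f.create_dataset("corner_index", data=mesh.corner_index)
        f.attrs["spacing"] = list(mesh.spacing)
        f.attrs["subdivision"] = mesh.subdivision
        for key, arr in (extra or {}).items():
            f.create_dataset(key, data=arr)


def load_mesh(path) -> TetMesh:
    with h5py.File(path, "r") as f:
        return TetMesh(
            vertices=f["vertices"][()],
            tets=f["tets"][()],
            spacing=tuple(f.attrs["spacing"]),
            corner_index=f["corner_index"][()],
            subdivision=str(f.attrs["subdivision"]),
        )


def export_mesh_vtk(path, mesh: TetMesh, positions: np.ndarray | None = None) -> None:
    """Legacy-ASCII VTK export for visual inspection (e.g. ParaView)."""
    pts = mesh.vertices if positions is None else positions
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\nomtapc mesh\nASCII\n")
        f.write("DATASET UNSTRUCTURED_GRID\n")
        f.write(f"POINTS {len(pts)} double\n")
        for p in pts:
            f.write(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}\n")
        f.write(f"CELLS {mesh.n_tets} {mesh.n_tets * 5}\n")
        for t in mesh.tets:
            f.write(f"4 {t[0]} {t[1]} {t[2]} {t[3]}\n")
        f.write(f"CELL_TYPES {mesh.n_tets}\n")
        f.write("\n".join(["10"] * mesh.n_tets) + "\n")
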