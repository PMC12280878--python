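"""Synthetic two-modality brain phantoms with planted tumors.

The generator emulates skull-stripped, co-registered, intensity-normalized
volumes (two channels standing in for T1CE and T2WI): an ellipsoidal brain
with smooth background texture, a spherical whole-tumor (WT) region with
elevated intensity, and a class-conditional mean shift inside the tumor on
channel 0 whose magnitude is ``effect_size`` noise standard deviations.
Channel 1 carries no class effect, so multiview models must learn that the
discriminative signal lives in one view.

Intensities are clipped to [0, 1000], the normalization range the rest of
the pipeline assumes.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

__all__ = [
    "PhantomSpec",
    "VoxelVolume",
    "generate_phantom",
    "generate_cohort",
    "save_phantom_nifti",
    "save_cohort",
]

INTENSITY_RANGE = (0.0, 1000.0)

#: background composition, in intensity units: mean level, amplitude of the
#: smooth texture (unit-SD Gaussian noise blurred with TEXTURE_SIGMA voxels),
#: and the additive tumor contrast applied to both channels. The texture
#: exists to keep histogram equalization nondegenerate; its amplitude stays
#: below the white-noise SD so that ``effect_size`` (a shift in noise-SD
#: units) keeps its meaning against the total between-subject variability.
BACKGROUND_LEVEL = 400.0
TEXTURE_AMPLITUDE = 20.0
TEXTURE_SIGMA = 2.5
TUMOR_CONTRAST = 180.0


@dataclasses.dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a single phantom subject.

    ``effect_size`` is the class-conditional mean intensity shift inside the
    tumor on channel 0, in units of ``noise_sd``.
    """

    grid_shape: tuple[int, int, int] = (32, 32, 32)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    brain_axes: tuple[float, float, float] = (13.0, 11.5, 10.0)
    tumor_center: tuple[float, float, float] | None = None
    tumor_radius: float = 4.0
    class_label: int = 0
    effect_size: float = 0.0
    noise_sd: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s < 16 for s in self.grid_shape):
            raise ValueError("grid_shape must be at least 16 per axis")
        if self.tumor_radius < 2.0:
            raise ValueError("tumor_radius must be at least 2 voxels")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.effect_size < 0:
            raise ValueError("effect_size must be nonnegative")
        if self.class_label not in (0, 1):
            raise ValueError("class_label must be 0 or 1")

    @property
    def brain_center(self) -> np.ndarray:
        return (np.asarray(self.grid_shape, float) - 1.0) / 2.0

    def resolved_tumor_center(self) -> np.ndarray:
        if self.tumor_center is None:
            return self.brain_center
        return np.asarray(self.tumor_center, float)


@dataclasses.dataclass
class VoxelVolume:
    """Two-channel intensity grid with brain and whole-tumor masks.

    ``intensities`` has shape ``(2, nx, ny, nz)``; masks are boolean grids of
    shape ``(nx, ny, nz)``; ``spacing`` is in mm.
    """

    intensities: np.ndarray
    brain_mask: np.ndarray
    wt_mask: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.intensities.ndim != 4 or self.intensities.shape[0] != 2:
            raise ValueError("intensities must have shape (2, nx, ny, nz)")
        if self.brain_mask.shape != self.intensities.shape[1:]:
            raise ValueError("brain_mask shape mismatch")
        if self.wt_mask.shape != self.brain_mask.shape:
            raise ValueError("wt_mask shape mismatch")
        if np.any(self.wt_mask & ~self.brain_mask):
            raise ValueError("wt_mask must be contained in brain_mask")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.brain_mask.shape

    @property
    def n_modalities(self) -> int:
        return self.intensities.shape[0]


def _fibonacci_directions(n: int = 256) -> np.ndarray:
    i = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    rho = np.sqrt(1.0 - z**2)
    return np.stack([rho * np.cos(phi), rho * np.sin(phi), z], axis=1)


_SPHERE_DIRS = _fibonacci_directions()


def tumor_inside_brain(
    center, radius, brain_center, brain_axes, margin: float = 0.97
) -> bool:
    """Whether the sphere (center, radius) lies inside the brain ellipsoid.

    Checked on a fixed direction sample of the sphere surface with a safety
    margin on the ellipsoid functional.
    """
    pts = np.asarray(center, float) + radius * _SPHERE_DIRS
    q = ((pts - np.asarray(brain_center, float)) / np.asarray(brain_axes, float)) ** 2
    return float(q.sum(axis=1).max()) < margin


def _tumor_inside_brain(spec: PhantomSpec) -> bool:
    return tumor_inside_brain(
        spec.resolved_tumor_center(), spec.tumor_radius, spec.brain_center, spec.brain_axes
    )


def _index_grid(shape: tuple[int, int, int]) -> tuple[np.ndarray, ...]:
    return np.meshgrid(*(np.arange(s, dtype=float) for s in shape), indexing="ij")


def generate_phantom(spec: PhantomSpec) -> VoxelVolume:
    """Deterministically generate one two-channel phantom from ``spec``.

    The same spec (including seed) always yields bit-identical arrays.
    """
    if not _tumor_inside_brain(spec):
        raise ValueError("tumor sphere must lie strictly inside the brain ellipsoid")

    rng = np.random.default_rng(spec.seed)
    xi, yi, zi = _index_grid(spec.grid_shape)
    c = spec.brain_center
    axes = np.asarray(spec.brain_axes, float)
    brain = (
        ((xi - c[0]) / axes[0]) ** 2
        + ((yi - c[1]) / axes[1]) ** 2
        + ((zi - c[2]) / axes[2]) ** 2
    ) <= 1.0

    tc = spec.resolved_tumor_center()
    r2 = (xi - tc[0]) ** 2 + (yi - tc[1]) ** 2 + (zi - tc[2]) ** 2
    wt = (r2 <= spec.tumor_radius**2) & brain

    channels = np.zeros((2, *spec.grid_shape))
    for ch in range(2):
        texture = gaussian_filter(rng.standard_normal(spec.grid_shape), TEXTURE_SIGMA)
        sd = texture.std()
        if sd > 0:
            texture /= sd
        img = BACKGROUND_LEVEL + TEXTURE_AMPLITUDE * texture
        img += rng.normal(scale=spec.noise_sd, size=spec.grid_shape)
        img[wt] += TUMOR_CONTRAST
        if ch == 0:
            img[wt] += spec.class_label * spec.effect_size * spec.noise_sd
        img[~brain] = 0.0
        channels[ch] = np.clip(img, *INTENSITY_RANGE)

    return VoxelVolume(
        intensities=channels,
        brain_mask=brain,
        wt_mask=wt,
        spacing=spec.spacing,
    )


def generate_cohort(
    n: int,
    class_balance: float = 0.5,
    effect_size: float = 3.0,
    seed: int = 0,
    grid_shape: tuple[int, int, int] = (18, 18, 18),
    brain_axes: tuple[float, float, float] = (7.0, 6.5, 6.0),
    tumor_radius_range: tuple[float, float] = (2.8, 3.8),
    noise_sd: float = 30.0,
) -> list[tuple[VoxelVolume, int]]:
    """Generate ``n`` phantoms with randomized tumor geometry and labels.

    The number of label-1 subjects is ``round(n * class_balance)`` (banker's
    rounding via :func:`round`), clamped so both classes have at least one
    subject; label order is shuffled deterministically under ``seed``.
    """
    if n < 2:
        raise ValueError("cohort needs n >= 2 (one subject per class)")
    if not 0.0 < class_balance < 1.0:
        raise ValueError("class_balance must lie in (0, 1)")

    rng = np.random.default_rng(seed)
    n_pos = int(round(n * class_balance))
    n_pos = min(max(n_pos, 1), n - 1)
    labels = np.array([1] * n_pos + [0] * (n - n_pos))
    rng.shuffle(labels)

    center0 = (np.asarray(grid_shape, float) - 1.0) / 2.0
    axes = np.asarray(brain_axes, float)
    subjects: list[tuple[VoxelVolume, int]] = []
    for i in range(n):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        radius = float(rng.uniform(*tumor_radius_range))
        # rejection-sample a center whose inflated sphere stays inside the brain
        sub_rng = np.random.default_rng(sub_seed)
        while True:
            offset = sub_rng.uniform(-0.35, 0.35, size=3) * axes
            if tumor_inside_brain(center0 + offset, radius, center0, axes, margin=0.93):
                break
        spec = PhantomSpec(
            grid_shape=grid_shape,
            brain_axes=tuple(axes),
            tumor_center=tuple(center0 + offset),
            tumor_radius=radius,
            class_label=int(labels[i]),
            effect_size=effect_size,
            noise_sd=noise_sd,
            seed=sub_seed,
        )
        subjects.append((generate_phantom(spec), int(labels[i])))
    return subjects


def _nifti_affine(spacing: tuple[float, float, float]) -> np.ndarray:
    affine = np.eye(4)
    affine[0, 0], affine[1, 1], affine[2, 2] = spacing
    return affine


def save_phantom_nifti(volume: VoxelVolume, out_dir: str | Path, subject_id: str) -> dict[str, str]:
    """Write one phantom as NIfTI files; returns the file map."""
    import nibabel as nib

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    affine = _nifti_affine(volume.spacing)
    files = {}
    for name, arr in (
        ("mod0", volume.intensities[0]),
        ("mod1", volume.intensities[1]),
        ("brain_mask", volume.brain_mask.astype(np.uint8)),
        ("wt_mask", volume.wt_mask.astype(np.uint8)),
    ):
        path = out_dir / f"{subject_id}_{name}.nii.gz"
        nib.save(nib.Nifti1Image(np.asarray(arr, dtype=np.float32), affine), path)
        files[name] = str(path)
    return files


def load_phantom_nifti(files: dict[str, str], spacing=None) -> VoxelVolume:
    """Load a phantom from the file map written by :func:`save_phantom_nifti`."""
    import nibabel as nib

    imgs = {k: nib.load(v) for k, v in files.items()}
    if spacing is None:
        zooms = imgs["mod0"].header.get_zooms()[:3]
        spacing = tuple(float(z) for z in zooms)
    return VoxelVolume(
        intensities=np.stack(
            [np.asarray(imgs["mod0"].dataobj, float), np.asarray(imgs["mod1"].dataobj, float)]
        ),
        brain_mask=np.asarray(imgs["brain_mask"].dataobj) > 0.5,
        wt_mask=np.asarray(imgs["wt_mask"].dataobj) > 0.5,
        spacing=spacing,
    )


def save_cohort(
    subjects: list[tuple[VoxelVolume, int]], out_dir: str | Path, seed: int = 0
) -> Path:
    """Write a cohort to NIfTI plus a CSV manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    rows = []
    for i, (vol, label) in enumerate(subjects):
        sid = f"sub-{i:03d}"
        files = save_phantom_nifti(vol, out_dir, sid)
        rows.append({"subject_id": sid, "label": label, "seed": seed, **files})
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
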