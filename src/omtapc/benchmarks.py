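"""Bundled benchmark definitions: the reference phantom and study runs.

These fix the desk-scale study conditions: a 48³ two-modality phantom with
an off-center bright tumor for the transport feasibility and γ-sweep
checks, the structured ball fixture for the uniform-density limit, and the
60-subject classification benchmark (see
:data:`omtapc.pipeline.DEFAULT_CONFIG`).
"""

from __future__ import annotations

import numpy as np

from .density import histogram_equalize, vertex_wt_mask
from .mesh import ball_mesh, build_tet_mesh
from .phantom import PhantomSpec, VoxelVolume, generate_cohort, generate_phantom
from .pipeline import DEFAULT_CONFIG, run_pipeline
from .transport import (
    OMTMap,
    compose_to_cube,
    resample_to_tensor,
    solve_gamma_ladder,
    solve_volume_preserving_cube_map,
    voxel_tensor,
)

__all__ = [
    "REFERENCE_PHANTOM",
    "SWEEP_GAMMAS",
    "reference_phantom",
    "gamma_sweep",
    "ball_fixture_mesh",
    "classification_benchmark",
    "null_calibration",
    "permutation_check",
    "SMOKE_CONFIG",
]

#: the bundled 48³ phantom used by the transport benchmarks
REFERENCE_PHANTOM = PhantomSpec(
    grid_shape=(48, 48, 48),
    brain_axes=(15.0, 13.0, 11.0),
    tumor_center=(26.0, 22.0, 24.0),
    tumor_radius=5.0,
    class_label=1,
    effect_size=3.0,
    noise_sd=30.0,
    seed=20240917,
)

#: γ values of the augmentation sweep (training uses γ = 1.75)
SWEEP_GAMMAS = (1.0, 1.5, 1.75, 2.0)

#: a small, fast end-to-end configuration (determinism / smoke checks)
SMOKE_CONFIG: dict = {
    "seed": 424242,
    "cohort": {
        "n": 8,
        "effect_size": 3.0,
        "grid_shape": [16, 16, 16],
        "brain_axes": [6.0, 5.5, 5.0],
        "tumor_radius_range": [2.0, 3.0],
    },
    "tensorize": {"method": "omt", "m_hat": 24, "cube_resolution": 6},
    "split": {"test_fraction": 0.25},
}


def reference_phantom() -> VoxelVolume:
    return generate_phantom(REFERENCE_PHANTOM)


def gamma_sweep(
    gammas=SWEEP_GAMMAS,
    m_hat: int = 64,
    cube_resolution: int = 12,
    tol: float = 1e-2,
    **solver_kwargs,
):
    """Solve the reference phantom at every sweep γ and tensorize each map.

    Returns (maps, wt_fractions): {γ: OMTMap} and {γ: WT voxel fraction of
    the m̂³ tensor}. The whole sweep shares one continuation ladder.
    """
    volume = reference_phantom()
    mesh = build_tet_mesh(volume, subdivision="center24")
    he = histogram_equalize(volume, mesh)
    wt_v = vertex_wt_mask(mesh, volume)
    solver_kwargs.setdefault("max_iter", 10)
    solver_kwargs.setdefault("inner_steps", 2)
    solver_kwargs.setdefault("cg_maxiter", 300)
    solver_kwargs.setdefault("polish_iters", (8, 10))
    maps = solve_gamma_ladder(mesh, he, wt_v, list(gammas), tol=tol, **solver_kwargs)
    cube_map = solve_volume_preserving_cube_map(cube_resolution, tol=tol)
    wt_fractions = {}
    for g, omt_map in sorted(maps.items()):
        composed = compose_to_cube(omt_map, cube_map, require_converged=False)
        tensor = resample_to_tensor(composed, volume, m_hat, gamma=g)
        wt_fractions[g] = tensor.wt_fraction
    return maps, wt_fractions


def ball_fixture_mesh(resolution: int = 10):
    """Structured ball mesh of volume 4π/3 (uniform-density fixed point)."""
    return ball_mesh(resolution)


def classification_benchmark(seed: int | None = None) -> dict:
    """The bundled 60-subject benchmark; returns the metrics dict."""
    cfg = dict(DEFAULT_CONFIG)
    if seed is not None:
        cfg = {**cfg, "seed": int(seed)}
    return run_pipeline(cfg).metrics


def _identity_auc(n: int, effect_size: float, seed: int, permute: bool = False) -> float | None:
    """Held-out APC AUC on raw-grid (identity-tensorized) phantom crops.

    Uses light 16³ cohorts: these calibration checks ask whether chance-level
    inputs yield chance-level output, which is geometry-independent.
    """
    from .apc import APCClassifier, crop_wt_tensor
    from .metrics import auc

    subjects = generate_cohort(
        n=n, effect_size=effect_size, seed=seed,
        grid_shape=(16, 16, 16), brain_axes=(6.0, 5.5, 5.0),
        tumor_radius_range=(2.0, 3.0),
    )
    crops = [crop_wt_tensor(voxel_tensor(v), m=32) for v, _ in subjects]
    labels = [l for _, l in subjects]
    rng = np.random.default_rng(seed + 17)
    idx = rng.permutation(n)
    n_test = max(2, int(round(0.2 * n)))
    test, train = idx[:n_test], idx[n_test:]
    train_labels = [labels[i] for i in train]
    if permute:
        train_labels = list(rng.permutation(train_labels))
    if len(set(train_labels)) < 2 or len(set(labels[i] for i in test)) < 2:
        return None
    clf = APCClassifier(j=8, k=2).fit([crops[i] for i in train], train_labels)
    scores = [clf.predict_proba(crops[i]) for i in test]
    return auc([labels[i] for i in test], scores)


def null_calibration(n_replicates: int = 20, n: int = 30, seed: int = 0) -> float:
    """Mean held-out AUC over replicate cohorts with zero class effect.

    Uses identity tensorization (raw phantom grids): the transport map is
    deterministic and label-independent, so it cannot introduce label
    leakage; the null calibration isolates the classifier itself.
    """
    vals = []
    for r in range(n_replicates):
        a = _identity_auc(n=n, effect_size=0.0, seed=seed + 1000 + r)
        if a is not None:
            vals.append(a)
    return float(np.mean(vals))


def permutation_check(n_permutations: int = 3, n: int = 60, seed: int = 0) -> float:
    """Mean held-out AUC after permuting training labels (effect size 3)."""
    vals = []
    for r in range(n_permutations):
        a = _identity_auc(n=n, effect_size=3.0, seed=seed + 2000 + r, permute=True)
        if a is not None:
            vals.append(a)
    return float(np.mean(vals))
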