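"""Tensorize one subject: mesh, density, transport, cube composition.

Runs the full geometric chain for a single phantom at γ = 1.75 and prints
the transport diagnostics: the per-tet mass residual (how well the map
preserves the weighted volume of every tetrahedron), the discrete image
volume (exactly 4π/3 by construction) and the tumor share of the resulting
tensor, which grows with γ.
"""

import numpy as np

from omtapc import PhantomSpec, generate_phantom, tensorize_subject

volume = generate_phantom(
    PhantomSpec(grid_shape=(20, 20, 20), brain_axes=(7.5, 7.0, 6.5),
                tumor_radius=3.0, class_label=1, effect_size=3.0, seed=5)
)

for gamma in (1.0, 1.75):
    tensor, omt_map = tensorize_subject(
        volume, gamma=gamma, m_hat=32, cube_resolution=8,
        tol=0.075, max_iter=10, inner_steps=2, target_factor=0.8,
    )
    print(f"gamma={gamma:4.2f}: max mass residual {omt_map.max_mass_residual:.3e}  "
          f"image volume {omt_map.image_volume:.6f} (4π/3 = {4*np.pi/3:.6f})  "
          f"WT tensor fraction {tensor.wt_fraction:.3f}")

# The WT fraction at γ=1.75 exceeds the γ=1.0 one: the density exp(γ·He)
# inflates the tumor's share of the transported volume, which is the
# mechanism the tensorization uses to enhance the tumor region.
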