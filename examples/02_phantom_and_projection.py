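"""Phantom generation, forward projection, and the detector model.

Generates the flat layered specimen phantom, projects it with a tilted
rotation axis, pushes the line integrals through the raw-intensity
detector model (flat field, dark current, optional Poisson noise), and
inverts the model again.
"""

import numpy as np

from auglam import (
    ScanGeometry,
    ScanMode,
    flat_specimen_preset,
    forward_project,
    make_phantom,
    normalize_flat_dark,
    simulate_raw,
)

spec = flat_specimen_preset(aspect_ratio=4.0, seed=1, nx=64)
truth = make_phantom(spec)
nx, ny, nz = spec.grid_shape
print(f"phantom: {nx} x {ny} x {nz} voxels, "
      f"mu in [{truth.data.min():.3f}, {truth.data.max():.3f}] / mm")

geom = ScanGeometry(mode=ScanMode.CL, sdd=500, sod=500, theta=29.8,
                    detector_pixel=1.0, detector_shape=(72, 104),
                    n_projections=8)
stack = forward_project(truth, geom)
print(f"projections: {stack.frames.shape} (angle, rows, cols), "
      f"max line integral = {stack.frames.max():.3f}")

raw, flat, dark = simulate_raw(stack, flat_level=1e4, dark_level=100.0,
                               poisson=True, seed=1)
recovered = normalize_flat_dark(raw, flat, dark)
err = np.mean(np.abs(recovered.frames - stack.frames))
print(f"raw counts in [{raw.frames.min():.0f}, {raw.frames.max():.0f}]")
print(f"mean |recovered - true| line integral after flat/dark correction "
      f"with Poisson noise at 1e4 counts: {err:.4f}")
print()
print("The correction inverts I = (flat - dark) exp(-p) + dark; residuals")
print("are photon noise only (exact to machine precision with noise off).")
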