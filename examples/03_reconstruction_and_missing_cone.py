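"""Filtered backprojection and the missing-cone signature.

Reconstructs a uniform sphere from a θ=0 scan (quantitative attenuation
recovery), then a smooth flat phantom from a tilted-axis scan, and shows
that the laminographic reconstruction leaves the double cone of
half-angle θ around k_z essentially empty while white noise fills it in
proportion to its solid angle.
"""

import numpy as np

from auglam import (
    GridSpec,
    ScanGeometry,
    ScanMode,
    Volume3D,
    cone_energy_ratio,
    forward_project,
    missing_cone_fraction,
    reconstruct,
)

# --- sphere: does FBP recover mu quantitatively?
n, radius, mu = 48, 16.0, 0.05
grid = GridSpec((n, n, n), 1.0)
X, Y, Z = grid.coords()
sphere = Volume3D(np.where(X**2 + Y**2 + Z**2 <= radius**2, mu, 0.0), 1.0)
geom = ScanGeometry(mode=ScanMode.CT, sdd=500, sod=500, detector_pixel=1.0,
                    detector_shape=(53, 73), n_projections=180,
                    angular_range=360)
rec = reconstruct(forward_project(sphere, geom), geom, grid)
center = rec.data[n // 2, n // 2, n // 2]
print(f"sphere phantom: true mu = {mu}, reconstructed center = {center:.4f} "
      f"({abs(center - mu) / mu * 100:.1f}% error)")

# --- tilted axis: the double cone goes unsampled
theta = 29.8
grid = GridSpec((32, 64, 64), 1.0)
X, Y, Z = grid.coords()
rng = np.random.default_rng(0)
data = np.zeros(grid.shape)
for _ in range(8):
    cx, cy, cz = *rng.uniform(-20, 20, 2), rng.uniform(-6, 6)
    s = rng.uniform(1.5, 3.0)
    data += 0.05 * np.exp(-(((X - cx) ** 2 + (Y - cy) ** 2 + (Z - cz) ** 2)
                            / (2 * s**2)))
vol = Volume3D(data, 1.0)
geom = ScanGeometry(mode=ScanMode.CL, sdd=500, sod=500, theta=theta,
                    detector_pixel=1.0, detector_shape=(72, 112),
                    n_projections=180, angular_range=360)
cl = reconstruct(forward_project(vol, geom), geom, grid)

noise = Volume3D(np.random.default_rng(1).normal(size=(64, 64, 64)), 1.0)
print(f"cone energy ratio at theta={theta} deg:")
print(f"  ground truth phantom : {cone_energy_ratio(vol, theta):.4f}")
print(f"  CL reconstruction    : {cone_energy_ratio(cl, theta):.4f}")
print(f"  white noise          : {cone_energy_ratio(noise, theta):.4f} "
      f"(solid-angle fraction 1 - cos(theta) = {missing_cone_fraction(theta):.4f})")
print()
print("The tilted-axis scan cannot measure frequencies within the double")
print("cone around the rotation axis; its reconstruction is depleted there.")
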