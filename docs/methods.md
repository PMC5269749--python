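# Methods

This note documents the model behind `auglam`, its conventions, the
defaults and why they were chosen, and what the simulations do and do
not show about real scans.

## Imaging model

All projections are **parallel-beam**. The physical experiment the
package emulates is cone-beam, but the Fourier-sampling argument that
motivates augmented laminography is exact in the parallel model:
conventional parallel-beam CT is the θ=0 limiting case, and cone-beam
magnification enters only as voxel-size bookkeeping (object-side
detector pitch = detector pitch / M, M = SDD/SOD). This keeps the
missing-cone geometry exact and every fusion step verifiable against
closed forms. Polychromatic effects (beam hardening, filtration),
scatter and detector blur are not modeled.

Conventions: arrays are `(z, y, x)` with one TIFF page per z slice;
physical vectors are `(x, y, z)`; lengths in mm, angles in degrees at
every interface; voxels are isotropic. The rotation axis is the object
z axis. At rotation angle φ the beam direction is

```
b(φ) = (cos θ cos φ, cos θ sin φ, sin θ)
```

so θ=0 gives an in-plane beam (CT) and θ=90° would send the beam along
the axis (plain radiography). The detector frame is `e_u = (−sin φ,
cos φ, 0)` (perpendicular to both beam and axis) and `e_v = b × e_u`
(carrying the axis projection, `e_v·ẑ = cos θ`).

A frequency direction is sampled iff it is perpendicular to some beam
direction; solving `k̂·b(φ) = 0` shows the unsampled set is exactly the
double cone of half-angle θ about k_z, with solid-angle fraction
`1 − cos θ`.

## Projector

Line integrals are computed by trilinear-interpolated ray marching at a
step of 0.5 voxel (configurable; steps above one voxel are rejected).
Rotation is implemented as ray-direction rotation with the object held
fixed. Each ray's integration window is clipped to its bounding-box
intersection, so flat specimens cost what their thickness dictates.
Sampling runs in float32 (coordinate rounding ~1e-5 voxel, far below
the interpolation error); sums accumulate in float64.

The detector model is `I = (flat − dark)·exp(−p) + dark` per pixel with
optional Poisson noise on the pre-dark term; the returned flat/dark
frames are noise-free calibration references, as if averaged over many
acquisitions. Correction inverts this as `p = −ln((I − dark)/(flat −
dark))`; non-positive transmittances (possible under noise) clamp to a
configurable maximum attenuation (default 20) and are counted in a log
message.

## Reconstruction

Filtered backprojection, generalized to the tilted axis. Frames are
filtered row-wise along u only (the axis direction is left unfiltered)
with the discrete Ram-Lak kernel assembled in the spatial domain
(h[0] = 1/4, h[odd n] = −1/(πn)², zero-padded FFT convolution), which
avoids the DC bias of sampling |k| directly; a Shepp-Logan window is
optional. Backprojection is voxel-driven with bilinear detector
sampling.

The voxel weight is `cos θ · π / n_projections` for half- or full-turn
scans. Derivation: writing the reconstruction as `c ∫ dφ Q_φ(u(r),
v(r))` and changing variables to the 3D frequency `k = k_u e_u + k_v
e_v`, the Jacobian of `(φ, k_u, k_v) → k` is `|k_u| cos θ`; the ramp
cancels `|k_u|`, each out-of-cone frequency is covered twice per full
turn, hence `c = cos θ / 2` over 360°. At θ=0 this is textbook
parallel-beam FBP (a delta phantom reconstructs to unit integral); the
sphere-phantom test recovers μ at the center to ~0.2%. Inside the cone
nothing is measured and the reconstruction is depleted there — the
laminographic blur.

`cone_energy_ratio` measures that depletion: spectral energy inside the
double cone divided by energy in the **inscribed Nyquist ball** (DC
excluded in both). Restricting to the ball rather than the full
rectangular frequency box is deliberate: only then does an isotropic
(white-noise) spectrum score the cone's solid-angle fraction
`1 − cos θ`, making the number interpretable as "fraction of
directions lost". The analytic cone mask's voxel-count fraction is
referenced to the same ball.

## Fusion

The CT volume is resampled onto the CL grid by trilinear interpolation
under a known rigid+scale transform (synthetic data makes manual
alignment unnecessary; full registration is out of scope, but the
resampler is verified to sub-quarter-voxel accuracy against a
correlation peak). Intensities are then matched by the affine fit
`a·ct + b ≈ cl` restricted to the frequency region both scans sample
reliably: the ball of radius `ct_band_radius · Nyquist` minus the
missing cone, **including DC** (without DC the offset b would be
unidentifiable). With both reconstructions properly normalized the fit
typically returns a ≈ 1, b ≈ 0.

The replacement mask is built either analytically (the cone intersected
with the CT band, never beyond it — no CT noise is implanted past the
CT's resolution) or data-driven: threshold `|F_cl| < τ·|F_ct|` within
the band, median filter, symmetrize with `mask(k) ← mask(k) ∨
mask(−k)`, always excluding DC. Two defaults matter here:

- **τ = 0.5.** On simulated pairs the two populations separate
  cleanly: outside the cone (within the band) the amplitude ratio is
  ≈ 1 and above (lower decile ≈ 1.0), inside the cone it sits well
  below (upper quartile ≈ 0.6). The default marks coefficients where
  the CL amplitude falls clearly — more than twofold — below the CT's,
  i.e. it sits in the gap between the two distributions rather than at
  either tail. At small grid sizes the laminographic residual inside
  the cone is a sizable fraction of the CT amplitude (see
  *Limitations*), so a much smaller τ would select nothing.
- **Median kernel isotropic in physical frequency.** On the default
  128×128×32 grid the k_z bins are 4× coarser than k_x/k_y bins; a
  cubic kernel would be 4× taller physically in k_z than laterally and
  would erase the few-bin-tall cone∩band region. The kernel edge is
  `median_size` bins on the finest-sampled axis, scaled down (min 1)
  on coarser axes; on cubic grids this is the ordinary cubic kernel.

Fusion itself is `F_al = (1−w)·F_cl + w·F_ct` with unitary FFTs; `w`
is the binary mask, optionally apodized by a raised cosine over a
configurable width (default 2 voxels) to suppress ringing at the mask
boundary — the hard mask (width 0) is the fidelity reference, with
exact out-of-mask energy preservation and idempotence. Masks must be
inversion symmetric; the output is the real part of the inverse
transform and the discarded imaginary part is checked to be < 1e-8 of
the output RMS.

## Synthetic specimens

`flat_specimen_preset` emulates the study regime: a flat slab
(aspect ratio 4 by default, grid 128×128×32) of three layers
(μ = 0.02/0.035/0.025 mm⁻¹) with a clear lateral margin, containing
seeded geometric primitives (spheres, boxes, cylinders; μ between 0.05
and 0.12 mm⁻¹) plus one fixed high-contrast calibration disk whose top
face and rim provide known axial and in-plane edges for the resolution
probes. Rendering decides voxel membership at voxel centers —
primitive volumes then match closed forms exactly — with an optional
supersampling flag for smoothed edges. Generation is byte-reproducible
for a fixed (spec, seed).

What the preset does **not** emulate: realistic fossil textures or
sediment statistics, partial-volume material mixtures, or any noise
beyond the Poisson detector model. Passing tests therefore demonstrate
the correctness and the relative behavior of the algorithms under the
stated geometry, not performance on any particular real specimen.

## The simulated study

The default experiment mirrors a microfocus scanner: SDD 1135 mm,
0.2 mm detector pitch, CL at SOD 137 mm (M = 8.28, θ = 29.8°) and CT at
five times that SOD (M = 1.66), so the CL voxels are 5× finer than the
CT's and `ct_band_radius = 1/5`. Both scans cover 360°.

Problem sizes are scaled to desk scale as the package's own choice: the
128×128×32 phantom needs ≈ 286 half-turn views for full angular
sampling of its lateral extent, and the default of 360 views per full
turn (≈ 180 unique directions) is slightly under that — adequate for
the fusion study, where the residual angular streaks affect CL and AL
alike. A full study runs in about two minutes; the reduced 64-voxel
variant in the examples in seconds.

On this study, across seeds, the fused volume beats both inputs in
RMSE against ground truth, keeps CL's sub-voxel in-plane edge widths
(the upsampled CT needs ~8 voxels), pulls the axial profile error from
the CL level toward the CT level, and raises the in-cone spectral
energy from a few percent to roughly the ground-truth level.

A note on edge metrics: the 10–90% edge width is referenced to a
profile's own end levels and is meaningful only where a method resolves
the edge at all. The laminographic scan erases the laterally extended
calibration edge *outright* (a flat, slightly wiggly profile), for
which the width metric degenerates; the per-probe profile RMS error
against ground truth is the faithful blur measure in that regime, and
the method report carries both.

## Numerical choices and degenerate inputs

- FFTs are unitary (`norm="ortho"`); masks are stored DC-centered.
- Ray step 0.5 voxel, trilinear volume interpolation, bilinear detector
  interpolation; reconstruction accumulates in float64.
- Geometry validation rejects SOD > SDD, θ outside [0, 90), CT mode
  with θ ≠ 0, and non-positive extents; frames narrower than 4 pixels
  cannot be ramp-filtered; flat = dark anywhere is a degenerate
  calibration.
- An all-true or all-false raw threshold mask is a warning, not an
  error (legitimate for identical inputs); an asymmetric mask passed to
  `fuse` is an error (it would break realness).
- Ties in phantom rendering: primitives overwrite layers in list
  order; membership is decided at voxel centers, boundary exactly on
  the surface counts as inside (`≤`).

## Limitations

- **Small-grid spectral leakage.** With only 32 z-slices the cone∩band
  region is ~3 k_z bins tall, and the laminographic blur tails that
  extend past the reconstruction window re-leak energy into the first
  k_z shell when the volume is windowed for the FFT. Even an ideal
  operator that zeroes the cone exactly on a finely padded spectrum
  shows a native-grid cone-energy ratio of ≈ 0.03 for the default
  phantom after cropping back; the FBP reconstruction measures
  ≈ 0.03–0.06 depending on the seed. At realistic volume sizes
  (hundreds of slices) the cone is dozens of bins tall and this floor
  becomes negligible. The same effect is why the data-driven threshold
  needs τ ≈ 0.5 here where a real-scale study could use a stricter
  value.
- The parallel-beam model ignores cone-beam artifacts (FDK weighting,
  variable magnification across the object depth).
- Registration is by known transform (+ verification); real correlative
  studies need actual alignment, whose residual errors the paper's own
  fused images show as artifacts.
- The fusion blends with a single scalar weight field; no per-frequency
  confidence weighting of the two acquisitions is attempted.
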