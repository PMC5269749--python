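# auglam — augmented laminography simulation & Fourier fusion

**auglam** is a toolkit for *augmented laminography* (AL), a correlative
3D x-ray imaging scheme for flat, laterally extended specimens such as
compressed fossils embedded in slabs of sediment.

Conventional computed tomography (CT) of a wide, thin object forces a
low geometric magnification: the whole object must fit on the detector
laterally at every rotation angle, or the reconstruction suffers
truncation artifacts. Computed laminography (CL) tilts the rotation
axis by the *laminographic angle* θ away from the conventional
orientation, so the beam always crosses the slab near its thin
direction. That permits much higher magnification — at a price: in the
parallel-beam model a frequency direction **k** is only sampled if it is
perpendicular to some beam direction, and tilting leaves a **double cone
of half-angle θ around k_z unsampled**. The missing cone occupies a
solid-angle fraction

```
f(θ) = 1 − cos θ        (θ = 0: CT, complete sampling; θ = 90°: radiography)
```

of frequency space (≈ 13.2% at θ = 29.8°) and causes the characteristic
laminographic blurring of coarse and axial structures.

**Augmented laminography** fills the missing cone of a high-resolution
CL reconstruction with the Fourier coefficients of a co-registered,
lower-resolution CT scan of the same object, restricted to the band the
CT actually resolves:

```
F_AL(k) = (1 − w(k)) · F_CL(k) + w(k) · F_CT(k),
w = 1 on the missing region (|k| ≤ CT band), 0 elsewhere
```

with the replacement region found either analytically (the cone) or
data-driven — thresholding the amplitude ratio |F_CL|/|F_CT| and median
filtering the binary mask. The package provides everything needed to
study this end to end without real scan data: seeded flat-slab
phantoms, a tilted-axis parallel-beam projector, the raw-intensity
detector model with flat-field/dark-frame correction, filtered
backprojection for arbitrary tilt, the Fourier fusion itself, and
quantitative quality metrics.

## Worked example

`examples/04_augmented_laminography.py` runs a reduced (64-voxel) study:

```
            rmse    psnr_db  inplane_edge_width  axial_edge_width  inplane_profile_rmse  axial_profile_rmse  cone_energy_ratio
method
CL      0.016434  17.013833            0.601863          3.002046              0.039446            0.042853           0.060076
CT      0.014337  18.199555            7.803101          4.043256              0.037408            0.030289           0.443945
AL      0.012528  19.370969            0.691925          3.314439              0.028175            0.035722           0.303310

AL improves RMSE vs CL by 24% and vs upsampled CT by 13%
mask: 14 Fourier coefficients implanted (data_driven mode)
```

Reading the table: the CL scan resolves in-plane edges in under one
voxel where the 5×-coarser CT needs almost eight, but its axial probe
profile (across a laterally extended edge, which lives in the missing
cone) is the worst of the three. The fused AL volume keeps CL's
in-plane sharpness, pulls the axial profile error toward the CT level,
restores energy inside the cone (`cone_energy_ratio` rises from 0.06
to 0.31), and beats **both** inputs in global RMSE — the quantitative
form of "most of the CL artifacts are removed while the high in-plane
resolution remains".

The other examples cover the geometry arithmetic and sampling
conditions (`01`), phantom generation and the detector model (`02`),
and FBP correctness plus the missing-cone spectral signature (`03`).

A `auglam` command-line tool wraps the same pipeline
(`auglam demo --seed 1 --outdir out/` writes the volumes, the metrics
CSV, a slice montage and a provenance file; `phantom`, `project`,
`reconstruct`, `fuse` and `report` expose the individual stages).

## Layout

```
src/auglam/
  geometry.py     scan geometry, magnification, sampling conditions, cone fraction
  phantom.py      seeded flat-slab phantoms with geometric primitives
  projector.py    tilted-axis parallel-beam projector + detector model
  reconstruct.py  ramp filter, tilted-axis FBP, cone energy ratio
  fusion.py       resampling, intensity matching, cone masks, Fourier implant
  metrics.py      RMSE/PSNR, edge widths, per-method report
  io.py           TIFF / MetaImage volumes with JSON sidecars
  pipeline.py     the end-to-end simulated experiment
  cli.py          thin command-line wrapper
docs/methods.md   model assumptions, conventions, numerical choices, limitations
```
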