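"""Fourier-domain fusion of laminography and CT volumes.

Augmented laminography (AL) fills the unsampled double cone in the
Fourier space of a laminographic (CL) reconstruction with coefficients
taken from a co-registered, lower-resolution CT reconstruction of the
same specimen, then inverse-transforms.  The steps are: resample the CT
onto the CL grid, match its intensity scale, build a binary mask of the
coefficients to replace (either the analytic double cone or a
data-driven amplitude-ratio estimate, median-filtered), and implant the
CT coefficients under that mask — never beyond the CT's own band limit.

FFT convention: unitary transforms (``norm="ortho"``); masks are stored
DC-centered (``fftshift`` layout) and must be inversion-symmetric,
``mask(k) = mask(−k)``, so that the fused spectrum stays conjugate
symmetric and the output real.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, asdict, field

import numpy as np
from scipy.ndimage import distance_transform_edt, map_coordinates, median_filter
from scipy.spatial.transform import Rotation

from .volume import GridSpec, Volume3D

__all__ = [
    "FourierMask",
    "FusionConfig",
    "RigidScaleTransform",
    "resample_to_grid",
    "match_intensity",
    "analytic_cone_mask",
    "estimate_mask",
    "fuse",
]

log = logging.getLogger(__name__)


def _freq_grids(shape, voxel_size, centered=False):
    """Per-axis physical frequencies (cycles/mm), broadcastable to shape."""
    nz, ny, nx = shape
    kz = np.fft.fftfreq(nz, d=voxel_size)
    ky = np.fft.fftfreq(ny, d=voxel_size)
    kx = np.fft.fftfreq(nx, d=voxel_size)
    if centered:
        kz, ky, kx = (np.fft.fftshift(k) for k in (kz, ky, kx))
    return kz[:, None, None], ky[None, :, None], kx[None, None, :]


def _reflect(m: np.ndarray) -> np.ndarray:
    """Map a DC-centered field f(k) to f(−k) (−k taken modulo the grid)."""
    out = np.flip(np.fft.ifftshift(m))
    out = np.roll(out, 1, axis=(0, 1, 2))
    return np.fft.fftshift(out)


@dataclass
class FourierMask:
    """Binary mask over the 3D frequency grid, DC-centered indexing.

    Marks the coefficients to be replaced by CT information.  Must be
    inversion symmetric and contained in the ball of radius
    ``ct_band_radius × Nyquist`` (no filling beyond the CT band); the
    DC coefficient is always excluded.
    """

    grid: np.ndarray
    voxel_size: float
    theta: float | None = None
    ct_band_radius: float = 1.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, bool)
        if self.grid.ndim != 3:
            raise ValueError("mask grid must be 3D")

    @property
    def is_symmetric(self) -> bool:
        return bool(np.array_equal(self.grid, _reflect(self.grid)))

    def to_fft_order(self) -> np.ndarray:
        return np.fft.ifftshift(self.grid)

    def count(self) -> int:
        return int(self.grid.sum())


@dataclass(frozen=True)
class FusionConfig:
    """Tunables of the mask-and-implant procedure.

    tau :
        Amplitude-ratio threshold: a coefficient is a candidate for
        replacement where ``|F_cl| < tau · |F_ct|``.  Outside the cone
        both scans agree within their common band (ratio ≈ 1 and above),
        while inside it the laminographic residual sits well below the
        CT amplitude, so the default marks coefficients where CL falls
        clearly — more than twofold — below CT.
    median_size :
        Odd edge length (in bins of the finest-sampled frequency axis)
        of the median filter that despeckles the raw threshold mask
        (1 = no filtering).  On anisotropic grids the kernel is scaled
        per axis so that it stays isotropic in physical frequency.
    apodization_width :
        Raised-cosine transition width at the mask boundary, voxels;
        0 = hard binary substitution (the fidelity reference).
    ct_band_radius :
        Fraction of the CL Nyquist frequency up to which the CT scan is
        trusted; typically the voxel-size ratio CL/CT.
    mask_mode :
        ``data_driven`` (amplitude comparison) or ``analytic`` (cone).
    """

    tau: float = 0.5
    median_size: int = 3
    apodization_width: float = 2.0
    ct_band_radius: float = 0.2
    mask_mode: str = "data_driven"

    def __post_init__(self) -> None:
        if not self.tau > 0:
            raise ValueError("tau must be positive")
        if self.median_size < 1 or self.median_size % 2 == 0:
            raise ValueError("median_size must be odd and >= 1")
        if not (0 < self.ct_band_radius <= 1):
            raise ValueError("ct_band_radius must be in (0, 1]")
        if self.mask_mode not in ("data_driven", "analytic"):
            raise ValueError("mask_mode must be 'data_driven' or 'analytic'")
        if self.apodization_width < 0:
            raise ValueError("apodization_width must be nonnegative")


@dataclass(frozen=True)
class RigidScaleTransform:
    """Rigid motion plus isotropic scale, moving → target physical coords.

    ``x_target = scale · R(angles) · x_moving + translation`` with
    extrinsic xyz Euler angles in degrees and translation in mm.
    """

    rotation_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translation_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    scale: float = 1.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.scale) and self.scale > 0):
            raise ValueError("degenerate transform: scale must be positive and finite")

    def matrix(self) -> np.ndarray:
        return Rotation.from_euler("xyz", self.rotation_deg, degrees=True).as_matrix()


def resample_to_grid(
    moving: Volume3D,
    transform: RigidScaleTransform,
    target: GridSpec,
    fill_value: float = 0.0,
) -> Volume3D:
    """Trilinearly resample ``moving`` onto ``target`` under ``transform``.

    Each target voxel center is pulled back through the inverse
    transform and sampled in the moving volume; out-of-support voxels
    take ``fill_value`` and their count is logged.
    """
    R = transform.matrix()
    X, Y, Z = target.coords()
    pts = np.stack([X.ravel(), Y.ravel(), Z.ravel()])  # (3, N) target physical
    pts = (R.T @ (pts - np.asarray(transform.translation_mm)[:, None])) / transform.scale
    ox, oy, oz = moving.origin
    iv = np.empty_like(pts)
    iv[0] = (pts[2] - oz) / moving.voxel_size  # z index
    iv[1] = (pts[1] - oy) / moving.voxel_size
    iv[2] = (pts[0] - ox) / moving.voxel_size
    out = map_coordinates(
        np.asarray(moving.data, float), iv, order=1,
        mode="constant", cval=np.nan, prefilter=False,
    )
    outside = np.isnan(out)
    n_out = int(outside.sum())
    if n_out:
        log.info("resample_to_grid: %d/%d target voxels outside moving support",
                 n_out, out.size)
        out[outside] = fill_value
    return Volume3D(out.reshape(target.shape), target.voxel_size, target.origin,
                    meta={**moving.meta, "resampled": True,
                          "outside_voxels": n_out})


def match_intensity(
    ct: Volume3D,
    cl: Volume3D,
    theta: float = 0.0,
    band_radius: float = 0.2,
) -> Volume3D:
    """Affine intensity match of CT against CL on their common band.

    Both volumes are low-pass filtered to the frequency region both
    scans sample reliably — the ball of radius ``band_radius × Nyquist``
    minus the missing cone of the CL scan (DC kept, so the offset is
    identifiable) — and ``a, b`` minimizing ``‖a·ct + b − cl‖²`` over
    that band are applied to the CT volume.
    """
    if not ct.same_grid(cl):
        raise ValueError("match_intensity requires volumes on the same grid")
    shape = ct.shape
    kz, ky, kx = _freq_grids(shape, ct.voxel_size)
    k2 = kx**2 + ky**2 + kz**2
    k_nyq = 0.5 / ct.voxel_size
    region = k2 <= (band_radius * k_nyq) ** 2
    if theta > 0:
        cos_th = math.cos(math.radians(theta))
        region &= ~((k2 > 0) & (kz**2 > k2 * cos_th**2))

    def lowpass(v):
        return np.real(np.fft.ifftn(np.fft.fftn(np.asarray(v.data, np.float64)) * region))

    x = lowpass(ct).ravel()
    y = lowpass(cl).ravel()
    if np.ptp(x) == 0:
        raise ValueError("zero-variance CT input: intensity match is undefined")
    a, b = np.polyfit(x, y, 1)
    out = ct.with_data(a * np.asarray(ct.data, float) + b)
    out.meta.update({"intensity_scale": float(a), "intensity_offset": float(b)})
    return out


def analytic_cone_mask(
    grid: GridSpec | tuple[int, int, int],
    theta: float,
    ct_band_radius: float = 1.0,
    voxel_size: float | None = None,
) -> FourierMask:
    """The missing double cone, intersected with the CT band.

    True exactly where the angle between k and the k_z axis is < θ and
    ``0 < |k| ≤ ct_band_radius × Nyquist``.  Inversion symmetric by
    construction.
    """
    if not (0 <= theta < 90):
        raise ValueError(f"theta must be in [0, 90), got {theta}")
    if isinstance(grid, GridSpec):
        shape, vox = grid.shape, grid.voxel_size
    else:
        shape, vox = tuple(grid), voxel_size or 1.0
    kz, ky, kx = _freq_grids(shape, vox, centered=True)
    k2 = kx**2 + ky**2 + kz**2
    k_nyq = 0.5 / vox
    cos_th = math.cos(math.radians(theta))
    mask = (k2 > 0) & (k2 <= (ct_band_radius * k_nyq) ** 2) & (kz**2 > k2 * cos_th**2)
    return FourierMask(mask, vox, theta=theta, ct_band_radius=ct_band_radius,
                       meta={"mode": "analytic"})


def estimate_mask(cl: Volume3D, ct: Volume3D, config: FusionConfig) -> FourierMask:
    """Data-driven missing-region mask from amplitude comparison.

    Raw mask: ``|F_cl(k)| < τ · |F_ct(k)|`` within the CT band; median
    filtered with a cubic kernel of edge ``median_size``; symmetrized by
    ``mask ← mask(k) OR mask(−k)``; DC always excluded.
    """
    if not cl.same_grid(ct):
        raise ValueError("estimate_mask requires volumes on the same grid")
    a_cl = np.abs(np.fft.fftshift(np.fft.fftn(np.asarray(cl.data, np.float64),
                                              norm="ortho")))
    a_ct = np.abs(np.fft.fftshift(np.fft.fftn(np.asarray(ct.data, np.float64),
                                              norm="ortho")))
    kz, ky, kx = _freq_grids(cl.shape, cl.voxel_size, centered=True)
    k2 = kx**2 + ky**2 + kz**2
    k_nyq = 0.5 / cl.voxel_size
    in_band = (k2 > 0) & (k2 <= (config.ct_band_radius * k_nyq) ** 2)

    raw = (a_cl < config.tau * a_ct) & in_band
    if raw.all() or not raw.any():
        log.warning("estimate_mask: raw threshold mask is all-%s",
                    "true" if raw.all() else "false")
    if config.median_size > 1:
        # Kernel spans scaled per axis: median_size bins on the finest
        # frequency axis, fewer on coarser ones, so the filter support
        # is isotropic in physical frequency.
        n_max = max(cl.shape)
        size = tuple(
            max(1, int(round(config.median_size * n / n_max)) | 1)
            for n in cl.shape
        )
        raw = median_filter(raw.astype(np.uint8), size=size) > 0
        raw &= in_band
    mask = raw | _reflect(raw)
    nz, ny, nx = mask.shape
    mask[nz // 2, ny // 2, nx // 2] = False  # DC
    return FourierMask(mask, cl.voxel_size, theta=None,
                       ct_band_radius=config.ct_band_radius,
                       meta={"mode": "data_driven", "config": asdict(config)})


def _apodized_weight(mask: FourierMask, width: float) -> np.ndarray:
    """Raised-cosine weight: 1 on the mask, 0 beyond ``width`` voxels out."""
    m = mask.grid
    if width <= 0:
        return m.astype(float)
    d_out = distance_transform_edt(~m)
    w = np.where(m, 1.0, 0.5 * (1 + np.cos(np.pi * np.clip(d_out / width, 0.0, 1.0))))
    w = 0.5 * (w + _reflect(w))  # keep strict inversion symmetry
    nz, ny, nx = w.shape
    w[nz // 2, ny // 2, nx // 2] = 0.0
    return w


def fuse(
    cl: Volume3D,
    ct_aligned: Volume3D,
    mask: FourierMask,
    apodization_width: float = 0.0,
) -> Volume3D:
    """Implant CT Fourier coefficients into the CL spectrum.

    ``F_al = (1−w)·F_cl + w·F_ct`` with ``w`` the (optionally
    raised-cosine apodized) mask weight; the output is the real part of
    the inverse transform, and the discarded imaginary part must be
    below 1e-8 of the output RMS (a realness check on the mask
    symmetry and FFT round-trip).
    """
    if not cl.same_grid(ct_aligned):
        raise ValueError("fuse requires volumes on the same grid")
    if mask.grid.shape != cl.shape:
        raise ValueError("mask shape does not match the volumes")
    if not mask.is_symmetric:
        raise ValueError("asymmetric mask would break realness of the output")
    w = np.fft.ifftshift(_apodized_weight(mask, apodization_width))
    # double precision throughout: single-precision FFT roundoff would
    # exceed the realness bound on the output
    F_cl = np.fft.fftn(np.asarray(cl.data, np.float64), norm="ortho")
    F_ct = np.fft.fftn(np.asarray(ct_aligned.data, np.float64), norm="ortho")
    F_al = (1.0 - w) * F_cl + w * F_ct
    out = np.fft.ifftn(F_al, norm="ortho")
    rms = float(np.sqrt(np.mean(np.real(out) ** 2)))
    imag_rms = float(np.sqrt(np.mean(np.imag(out) ** 2)))
    if rms > 0 and imag_rms > 1e-8 * rms:
        raise RuntimeError(
            f"fused volume is not real: imag RMS {imag_rms:.3e} vs RMS {rms:.3e}"
        )
    return Volume3D(np.real(out), cl.voxel_size, cl.origin,
                    meta={"fused": True, "mask": dict(mask.meta),
                          "apodization_width": apodization_width})
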