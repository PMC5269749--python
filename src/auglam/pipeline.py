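"""End-to-end simulated augmented-laminography experiments.

``run_al_experiment`` generates a flat layered phantom, simulates a
high-magnification laminographic scan (tilted axis, fine voxels) and a
low-magnification conventional CT scan (5× coarser voxels) of the same
specimen, reconstructs both by filtered backprojection, aligns and
intensity-matches the CT onto the CL grid, estimates the missing-cone
mask, implants the CT Fourier coefficients, and reports quality metrics
for all three volumes against the ground truth.

The default geometry mirrors a microfocus scanner: SDD 1135 mm,
detector pitch 0.2 mm, laminographic angle 29.8°, CL magnification 8.28
(SOD 137 mm) and a CT scan at one fifth of that magnification.  The
default 128×128×32 grid and 360 projections per turn are desk-scale
stand-ins for a full scan; see docs/methods.md for the scaling
rationale.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, asdict

import numpy as np

from .fusion import (
    FusionConfig,
    RigidScaleTransform,
    analytic_cone_mask,
    estimate_mask,
    fuse,
    match_intensity,
    resample_to_grid,
)
from .geometry import ScanGeometry, ScanMode
from .metrics import method_report, rmse
from .phantom import PhantomSpec, flat_specimen_preset, make_phantom
from .projector import forward_project, normalize_flat_dark, simulate_raw
from .reconstruct import reconstruct
from .volume import GridSpec, Volume3D

__all__ = ["DemoConfig", "run_al_experiment", "default_probes"]

log = logging.getLogger(__name__)

SDD_MM = 1135.0
SOD_CL_MM = 137.0
DETECTOR_PIXEL_MM = 0.2


@dataclass(frozen=True)
class DemoConfig:
    """Conditions of the simulated CL/CT/AL comparison."""

    nx: int = 128
    aspect_ratio: float = 4.0
    theta: float = 29.8
    magnification_ratio: float = 5.0  # CL voxels this much finer than CT
    n_projections: int = 360
    angular_range: float = 360.0
    flat_level: float = 1.0e4
    dark_level: float = 100.0
    poisson: bool = False
    fusion: FusionConfig = field(default_factory=FusionConfig)
    apodization_width: float = 2.0
    filter_window: str = "ram-lak"
    seed: int = 1

    def to_dict(self) -> dict:
        d = asdict(self)
        d["fusion"] = asdict(self.fusion)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DemoConfig":
        d = dict(d)
        if "fusion" in d and isinstance(d["fusion"], dict):
            d["fusion"] = FusionConfig(**d["fusion"])
        return cls(**d)


def cl_geometry(config: DemoConfig) -> ScanGeometry:
    """Laminographic scan geometry at the fine (CL) magnification."""
    nx = config.nx
    cols = int(np.ceil(nx * np.sqrt(2) / 16)) * 16 + 16
    rows = max(int(np.ceil(nx * 1.1 / 16)) * 16, 32)
    return ScanGeometry(
        mode=ScanMode.CL,
        sdd=SDD_MM,
        sod=SOD_CL_MM,
        theta=config.theta,
        detector_pixel=DETECTOR_PIXEL_MM,
        detector_shape=(rows, cols),
        n_projections=config.n_projections,
        angular_range=config.angular_range,
    )


def ct_geometry(config: DemoConfig) -> ScanGeometry:
    """Conventional CT geometry at ``magnification_ratio`` lower zoom."""
    nx_coarse = config.nx / config.magnification_ratio
    cols = max(int(np.ceil(nx_coarse * np.sqrt(2) / 8)) * 8 + 8, 24)
    rows = max(int(np.ceil(nx_coarse / config.aspect_ratio / 4)) * 4 + 8, 16)
    return ScanGeometry(
        mode=ScanMode.CT,
        sdd=SDD_MM,
        sod=SOD_CL_MM * config.magnification_ratio,
        theta=0.0,
        detector_pixel=DETECTOR_PIXEL_MM,
        detector_shape=(rows, cols),
        n_projections=config.n_projections,
        angular_range=config.angular_range,
    )


def default_probes(spec: PhantomSpec) -> dict:
    """Edge probes through the preset's fixed calibration cylinder.

    The flat preset always embeds a high-contrast cylinder at a known
    position, clear of the randomized primitives; the axial probe
    crosses its top face (a z edge destroyed by the missing cone in a
    CL scan), the in-plane probe its lateral rim (preserved by CL).
    """
    nx, ny, nz = spec.grid_shape
    cy, cx = int(round(0.25 * ny)), int(round(0.25 * nx))
    r = 0.13 * nx
    z_edge = nz // 2  # top face of the calibration cylinder
    z_in = (nz // 4 + z_edge) // 2  # mid-height of the cylinder
    x_edge = int(round(cx - r))
    return {
        "inplane": ((z_in, cy, x_edge), 2, min(6, x_edge)),
        "axial": ((z_edge, cy, cx), 0, min(6, nz - z_edge - 1, z_edge)),
    }


def _scan(truth: Volume3D, geometry: ScanGeometry, config: DemoConfig,
          noise_seed: int, out_grid: GridSpec) -> Volume3D:
    """Project, run the detector model and its correction, reconstruct."""
    t0 = time.perf_counter()
    stack = forward_project(truth, geometry)
    raw, flat, dark = simulate_raw(
        stack, config.flat_level, config.dark_level,
        poisson=config.poisson, seed=noise_seed,
    )
    corrected = normalize_flat_dark(raw, flat, dark)
    vol = reconstruct(corrected, geometry, out_grid, window=config.filter_window)
    log.info("%s scan (%d projections): %.1f s", geometry.mode.value,
             geometry.n_projections, time.perf_counter() - t0)
    return vol


def run_al_experiment(config: DemoConfig | None = None, seed: int | None = None) -> dict:
    """Run the full simulated CL/CT/AL comparison.

    Returns a dict with the ground truth, the CL, upsampled CT and AL
    volumes, the Fourier mask, the metrics table (``report``) and the
    RMSE ordering flag ``al_wins`` (AL strictly better than both CL and
    upsampled CT against ground truth).
    """
    config = config or DemoConfig()
    if seed is not None:
        config = DemoConfig.from_dict({**config.to_dict(), "seed": int(seed)})
    geom_cl = cl_geometry(config)
    geom_ct = ct_geometry(config)

    vox_cl = geom_cl.pixel_at_object
    vox_ct = geom_ct.pixel_at_object
    spec = flat_specimen_preset(
        aspect_ratio=config.aspect_ratio, seed=config.seed,
        nx=config.nx, voxel_size=vox_cl,
    )
    truth = make_phantom(spec)
    nx, ny, nz = spec.grid_shape

    cl_vol = _scan(truth, geom_cl, config, noise_seed=config.seed + 1001,
                   out_grid=truth.grid)

    n_lat = int(np.ceil(nx / config.magnification_ratio / 2)) * 2 + 8
    n_ax = max(int(np.ceil(nz / config.magnification_ratio / 2)) * 2 + 6, 8)
    ct_grid = GridSpec((n_ax, n_lat, n_lat), vox_ct)
    ct_vol = _scan(truth, geom_ct, config, noise_seed=config.seed + 2002,
                   out_grid=ct_grid)

    ct_up = resample_to_grid(ct_vol, RigidScaleTransform(), truth.grid)
    ct_matched = match_intensity(ct_up, cl_vol, theta=config.theta,
                                 band_radius=config.fusion.ct_band_radius)

    if config.fusion.mask_mode == "analytic":
        mask = analytic_cone_mask(truth.grid, config.theta,
                                  config.fusion.ct_band_radius)
    else:
        mask = estimate_mask(cl_vol, ct_matched, config.fusion)
    al_vol = fuse(cl_vol, ct_matched, mask, config.apodization_width)

    probes = default_probes(spec)
    report = method_report(truth, cl_vol, ct_matched, al_vol,
                           theta=config.theta, probes=probes)
    r = report["rmse"]
    al_wins = bool(r["AL"] < r["CL"] and r["AL"] < r["CT"])
    return {
        "config": config,
        "spec": spec,
        "truth": truth,
        "cl": cl_vol,
        "ct": ct_vol,
        "ct_up": ct_matched,
        "mask": mask,
        "al": al_vol,
        "report": report,
        "probes": probes,
        "al_wins": al_wins,
        "geometry_cl": geom_cl,
        "geometry_ct": geom_ct,
    }
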