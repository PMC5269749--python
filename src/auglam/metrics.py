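"""Quantitative comparison of CL / CT / AL volumes.

Turns the qualitative trade-offs of the three acquisition schemes
(high in-plane resolution for CL and AL, artifact-free but coarse CT,
axial blurring for CL) into numbers: RMSE and PSNR against ground
truth, 10-90% edge widths along in-plane and axial probes, and the
spectral energy fraction restored inside the missing cone.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .reconstruct import cone_energy_ratio
from .volume import Volume3D

__all__ = ["rmse", "psnr", "edge_width", "method_report"]


def _check_grids(a: Volume3D, b: Volume3D) -> None:
    if not a.same_grid(b):
        raise ValueError(f"volumes are on different grids: {a.shape} vs {b.shape}")


def rmse(a: Volume3D, b: Volume3D) -> float:
    """Root-mean-square error between two volumes on the same grid."""
    _check_grids(a, b)
    return float(np.sqrt(np.mean((np.asarray(a.data, float) - np.asarray(b.data, float)) ** 2)))


def psnr(a: Volume3D, b: Volume3D, data_range: float | None = None) -> float:
    """Peak signal-to-noise ratio in dB; ``a`` is the reference.

    ``psnr = 20·log10(data_range / rmse)``; the default range is the
    reference's min-to-max span.
    """
    _check_grids(a, b)
    if data_range is None:
        data_range = float(np.ptp(a.data))
    if data_range <= 0:
        raise ValueError("data_range must be positive (constant reference needs an explicit range)")
    err = rmse(a, b)
    if err == 0:
        return float("inf")
    return float(20.0 * np.log10(data_range / err))


def edge_width(profile: np.ndarray, x: np.ndarray | None = None) -> float:
    """10-90% rise distance of a (near-)monotone edge profile, sub-sample.

    The profile is treated as piecewise linear between samples at
    positions ``x`` (default: unit spacing).  The low and high levels
    are the profile's end means; the width is the distance between the
    first crossings of the 10% and 90% levels.  A continuous ideal step
    (two samples at the same position) has width 0; a step sampled at
    unit spacing is indistinguishable from a one-voxel linear ramp and
    yields 0.8.
    """
    p = np.asarray(profile, float)
    if p.ndim != 1 or p.size < 2:
        raise ValueError("profile must be a 1D array with at least 2 samples")
    x = np.arange(p.size, dtype=float) if x is None else np.asarray(x, float)
    if p[-1] < p[0]:  # falling edge: mirror into a rising one
        p = p[::-1]
        x = x.max() - x[::-1]
    lo_level, hi_level = p[0], p[-1]
    span = hi_level - lo_level
    if span == 0:
        return 0.0
    lo = lo_level + 0.1 * span
    hi = lo_level + 0.9 * span

    def first_crossing(level: float, start: int = 0) -> float:
        for i in range(start, p.size - 1):
            p0, p1 = p[i], p[i + 1]
            if (p0 - level) * (p1 - level) <= 0 and p1 != p0:
                return x[i] + (level - p0) / (p1 - p0) * (x[i + 1] - x[i])
            if p0 == level == p1:
                return x[i]
        return x[-1]

    x10 = first_crossing(lo)
    x90 = first_crossing(hi)
    return float(max(x90 - x10, 0.0))


def method_report(
    truth: Volume3D,
    cl: Volume3D,
    ct: Volume3D,
    al: Volume3D,
    theta: float,
    probes: dict | None = None,
) -> pd.DataFrame:
    """Per-method quality table on a common grid (CT upsampled to CL's).

    Columns: RMSE and PSNR vs ground truth, 10-90% edge widths along an
    in-plane and an axial probe, the RMS error of each probe profile
    against the ground-truth profile, and the cone-energy ratio at tilt
    θ.  ``probes`` maps ``"inplane"``/``"axial"`` to ``(point, axis,
    half)``: a ``(z, y, x)`` voxel index, the axis (0=z, 2=x) of a
    profile of half-length ``half`` centered there.  The default probes
    run through the volume center.

    The edge widths are referenced to each profile's own end levels, so
    they are meaningful only where the method resolves the edge at all;
    a laminographic scan flattens laterally extended axial edges
    entirely, and for such profiles the *profile RMS error* is the
    faithful blur measure while the width degenerates.
    """
    vols = {"CL": cl, "CT": ct, "AL": al}
    for v in vols.values():
        _check_grids(truth, v)
    nz, ny, nx = truth.shape
    if probes is None:
        probes = {
            "inplane": ((nz // 2, ny // 2, nx // 2), 2, min(nx // 4, 16)),
            "axial": ((nz // 2, ny // 2, nx // 2), 0, min(nz // 2, 16)),
        }

    def profile(vol: Volume3D, probe) -> np.ndarray:
        (z, y, x), axis, half = probe
        if axis == 0:
            sl = vol.data[max(z - half, 0): z + half + 1, y, x]
        elif axis == 1:
            sl = vol.data[z, max(y - half, 0): y + half + 1, x]
        else:
            sl = vol.data[z, y, max(x - half, 0): x + half + 1]
        return np.asarray(sl, float)

    rows = []
    rng = float(np.ptp(truth.data))
    ref = {k: profile(truth, p) for k, p in probes.items()}
    for name, vol in vols.items():
        rows.append({
            "method": name,
            "rmse": rmse(truth, vol),
            "psnr_db": psnr(truth, vol, data_range=rng if rng > 0 else None),
            "inplane_edge_width": edge_width(profile(vol, probes["inplane"])),
            "axial_edge_width": edge_width(profile(vol, probes["axial"])),
            "inplane_profile_rmse": float(np.sqrt(np.mean(
                (profile(vol, probes["inplane"]) - ref["inplane"]) ** 2))),
            "axial_profile_rmse": float(np.sqrt(np.mean(
                (profile(vol, probes["axial"]) - ref["axial"]) ** 2))),
            "cone_energy_ratio": cone_energy_ratio(vol, theta),
        })
    return pd.DataFrame(rows).set_index("method")
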