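"""Volume and projection I/O: multi-page TIFF, MetaImage, JSON sidecars.

Volumes are written as 32-bit float multi-page TIFF stacks (one page
per z-slice) or MetaImage ``.mha``/``.mhd``; each file gets a JSON
sidecar (``<stem>.json``) carrying voxel size, origin and provenance so
that a round trip is lossless including metadata.  MetaImage files are
written through SimpleITK and therefore conform to the standard header
(NDims=3, ElementSpacing, Offset).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import SimpleITK as sitk
import tifffile

from .geometry import ScanGeometry
from .projector import ProjectionStack
from .volume import Volume3D

__all__ = ["read_volume", "write_volume", "read_projections", "write_projections",
           "write_mask"]

log = logging.getLogger(__name__)

_TIFF_SUFFIXES = {".tif", ".tiff"}
_META_SUFFIXES = {".mha", ".mhd"}


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def _write_sidecar(path: Path, payload: dict) -> None:
    _sidecar_path(path).write_text(json.dumps(payload, indent=2, default=str))


def _read_sidecar(path: Path) -> dict | None:
    sc = _sidecar_path(path)
    if not sc.exists():
        return None
    return json.loads(sc.read_text())


def write_volume(volume: Volume3D, path: str | Path) -> Path:
    """Write a volume as TIFF stack or MetaImage, plus a JSON sidecar."""
    path = Path(path)
    data = np.asarray(volume.data, dtype=np.float32)
    if path.suffix.lower() in _TIFF_SUFFIXES:
        tifffile.imwrite(path, data, photometric="minisblack")
    elif path.suffix.lower() in _META_SUFFIXES:
        img = sitk.GetImageFromArray(data)  # sitk uses (z, y, x) arrays
        img.SetSpacing((volume.voxel_size,) * 3)
        img.SetOrigin(tuple(volume.origin))
        sitk.WriteImage(img, str(path))
    else:
        raise ValueError(f"unknown volume format {path.suffix!r}; use .tif/.tiff/.mha/.mhd")
    _write_sidecar(path, {
        "voxel_size_mm": volume.voxel_size,
        "origin_mm": list(volume.origin),
        "shape_zyx": list(volume.shape),
        "meta": volume.meta,
    })
    return path


def read_volume(path: str | Path) -> Volume3D:
    """Read a TIFF stack or MetaImage volume (with sidecar if present)."""
    path = Path(path)
    sidecar = _read_sidecar(path)
    if path.suffix.lower() in _TIFF_SUFFIXES:
        data = tifffile.imread(path)
        if data.ndim != 3:
            raise ValueError(
                f"{path.name} is a {data.ndim}D TIFF; expected a 3D multi-page stack"
            )
        if sidecar is None:
            log.warning("%s: no sidecar found, assuming voxel_size=1 mm", path.name)
            voxel, origin = 1.0, None
        else:
            voxel = sidecar["voxel_size_mm"]
            origin = tuple(sidecar["origin_mm"])
    elif path.suffix.lower() in _META_SUFFIXES:
        img = sitk.ReadImage(str(path))
        data = sitk.GetArrayFromImage(img)
        if data.ndim != 3:
            raise ValueError(f"{path.name}: expected a 3D MetaImage")
        sp = img.GetSpacing()
        voxel = float(sp[0])
        origin = tuple(img.GetOrigin())
    else:
        raise ValueError(f"unknown volume format {path.suffix!r}; use .tif/.tiff/.mha/.mhd")
    meta = (sidecar or {}).get("meta", {})
    return Volume3D(np.asarray(data, np.float32), voxel, origin, meta)


def write_projections(stack: ProjectionStack, path: str | Path) -> Path:
    """Write a projection stack as a multi-page TIFF (one page per angle)."""
    path = Path(path)
    if path.suffix.lower() not in _TIFF_SUFFIXES:
        raise ValueError("projection stacks are written as .tif/.tiff")
    tifffile.imwrite(path, np.asarray(stack.frames, np.float32),
                     photometric="minisblack")
    _write_sidecar(path, {
        "kind": stack.kind,
        "angles_deg": list(map(float, stack.angles)),
        "geometry": stack.geometry.to_dict(),
        "meta": stack.meta,
    })
    return path


def read_projections(path: str | Path) -> ProjectionStack:
    path = Path(path)
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    sidecar = _read_sidecar(path)
    if sidecar is None:
        raise ValueError(f"{path.name}: projection stacks require a JSON sidecar")
    geometry = ScanGeometry.from_dict(sidecar["geometry"])
    return ProjectionStack(
        frames=np.asarray(frames, np.float64),
        angles=np.asarray(sidecar["angles_deg"]),
        kind=sidecar["kind"],
        geometry=geometry,
        meta=sidecar.get("meta", {}),
    )


def write_mask(mask, path: str | Path) -> Path:
    """Persist a FourierMask as an 8-bit MetaImage with its config sidecar."""
    path = Path(path)
    if path.suffix.lower() not in _META_SUFFIXES:
        raise ValueError("masks are written as .mha/.mhd")
    img = sitk.GetImageFromArray(mask.grid.astype(np.uint8))
    img.SetSpacing((mask.voxel_size,) * 3)
    sitk.WriteImage(img, str(path))
    _write_sidecar(path, {
        "theta_deg": mask.theta,
        "ct_band_radius": mask.ct_band_radius,
        "voxel_size_mm": mask.voxel_size,
        "meta": mask.meta,
    })
    return path
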