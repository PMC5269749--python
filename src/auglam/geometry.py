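"""Acquisition geometry for computed tomography and computed laminography.

Computed laminography (CL) generalizes CT by tilting the rotation axis
away from the conventional orientation (axis perpendicular to the beam)
by the laminographic angle θ.  θ = 0 recovers conventional CT; θ = 90°
degenerates into a sequence of rotated radiographies.  The tilt causes a
double cone of half-angle θ about the axis frequency direction k_z to go
unsampled — the "missing cone" responsible for the characteristic axial
blurring of laminographic reconstructions.

Conventions: lengths in mm, angles in degrees at every interface.  The
rotation axis is the object-frame z axis; at rotation angle φ the beam
direction is ``(cos θ cos φ, cos θ sin φ, sin θ)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from enum import Enum

import numpy as np

__all__ = [
    "ScanMode",
    "ScanGeometry",
    "SamplingReport",
    "magnification",
    "effective_voxel_size",
    "check_ct_sampling",
    "missing_cone_fraction",
    "beam_direction",
    "detector_basis",
]


class ScanMode(str, Enum):
    CT = "CT"
    CL = "CL"


class GeometryError(ValueError):
    """Raised for physically invalid acquisition geometries."""


@dataclass(frozen=True)
class ScanGeometry:
    """Cone-beam acquisition description.

    The projection model in this package is parallel-beam; the cone-beam
    magnification ``M = sdd/sod`` enters only as voxel-size bookkeeping
    (object-side detector pixel = ``detector_pixel / M``).

    Parameters
    ----------
    mode :
        ``CT`` (θ must be 0) or ``CL``.
    sdd, sod :
        Source-to-detector and source-to-object distances, mm.
    theta :
        Laminographic angle in degrees: tilt of the rotation axis away
        from the conventional-CT orientation.  0 ≤ θ < 90.
    detector_pixel :
        Detector pixel pitch, mm (at the detector plane).
    detector_shape :
        ``(rows, cols)``; rows index the v (axis-projection) direction.
    n_projections :
        Number of equally spaced projections over ``angular_range``.
    angular_range :
        Total rotation interval, degrees, in (0, 360].
    """

    mode: ScanMode
    sdd: float
    sod: float
    theta: float = 0.0
    detector_pixel: float = 0.2
    detector_shape: tuple[int, int] = (256, 256)
    n_projections: int = 360
    angular_range: float = 360.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "mode", ScanMode(self.mode))
        if not (self.sdd >= self.sod > 0):
            raise GeometryError(
                f"need sdd >= sod > 0, got sdd={self.sdd}, sod={self.sod}"
            )
        if not (0 <= self.theta < 90):
            raise GeometryError(f"theta must be in [0, 90), got {self.theta}")
        if self.mode == ScanMode.CT and self.theta != 0:
            raise GeometryError("mode=CT requires theta=0")
        if not self.detector_pixel > 0:
            raise GeometryError("detector_pixel must be positive")
        rows, cols = self.detector_shape
        if rows < 1 or cols < 1:
            raise GeometryError("detector_shape entries must be positive")
        if self.n_projections < 1:
            raise GeometryError("n_projections must be >= 1")
        if not (0 < self.angular_range <= 360):
            raise GeometryError("angular_range must be in (0, 360]")

    @property
    def magnification(self) -> float:
        return self.sdd / self.sod

    @property
    def pixel_at_object(self) -> float:
        """Object-side sampling pitch: detector_pixel / M, mm."""
        return self.detector_pixel / self.magnification

    @property
    def angles(self) -> np.ndarray:
        """Projection angles φ in degrees (endpoint excluded)."""
        return np.linspace(0.0, self.angular_range, self.n_projections, endpoint=False)

    def to_dict(self) -> dict:
        d = asdict(self)
        return {
            "mode": self.mode.value,
            "sdd_mm": d["sdd"],
            "sod_mm": d["sod"],
            "theta_deg": d["theta"],
            "detector_pixel_mm": d["detector_pixel"],
            "detector_shape": list(self.detector_shape),
            "n_projections": d["n_projections"],
            "angular_range_deg": d["angular_range"],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScanGeometry":
        return cls(
            mode=d["mode"],
            sdd=d["sdd_mm"],
            sod=d["sod_mm"],
            theta=d.get("theta_deg", 0.0),
            detector_pixel=d.get("detector_pixel_mm", 0.2),
            detector_shape=tuple(d.get("detector_shape", (256, 256))),
            n_projections=d.get("n_projections", 360),
            angular_range=d.get("angular_range_deg", 360.0),
        )


@dataclass(frozen=True)
class SamplingReport:
    """Outcome of the two truncation-free-imaging conditions.

    Condition 1: the projected region of interest must stay on the
    detector at every rotation angle.  Condition 2: material outside the
    field of view must not cast its shadow onto the ROI during rotation.
    """

    roi_on_detector: bool
    no_overlap: bool
    limiting_condition: str = ""

    @property
    def valid(self) -> bool:
        return self.roi_on_detector and self.no_overlap


def magnification(geometry: ScanGeometry) -> float:
    """Geometric magnification M = SDD / SOD."""
    return geometry.magnification


def effective_voxel_size(geometry: ScanGeometry) -> float:
    """Object-side voxel size, mm: detector pixel pitch / M."""
    return geometry.pixel_at_object


def beam_direction(theta_deg: float, phi_deg: float) -> np.ndarray:
    """Unit beam direction ``(x, y, z)`` for tilt θ and rotation φ.

    θ=0 gives an in-plane beam (conventional CT); θ=90° would send the
    beam along the rotation axis (plain radiography).
    """
    th = math.radians(theta_deg)
    ph = math.radians(phi_deg)
    return np.array(
        [math.cos(th) * math.cos(ph), math.cos(th) * math.sin(ph), math.sin(th)]
    )


def detector_basis(
    theta_deg: float, phi_deg: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Orthonormal detector frame ``(e_u, e_v, b)`` at rotation angle φ.

    ``e_u`` is the horizontal detector direction (perpendicular to both
    the beam and the rotation axis), ``e_v`` completes the right-handed
    frame and carries the rotation-axis projection (``e_v · ẑ = cos θ``),
    ``b`` is the beam direction.
    """
    th = math.radians(theta_deg)
    ph = math.radians(phi_deg)
    b = np.array([math.cos(th) * math.cos(ph), math.cos(th) * math.sin(ph), math.sin(th)])
    e_u = np.array([-math.sin(ph), math.cos(ph), 0.0])
    e_v = np.array([-math.sin(th) * math.cos(ph), -math.sin(th) * math.sin(ph), math.cos(th)])
    return e_u, e_v, b


def missing_cone_fraction(theta: float) -> float:
    """Solid-angle fraction of the unsampled double cone: 1 − cos θ.

    In the parallel-beam model a frequency direction k̂ is sampled iff it
    is perpendicular to some beam direction on the acquisition cone,
    i.e. iff ``∃φ: k̂ · b(φ) = 0``.  Writing k̂ at polar angle ψ from the
    axis, the condition reads ``cos(α − φ) = −tan θ / tan ψ`` and is
    solvable exactly when ψ ≥ θ.  The unsampled set is therefore the
    double cone of half-angle θ about the axis, whose solid angle is
    ``2 · 2π(1 − cos θ)`` out of 4π.

    At θ=0 the cones vanish (complete sampling); at θ=90° only the
    central plane — a measure-zero set — is sampled and the fraction is 1.
    """
    if not (0 <= theta <= 90):
        raise ValueError(f"theta must be in [0, 90], got {theta}")
    return 1.0 - math.cos(math.radians(theta))


def check_ct_sampling(
    object_lateral_extent: float,
    object_thickness: float,
    geometry: ScanGeometry,
) -> SamplingReport:
    """Evaluate the two truncation-free-imaging conditions.

    The object is modeled as a centered cylinder (radius = lateral
    extent / 2, height = thickness) rotating about the possibly tilted
    axis; projections are orthographic with the cone-beam magnification
    applied as a scale factor onto the detector.

    The region of interest is the part of that cylinder that fits the
    detector laterally: diameter ``d_roi = min(extent, width / M)``.

    Condition 1 (*roi_on_detector*): the projected ROI must stay on the
    detector at all φ.  Laterally this holds by construction of d_roi;
    vertically the footprint is ``thickness·cos θ + d_roi·sin θ`` (the
    cylinder's projection onto the v axis, φ-independent by symmetry).

    Condition 2 (*no_overlap*): material sharing rays with the ROI must
    itself project onto the detector at all φ.  At θ=0 the beam travels
    in the specimen plane, so the full lateral extent is traversed and
    the condition requires ``M · extent ≤ width`` — this is what forces
    low magnification in conventional CT of wide objects.  At θ>0 the
    beam crosses the slab at angle θ to its plane, limiting the lateral
    run along any ray to ``thickness / tan θ``, so the effective
    footprint is ``min(extent, thickness / tan θ)``.
    """
    if object_lateral_extent <= 0 or object_thickness <= 0:
        raise ValueError("object extents must be positive")
    M = geometry.magnification
    th = math.radians(geometry.theta)
    rows, cols = geometry.detector_shape
    width = cols * geometry.detector_pixel
    height = rows * geometry.detector_pixel

    d_roi = min(object_lateral_extent, width / M)
    v_extent = object_thickness * math.cos(th) + d_roi * math.sin(th)
    roi_on_detector = M * v_extent <= height and M * d_roi <= width * (1 + 1e-12)

    if geometry.theta == 0:
        effective_lateral = object_lateral_extent
    else:
        effective_lateral = min(object_lateral_extent, object_thickness / math.tan(th))
    no_overlap = M * effective_lateral <= width

    if roi_on_detector and no_overlap:
        limiting = ""
    elif not no_overlap:
        limiting = (
            "overlap: magnified lateral footprint "
            f"{M * effective_lateral:.1f} mm exceeds detector width {width:.1f} mm"
        )
    else:
        limiting = (
            "roi-off-detector: projected ROI "
            f"({M * d_roi:.1f} × {M * v_extent:.1f} mm) exceeds detector "
            f"({width:.1f} × {height:.1f} mm)"
        )
    return SamplingReport(
        roi_on_detector=bool(roi_on_detector),
        no_overlap=bool(no_overlap),
        limiting_condition=limiting,
    )
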