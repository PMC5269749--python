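"""Seeded ground-truth attenuation phantoms.

The reference scene is a flat, laterally extended specimen: a layered
slab (nz ≪ nx, ny) containing assorted geometric primitives of distinct
attenuation — the regime where laminography beats conventional CT.
Voxel membership is decided at voxel centers (no antialiasing) so that
primitive volumes can be checked against closed forms; an optional
supersampling flag smooths edges for reconstruction experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .volume import GridSpec, Volume3D

__all__ = ["Primitive", "PhantomSpec", "make_phantom", "flat_specimen_preset"]

_KINDS = ("sphere", "box", "cylinder")


@dataclass(frozen=True)
class Primitive:
    """A geometric primitive in voxel coordinates.

    ``center`` is ``(z, y, x)`` in (fractional) voxel indices.  ``size``
    is the radius for spheres, the ``(z, y, x)`` half-extents for boxes,
    and ``(half_height, radius)`` for z-aligned cylinders.
    """

    kind: str
    center: tuple[float, ...]
    size: tuple[float, ...]
    mu: float

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown primitive kind {self.kind!r}")
        if self.mu < 0:
            raise ValueError("attenuation must be nonnegative")

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """Axis-aligned ``(z, y, x)`` bounding box (lo, hi) in voxels."""
        c = np.asarray(self.center, float)
        if self.kind == "sphere":
            r = float(self.size[0])
            half = np.array([r, r, r])
        elif self.kind == "box":
            half = np.asarray(self.size, float)
        else:  # cylinder
            hh, r = float(self.size[0]), float(self.size[1])
            half = np.array([hh, r, r])
        return c - half, c + half

    def mask(self, Z: np.ndarray, Y: np.ndarray, X: np.ndarray) -> np.ndarray:
        c = np.asarray(self.center, float)
        if self.kind == "sphere":
            r = float(self.size[0])
            return (Z - c[0]) ** 2 + (Y - c[1]) ** 2 + (X - c[2]) ** 2 <= r * r
        if self.kind == "box":
            hz, hy, hx = (float(s) for s in self.size)
            return (
                (np.abs(Z - c[0]) <= hz)
                & (np.abs(Y - c[1]) <= hy)
                & (np.abs(X - c[2]) <= hx)
            )
        hh, r = float(self.size[0]), float(self.size[1])
        return (np.abs(Z - c[0]) <= hh) & ((Y - c[1]) ** 2 + (X - c[2]) ** 2 <= r * r)


@dataclass(frozen=True)
class PhantomSpec:
    """Declarative phantom description.

    ``layers`` are ``((z_lo, z_hi), mu)`` pairs painted first (half-open
    voxel-index intervals over an optional lateral support margin);
    primitives overwrite layers in list order.
    """

    grid_shape: tuple[int, int, int]  # (nx, ny, nz), matching user-facing docs
    voxel_size: float = 1.0
    background_mu: float = 0.0
    layers: tuple = ()
    primitives: tuple = ()
    seed: int = 0
    lateral_margin: float = 0.0  # fraction of nx/ny left clear around layers
    supersample: int = 1

    def __post_init__(self) -> None:
        nx, ny, nz = self.grid_shape
        if min(nx, ny, nz) < 1:
            raise ValueError("grid_shape must be positive")
        if self.background_mu < 0 or any(mu < 0 for _, mu in self.layers):
            raise ValueError("attenuation must be nonnegative")
        for (z_lo, z_hi), _ in self.layers:
            if not (0 <= z_lo < z_hi <= nz):
                raise ValueError(f"layer interval ({z_lo}, {z_hi}) outside grid")
        if not (0 <= self.lateral_margin < 0.5):
            raise ValueError("lateral_margin must be in [0, 0.5)")
        object.__setattr__(
            self, "primitives", tuple(p if isinstance(p, Primitive) else Primitive(**p)
                                      for p in self.primitives)
        )
        for p in self.primitives:
            lo, hi = p.bounds()
            if np.any(lo < -0.5) or np.any(hi > np.array([nz, ny, nx]) - 0.5):
                raise ValueError(f"primitive {p.kind} at {p.center} extends outside grid")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["primitives"] = [asdict(p) for p in self.primitives]
        d["layers"] = [[list(iv), mu] for iv, mu in self.layers]
        return d


def make_phantom(spec: PhantomSpec) -> Volume3D:
    """Render a :class:`PhantomSpec` into a :class:`Volume3D`.

    Deterministic for a fixed spec; the spec's seed only influences the
    *construction* of randomized specs (see :func:`flat_specimen_preset`),
    not the rendering.  With ``supersample=s`` each voxel is decided by
    averaging s³ subsamples instead of its center, smoothing edges.
    """
    nx, ny, nz = spec.grid_shape
    s = int(spec.supersample)
    if s < 1:
        raise ValueError("supersample must be >= 1")

    def render(Z, Y, X):
        data = np.full(Z.shape, float(spec.background_mu))
        m = spec.lateral_margin
        lateral = np.ones(Z.shape, bool)
        if m > 0:
            lateral = (
                (X >= m * nx) & (X <= (1 - m) * nx - 1)
                & (Y >= m * ny) & (Y <= (1 - m) * ny - 1)
            )
        for (z_lo, z_hi), mu in spec.layers:
            sel = lateral & (Z >= z_lo - 0.5) & (Z < z_hi - 0.5)
            data[sel] = mu
        for p in spec.primitives:
            data[p.mask(Z, Y, X)] = p.mu
        return data

    if s == 1:
        Z, Y, X = np.meshgrid(
            np.arange(nz, dtype=float),
            np.arange(ny, dtype=float),
            np.arange(nx, dtype=float),
            indexing="ij",
        )
        data = render(Z, Y, X)
    else:
        offs = (np.arange(s) + 0.5) / s - 0.5
        data = np.zeros((nz, ny, nx))
        for dz in offs:
            for dy in offs:
                for dx in offs:
                    Z, Y, X = np.meshgrid(
                        np.arange(nz) + dz, np.arange(ny) + dy, np.arange(nx) + dx,
                        indexing="ij",
                    )
                    data += render(Z, Y, X)
        data /= s**3
    return Volume3D(data.astype(np.float32), spec.voxel_size,
                    meta={"phantom_spec": spec.to_dict()})


def flat_specimen_preset(
    aspect_ratio: float = 4.0,
    seed: int = 0,
    nx: int = 128,
    voxel_size: float = 1.0,
    n_primitives: int = 8,
) -> PhantomSpec:
    """Randomized flat-slab phantom: layered structure + embedded primitives.

    The slab occupies the central ``nz/2`` z-range split into three
    layers of distinct attenuation, with a clear lateral margin so the
    specimen is compactly supported inside the grid.  ``aspect_ratio``
    = nx/nz must exceed 1 (the specimen must be flat).  Primitive
    placement is reproducible for a fixed seed.

    Besides the seeded primitives, every preset carries one *fixed*
    calibration cylinder (high contrast, known position, appended last)
    whose upper z-face and lateral rim provide clean axial and in-plane
    edges for resolution probes; the random primitives are confined to
    the central region so they can never touch it.
    """
    if aspect_ratio <= 1:
        raise ValueError("aspect_ratio must exceed 1 (flat specimen)")
    nz = max(8, int(round(nx / aspect_ratio)))
    ny = nx
    rng = np.random.default_rng(seed)

    # Layered slab through the central half of z; contrasts ~ limestone-like
    # scale (order 0.01-0.1 / mm at the mm voxel sizes used in the demo).
    z0, z1 = nz // 4, nz - nz // 4
    cut1 = z0 + (z1 - z0) // 3
    cut2 = z0 + 2 * (z1 - z0) // 3
    layers = (
        ((z0, cut1), 0.02),
        ((cut1, cut2), 0.035),
        ((cut2, z1), 0.025),
    )

    margin = 0.12
    prims = []
    mus = rng.uniform(0.05, 0.12, size=n_primitives)
    for i in range(n_primitives):
        kind = _KINDS[int(rng.integers(len(_KINDS)))]
        cz = rng.uniform(z0 + 2, z1 - 2)
        cy = rng.uniform(0.45 * ny, 0.70 * ny)
        cx = rng.uniform(0.45 * nx, 0.70 * nx)
        r_lat = rng.uniform(0.03 * nx, 0.08 * nx)
        r_z = min(rng.uniform(1.5, 0.2 * nz), cz - z0 - 0.5, z1 - cz - 0.5)
        r_z = max(r_z, 1.0)
        if kind == "sphere":
            r = min(r_lat, r_z)
            prims.append(Primitive("sphere", (cz, cy, cx), (r,), float(mus[i])))
        elif kind == "box":
            prims.append(Primitive("box", (cz, cy, cx), (r_z, r_lat, r_lat * rng.uniform(0.5, 1.5)),
                                   float(mus[i])))
        else:
            prims.append(Primitive("cylinder", (cz, cy, cx), (r_z, r_lat), float(mus[i])))

    # Fixed calibration disk: laterally extended (its top face is a
    # "coarse lateral structure" whose spectrum lives in the missing
    # cone), spanning the lower half of the slab so that its top face
    # (at z = nz/2) gives a clean axial edge and its rim a clean
    # in-plane edge, both clear of the randomized primitives.
    z_mid = nz // 2
    hh = (z_mid - z0) / 2
    prims.append(
        Primitive("cylinder", (z0 + hh, 0.25 * ny, 0.25 * nx), (hh, 0.13 * nx), 0.10)
    )
    return PhantomSpec(
        grid_shape=(nx, ny, nz),
        voxel_size=voxel_size,
        background_mu=0.0,
        layers=layers,
        primitives=tuple(prims),
        seed=seed,
        lateral_margin=margin,
    )
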