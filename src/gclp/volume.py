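"""Core data model: OCTA volumes, retinal surfaces, slabs, and en face maps.

Coordinate conventions
----------------------
Volumes are indexed ``(x, y, z)`` with 0-based indices: ``x`` is the fast
(A-line) axis, ``y`` the B-scan axis, and ``z`` increases with depth from the
vitreous toward the choroid.  Surface depths are fractional voxel coordinates.
A voxel with integer index ``z`` has its center at depth ``z + 0.5``; a voxel
belongs to a slab iff its center lies in the half-open interval
``[top_z, bottom_z)``.  This makes any subdivision of a slab a gap-free,
overlap-free tiling.

Right eyes (OD) are the canonical orientation, with the nasal side at
increasing ``x`` and the superior side at increasing ``y``.  Left-eye (OS)
data are mirrored along ``x`` on load so all downstream analysis runs in OD
orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InvalidGeometryError, SegmentationError

__all__ = [
    "ScanVolume",
    "SurfaceSet",
    "Slab",
    "EnFaceMap",
    "validate_surfaces",
    "gcipl_fraction_slab",
    "subdivide_gcipl",
    "thickness_map",
    "slab_voxel_mask",
]

MAP_KINDS = ("angiogram", "threshold", "mask", "vd", "thickness", "exclusion")


@dataclass
class ScanVolume:
    """A co-registered pair of structural-reflectance and flow volumes.

    The flow array carries a decorrelation-like signal (the output of an
    amplitude-decorrelation angiography computation, which is upstream of this
    package); the structure array carries relative reflectance.
    """

    structure: np.ndarray  # (nx, ny, nz), non-negative
    flow: np.ndarray  # same shape, non-negative
    lateral_spacing_mm: float
    axial_spacing_um: float
    laterality: str = "OD"

    def __post_init__(self):
        self.structure = np.asarray(self.structure)
        self.flow = np.asarray(self.flow)
        if self.structure.shape != self.flow.shape:
            raise InvalidGeometryError(
                f"structure shape {self.structure.shape} != flow shape {self.flow.shape}"
            )
        if self.structure.ndim != 3:
            raise InvalidGeometryError("volumes must be 3-D (x, y, z)")
        if self.lateral_spacing_mm <= 0 or self.axial_spacing_um <= 0:
            raise InvalidGeometryError("spacings must be positive")
        if self.laterality not in ("OD", "OS"):
            raise InvalidGeometryError(f"laterality must be OD or OS, got {self.laterality!r}")

    @property
    def shape(self):
        return self.structure.shape

    def mirrored(self) -> "ScanVolume":
        """Flip along x (nasal/temporal) and toggle laterality."""
        return ScanVolume(
            structure=self.structure[::-1].copy(),
            flow=self.flow[::-1].copy(),
            lateral_spacing_mm=self.lateral_spacing_mm,
            axial_spacing_um=self.axial_spacing_um,
            laterality="OS" if self.laterality == "OD" else "OD",
        )


@dataclass
class SurfaceSet:
    """Per-A-line depths (fractional voxel units) of the three segmented
    surfaces: ILM, NFL/GCL, and IPL/INL."""

    ilm_z: np.ndarray
    nflgcl_z: np.ndarray
    iplinl_z: np.ndarray

    def __post_init__(self):
        self.ilm_z = np.asarray(self.ilm_z, dtype=float)
        self.nflgcl_z = np.asarray(self.nflgcl_z, dtype=float)
        self.iplinl_z = np.asarray(self.iplinl_z, dtype=float)
        if not (self.ilm_z.shape == self.nflgcl_z.shape == self.iplinl_z.shape):
            raise InvalidGeometryError("surface arrays must share one lateral shape")

    @property
    def shape(self):
        return self.ilm_z.shape

    def mirrored(self) -> "SurfaceSet":
        return SurfaceSet(
            self.ilm_z[::-1].copy(), self.nflgcl_z[::-1].copy(), self.iplinl_z[::-1].copy()
        )


@dataclass
class Slab:
    """A depth slab bounded by per-(x, y) fractional voxel depths."""

    top_z: np.ndarray
    bottom_z: np.ndarray
    name: str = ""

    def __post_init__(self):
        self.top_z = np.asarray(self.top_z, dtype=float)
        self.bottom_z = np.asarray(self.bottom_z, dtype=float)
        if self.top_z.shape != self.bottom_z.shape:
            raise InvalidGeometryError("slab bound arrays must share one shape")
        if np.any(self.top_z > self.bottom_z + 1e-9):
            raise InvalidGeometryError(f"slab {self.name!r}: top_z exceeds bottom_z somewhere")


@dataclass
class EnFaceMap:
    """A 2-D lateral map sharing the volume's lateral geometry."""

    values: np.ndarray
    kind: str
    lateral_spacing_mm: float

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise InvalidGeometryError("en face maps are 2-D")
        if self.kind not in MAP_KINDS:
            raise InvalidGeometryError(f"unknown map kind {self.kind!r}")
        if self.kind == "mask" or self.kind == "exclusion":
            vals = np.unique(self.values)
            if not np.all(np.isin(vals, (0, 1))):
                raise InvalidGeometryError(f"{self.kind} maps must be binary")
        if self.kind == "vd":
            if np.any(self.values < -1e-9) or np.any(self.values > 1 + 1e-9):
                raise InvalidGeometryError("vd maps must lie in [0, 1]")
        if self.kind == "thickness" and np.any(self.values < 0):
            raise InvalidGeometryError("thickness maps must be non-negative")

    @property
    def shape(self):
        return self.values.shape

    def mirrored(self) -> "EnFaceMap":
        return replace(self, values=self.values[::-1].copy())


def validate_surfaces(s: SurfaceSet, v: ScanVolume) -> SurfaceSet:
    """Check surface ordering and bounds against a volume.

    Returns the surfaces unchanged when ``ilm <= nflgcl <= iplinl`` holds at
    every A-line and all depths lie inside the volume; otherwise raises
    :class:`SegmentationError` listing the offending A-line indices.
    """
    if s.shape != v.shape[:2]:
        raise InvalidGeometryError(
            f"surface lateral shape {s.shape} != volume lateral shape {v.shape[:2]}"
        )
    nz = v.shape[2]
    bad_order = (s.nflgcl_z < s.ilm_z) | (s.iplinl_z < s.nflgcl_z)
    bad_bounds = (s.ilm_z < 0) | (s.iplinl_z > nz)
    if np.any(bad_order):
        idx = np.argwhere(bad_order)
        raise SegmentationError(
            f"surface ordering violated at {idx.shape[0]} A-line(s), first at {tuple(idx[0])}",
            alines=idx,
        )
    if np.any(bad_bounds):
        idx = np.argwhere(bad_bounds)
        raise SegmentationError(
            f"surface depth out of volume bounds at {idx.shape[0]} A-line(s), "
            f"first at {tuple(idx[0])}",
            alines=idx,
        )
    return s


def gcipl_fraction_slab(s: SurfaceSet, f_top: float, f_bottom: float, name: str = "") -> Slab:
    """Slab bounded by depth fractions of the GCIPL (0 at NFL/GCL, 1 at IPL/INL).

    ``top_z = nflgcl_z + f_top * (iplinl_z - nflgcl_z)`` per A-line, and
    analogously for the bottom.
    """
    if not (0.0 <= f_top < f_bottom <= 1.0):
        raise ValueError(f"require 0 <= f_top < f_bottom <= 1, got ({f_top}, {f_bottom})")
    thick = s.iplinl_z - s.nflgcl_z
    return Slab(
        top_z=s.nflgcl_z + f_top * thick,
        bottom_z=s.nflgcl_z + f_bottom * thick,
        name=name or f"GCIPL[{f_top:g},{f_bottom:g}]",
    )


def subdivide_gcipl(s: SurfaceSet, n: int) -> list[Slab]:
    """Divide the GCIPL into ``n`` equal-depth-fraction sub-slabs.

    Sub-slab ``i`` spans fractions ``(i/n, (i+1)/n)``; adjacent slabs share
    their boundary exactly, so with half-open voxel inclusion the sub-slabs
    tile the GCIPL with no gap and no overlap.
    """
    if n < 2:
        raise ValueError(f"need at least 2 sub-slabs, got {n}")
    thick = s.iplinl_z - s.nflgcl_z
    bounds = [s.nflgcl_z + (i / n) * thick for i in range(n + 1)]
    return [
        Slab(top_z=bounds[i], bottom_z=bounds[i + 1], name=f"GCIPL-sub{i:02d}/{n}")
        for i in range(n)
    ]


def thickness_map(slab: Slab, axial_spacing_um: float, lateral_spacing_mm: float) -> EnFaceMap:
    """Per-(x, y) slab thickness in µm."""
    return EnFaceMap(
        values=(slab.bottom_z - slab.top_z) * axial_spacing_um,
        kind="thickness",
        lateral_spacing_mm=lateral_spacing_mm,
    )


def slab_voxel_mask(slab: Slab, nz: int, z0: int = 0) -> np.ndarray:
    """Boolean (nx, ny, nz) mask of voxels whose centers fall in the slab.

    ``z0`` offsets the voxel index axis, for use with z-cropped volumes.
    """
    zc = np.arange(z0, z0 + nz) + 0.5
    return (zc >= slab.top_z[..., None]) & (zc < slab.bottom_z[..., None])
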