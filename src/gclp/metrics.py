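"""En face angiogram metrics: slab projection, reflectance-compensated
binarization, vessel-density mapping, and low-signal exclusion.

The vessel density (VD) of a region is the fraction of its en face area
occupied by vessel pixels.  Binarization uses a threshold map linear in a
local reflectance reference, which compensates for OCT signal-strength
variation (shadowing, vignetting): scaling structure and flow jointly leaves
the vessel mask unchanged when the threshold offset is zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter

from .errors import InvalidGeometryError, MissingDataError
from .volume import EnFaceMap, Slab, SurfaceSet

__all__ = [
    "VDParams",
    "enface_max_projection",
    "reflectance_reference",
    "adaptive_threshold_map",
    "binarize",
    "vessel_density_map",
    "low_signal_exclusion",
    "vd_in_region",
]


@dataclass
class VDParams:
    """Parameters of the vessel-density pipeline.

    threshold(x, y) = threshold_offset + threshold_slope * reference(x, y).
    Defaults are calibrated to the phantom generator's reflectance stack and
    noise floor (see docs/methods.md); on other data they are run-config
    settings, not constants.
    """

    threshold_slope: float = 1.16
    threshold_offset: float = 0.03
    lowpass_kernel_px: int = 7
    low_signal_cutoff: float = 0.12
    reference_extent_um: float = 120.0  # reference slab depth below IPL/INL

    def __post_init__(self):
        if self.lowpass_kernel_px < 1 or self.lowpass_kernel_px % 2 == 0:
            raise ValueError("lowpass kernel must be odd and >= 1")
        if self.threshold_slope < 0:
            raise ValueError("threshold slope must be >= 0")


def _check_same_geometry(*maps: EnFaceMap):
    shapes = {m.shape for m in maps}
    if len(shapes) > 1:
        raise InvalidGeometryError(f"en face maps disagree in shape: {shapes}")


def enface_max_projection(flow: np.ndarray, slab: Slab, lateral_spacing_mm: float,
                          axial_spacing_um: float | None = None) -> EnFaceMap:
    """Maximum flow projection over a slab (voxel-center inclusion).

    Columns where the slab has zero thickness (no voxel centers inside)
    project to 0.
    """
    flow = np.asarray(flow)
    if slab.top_z.shape != flow.shape[:2]:
        raise InvalidGeometryError("slab lateral shape must match the volume")
    z0 = max(int(np.floor(slab.top_z.min())), 0)
    z1 = min(int(np.ceil(slab.bottom_z.max())) + 1, flow.shape[2])
    if z1 <= z0:
        vals = np.zeros(flow.shape[:2], dtype=flow.dtype)
    else:
        sub = flow[:, :, z0:z1]
        zc = np.arange(z0, z1) + 0.5
        inside = (zc >= slab.top_z[..., None]) & (zc < slab.bottom_z[..., None])
        vals = np.where(inside, sub, 0).max(axis=-1)
    return EnFaceMap(values=vals, kind="angiogram", lateral_spacing_mm=lateral_spacing_mm)


def reflectance_reference(structure: np.ndarray, surfaces: SurfaceSet,
                          lateral_spacing_mm: float, axial_spacing_um: float,
                          extent_um: float = 120.0) -> EnFaceMap:
    """Mean structural signal in a reference slab below the IPL/INL surface.

    The reference slab spans from the IPL/INL surface down by ``extent_um``,
    covering the INL and outer layers whose reflectance tracks overall signal
    strength rather than inner-retinal pathology.
    """
    structure = np.asarray(structure)
    top = surfaces.iplinl_z
    bottom = surfaces.iplinl_z + extent_um / axial_spacing_um
    z0 = max(int(np.floor(top.min())), 0)
    z1 = min(int(np.ceil(bottom.max())) + 1, structure.shape[2])
    sub = structure[:, :, z0:z1]
    zc = np.arange(z0, z1) + 0.5
    inside = (zc >= top[..., None]) & (zc < bottom[..., None])
    counts = inside.sum(axis=-1)
    sums = np.where(inside, sub, 0).sum(axis=-1)
    vals = np.divide(sums, counts, out=np.zeros_like(sums, dtype=float),
                     where=counts > 0)
    return EnFaceMap(values=vals, kind="angiogram", lateral_spacing_mm=lateral_spacing_mm)


def adaptive_threshold_map(ref: EnFaceMap, p: VDParams) -> EnFaceMap:
    """Threshold map linear in the reflectance reference."""
    if np.any(ref.values < 0):
        raise ValueError("reference map must be non-negative")
    vals = p.threshold_offset + p.threshold_slope * ref.values
    return EnFaceMap(values=vals, kind="threshold", lateral_spacing_mm=ref.lateral_spacing_mm)


def binarize(angio: EnFaceMap, thr: EnFaceMap) -> EnFaceMap:
    """Vessel mask: 1 where angiogram strictly exceeds the threshold map."""
    _check_same_geometry(angio, thr)
    mask = (angio.values > thr.values).astype(np.uint8)
    return EnFaceMap(values=mask, kind="mask", lateral_spacing_mm=angio.lateral_spacing_mm)


def vessel_density_map(mask: EnFaceMap, p: VDParams) -> EnFaceMap:
    """Moving-average of the vessel mask with a square kernel."""
    if mask.kind != "mask":
        raise InvalidGeometryError("vessel_density_map needs a binary mask map")
    vd = uniform_filter(mask.values.astype(float), size=p.lowpass_kernel_px,
                        mode="nearest")
    vd = np.clip(vd, 0.0, 1.0)
    return EnFaceMap(values=vd, kind="vd", lateral_spacing_mm=mask.lateral_spacing_mm)


def low_signal_exclusion(ref: EnFaceMap, p: VDParams) -> EnFaceMap:
    """Flag pixels whose reflectance reference is too low for reliable
    vessel detection (floaters, vignetting)."""
    ex = (ref.values < p.low_signal_cutoff).astype(np.uint8)
    return EnFaceMap(values=ex, kind="exclusion", lateral_spacing_mm=ref.lateral_spacing_mm)


def vd_in_region(vd_or_mask: EnFaceMap, region: EnFaceMap,
                 exclusion: EnFaceMap | None = None) -> float:
    """Mean of a VD map (or vessel mask) over a region, minus excluded pixels."""
    if exclusion is not None:
        _check_same_geometry(vd_or_mask, region, exclusion)
        keep = (region.values > 0) & (exclusion.values == 0)
    else:
        _check_same_geometry(vd_or_mask, region)
        keep = region.values > 0
    if not np.any(keep):
        raise MissingDataError("region is empty after low-signal exclusion")
    return float(vd_or_mask.values[keep].mean())
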