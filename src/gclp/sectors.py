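"""FAZ-centered polar sector grid and sector-mean aggregation.

The macular en face plane is partitioned into annuli of 0.5 mm radial
increment and 16 angular slices (22.5° each), centered on the foveal
avascular zone.  The central 1-mm-diameter circle is excluded because the
plexuses merge near the FAZ.  Angle is measured from the temporal horizontal,
counter-clockwise in OD orientation (nasal at +x, superior at +y); quadrants
are four contiguous slices spanning 90° centered on each principal axis.
Radial and angular bins are half-open with ties to the lower bin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import InvalidGeometryError
from .volume import EnFaceMap

__all__ = ["SectorGrid", "find_faz_center", "build_polar_grid", "sector_means",
           "QUADRANTS"]

log = logging.getLogger(__name__)

# quadrant of each of 16 slices, slice 0 starting at the temporal horizontal:
# 90° quadrants centered on temporal (theta=0), superior (90°), nasal (180°),
# inferior (270°)
QUADRANTS = ("T", "S", "N", "I")


def _quadrant_of_slice(n_theta: int) -> list:
    """Quadrant label per slice: 4 contiguous slices centered on each axis."""
    per_quadrant = n_theta // 4
    out = []
    for s in range(n_theta):
        # rotate by half a quadrant so quadrants are centered on the axes
        q = int(((s + per_quadrant / 2) % n_theta) // per_quadrant)
        out.append(QUADRANTS[q])
    return out


@dataclass
class SectorGrid:
    center_px: tuple  # (x, y), fractional pixels
    dr_mm: float
    n_theta: int
    r_inner_mm: float
    r_outer_mm: float
    lateral_spacing_mm: float
    sector_id_map: np.ndarray  # int, -1 outside the annulus
    ring_of_sector: np.ndarray
    slice_of_sector: np.ndarray
    quadrant_of_sector: np.ndarray  # 'T'/'S'/'N'/'I'
    partial_ring_start: int  # first ring index extending beyond the inscribed circle

    @property
    def n_rings(self) -> int:
        return int(np.ceil((self.r_outer_mm - self.r_inner_mm) / self.dr_mm))

    @property
    def n_sectors(self) -> int:
        return self.n_rings * self.n_theta


def find_faz_center(vd: EnFaceMap, cutoff: float = 0.05, box_mm: float = 1.5) -> tuple:
    """Locate the FAZ as the centroid of the largest connected low-VD
    component within the central box; falls back to the scan center."""
    n, m = vd.shape
    cx, cy = (n - 1) / 2.0, (m - 1) / 2.0
    half = box_mm / 2.0 / vd.lateral_spacing_mm
    x0, x1 = max(0, int(cx - half)), min(n, int(cx + half) + 1)
    y0, y1 = max(0, int(cy - half)), min(m, int(cy + half) + 1)
    box = vd.values[x0:x1, y0:y1] < cutoff
    labels, n_comp = ndimage.label(box)
    if n_comp == 0:
        log.info("no avascular component found; falling back to scan center")
        return (cx, cy)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n_comp + 1))
    largest = int(np.argmax(sizes)) + 1
    xs, ys = np.nonzero(labels == largest)
    return (float(xs.mean()) + x0, float(ys.mean()) + y0)


def build_polar_grid(center_px: tuple, shape: tuple, lateral_spacing_mm: float,
                     dr_mm: float = 0.5, n_theta: int = 16,
                     r_inner_mm: float = 0.5, r_outer_mm: float | None = None) -> SectorGrid:
    """Build the polar sector partition of the en face plane.

    ``ring = floor((r - r_inner)/dr)``, ``slice = floor(n_theta * theta/2pi)``
    with theta from the temporal horizontal (the -x direction in canonical OD
    orientation), counter-clockwise; ``sector_id = ring*n_theta + slice``.
    By default all pixels of the field are kept; rings at or beyond the
    inscribed circle are reported via ``partial_ring_start`` so corner
    sectors can be excluded by callers.
    """
    if n_theta < 4 or n_theta % 4 != 0 or dr_mm <= 0:
        raise InvalidGeometryError("need dr_mm > 0 and n_theta a positive multiple of 4")
    n, m = shape
    cx, cy = center_px
    if not (0 <= cx < n and 0 <= cy < m):
        raise InvalidGeometryError("grid center must lie inside the field")
    xs = (np.arange(n)[:, None] - cx) * lateral_spacing_mm
    ys = (np.arange(m)[None, :] - cy) * lateral_spacing_mm
    r = np.hypot(xs, ys)
    if r_outer_mm is None:
        r_outer_mm = float(r.max()) + 1e-9
    # temporal horizontal = -x for OD; counter-clockwise toward superior (+y)
    theta = np.mod(np.arctan2(ys, -xs), 2 * np.pi)
    ring = np.floor((r - r_inner_mm) / dr_mm).astype(int)
    slc = np.floor(n_theta * theta / (2 * np.pi)).astype(int)
    slc = np.clip(slc, 0, n_theta - 1)  # guard the theta == 2*pi edge case
    n_rings = int(np.ceil((r_outer_mm - r_inner_mm) / dr_mm))
    ids = ring * n_theta + slc
    ids[(ring < 0) | (r >= r_outer_mm)] = -1

    n_sectors = n_rings * n_theta
    ring_of = np.repeat(np.arange(n_rings), n_theta)
    slice_of = np.tile(np.arange(n_theta), n_rings)
    quad_slice = _quadrant_of_slice(n_theta)
    quad_of = np.array([quad_slice[s] for s in slice_of])

    # inscribed-circle radius from the grid center; rings beyond it touch the
    # field corners and may be partially outside the scan
    half_field_mm = min(cx, n - 1 - cx, cy, m - 1 - cy) * lateral_spacing_mm
    partial_start = int(np.floor((half_field_mm - r_inner_mm) / dr_mm))

    return SectorGrid(
        center_px=(float(cx), float(cy)), dr_mm=dr_mm, n_theta=n_theta,
        r_inner_mm=r_inner_mm, r_outer_mm=float(r_outer_mm),
        lateral_spacing_mm=lateral_spacing_mm, sector_id_map=ids,
        ring_of_sector=ring_of, slice_of_sector=slice_of,
        quadrant_of_sector=quad_of, partial_ring_start=partial_start,
    )


def sector_means(emap: EnFaceMap, grid: SectorGrid,
                 exclusion: EnFaceMap | None = None) -> pd.DataFrame:
    """Per-sector mean of a map over non-excluded pixels.

    Returns a table with one row per sector id (including empty sectors):
    sector_id, ring_index, slice_index, quadrant, n_pixels, n_excluded,
    mean_value (NaN when every pixel is excluded or the sector is empty,
    flagged in the ``missing`` column).
    """
    if emap.shape != grid.sector_id_map.shape:
        raise InvalidGeometryError("map and grid shapes differ")
    ids = grid.sector_id_map
    inside = ids >= 0
    if exclusion is not None:
        if exclusion.shape != emap.shape:
            raise InvalidGeometryError("exclusion map shape differs")
        keep = inside & (exclusion.values == 0)
    else:
        keep = inside
    n_sec = grid.n_sectors
    n_pixels = np.bincount(ids[inside], minlength=n_sec)
    n_kept = np.bincount(ids[keep], minlength=n_sec)
    sums = np.bincount(ids[keep], weights=emap.values[keep].astype(float),
                       minlength=n_sec)
    with np.errstate(invalid="ignore"):
        means = np.where(n_kept > 0, sums / np.maximum(n_kept, 1), np.nan)
    return pd.DataFrame({
        "sector_id": np.arange(n_sec),
        "ring_index": grid.ring_of_sector,
        "slice_index": grid.slice_of_sector,
        "quadrant": grid.quadrant_of_sector,
        "n_pixels": n_pixels,
        "n_excluded": n_pixels - n_kept,
        "mean_value": means,
        "missing": n_kept == 0,
    })
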