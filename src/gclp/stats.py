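"""Named slab definitions and cohort statistics.

The watershed analysis places the GCLP/ICP boundary at 75% of the GCIPL
depth, so the named slabs are:

* GCLP — NFL/GCL surface to 75% GCIPL depth,
* SVC  — ILM to 75% GCIPL depth (NFLP + GCLP),
* GCC  — ILM to IPL/INL,
* GCIPL — NFL/GCL to IPL/INL,
* NFL  — ILM to NFL/GCL.

This module also compares the present 75%-GCIPL posterior boundary with the
older 80%-GCC rule, and provides the cohort statistics used on slab maps:
sector-level Pearson correlation, paired t-tests, within-subject repeat
coefficient of variation, and population mean/SD maps with left eyes
mirrored into right-eye orientation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import InvalidGeometryError
from .volume import EnFaceMap, Slab, SurfaceSet

__all__ = [
    "SlabDefinition",
    "NAMED_SLABS",
    "GCLP_GCIPL_FRACTION",
    "resolve_slab",
    "compare_gcc80_gcipl75",
    "pearson_r2",
    "paired_t",
    "repeatability_cv",
    "population_maps",
    "CohortStats",
    "bootstrap_r2_difference",
]

log = logging.getLogger(__name__)

# posterior GCLP boundary as a GCIPL depth fraction
GCLP_GCIPL_FRACTION = 0.75


@dataclass
class SlabDefinition:
    """A slab anchored to surfaces: each anchor is (surface_name, fraction)
    where fraction interpolates from that surface toward IPL/INL along the
    GCIPL span (0 = at the surface)."""

    name: str
    top: tuple  # (surface, gcipl_fraction)
    bottom: tuple

    def _anchor_z(self, anchor: tuple, s: SurfaceSet) -> np.ndarray:
        surface, frac = anchor
        bases = {"ilm": s.ilm_z, "nflgcl": s.nflgcl_z, "iplinl": s.iplinl_z}
        if surface not in bases:
            raise InvalidGeometryError(f"unknown surface anchor {surface!r}")
        return bases[surface] + frac * (s.iplinl_z - s.nflgcl_z)


NAMED_SLABS = {
    "GCLP": SlabDefinition("GCLP", ("nflgcl", 0.0), ("nflgcl", GCLP_GCIPL_FRACTION)),
    "SVC": SlabDefinition("SVC", ("ilm", 0.0), ("nflgcl", GCLP_GCIPL_FRACTION)),
    "GCC": SlabDefinition("GCC", ("ilm", 0.0), ("iplinl", 0.0)),
    "GCIPL": SlabDefinition("GCIPL", ("nflgcl", 0.0), ("iplinl", 0.0)),
    "NFL": SlabDefinition("NFL", ("ilm", 0.0), ("nflgcl", 0.0)),
}


def resolve_slab(definition: SlabDefinition | str, s: SurfaceSet) -> Slab:
    """Resolve a slab definition (or a named slab) against a surface set."""
    if isinstance(definition, str):
        definition = NAMED_SLABS[definition]
    return Slab(top_z=definition._anchor_z(definition.top, s),
                bottom_z=definition._anchor_z(definition.bottom, s),
                name=definition.name)


def compare_gcc80_gcipl75(s: SurfaceSet, axial_spacing_um: float,
                          lateral_spacing_mm: float) -> EnFaceMap:
    """Signed depth difference (µm) between the 80%-GCC and 75%-GCIPL
    posterior boundaries, measured from the ILM.

    ``diff = 0.8*(NFL + GCIPL) - (NFL + 0.75*GCIPL) = 0.05*GCIPL - 0.2*NFL``,
    so the 80%-GCC boundary is shallower (diff < 0) exactly where
    ``NFL > GCIPL/4`` — i.e. where the NFL is thick.
    """
    nfl = (s.nflgcl_z - s.ilm_z) * axial_spacing_um
    gcipl = (s.iplinl_z - s.nflgcl_z) * axial_spacing_um
    diff = 0.8 * (nfl + gcipl) - (nfl + 0.75 * gcipl)
    return EnFaceMap(values=diff, kind="angiogram", lateral_spacing_mm=lateral_spacing_mm)


def pearson_r2(x, y) -> float:
    """Squared Pearson correlation over paired sector values."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError("need at least 3 paired sectors")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    r, _ = sps.pearsonr(x, y)
    return float(r ** 2)


def paired_t(a, b) -> tuple:
    """Two-sided paired t-test; returns (t, p, mean difference).

    Zero-variance differences (perfectly constant shift) are degenerate:
    (inf-signed t, p = 0 when the shift is nonzero) is not meaningful, so
    they raise ValueError for the caller to flag.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need paired samples of equal length >= 2")
    d = a - b
    if np.std(d, ddof=1) == 0:
        if np.allclose(d, 0):
            return 0.0, 1.0, 0.0
        raise ValueError("zero-variance nonzero differences: t degenerate")
    t, p = sps.ttest_rel(a, b)
    return float(t), float(p), float(d.mean())


def repeatability_cv(repeat1, repeat2) -> float:
    """Within-subject coefficient of variation of paired repeat scans.

    within-subject SD = sqrt(mean(d^2 / 2)) over eyes, d the repeat
    difference; CV = within-subject SD / grand mean.
    """
    a = np.asarray(repeat1, dtype=float)
    b = np.asarray(repeat2, dtype=float)
    if a.shape != b.shape or a.size < 1:
        raise ValueError("need paired repeats per eye")
    grand = float(np.mean((a + b) / 2.0))
    if grand == 0:
        raise ValueError("grand mean is zero: CV undefined")
    ws_sd = float(np.sqrt(np.mean((a - b) ** 2 / 2.0)))
    return ws_sd / grand


@dataclass
class CohortStats:
    mean_map: EnFaceMap
    sd_map: EnFaceMap
    n_eyes: int
    nasal_mean: float
    temporal_mean: float


def population_maps(maps: list, lateralities: list, kind: str = "vd") -> CohortStats:
    """Pixelwise population mean and SD maps, left eyes mirrored to OD
    orientation before pooling; reports the nasal vs temporal half means of
    the mean map (nasal at +x in OD orientation)."""
    if len(maps) < 2 or len(maps) != len(lateralities):
        raise ValueError("need >= 2 eyes with one laterality each")
    arrs = []
    shape = maps[0].shape
    for m, lat in zip(maps, lateralities):
        if m.shape != shape:
            raise InvalidGeometryError("population maps must share one geometry")
        arrs.append(m.values[::-1] if lat == "OS" else m.values)
    stack = np.stack(arrs).astype(float)
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    half = shape[0] // 2
    return CohortStats(
        mean_map=EnFaceMap(mean, kind, maps[0].lateral_spacing_mm),
        sd_map=EnFaceMap(np.maximum(sd, 0.0),
                         "vd" if kind == "vd" else kind,
                         maps[0].lateral_spacing_mm),
        n_eyes=len(maps),
        nasal_mean=float(mean[shape[0] - half:].mean()),
        temporal_mean=float(mean[:half].mean()),
    )


def bootstrap_r2_difference(x1, x2, y, n_boot: int = 2000, seed: int = 0) -> tuple:
    """Bootstrap (over sectors) test that r2(x1, y) exceeds r2(x2, y).

    Returns (delta_r2, p_one_sided) where p is the bootstrap fraction of
    resamples with r2(x1,y) <= r2(x2,y).
    """
    x1 = np.asarray(x1, float); x2 = np.asarray(x2, float); y = np.asarray(y, float)
    n = len(y)
    rng = np.random.default_rng(seed)
    delta = pearson_r2(x1, y) - pearson_r2(x2, y)
    worse = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        try:
            d = pearson_r2(x1[idx], y[idx]) - pearson_r2(x2[idx], y[idx])
        except ValueError:
            continue
        if d <= 0:
            worse += 1
    return float(delta), worse / n_boot
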