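"""End-to-end analysis: one scan to watershed + slab metrics, and cohorts.

Per eye, in canonical OD orientation (OS scans are mirrored on entry):

1. validate surfaces, resolve projection artifacts (strict axial-peak
   retention),
2. build the reflectance reference, adaptive threshold and low-signal
   exclusion maps,
3. locate the FAZ on the whole-GCIPL VD map and build the polar sector grid
   (0.5 mm annuli, 16 slices, central 1 mm excluded),
4. compute the 20-sub-slab VD depth profiles per sector, fit the
   sixth-degree polynomial, and locate the GCLP peak and GCLP/ICP watershed,
5. measure GCLP and SVC vessel density (with and without projection
   resolution) and slab thicknesses over the full-ring annulus.

Cohort helpers aggregate eyes: population maps (left eyes mirrored),
repeatability CVs over paired repeats, and sector-level correlations of
GCLP VD against NFL / GCIPL / GCC thickness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import NoWatershedError
from .metrics import (VDParams, adaptive_threshold_map, binarize,
                      enface_max_projection, low_signal_exclusion,
                      reflectance_reference, vd_in_region, vessel_density_map)
from .projection import resolve_projection
from .sectors import build_polar_grid, find_faz_center, sector_means
from .stats import (NAMED_SLABS, paired_t, pearson_r2, population_maps,
                    repeatability_cv, resolve_slab)
from .volume import (EnFaceMap, ScanVolume, SurfaceSet, gcipl_fraction_slab,
                     thickness_map, validate_surfaces)
from .watershed import (aggregate_quadrants, find_watershed, profile_for_group,
                        raw_profile_minimum, subslab_vd_profiles)

__all__ = ["EyeAnalysis", "CohortAnalysis", "analyze_eye", "analyze_cohort"]

SLAB_NAMES = ("GCLP", "SVC", "GCC", "GCIPL", "NFL")


@dataclass
class EyeAnalysis:
    grid: object
    threshold: EnFaceMap
    exclusion: EnFaceMap
    profiles: pd.DataFrame
    watershed: object | None
    raw_minimum: float
    quadrants: pd.DataFrame
    slab_vd: dict  # name -> {"with_pr": float, "without_pr": float}
    slab_thickness_um: dict  # name -> annulus mean thickness
    vd_maps: dict  # name -> EnFaceMap (projection-resolved)
    thickness_maps: dict
    vd_sectors: dict  # name -> per-sector VD table
    thickness_sectors: dict


def _region_map(grid) -> EnFaceMap:
    """Full-ring annulus region (partial corner rings excluded)."""
    ids = grid.sector_id_map
    ring = np.where(ids >= 0, ids // grid.n_theta, -1)
    region = ((ids >= 0) & (ring < grid.partial_ring_start)).astype(np.uint8)
    return EnFaceMap(region, "mask", grid.lateral_spacing_mm)


def analyze_eye(volume: ScanVolume, surfaces: SurfaceSet,
                params: VDParams | None = None, n_subslabs: int = 20,
                use_pr: bool = True, faz_center: tuple | None = None) -> EyeAnalysis:
    """Run the full single-eye analysis.  ``use_pr=False`` bypasses
    projection resolution everywhere (for with/without comparisons)."""
    if params is None:
        params = VDParams()
    if volume.laterality == "OS":
        volume = volume.mirrored()
        surfaces = surfaces.mirrored()
    validate_surfaces(surfaces, volume)
    sp = volume.lateral_spacing_mm

    pr_flow = resolve_projection(volume).pr_flow if use_pr else volume.flow

    ref = reflectance_reference(volume.structure, surfaces, sp,
                                volume.axial_spacing_um, params.reference_extent_um)
    threshold = adaptive_threshold_map(ref, params)
    exclusion = low_signal_exclusion(ref, params)

    # FAZ localization on the whole-GCIPL VD map
    gcipl = gcipl_fraction_slab(surfaces, 0.0, 1.0)
    whole_angio = enface_max_projection(pr_flow, gcipl, sp)
    whole_vd = vessel_density_map(binarize(whole_angio, threshold), params)
    if faz_center is None:
        faz_center = find_faz_center(whole_vd)
    grid = build_polar_grid(faz_center, whole_vd.shape, sp)
    region = _region_map(grid)

    profiles = subslab_vd_profiles(pr_flow, surfaces, grid, params, threshold,
                                   n=n_subslabs, exclusion=exclusion,
                                   max_ring=grid.partial_ring_start)
    aggregate = profile_for_group(profiles, label="aggregate")
    try:
        ws = find_watershed(aggregate)
    except NoWatershedError:
        ws = None
    raw_min = raw_profile_minimum(aggregate)
    quadrants = aggregate_quadrants(profiles)

    slab_vd, slab_thick = {}, {}
    vd_maps, thick_maps, vd_sectors, thick_sectors = {}, {}, {}, {}
    for name in SLAB_NAMES:
        slab = resolve_slab(NAMED_SLABS[name], surfaces)
        tmap = thickness_map(slab, volume.axial_spacing_um, sp)
        thick_maps[name] = tmap
        thick_sectors[name] = sector_means(tmap, grid, exclusion)
        slab_thick[name] = vd_in_region(tmap, region, exclusion)
        if name in ("GCLP", "SVC"):
            masks = {}
            for tag, fl in (("with_pr", pr_flow), ("without_pr", volume.flow)):
                angio = enface_max_projection(fl, slab, sp)
                masks[tag] = binarize(angio, threshold)
            slab_vd[name] = {tag: vd_in_region(m, region, exclusion)
                             for tag, m in masks.items()}
            vd_maps[name] = vessel_density_map(masks["with_pr"], params)
            vd_sectors[name] = sector_means(vd_maps[name], grid, exclusion)

    return EyeAnalysis(grid=grid, threshold=threshold, exclusion=exclusion,
                       profiles=profiles, watershed=ws, raw_minimum=raw_min,
                       quadrants=quadrants, slab_vd=slab_vd,
                       slab_thickness_um=slab_thick, vd_maps=vd_maps,
                       thickness_maps=thick_maps, vd_sectors=vd_sectors,
                       thickness_sectors=thick_sectors)


@dataclass
class CohortAnalysis:
    eye_results: list  # list of lists (per eye, per repeat)
    summary: dict = field(default_factory=dict)
    sector_table: pd.DataFrame | None = None
    population: dict = field(default_factory=dict)


def _common_sector_frame(results: list) -> pd.DataFrame:
    """Across-eye sector means of GCLP VD and slab thicknesses, joined on
    sector_id over sectors valid in every eye."""
    frames = []
    for i, res in enumerate(results):
        t = res.vd_sectors["GCLP"][["sector_id", "mean_value", "missing"]].rename(
            columns={"mean_value": "gclp_vd"})
        for name in ("NFL", "GCIPL", "GCC"):
            t[f"{name.lower()}_um"] = res.thickness_sectors[name]["mean_value"]
        ring = res.vd_sectors["GCLP"]["ring_index"]
        t = t[(~t["missing"]) & (ring < res.grid.partial_ring_start)]
        t["eye"] = i
        frames.append(t.drop(columns="missing"))
    longf = pd.concat(frames, ignore_index=True)
    counts = longf.groupby("sector_id")["eye"].nunique()
    keep = counts[counts == len(results)].index
    longf = longf[longf["sector_id"].isin(keep)]
    return longf.groupby("sector_id").mean().drop(columns="eye").reset_index()


def analyze_cohort(eyes: list, params: VDParams | None = None,
                   n_subslabs: int = 20) -> CohortAnalysis:
    """Analyze a cohort of phantom (or loaded) eyes.

    ``eyes`` is an iterable of objects with ``volumes`` (one ScanVolume per
    repeat), ``surfaces`` and ``laterality``; an iterator/generator keeps
    only one eye's volumes in memory at a time.  The first repeat carries
    the primary per-eye metrics; repeat pairs feed the repeatability CVs.
    """
    all_results = []
    for eye in eyes:
        per_repeat = [analyze_eye(v, eye.surfaces, params, n_subslabs)
                      for v in eye.volumes]
        all_results.append(per_repeat)
    n_eyes = len(all_results)
    primary = [r[0] for r in all_results]

    troughs = [r.watershed.trough_fraction for r in primary if r.watershed]
    peaks = [r.watershed.peak_fraction for r in primary if r.watershed]
    gclp_pr = [r.slab_vd["GCLP"]["with_pr"] for r in primary]
    gclp_nopr = [r.slab_vd["GCLP"]["without_pr"] for r in primary]
    svc_pr = [r.slab_vd["SVC"]["with_pr"] for r in primary]
    svc_nopr = [r.slab_vd["SVC"]["without_pr"] for r in primary]

    summary = {
        "n_eyes": n_eyes,
        "watershed_mean": float(np.mean(troughs)) if troughs else float("nan"),
        "watershed_sd": float(np.std(troughs, ddof=1)) if len(troughs) > 1 else float("nan"),
        "peak_mean": float(np.mean(peaks)) if peaks else float("nan"),
        "peak_sd": float(np.std(peaks, ddof=1)) if len(peaks) > 1 else float("nan"),
        "gclp_vd_with_pr": float(np.mean(gclp_pr)),
        "gclp_vd_without_pr": float(np.mean(gclp_nopr)),
        "svc_vd_with_pr": float(np.mean(svc_pr)),
        "svc_vd_without_pr": float(np.mean(svc_nopr)),
    }
    if n_eyes >= 2:
        t, pval, md = paired_t(gclp_nopr, gclp_pr)
        summary["gclp_pr_paired_t"] = t
        summary["gclp_pr_paired_p"] = pval
        summary["gclp_pr_mean_diff"] = md

    # repeatability over paired repeats
    if all(len(r) >= 2 for r in all_results) and all_results:
        def _cv(metric):
            a = [metric(r[0]) for r in all_results]
            b = [metric(r[1]) for r in all_results]
            return repeatability_cv(a, b)
        summary["cv_gclp_vd"] = _cv(lambda r: r.slab_vd["GCLP"]["with_pr"])
        summary["cv_svc_vd"] = _cv(lambda r: r.slab_vd["SVC"]["with_pr"])
        summary["cv_gcipl_thickness"] = _cv(lambda r: r.slab_thickness_um["GCIPL"])
        summary["cv_gcc_thickness"] = _cv(lambda r: r.slab_thickness_um["GCC"])

    sector_table = None
    if len(primary) >= 2:
        sector_table = _common_sector_frame(primary)
        if len(sector_table) >= 3:
            for name in ("nfl", "gcipl", "gcc"):
                summary[f"r2_gclp_vd_vs_{name}"] = pearson_r2(
                    sector_table[f"{name}_um"], sector_table["gclp_vd"])

    population = {}
    if len(primary) >= 2:
        # analyze_eye already mirrors OS scans into OD orientation, so the
        # per-eye maps are canonical here and need no further flipping
        lats = ["OD"] * len(primary)
        for name in ("GCLP", "SVC"):
            population[name] = population_maps(
                [r.vd_maps[name] for r in primary], lats)
        summary["gclp_vd_nasal_mean"] = population["GCLP"].nasal_mean
        summary["gclp_vd_temporal_mean"] = population["GCLP"].temporal_mean

    return CohortAnalysis(eye_results=all_results, summary=summary,
                          sector_table=sector_table, population=population)
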