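"""Synthetic macular OCTA phantoms with per-voxel ground truth.

The generator emulates the anatomy the analysis relies on: a layered
reflectance stack (bright NFL, dim GCL, bright IPL, dim INL), a foveal pit
with an avascular zone, four capillary plexuses at controllable depths
(NFLP in the NFL, GCLP in the GCL/anterior IPL, ICP straddling the IPL/INL
border, DCP deeper), flow projection tails decaying below every vessel,
nasal NFL thickening with arcuate fiber orientation, multiplicative speckle
on structure and a flow noise floor, and paired repeat scans that share a
vascular scene but not the noise.

Vessels are rendered as randomly oriented capillary segments (short tubes of
1–2 px lateral radius, one voxel axially) rather than full vascular trees;
this is sufficient for vessel-density statistics.  Every vessel voxel is
labelled with its plexus, the tail-free flow volume is kept, and the true
GCLP/ICP watershed depth is computed by brute-force minimization of the
planted axial density — so parameter-recovery tests need no external data.

Depth coordinates: NFLP vessels are placed at a fraction of the local NFL
span (ILM → NFL/GCL); GCLP, ICP and DCP at a fraction of the local GCIPL
span (NFL/GCL → IPL/INL), where fractions above 1 extend below the IPL/INL
surface (the ICP straddles it, the DCP lies well below).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import truncnorm
from skimage.draw import line as draw_line

from .errors import InvalidGeometryError, NoWatershedTruthError
from .volume import ScanVolume, SurfaceSet

__all__ = [
    "PlexusSpec",
    "TailSpec",
    "NoiseSpec",
    "ShadowSpec",
    "PhantomConfig",
    "TruthScene",
    "PhantomEye",
    "make_surfaces",
    "plant_vessels",
    "render_volumes",
    "generate_cohort",
    "iter_cohort",
    "config_for_watershed",
    "planted_axial_density",
]

# truncation of plexus axial profiles, in units of sigma
_TRUNC = 3.0

# NFLP disappears where the NFL is thinner than this (µm)
NFLP_MIN_NFL_UM = 18.0


@dataclass
class PlexusSpec:
    """One capillary plexus: axial placement and areal coverage.

    center_frac / sigma_frac are in the plexus's anchor-span fraction
    coordinate; areal_fraction is the target fraction of usable en face area
    covered by vessel pixels.  A segment's decorrelation amplitude
    interpolates from amp_lo (shallowest of the plexus's axial span) to
    amp_hi (deepest); per-plexus bands are staggered so that flow amplitude
    is monotone with depth, which is the regime in which axial-peak
    retention keeps in-situ deeper vessels.
    """

    center_frac: float
    sigma_frac: float
    areal_fraction: float
    radius_px: int = 1
    amp_lo: float = 0.8
    amp_hi: float = 0.9
    anchor: str = "gcipl"  # "nfl" or "gcipl"
    oriented: bool = False  # arcuate orientation (nerve-fiber-like)
    center_frac_temporal: float | None = None  # override in the temporal quadrant


@dataclass
class TailSpec:
    """Geometric flow-projection tail: at depth d voxels below a vessel of
    flow f the tail contributes f * decay**d."""

    decay: float = 0.9
    enabled: bool = True


@dataclass
class NoiseSpec:
    speckle_sd: float = 0.2  # multiplicative, structure
    flow_noise: float = 0.015  # additive uniform [0, flow_noise], flow


@dataclass
class ShadowSpec:
    """A floater-like shadow disc attenuating both structure and flow."""

    center_mm: tuple = (1.5, 1.5)  # offset from scan center
    radius_mm: float = 0.5
    attenuation: float = 0.1  # multiplier inside the disc


def _default_plexuses() -> dict:
    # Per-plexus amplitude bands are staggered with depth and separated by
    # more than twice the flow noise so that an in-situ deeper vessel always
    # presents a fresh axial peak (see docs/methods.md).
    return {
        "NFLP": PlexusSpec(0.60, 0.15, 0.35, radius_px=1, amp_lo=0.72, amp_hi=0.78,
                           anchor="nfl", oriented=True),
        "GCLP": PlexusSpec(0.35, 0.19, 0.50, radius_px=1, amp_lo=0.82, amp_hi=0.88),
        "ICP": PlexusSpec(1.02, 0.10, 0.42, radius_px=1, amp_lo=0.92, amp_hi=0.98),
        "DCP": PlexusSpec(1.45, 0.10, 0.42, radius_px=1, amp_lo=1.02, amp_hi=1.08),
    }


PLEXUS_IDS = {"NFLP": 1, "GCLP": 2, "ICP": 3, "DCP": 4}


@dataclass
class PhantomConfig:
    """All knobs of one phantom eye.  Lateral grid and field of view default
    to the 6 × 6 mm, 400 × 400 A-line macular scan pattern."""

    lateral_size_mm: float = 6.0
    grid_n: int = 400
    n_z: int = 320
    axial_spacing_um: float = 3.0
    seed: int = 0

    # foveal pit (ILM depression) and avascular zone
    pit_depth_um: float = 120.0
    pit_radius_mm: float = 0.45
    faz_radius_mm: float = 0.5
    faz_offset_mm: tuple = (0.0, 0.0)

    # layer thickness fields (µm)
    ilm_offset_um: float = 60.0
    nfl_iso_um: float = 10.0  # rotationally symmetric component at field edge
    nfl_wedge_um: float = 35.0  # nasal wedge amplitude at field edge
    gcipl_far_um: float = 45.0
    gcipl_peak_um: float = 95.0
    gcipl_peak_r_mm: float = 1.2
    gcipl_sigma_r_mm: float = 0.8
    pit_thinning: float = 0.65  # fractional GCIPL thinning at the pit center
    inl_um: float = 30.0
    opl_um: float = 20.0
    onl_um: float = 60.0
    flat: bool = False  # constant thickness maps, no pit (test geometry)

    plexus_spec: dict = field(default_factory=_default_plexuses)
    tail_spec: TailSpec = field(default_factory=TailSpec)
    noise_spec: NoiseSpec = field(default_factory=NoiseSpec)
    shadow_spec: ShadowSpec | None = None

    # relative reflectance per layer
    reflectance: dict = field(default_factory=lambda: {
        "vitreous": 0.02, "nfl": 1.0, "gcl": 0.45, "ipl": 0.8,
        "inl": 0.35, "opl": 0.7, "onl": 0.3, "deep": 0.6,
    })

    # segment geometry (lateral, px at the 400-grid scale in mm)
    segment_len_mm: tuple = (0.15, 0.40)

    # when True the GCLP areal density tracks local GCC thickness
    gclp_density_from_gcc: bool = False

    # cohort jitter (relative SDs)
    thickness_jitter_sd: float = 0.06
    density_jitter_sd: float = 0.05

    def __post_init__(self):
        if self.grid_n <= 0 or self.n_z <= 0:
            raise InvalidGeometryError("grid_n and n_z must be positive")
        for nm in ("nfl_iso_um", "gcipl_far_um", "gcipl_peak_um", "inl_um",
                   "opl_um", "onl_um"):
            if getattr(self, nm) <= 0:
                raise InvalidGeometryError(f"{nm} must be positive")
        for name, p in self.plexus_spec.items():
            if not (0.0 < p.areal_fraction < 1.0):
                raise InvalidGeometryError(f"{name}: areal fraction must be in (0,1)")
        if not (0.0 <= self.tail_spec.decay < 1.0):
            raise InvalidGeometryError("tail decay must be in [0,1)")
        if not (0.0 <= self.faz_radius_mm < self.lateral_size_mm / 2):
            raise InvalidGeometryError("faz_radius_mm must be < lateral_size_mm/2")

    @property
    def lateral_spacing_mm(self) -> float:
        return self.lateral_size_mm / self.grid_n

    def lateral_grid_mm(self):
        """(x_mm, y_mm) coordinates of pixel centers relative to scan center."""
        c = (self.grid_n - 1) / 2.0
        ax = (np.arange(self.grid_n) - c) * self.lateral_spacing_mm
        return np.meshgrid(ax, ax, indexing="ij")


@dataclass
class TruthScene:
    """Ground truth of one phantom eye."""

    plexus_label_volume: np.ndarray  # uint8, 0=none 1=NFLP 2=GCLP 3=ICP 4=DCP
    clean_flow: np.ndarray  # tail-free, noise-free flow
    # GCIPL fraction of the planted density minimum; None when the scene was
    # deliberately planted without a GCLP/ICP watershed
    true_watershed_fraction: float | None
    faz_center_px: tuple

    def mirrored(self) -> "TruthScene":
        nx = self.plexus_label_volume.shape[0]
        cx, cy = self.faz_center_px
        return TruthScene(
            plexus_label_volume=self.plexus_label_volume[::-1].copy(),
            clean_flow=self.clean_flow[::-1].copy(),
            true_watershed_fraction=self.true_watershed_fraction,
            faz_center_px=(nx - 1 - cx, cy),
        )


@dataclass
class PhantomEye:
    """One phantom eye of a cohort: repeat scans sharing a vascular scene."""

    eye_id: int
    laterality: str
    volumes: list  # one ScanVolume per repeat
    surfaces: SurfaceSet
    scene: TruthScene
    config: PhantomConfig


# ---------------------------------------------------------------------------
# surfaces


def make_surfaces(cfg: PhantomConfig) -> SurfaceSet:
    """Build the three retinal surfaces from the config's thickness fields.

    The NFL thins to ~0 at the fovea and is thickest nasally; the GCIPL is
    thickest in a parafoveal annulus and thinnest at the pit.  Raises
    :class:`InvalidGeometryError` if the stack does not fit in the volume.
    """
    x_mm, y_mm = cfg.lateral_grid_mm()
    r = np.hypot(x_mm, y_mm)
    ax = cfg.axial_spacing_um

    if cfg.flat:
        t_nfl = np.full_like(r, cfg.nfl_iso_um)
        t_gcipl = np.full_like(r, cfg.gcipl_peak_um)
        pit = np.zeros_like(r)
    else:
        # nasal is +x in canonical OD orientation
        theta = np.arctan2(y_mm, x_mm)
        wedge = (1.0 + np.cos(theta)) / 2.0
        growth = np.clip(r / (cfg.lateral_size_mm / 2), 0.0, 1.0)
        t_nfl = growth * (cfg.nfl_iso_um + cfg.nfl_wedge_um * wedge)
        annulus = np.exp(-((r - cfg.gcipl_peak_r_mm) ** 2) / (2 * cfg.gcipl_sigma_r_mm ** 2))
        t_gcipl = cfg.gcipl_far_um + (cfg.gcipl_peak_um - cfg.gcipl_far_um) * annulus
        t_gcipl = t_gcipl * (1.0 - cfg.pit_thinning * np.exp(-(r ** 2) / (2 * cfg.pit_radius_mm ** 2)))
        pit = cfg.pit_depth_um * np.exp(-(r ** 2) / (2 * cfg.pit_radius_mm ** 2))

    ilm = (cfg.ilm_offset_um + pit) / ax
    nflgcl = ilm + t_nfl / ax
    iplinl = nflgcl + t_gcipl / ax
    if np.any(t_gcipl <= 0) or np.any(t_nfl < 0):
        raise InvalidGeometryError("layer thickness fields must stay positive")
    if np.any(iplinl + (cfg.inl_um + cfg.opl_um + cfg.onl_um) / ax > cfg.n_z):
        raise InvalidGeometryError(
            "layer stack exceeds volume depth; increase n_z or reduce thicknesses"
        )
    return SurfaceSet(ilm_z=ilm, nflgcl_z=nflgcl, iplinl_z=iplinl)


# ---------------------------------------------------------------------------
# vessel planting


def planted_axial_density(cfg: PhantomConfig, step: float = 0.001) -> tuple:
    """Planted GCIPL-fraction axial density of the GCLP + ICP mixture.

    Returns ``(fractions, density)`` on a dense grid over (0, 1).  Each
    plexus contributes its areal fraction times its truncated-Gaussian depth
    profile; this is the quantity whose interior minimum defines the true
    watershed.
    """
    t = np.arange(step / 2, 1.0, step)
    rho = np.zeros_like(t)
    for name in ("GCLP", "ICP"):
        if name not in cfg.plexus_spec:
            continue
        p = cfg.plexus_spec[name]
        rho += p.areal_fraction * truncnorm.pdf(
            t, -_TRUNC, _TRUNC, loc=p.center_frac, scale=p.sigma_frac
        )
    return t, rho


def _true_watershed(cfg: PhantomConfig, step: float = 0.001) -> float:
    """Brute-force the interior minimum of the planted axial density between
    the GCLP and ICP centers."""
    if "GCLP" not in cfg.plexus_spec or "ICP" not in cfg.plexus_spec:
        raise NoWatershedTruthError("need both GCLP and ICP to define a watershed")
    c1 = cfg.plexus_spec["GCLP"].center_frac
    c2 = cfg.plexus_spec["ICP"].center_frac
    t, rho = planted_axial_density(cfg, step)
    sel = (t > c1) & (t < c2)
    if not np.any(sel):
        raise NoWatershedTruthError("no interior depth between the GCLP and ICP centers")
    ts, rs = t[sel], rho[sel]
    i = int(np.argmin(rs))
    if i == 0 or i == len(ts) - 1:
        raise NoWatershedTruthError(
            "planted axial density has no interior minimum between the plexuses "
            "(overlapping axial supports)"
        )
    return float(ts[i])


def _sample_truncnorm(rng, center, sigma, n):
    """Rejection-sample a +/- _TRUNC sigma truncated normal."""
    out = np.empty(n)
    got = 0
    while got < n:
        draw = rng.normal(center, sigma, size=2 * (n - got))
        draw = draw[np.abs(draw - center) <= _TRUNC * sigma]
        take = min(len(draw), n - got)
        out[got:got + take] = draw[:take]
        got += take
    return out


def _segment_pixels(rng, cfg: PhantomConfig, p: PlexusSpec, theta_map=None):
    """Lateral pixels of one capillary segment (center, orientation, tube)."""
    n = cfg.grid_n
    x0 = rng.integers(0, n)
    y0 = rng.integers(0, n)
    if p.oriented and theta_map is not None:
        # arcuate: roughly tangential to circles about the fovea
        ang = theta_map[x0, y0] + math.pi / 2 + rng.normal(0, 0.25)
    else:
        ang = rng.uniform(0, 2 * math.pi)
    lmin, lmax = cfg.segment_len_mm
    length_px = max(2, int(rng.uniform(lmin, lmax) / cfg.lateral_spacing_mm))
    dx, dy = math.cos(ang), math.sin(ang)
    x1 = int(round(x0 - dx * length_px / 2)); y1 = int(round(y0 - dy * length_px / 2))
    x2 = int(round(x0 + dx * length_px / 2)); y2 = int(round(y0 + dy * length_px / 2))
    x1, x2 = np.clip((x1, x2), 0, n - 1); y1, y2 = np.clip((y1, y2), 0, n - 1)
    xs, ys = draw_line(x1, y1, x2, y2)
    if p.radius_px > 0:
        # thicken the tube perpendicular to its axis
        px, py = -dy, dx
        allx, ally = [xs], [ys]
        for k in range(1, p.radius_px + 1):
            for s in (-k, k):
                allx.append(xs + int(round(px * s)))
                ally.append(ys + int(round(py * s)))
        xs = np.concatenate(allx); ys = np.concatenate(ally)
        keep = (xs >= 0) & (xs < n) & (ys >= 0) & (ys < n)
        xs, ys = xs[keep], ys[keep]
    return xs, ys


def plant_vessels(cfg: PhantomConfig, surfaces: SurfaceSet, rng=None,
                  require_watershed_truth: bool = True) -> TruthScene:
    """Plant capillary segments for every configured plexus.

    NFLP areal density scales with local NFL thickness and is zero wherever
    the NFL is thinner than 18 µm; no vessels are planted inside the FAZ.
    The true watershed fraction is recorded from a brute-force grid search
    over the planted GCLP/ICP axial density.  With
    ``require_watershed_truth=False`` a scene without a GCLP/ICP watershed
    (e.g. superficial plexuses only) is allowed and the truth is ``None``.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    try:
        true_ws = _true_watershed(cfg)
    except NoWatershedTruthError:
        if require_watershed_truth:
            raise
        true_ws = None

    n, nz = cfg.grid_n, cfg.n_z
    clean = np.zeros((n, n, nz), dtype=np.float32)
    labels = np.zeros((n, n, nz), dtype=np.uint8)

    x_mm, y_mm = cfg.lateral_grid_mm()
    fx, fy = cfg.faz_offset_mm
    r_faz = np.hypot(x_mm - fx, y_mm - fy)
    theta_map = np.arctan2(y_mm, x_mm)
    ax = cfg.axial_spacing_um
    t_nfl_um = (surfaces.nflgcl_z - surfaces.ilm_z) * ax
    t_gcc_um = (surfaces.iplinl_z - surfaces.ilm_z) * ax

    cx = cy = (n - 1) / 2.0
    faz_center = (cx + fx / cfg.lateral_spacing_mm, cy + fy / cfg.lateral_spacing_mm)

    for name, p in cfg.plexus_spec.items():
        pid = PLEXUS_IDS[name]
        usable = r_faz >= cfg.faz_radius_mm
        if p.anchor == "nfl":
            usable &= t_nfl_um >= NFLP_MIN_NFL_UM
        usable_frac = float(usable.mean())
        if usable_frac == 0.0:
            continue
        lmin, lmax = cfg.segment_len_mm
        mean_len_px = 0.5 * (lmin + lmax) / cfg.lateral_spacing_mm
        px_per_seg = mean_len_px * (2 * p.radius_px + 1)
        n_seg = int(round(p.areal_fraction * usable_frac * n * n / px_per_seg))

        if p.anchor == "nfl":
            weight = np.clip(t_nfl_um / max(cfg.nfl_iso_um + cfg.nfl_wedge_um, 1e-9), 0, 1)
        elif name == "GCLP" and cfg.gclp_density_from_gcc:
            weight = t_gcc_um / max(float(t_gcc_um.max()), 1e-9)
        else:
            weight = None

        planted = 0
        attempts = 0
        max_attempts = 20 * n_seg + 100
        while planted < n_seg and attempts < max_attempts:
            attempts += 1
            xs, ys = _segment_pixels(rng, cfg, p, theta_map)
            if weight is not None:
                # thin segments by local density weight at their midpoint
                w = weight[xs[len(xs) // 2], ys[len(ys) // 2]]
                if rng.uniform() > w:
                    continue
            keep = usable[xs, ys]
            xs, ys = xs[keep], ys[keep]
            if len(xs) == 0:
                continue
            center = p.center_frac
            if p.center_frac_temporal is not None:
                # temporal quadrant: within 45 deg of the -x axis (OD)
                xm, ym = (x_mm[xs[len(xs) // 2], ys[len(ys) // 2]],
                          y_mm[xs[len(xs) // 2], ys[len(ys) // 2]])
                if xm < 0 and abs(ym) <= -xm:
                    center = p.center_frac_temporal
            tfrac = _sample_truncnorm(rng, center, p.sigma_frac, 1)[0]
            rel = (tfrac - (center - _TRUNC * p.sigma_frac)) / (2 * _TRUNC * p.sigma_frac)
            amp_depth = p.amp_lo + (p.amp_hi - p.amp_lo) * float(np.clip(rel, 0, 1))
            if p.anchor == "nfl":
                zc = surfaces.ilm_z[xs, ys] + tfrac * (
                    surfaces.nflgcl_z[xs, ys] - surfaces.ilm_z[xs, ys])
            else:
                zc = surfaces.nflgcl_z[xs, ys] + tfrac * (
                    surfaces.iplinl_z[xs, ys] - surfaces.nflgcl_z[xs, ys])
            # clamp vessels into their anchor layer so truncated-Gaussian
            # tails never spill across the slab-defining surfaces: NFLP stays
            # within the NFL, GCIPL-anchored plexuses never rise above the
            # NFL/GCL junction (the ICP/DCP extend below the IPL/INL freely)
            if p.anchor == "nfl":
                lo_z = surfaces.ilm_z[xs, ys] + 1.0
                hi_z = np.maximum(surfaces.nflgcl_z[xs, ys] - 1.0, lo_z)
            else:
                lo_z = surfaces.nflgcl_z[xs, ys] + 1.0
                hi_z = np.full_like(lo_z, nz - 2.0)
            zc = np.clip(zc, lo_z, hi_z)
            amp = np.float32(amp_depth)
            # vessel occupies the voxel containing zc (one voxel axially)
            zi = np.floor(zc).astype(int)
            ok = (zi >= 0) & (zi < nz)
            xo, yo, zo = xs[ok], ys[ok], zi[ok]
            sel = amp > clean[xo, yo, zo]
            clean[xo[sel], yo[sel], zo[sel]] = amp
            labels[xo[sel], yo[sel], zo[sel]] = pid
            planted += 1

    return TruthScene(
        plexus_label_volume=labels,
        clean_flow=clean,
        true_watershed_fraction=true_ws,
        faz_center_px=faz_center,
    )


# ---------------------------------------------------------------------------
# rendering


def _layer_reflectance(cfg: PhantomConfig, surfaces: SurfaceSet) -> np.ndarray:
    """Noise-free structural volume from per-layer reflectances."""
    n, nz, ax = cfg.grid_n, cfg.n_z, cfg.axial_spacing_um
    refl = cfg.reflectance
    zc = (np.arange(nz) + 0.5)[None, None, :]
    ilm = surfaces.ilm_z[..., None]
    nflgcl = surfaces.nflgcl_z[..., None]
    iplinl = surfaces.iplinl_z[..., None]
    gcl_ipl_split = nflgcl + 0.5 * (iplinl - nflgcl)
    inl_b = iplinl + cfg.inl_um / ax
    opl_b = inl_b + cfg.opl_um / ax
    onl_b = opl_b + cfg.onl_um / ax

    out = np.full((n, n, nz), refl["vitreous"], dtype=np.float32)
    out = np.where(zc >= ilm, refl["nfl"], out)
    out = np.where(zc >= nflgcl, refl["gcl"], out)
    out = np.where(zc >= gcl_ipl_split, refl["ipl"], out)
    out = np.where(zc >= iplinl, refl["inl"], out)
    out = np.where(zc >= inl_b, refl["opl"], out)
    out = np.where(zc >= opl_b, refl["onl"], out)
    out = np.where(zc >= onl_b, refl["deep"], out)
    return out.astype(np.float32)


def _project_tails(clean: np.ndarray, decay: float) -> np.ndarray:
    """Tail volume: tail[z] accumulates decay * (clean[z-1] + tail[z-1])."""
    tail = np.zeros_like(clean)
    if decay <= 0:
        return tail
    for z in range(1, clean.shape[2]):
        tail[:, :, z] = decay * (clean[:, :, z - 1] + tail[:, :, z - 1])
    return tail


def render_volumes(scene: TruthScene, surfaces: SurfaceSet, cfg: PhantomConfig,
                   rng=None) -> ScanVolume:
    """Render structure and flow volumes from a planted scene.

    Structure = per-layer reflectance × multiplicative speckle.  Flow =
    clean flow + geometric projection tails + additive noise floor.  A
    configured shadow disc attenuates both signals.  Deterministic for a
    given rng/seed.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    structure = _layer_reflectance(cfg, surfaces)
    ns = cfg.noise_spec
    if ns.speckle_sd > 0:
        structure = structure * np.clip(
            1.0 + ns.speckle_sd * rng.standard_normal(structure.shape, dtype=np.float32),
            0.0, None)

    flow = scene.clean_flow.copy()
    if cfg.tail_spec.enabled and cfg.tail_spec.decay > 0:
        flow = flow + _project_tails(scene.clean_flow, cfg.tail_spec.decay)

    if cfg.shadow_spec is not None:
        sh = cfg.shadow_spec
        x_mm, y_mm = cfg.lateral_grid_mm()
        disc = np.hypot(x_mm - sh.center_mm[0], y_mm - sh.center_mm[1]) < sh.radius_mm
        structure[disc] *= sh.attenuation
        flow[disc] *= sh.attenuation

    if ns.flow_noise > 0:
        flow = flow + rng.uniform(0.0, ns.flow_noise, size=flow.shape).astype(np.float32)

    return ScanVolume(
        structure=structure.astype(np.float32),
        flow=flow.astype(np.float32),
        lateral_spacing_mm=cfg.lateral_spacing_mm,
        axial_spacing_um=cfg.axial_spacing_um,
        laterality="OD",
    )


# ---------------------------------------------------------------------------
# cohorts


def _jitter_config(cfg: PhantomConfig, rng) -> PhantomConfig:
    """Per-eye anatomical jitter: thickness fields and plexus densities."""
    tj = cfg.thickness_jitter_sd
    dj = cfg.density_jitter_sd
    t_scale = max(0.2, 1.0 + tj * rng.standard_normal()) if tj > 0 else 1.0
    plex = {}
    for name, p in cfg.plexus_spec.items():
        if dj > 0:
            f = float(np.clip(p.areal_fraction * (1.0 + dj * rng.standard_normal()),
                              0.01, 0.9))
        else:
            f = p.areal_fraction
        plex[name] = replace(p, areal_fraction=f)
    return replace(
        cfg,
        nfl_iso_um=cfg.nfl_iso_um * t_scale,
        nfl_wedge_um=cfg.nfl_wedge_um * t_scale,
        gcipl_far_um=cfg.gcipl_far_um * t_scale,
        gcipl_peak_um=cfg.gcipl_peak_um * t_scale,
        plexus_spec=plex,
    )


def iter_cohort(cfg: PhantomConfig, n_eyes: int, repeats: int = 1,
                seed: int | None = None, render: bool = True):
    """Yield phantom eyes one at a time (memory-friendly for large cohorts).

    Each eye gets jittered anatomy and densities; repeats share the vascular
    scene and differ only in the noise realization.  Eyes alternate OD/OS;
    left-eye phantoms are mirrored along the nasal/temporal axis.  With
    ``render=False`` only surfaces and truth scenes are produced.
    """
    if n_eyes < 1 or repeats < 1:
        raise ValueError("n_eyes and repeats must be >= 1")
    if seed is None:
        seed = cfg.seed
    master = np.random.default_rng(seed)
    for i in range(n_eyes):
        eye_rng = np.random.default_rng(master.integers(0, 2 ** 31))
        ecfg = _jitter_config(cfg, eye_rng)
        surfaces = make_surfaces(ecfg)
        scene = plant_vessels(ecfg, surfaces, rng=eye_rng)
        laterality = "OD" if i % 2 == 0 else "OS"
        vols = []
        if render:
            for _ in range(repeats):
                noise_rng = np.random.default_rng(master.integers(0, 2 ** 31))
                v = render_volumes(scene, surfaces, ecfg, rng=noise_rng)
                vols.append(v)
        if laterality == "OS":
            surfaces = surfaces.mirrored()
            scene = scene.mirrored()
            vols = [v.mirrored() for v in vols]  # toggles laterality to OS
        yield PhantomEye(eye_id=i, laterality=laterality, volumes=vols,
                        surfaces=surfaces, scene=scene, config=ecfg)


def generate_cohort(cfg: PhantomConfig, n_eyes: int, repeats: int = 1,
                    seed: int | None = None, render: bool = True) -> list:
    """Materialized list form of :func:`iter_cohort` (small cohorts only)."""
    return list(iter_cohort(cfg, n_eyes, repeats, seed, render))


def config_for_watershed(target_fraction: float, delta: float = 0.35,
                         sigma: float = 0.17, gclp_areal: float = 0.50,
                         icp_areal: float = 0.42, **overrides) -> PhantomConfig:
    """Config whose planted GCLP/ICP watershed sits exactly at ``target_fraction``.

    The GCLP is placed ``delta`` above the target; the ICP offset below is
    solved so that the weighted two-Gaussian mixture has zero slope at the
    target (the stationarity condition ``w1*d1*phi(d1/s) = w2*d2*phi(d2/s)``).
    The GCLP keeps a higher areal fraction than the ICP, as in the macula,
    so its bump dominates the depth profile.
    """
    if not (0.0 < target_fraction < 1.0):
        raise ValueError("target watershed fraction must be in (0,1)")
    from scipy.optimize import brentq

    lhs = gclp_areal * delta * math.exp(-delta ** 2 / (2 * sigma ** 2))

    def f(d2):
        return icp_areal * d2 * math.exp(-d2 ** 2 / (2 * sigma ** 2)) - lhs

    # x*exp(-x^2/2s^2) peaks at x = sigma; search the decreasing branch
    d2 = brentq(f, sigma, delta)
    plex = _default_plexuses()
    plex["GCLP"] = replace(plex["GCLP"], center_frac=target_fraction - delta,
                           sigma_frac=sigma, areal_fraction=gclp_areal)
    plex["ICP"] = replace(plex["ICP"], center_frac=target_fraction + d2,
                          sigma_frac=sigma, areal_fraction=icp_areal)
    cfg = PhantomConfig(plexus_spec=plex, **overrides)
    planted = _true_watershed(cfg)
    if abs(planted - target_fraction) > 0.002:
        raise NoWatershedTruthError(
            f"solved configuration plants the watershed at {planted:.4f}, "
            f"not the requested {target_fraction:.4f}")
    return cfg
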