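"""Phantom generator: surfaces, vessel planting, rendering, cohorts."""

import numpy as np
import pytest
from scipy.stats import truncnorm

from gclp.errors import InvalidGeometryError, NoWatershedTruthError
from gclp.synthetic import (NFLP_MIN_NFL_UM, PhantomConfig, PlexusSpec,
                            TruthScene, _default_plexuses, generate_cohort,
                            make_surfaces, plant_vessels, render_volumes)


class TestSurfaces:
    def test_flat_config_parallel_planes(self, flat_surfaces):
        _, s = flat_surfaces
        for arr in (s.ilm_z, s.nflgcl_z, s.iplinl_z):
            assert np.ptp(arr) == 0
        assert np.all(s.ilm_z < s.nflgcl_z) and np.all(s.nflgcl_z < s.iplinl_z)

    def test_nasal_nfl_thicker_than_temporal(self, small_eye):
        cfg, s, _, _ = small_eye
        nfl = s.nflgcl_z - s.ilm_z
        n = cfg.grid_n
        assert nfl[2 * n // 3:].mean() > nfl[: n // 3].mean()

    def test_nfl_vanishes_at_fovea_gcipl_annulus(self, small_eye):
        cfg, s, _, _ = small_eye
        n = cfg.grid_n
        c = n // 2
        nfl_um = (s.nflgcl_z - s.ilm_z) * cfg.axial_spacing_um
        assert nfl_um[c, c] < 2.0
        gcipl_um = (s.iplinl_z - s.nflgcl_z) * cfg.axial_spacing_um
        ring_px = int(cfg.gcipl_peak_r_mm / cfg.lateral_spacing_mm)
        assert gcipl_um[c + ring_px, c] > gcipl_um[c, c]
        assert gcipl_um[c + ring_px, c] > gcipl_um[2, c]

    def test_rotational_symmetry_without_pit_and_wedge(self):
        cfg = PhantomConfig(grid_n=80, n_z=256, pit_depth_um=0.0, nfl_wedge_um=0.0,
                            seed=2)
        s = make_surfaces(cfg)
        for arr in (s.nflgcl_z - s.ilm_z, s.iplinl_z - s.nflgcl_z):
            assert np.abs(arr - arr[::-1, :]).max() < 1.0
            assert np.abs(arr - arr[:, ::-1]).max() < 1.0
            assert np.abs(arr - arr.T).max() < 1.0

    def test_stack_must_fit_volume(self):
        with pytest.raises(InvalidGeometryError):
            make_surfaces(PhantomConfig(grid_n=20, n_z=60))

    @pytest.mark.parametrize("kw", [dict(grid_n=0), dict(gcipl_far_um=-1),
                                    dict(faz_radius_mm=4.0)])
    def test_config_invariants(self, kw):
        with pytest.raises(InvalidGeometryError):
            PhantomConfig(**kw)


def _two_gaussian_truth_oracle(gclp, icp, step=0.001):
    """Independent brute-force minimum of the planted two-plexus density."""
    t = np.arange(step / 2, 1.0, step)
    rho = (gclp.areal_fraction * truncnorm.pdf(t, -3, 3, gclp.center_frac, gclp.sigma_frac)
           + icp.areal_fraction * truncnorm.pdf(t, -3, 3, icp.center_frac, icp.sigma_frac))
    sel = (t > gclp.center_frac) & (t < icp.center_frac)
    return t[sel][np.argmin(rho[sel])]


class TestPlanting:
    def test_truth_matches_brute_force_oracle(self):
        plex = _default_plexuses()
        plex["GCLP"] = PlexusSpec(0.30, 0.10, 0.20, amp_lo=0.82, amp_hi=0.88)
        plex["ICP"] = PlexusSpec(1.00, 0.10, 0.20, amp_lo=0.92, amp_hi=0.98)
        cfg = PhantomConfig(grid_n=60, n_z=256, plexus_spec=plex, seed=3)
        scene = plant_vessels(cfg, make_surfaces(cfg))
        expected = _two_gaussian_truth_oracle(plex["GCLP"], plex["ICP"])
        assert abs(scene.true_watershed_fraction - expected) <= 0.001

    def test_default_truth_near_75_percent(self, small_eye):
        _, _, scene, _ = small_eye
        assert abs(scene.true_watershed_fraction - 0.75) < 0.02

    def test_single_plexus_has_no_watershed_truth(self):
        plex = {"GCLP": PlexusSpec(0.35, 0.15, 0.2)}
        cfg = PhantomConfig(grid_n=40, n_z=256, plexus_spec=plex, seed=4)
        with pytest.raises(NoWatershedTruthError):
            plant_vessels(cfg, make_surfaces(cfg))
        scene = plant_vessels(cfg, make_surfaces(cfg), require_watershed_truth=False)
        assert scene.true_watershed_fraction is None

    def test_thin_nfl_kills_nflp(self):
        cfg = PhantomConfig(grid_n=80, n_z=256, flat=True, seed=5,
                            nfl_iso_um=NFLP_MIN_NFL_UM - 6)
        scene = plant_vessels(cfg, make_surfaces(cfg))
        assert not np.any(scene.plexus_label_volume == 1)
        assert np.any(scene.plexus_label_volume == 2)

    def test_faz_is_avascular(self, small_eye):
        cfg, _, scene, _ = small_eye
        xs, ys, _ = np.nonzero(scene.plexus_label_volume)
        cx, cy = scene.faz_center_px
        r_mm = np.hypot(xs - cx, ys - cy) * cfg.lateral_spacing_mm
        assert r_mm.min() >= cfg.faz_radius_mm

    def test_labels_only_on_clean_flow(self, small_eye):
        _, _, scene, _ = small_eye
        labelled = scene.plexus_label_volume > 0
        assert np.all(scene.clean_flow[labelled] > 0.5)
        assert not np.any(scene.clean_flow[~labelled] > 0)


class TestRendering:
    def _tiny_scene(self, cfg, z_vessel=40, amp=0.8):
        clean = np.zeros((cfg.grid_n, cfg.grid_n, cfg.n_z), dtype=np.float32)
        labels = np.zeros_like(clean, dtype=np.uint8)
        clean[5, 5, z_vessel] = amp
        labels[5, 5, z_vessel] = 2
        return TruthScene(labels, clean, 0.5, (cfg.grid_n / 2, cfg.grid_n / 2))

    def _quiet(self, **kw):
        from gclp.synthetic import NoiseSpec, TailSpec
        cfg = PhantomConfig(grid_n=12, n_z=120, flat=True, nfl_iso_um=30, seed=6,
                            noise_spec=NoiseSpec(speckle_sd=0.0, flow_noise=0.0),
                            tail_spec=TailSpec(**kw))
        return cfg, make_surfaces(cfg)

    def test_zero_decay_flow_equals_clean(self):
        cfg, s = self._quiet(decay=0.0)
        scene = self._tiny_scene(cfg)
        vol = render_volumes(scene, s, cfg)
        assert np.array_equal(vol.flow, scene.clean_flow)

    def test_geometric_tail_law(self):
        cfg, s = self._quiet(decay=0.5)
        scene = self._tiny_scene(cfg, z_vessel=40, amp=0.8)
        vol = render_volumes(scene, s, cfg)
        assert vol.flow[5, 5, 41] == pytest.approx(0.4)
        assert vol.flow[5, 5, 42] == pytest.approx(0.2)  # f/4 two voxels below

    def test_tail_monotone_below_deepest_vessel(self, small_cfg):
        from dataclasses import replace
        from gclp.synthetic import NoiseSpec
        cfg = replace(small_cfg, grid_n=60, noise_spec=NoiseSpec(0.0, 0.0), seed=9)
        s = make_surfaces(cfg)
        scene = plant_vessels(cfg, s)
        vol = render_volumes(scene, s, cfg)
        has = scene.clean_flow > 0
        xs, ys = np.nonzero(has.any(axis=2))
        for x, y in zip(xs[:50], ys[:50]):
            zlast = np.nonzero(has[x, y])[0][-1]
            tail = vol.flow[x, y, zlast + 1:]
            tail = tail[tail > 0]
            assert np.all(np.diff(tail) < 0)

    def test_deterministic_given_seed(self):
        cfg = PhantomConfig(grid_n=40, n_z=256, seed=11)
        out = []
        for _ in range(2):
            s = make_surfaces(cfg)
            scene = plant_vessels(cfg, s)
            out.append(render_volumes(scene, s, cfg))
        assert np.array_equal(out[0].flow, out[1].flow)
        assert np.array_equal(out[0].structure, out[1].structure)

    def test_shadow_attenuates_both_signals(self):
        from gclp.synthetic import ShadowSpec
        cfg, s = self._quiet(decay=0.0)
        cfg = PhantomConfig(grid_n=12, n_z=120, flat=True, nfl_iso_um=30, seed=6,
                            noise_spec=cfg.noise_spec, tail_spec=cfg.tail_spec,
                            shadow_spec=ShadowSpec(center_mm=(0, 0), radius_mm=3.0,
                                                   attenuation=0.1))
        scene = self._tiny_scene(cfg)
        vol = render_volumes(scene, s, cfg)
        assert vol.flow[5, 5, 40] == pytest.approx(0.08)


class TestCohort:
    def test_zero_noise_repeats_identical(self):
        from gclp.synthetic import NoiseSpec
        cfg = PhantomConfig(grid_n=40, n_z=256, seed=13,
                            noise_spec=NoiseSpec(0.0, 0.0))
        eyes = generate_cohort(cfg, n_eyes=1, repeats=2, seed=13)
        a, b = eyes[0].volumes
        assert np.array_equal(a.flow, b.flow)
        assert np.array_equal(a.structure, b.structure)

    def test_zero_jitter_identical_surfaces(self):
        cfg = PhantomConfig(grid_n=40, n_z=256, seed=14,
                            thickness_jitter_sd=0.0, density_jitter_sd=0.0)
        eyes = generate_cohort(cfg, n_eyes=3, repeats=1, seed=14, render=False)
        for e in eyes[1:]:
            ref = eyes[0].surfaces
            s = e.surfaces.mirrored() if e.laterality == "OS" else e.surfaces
            assert np.allclose(s.ilm_z, ref.ilm_z)
            assert np.allclose(s.iplinl_z, ref.iplinl_z)

    def test_population_thickness_spread_tracks_jitter(self):
        cfg = PhantomConfig(grid_n=60, n_z=256, seed=15)
        eyes = generate_cohort(cfg, n_eyes=38, repeats=1, seed=15, render=False)
        # parafoveal GCIPL thickness per eye (OD orientation)
        vals = []
        for e in eyes:
            s = e.surfaces.mirrored() if e.laterality == "OS" else e.surfaces
            gcipl = (s.iplinl_z - s.nflgcl_z) * cfg.axial_spacing_um
            c = cfg.grid_n // 2
            ring = int(cfg.gcipl_peak_r_mm / cfg.lateral_spacing_mm)
            vals.append(gcipl[c + ring, c])
        rel_sd = np.std(vals, ddof=1) / np.mean(vals)
        assert rel_sd <= 3 * cfg.thickness_jitter_sd
        assert rel_sd > 0

    def test_left_eyes_mirrored(self):
        cfg = PhantomConfig(grid_n=40, n_z=256, seed=16)
        eyes = generate_cohort(cfg, n_eyes=2, repeats=1, seed=16)
        assert eyes[0].laterality == "OD" and eyes[1].laterality == "OS"
        assert eyes[1].volumes[0].laterality == "OS"
        # the OS eye's nasal side (thick NFL) sits at low x after mirroring
        s = eyes[1].surfaces
        nfl = s.nflgcl_z - s.ilm_z
        n = cfg.grid_n
        assert nfl[: n // 3].mean() > nfl[2 * n // 3:].mean()
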