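"""Depth profiles, polynomial fitting, and watershed localization."""

import numpy as np
import numpy.polynomial.polynomial as P
import pytest

from gclp.errors import NoWatershedError
from gclp.watershed import (DepthProfile, PolyFit, aggregate_quadrants,
                            find_watershed, fit_profile, locate_extrema,
                            profile_for_group, raw_profile_minimum)

CENTERS = (np.arange(20) + 0.5) / 20


class TestFit:
    def test_exact_degree6_recovered(self):
        rng = np.random.default_rng(8)
        coeffs = rng.normal(0, 1, 7)
        prof = DepthProfile(CENTERS, P.polyval(CENTERS, coeffs))
        fit = fit_profile(prof)
        assert np.allclose(fit.coefficients, coeffs, atol=1e-8)
        assert fit.r_squared == pytest.approx(1.0)

    def test_constant_profile_flagged(self):
        fit = fit_profile(DepthProfile(CENTERS, np.full(20, 0.3)))
        assert fit.degenerate and fit.r_squared == 0.0
        assert np.allclose(fit.coefficients[1:], 0.0, atol=1e-8)

    def test_ssres_matches_normal_equations_oracle(self):
        """OLS residual equals an independent normal-equations solution."""
        rng = np.random.default_rng(9)
        for _ in range(20):
            y = rng.uniform(0, 1, 20)
            fit = fit_profile(DepthProfile(CENTERS, y))
            X = np.vander(CENTERS, 7, increasing=True)
            beta = np.linalg.solve(X.T @ X, X.T @ y)
            ss_oracle = float(np.sum((y - X @ beta) ** 2))
            ss_fit = float(np.sum((y - P.polyval(CENTERS, fit.coefficients)) ** 2))
            assert abs(ss_fit - ss_oracle) <= 1e-8 * max(ss_oracle, 1e-12)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            fit_profile(DepthProfile(CENTERS[:7], np.ones(7)))


def _fit_from_coeffs(coeffs):
    return PolyFit(degree=len(coeffs) - 1, coefficients=np.asarray(coeffs, float),
                   r_squared=1.0, n_points=20)


class TestExtrema:
    def test_closed_form_two_well(self):
        # f(x) = (x-0.3)^2 (x-0.75)^2 + c: minima at 0.3 and 0.75,
        # local max at their midpoint 0.525
        c = 0.01
        coeffs = np.array(np.polynomial.polynomial.polymul(
            np.polynomial.polynomial.polypow([0.09, -0.6, 1.0], 1),
            [0.5625, -1.5, 1.0]))
        coeffs[0] += c
        res = locate_extrema(_fit_from_coeffs(coeffs))
        assert res.peak_fraction == pytest.approx(0.525, abs=1e-3)
        assert res.trough_fraction == pytest.approx(0.75, abs=1e-3)
        assert res.trough_vd == pytest.approx(c, abs=1e-9)

    def test_monotone_has_no_watershed(self):
        with pytest.raises(NoWatershedError):
            locate_extrema(_fit_from_coeffs([0.0, 1.0, 0.5, 0.1, 0, 0, 0]))

    def test_agrees_with_dense_grid_search(self):
        """Derivative-root extrema match a 1e-3 grid oracle on random fits."""
        rng = np.random.default_rng(10)
        step = 1e-3
        g = np.arange(step, 1.0, step)
        checked = 0
        for _ in range(100):
            y = np.clip(rng.uniform(0, 0.2, 20)
                        + rng.uniform(0.2, 0.6) * np.exp(-(CENTERS - rng.uniform(0.2, 0.4)) ** 2 / 0.02)
                        + rng.uniform(0.1, 0.5) * np.exp(-(CENTERS - rng.uniform(0.8, 1.0)) ** 2 / 0.01),
                        0, 1)
            fit = fit_profile(DepthProfile(CENTERS, y))
            try:
                res = locate_extrema(fit, lo=CENTERS[0], hi=CENTERS[-1])
            except NoWatershedError:
                continue
            checked += 1
            v = P.polyval(g, fit.coefficients)
            inner = (g > CENTERS[0]) & (g < CENTERS[-1])
            mins = np.where((v[1:-1] < v[:-2]) & (v[1:-1] <= v[2:]))[0] + 1
            mins = [i for i in mins if inner[i]]
            assert mins, "oracle found no grid minimum where analytic did"
            nearest = min((abs(g[i] - res.trough_fraction) for i in mins))
            assert nearest <= 1e-3
        assert checked >= 50

    def test_spurious_flat_region_minima_rejected(self):
        # profile that is numerically zero anteriorly and has one real bump
        # and valley posteriorly: fit oscillation in the flat region must not
        # be selected as the watershed
        y = np.zeros(20)
        y[8:] = 0.3 * np.exp(-(CENTERS[8:] - 0.5) ** 2 / 0.01) \
            + 0.25 * np.exp(-(CENTERS[8:] - 0.95) ** 2 / 0.005)
        res = find_watershed(DepthProfile(CENTERS, y))
        assert 0.6 < res.trough_fraction < 0.9


class TestRawMinimum:
    def test_interior_argmin(self):
        y = np.full(20, 0.5)
        y[0] = 0.0  # boundary value must be ignored
        y[14] = 0.1
        assert raw_profile_minimum(DepthProfile(CENTERS, y)) == CENTERS[14]


class TestProfilesOnPhantoms:
    def test_two_plexus_profile_has_trough_near_truth(self, small_eye):
        from gclp import analyze_eye
        cfg, s, scene, vol = small_eye
        res = analyze_eye(vol, s)
        assert res.watershed is not None
        assert res.watershed.trough_fraction == pytest.approx(
            scene.true_watershed_fraction, abs=0.05)
        assert res.watershed.peak_fraction < res.watershed.trough_fraction

    def test_gclp_only_profile_has_no_trough(self):
        from gclp import analyze_eye
        from gclp.synthetic import (PhantomConfig, PlexusSpec, make_surfaces,
                                    plant_vessels, render_volumes)
        plex = {"GCLP": PlexusSpec(0.35, 0.12, 0.5, amp_lo=0.82, amp_hi=0.88)}
        cfg = PhantomConfig(grid_n=120, n_z=256, seed=51, plexus_spec=plex)
        s = make_surfaces(cfg)
        scene = plant_vessels(cfg, s, require_watershed_truth=False)
        vol = render_volumes(scene, s, cfg)
        res = analyze_eye(vol, s)
        assert res.watershed is None

    def test_zero_flow_gives_zero_profile(self, small_eye):
        from gclp.metrics import VDParams
        from gclp.sectors import build_polar_grid
        from gclp.volume import EnFaceMap
        from gclp.watershed import subslab_vd_profiles
        cfg, s, _, _ = small_eye
        n = cfg.grid_n
        grid = build_polar_grid(((n - 1) / 2, (n - 1) / 2), (n, n),
                                cfg.lateral_spacing_mm)
        thr = EnFaceMap(np.full((n, n), 0.5), "threshold", cfg.lateral_spacing_mm)
        table = subslab_vd_profiles(np.zeros((n, n, cfg.n_z)), s, grid,
                                    VDParams(), thr)
        assert np.nanmax(table["vd"].to_numpy()) == 0.0


class TestQuadrants:
    def _synthetic_table(self, trough_by_quadrant):
        """Homogeneous per-sector profiles built from known two-well curves."""
        import pandas as pd
        rows = []
        quads = {"T": (14, 15, 0, 1), "S": (2, 3, 4, 5), "N": (6, 7, 8, 9),
                 "I": (10, 11, 12, 13)}
        for ring in range(3):
            for q, slices in quads.items():
                tr = trough_by_quadrant[q]
                peak = tr - 0.4
                y = (0.4 * np.exp(-(CENTERS - peak) ** 2 / 0.02)
                     + 0.3 * np.exp(-(CENTERS - (tr + 0.30)) ** 2 / 0.01))
                for s in slices:
                    for i, (f, v) in enumerate(zip(CENTERS, y)):
                        rows.append(dict(sector_id=ring * 16 + s, ring_index=ring,
                                         slice_index=s, quadrant=q,
                                         subslab_index=i, depth_fraction=f,
                                         vd=v, n_pixels=100, n_excluded=0,
                                         missing=False))
        return pd.DataFrame(rows)

    def test_quadrant_contrast_recovered(self):
        table = self._synthetic_table({"T": 0.80, "S": 0.70, "N": 0.70, "I": 0.70})
        out = aggregate_quadrants(table).set_index("quadrant")
        assert out.loc["T", "pooled_trough"] > out.loc["S", "pooled_trough"] + 0.05
        assert out.loc["S", "pooled_trough"] == pytest.approx(
            out.loc["N", "pooled_trough"], abs=1e-9)

    def test_homogeneous_quadrants_agree(self):
        table = self._synthetic_table({q: 0.75 for q in "TSNI"})
        out = aggregate_quadrants(table)
        assert out["pooled_peak"].max() - out["pooled_peak"].min() < 0.02
        # pooled trough equals the mean of per-sector troughs when all
        # sectors share one profile
        assert np.allclose(out["pooled_trough"], out["sector_trough_mean"],
                           atol=0.01)

    def test_planted_temporal_depth_contrast(self):
        """GCLP planted deeper temporally shifts the temporal quadrant peak."""
        from gclp import analyze_eye
        from gclp.synthetic import (PhantomConfig, _default_plexuses,
                                    make_surfaces, plant_vessels,
                                    render_volumes)
        from dataclasses import replace
        plex = _default_plexuses()
        plex["GCLP"] = replace(plex["GCLP"], center_frac=0.30,
                               center_frac_temporal=0.43, sigma_frac=0.12)
        cfg = PhantomConfig(grid_n=160, n_z=256, seed=52, plexus_spec=plex)
        s = make_surfaces(cfg)
        scene = plant_vessels(cfg, s)
        vol = render_volumes(scene, s, cfg)
        res = analyze_eye(vol, s)
        q = res.quadrants.set_index("quadrant")
        others = [q.loc[x, "pooled_peak"] for x in "SNI"]
        assert q.loc["T", "pooled_peak"] > max(others) + 0.05


def test_profile_plot_renders(tmp_path):
    """The quadrant VD-depth plot writes a figure with fitted curves."""
    table = TestQuadrants()._synthetic_table({q: 0.75 for q in "TSNI"})
    from gclp.plots import plot_vd_depth_profiles
    out = tmp_path / "profiles.png"
    ax = plot_vd_depth_profiles(table, path=out)
    assert out.exists() and out.stat().st_size > 0
    assert len(ax.lines) >= 8  # points + fit per quadrant
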