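"""Diagnostic plots: VD-versus-depth profiles with their polynomial fits."""

from __future__ import annotations

import numpy as np

from .errors import NoWatershedError
from .sectors import QUADRANTS
from .watershed import find_watershed, profile_for_group

__all__ = ["plot_vd_depth_profiles"]


def plot_vd_depth_profiles(profile_table, path=None, ax=None):
    """Plot per-quadrant VD depth profiles, fitted curves, and extrema.

    ``profile_table`` is the long table from :func:`subslab_vd_profiles`.
    Saves to ``path`` when given; returns the matplotlib Axes.
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    grid = np.linspace(0.025, 0.975, 400)
    for q, color in zip(QUADRANTS, ("tab:red", "tab:blue", "tab:green", "tab:orange")):
        prof = profile_for_group(profile_table, label=q, quadrant=q)
        if prof.depth_fractions.size == 0:
            continue
        ax.plot(prof.depth_fractions, prof.vd_values, "o", ms=3, color=color,
                alpha=0.6)
        try:
            res = find_watershed(prof)
        except (NoWatershedError, ValueError):
            continue
        fit = np.polynomial.polynomial.polyval(grid, res.fit.coefficients)
        ax.plot(grid, fit, color=color, lw=1.2,
                label=f"{q}: trough {res.trough_fraction:.2f}")
        ax.axvline(res.trough_fraction, color=color, ls=":", lw=0.8)
    ax.set_xlabel("GCIPL depth fraction")
    ax.set_ylabel("vessel density")
    ax.set_xlim(0, 1)
    ax.legend(fontsize=8)
    if path is not None:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
    return ax
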