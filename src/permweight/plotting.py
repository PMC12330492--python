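"""Minimal plotting helpers for profiles and flux series."""

from __future__ import annotations

import numpy as np

from .profiles import ProfileSet

__all__ = ["plot_profile", "plot_flux_series"]


def plot_profile(profile: ProfileSet, ax=None, quantity: str = "pmf", **kwargs):
    """Plot a profile quantity ('pmf', 'deprotonated_fraction' or a channel
    name) against z; empty bins are left as gaps unless interpolate=True."""
    import matplotlib.pyplot as plt

    interpolate = kwargs.pop("interpolate", False)
    if ax is None:
        _, ax = plt.subplots()
    if quantity == "pmf":
        y = profile.pmf
        ax.set_ylabel("free energy (kcal/mol)")
    elif quantity == "deprotonated_fraction":
        y = profile.deprotonated_fraction
        ax.set_ylabel("deprotonated fraction")
    else:
        y = profile.observable_means[quantity]
        ax.set_ylabel(quantity)
    y = np.asarray(y, dtype=float)
    if interpolate and np.isnan(y).any() and np.isfinite(y).sum() > 1:
        ok = np.isfinite(y)
        y = np.interp(profile.z_grid, profile.z_grid[ok], y[ok])
    ax.plot(profile.z_grid, y, **kwargs)
    ax.set_xlabel("z (Å)")
    return ax


def plot_flux_series(flux, ax=None, **kwargs):
    """Plot the per-iteration flux (1/s) on a log scale where positive."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    flux = np.asarray(flux, dtype=float)
    ax.plot(np.arange(flux.size), flux, **kwargs)
    if np.any(flux > 0):
        ax.set_yscale("symlog", linthresh=max(flux[flux > 0].min(), 1e-300))
    ax.set_xlabel("WE iteration")
    ax.set_ylabel("flux (1/s)")
    return ax
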