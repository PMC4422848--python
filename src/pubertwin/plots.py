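"""Plotting helpers (matplotlib is imported lazily).

Stacked rph bars show how a phenotypic (change) correlation splits into
its genetic, common-environment and unique-environment parts — the three
segments add up to the plotted correlation.
"""

from __future__ import annotations

import numpy as np

from .changes import ChangeStats

__all__ = ["plot_rph_bars", "plot_significance_slices"]

_COMPONENT_COLORS = {"rph_a": "#444444", "rph_c": "#888888", "rph_e": "#cccccc"}


def plot_rph_bars(stats, labels=None, ax=None):
    """Stacked-bar decomposition of one or more correlations.

    Parameters
    ----------
    stats
        A :class:`~pubertwin.changes.ChangeStats` or a sequence of them
        (e.g. one per region or voxel cluster).
    """
    import matplotlib.pyplot as plt

    if isinstance(stats, ChangeStats):
        stats = [stats]
    if labels is None:
        labels = [f"unit {i}" for i in range(len(stats))]
    if ax is None:
        _, ax = plt.subplots(figsize=(1.2 + 0.9 * len(stats), 3.5))
    x = np.arange(len(stats))
    for comp in ("rph_a", "rph_c", "rph_e"):
        vals = np.array([getattr(s, comp) for s in stats])
        pos = np.zeros(len(stats))
        for prev in ("rph_a", "rph_c", "rph_e"):
            if prev == comp:
                break
            prev_vals = np.array([getattr(s, prev) for s in stats])
            pos += np.where(np.sign(prev_vals) == np.sign(vals), prev_vals, 0.0)
        ax.bar(x, vals, bottom=pos, color=_COMPONENT_COLORS[comp],
               label=comp.replace("rph_", "rph-"))
    ax.scatter(x, [s.r_ch for s in stats], color="black", zorder=3, s=12,
               label="r (total)")
    ax.axhline(0.0, color="black", lw=0.5)
    ax.set_xticks(x, labels, rotation=45, ha="right")
    ax.set_ylabel("correlation")
    ax.legend(frameon=False, fontsize=8)
    return ax


def plot_significance_slices(vmap, fdr, axis=2, ax=None):
    """Montage of axial slices: fitted correlation masked to FDR survivors."""
    import matplotlib.pyplot as plt

    r_vol = vmap.to_volume("r")
    sig = np.zeros(int(np.prod(vmap.grid_shape)), dtype=bool)
    usable = vmap.usable()
    sig[vmap.voxel_indices[np.flatnonzero(usable)[fdr.mask]]] = True
    sig = sig.reshape(vmap.grid_shape)
    masked = np.where(sig, r_vol, np.nan)
    n_sl = vmap.grid_shape[axis]
    if ax is None:
        _, axes = plt.subplots(1, n_sl, figsize=(1.6 * n_sl, 1.8))
    else:
        axes = ax
    vmax = np.nanmax(np.abs(masked)) if np.isfinite(masked).any() else 1.0
    for k, a in enumerate(np.atleast_1d(axes)):
        sl = np.take(masked, k, axis=axis)
        a.imshow(sl.T, origin="lower", cmap="coolwarm", vmin=-vmax, vmax=vmax)
        a.set_title(f"z={k}", fontsize=7)
        a.axis("off")
    return axes
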