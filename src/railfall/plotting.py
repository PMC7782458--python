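"""Region-map plots: shaded slip, tilt and overlap areas in the (beta, alpha) plane."""

from __future__ import annotations

import numpy as np

from .regions import RegionMap
from .statics import StabilityCategory

__all__ = ["plot_region_map"]

_CLASS_COLORS = {
    StabilityCategory.STABLE: "#f5f5f5",
    StabilityCategory.SLIP_ONLY: "#7fb3d5",
    StabilityCategory.TILT_ONLY: "#f5b041",
    StabilityCategory.FALL_POSSIBLE: "#c0392b",
    StabilityCategory.INVALID_GEOMETRY: "#bdbdbd",
}


def plot_region_map(rmap: RegionMap, path: str | None = None, ax=None):
    """Render a stability-region map.

    beta on the x-axis, alpha on the y-axis; slip-only, tilt-only and
    fall-possible (overlap) cells shaded in distinct colours.  Saves to
    ``path`` when given, otherwise returns the axes for further styling.
    """
    import matplotlib

    if path is not None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap
    from matplotlib.patches import Patch

    categories = list(_CLASS_COLORS)
    index = {c: k for k, c in enumerate(categories)}
    coded = np.vectorize(index.__getitem__)(rmap.classes)

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 5))
    ax.pcolormesh(
        rmap.beta_deg,
        rmap.alpha_deg,
        coded,
        cmap=ListedColormap([_CLASS_COLORS[c] for c in categories]),
        vmin=-0.5,
        vmax=len(categories) - 0.5,
        shading="nearest",
    )
    ax.set_xlabel(r"$\beta$ (deg)")
    ax.set_ylabel(r"$\alpha$ (deg)")
    mu = rmap.scenario.friction_coefficient
    ax.set_title(rf"Slip/tilt stability regions, $\mu$ = {mu:g}")
    ax.legend(
        handles=[
            Patch(color=_CLASS_COLORS[c], label=c.value.replace("_", " ").lower())
            for c in categories[:4]
        ],
        loc="upper right",
        fontsize=8,
    )
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
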