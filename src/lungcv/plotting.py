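"""Optional plots: tri-colour CV slices and density-curve overlays."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from matplotlib.colors import BoundaryNorm, ListedColormap

from .cvmap import CVMatrix
from .density import DensityCurve
from .metrics import CV_T_INTERSECT, CV_T_MODE


def plot_cv_slice(
    cv: CVMatrix,
    axis: int = 1,
    index: int | None = None,
    path: str | Path | None = None,
):
    """Coronal-style tri-colour slice of a CV matrix.

    CV below 9.5% is drawn green, 9.5-20% yellow, above 20% red; voxels
    outside the lung are white.
    """
    if index is None:
        index = cv.values.shape[axis] // 2
    sl = np.take(cv.values, index, axis=axis)
    cmap = ListedColormap(["#2ca02c", "#ffdf00", "#d62728"])
    norm = BoundaryNorm([0.0, CV_T_MODE, CV_T_INTERSECT, np.inf], cmap.N)
    fig, ax = plt.subplots(figsize=(4, 4))
    masked = np.ma.masked_invalid(sl.T)
    ax.imshow(masked, cmap=cmap, norm=norm, origin="lower", interpolation="nearest")
    ax.set_title(f"CV map slice (axis {axis}, index {index})")
    ax.set_xticks([])
    ax.set_yticks([])
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig


def plot_density_curves(
    curves: dict[str, DensityCurve],
    cv_t: float | None = None,
    path: str | Path | None = None,
):
    """Overlay density curves; optionally shade the area above ``cv_t``."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for label, curve in curves.items():
        ax.plot(curve.bin_centers, curve.density, label=label, lw=1.2)
        if cv_t is not None:
            above = curve.bin_centers >= cv_t
            ax.fill_between(
                curve.bin_centers[above], curve.density[above], alpha=0.15, step="mid"
            )
    ax.set_xlabel("CV [%]")
    ax.set_ylabel("density [% per CV%]")
    ax.legend(fontsize=8)
    if cv_t is not None:
        ax.axvline(cv_t, color="k", ls="--", lw=0.8)
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
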