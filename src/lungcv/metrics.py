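"""Heterogeneity statistics: AUC(CV > CV_T) and the inner/outer split.

The heterogeneity measure is the area of the normalized density curve
above a CV threshold, AUC(CV > CV_T), in percent of the total area.
Two reference thresholds are exposed: 9.5 CV% (the mode of the healthy
reference mean curve) and 20 CV% (approximately where patient curves
intersect the reference mean curve, giving a wider dynamic range across
subjects).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cvmap import CVMatrix
from .density import DensityCurve, estimate_density
from .segmentation import LungMask

#: Mode of the healthy reference mean curve.
CV_T_MODE = 9.5

#: Intersection of patient curves with the reference mean curve.
CV_T_INTERSECT = 20.0


@dataclass(frozen=True)
class AucResult:
    """Area of a density curve above a CV threshold, in % of total."""

    cv_t: float
    auc_percent: float
    n_values: int
    compensated: bool = False


def auc_above(curve: DensityCurve, cv_t: float, compensated: bool = False) -> AucResult:
    """Area of the density curve above ``cv_t`` (rectangle rule).

    Bins entirely above the threshold contribute their full area; the
    bin containing the threshold contributes the linear fraction of its
    width that lies above it.
    """
    if cv_t < 0:
        raise ValueError("cv_t must be >= 0")
    right = curve.bin_centers + curve.bin_width / 2
    frac = np.clip((right - cv_t) / curve.bin_width, 0.0, 1.0)
    auc = float(np.sum(frac * curve.density * curve.bin_width))
    return AucResult(
        cv_t=float(cv_t),
        auc_percent=auc,
        n_values=curve.n_values,
        compensated=compensated,
    )


def decompose_inner_outer(
    cv: CVMatrix,
    inner: LungMask,
    outer: LungMask,
    bin_width: float | None = None,
) -> tuple[DensityCurve, DensityCurve, DensityCurve]:
    """Split the full density curve into inner and outer volume components.

    Component curves are histogrammed on the full curve's bin grid and
    scaled by the total (not per-component) value count, so the two
    component densities sum bin-wise to the full curve and their areas
    equal the components' shares of the total 100%.
    """
    if inner.shape != cv.mask.shape or outer.shape != cv.mask.shape:
        raise ValueError("partition mismatch: masks must share the CV matrix grid")
    if np.any(inner.grid & outer.grid):
        raise ValueError("partition mismatch: inner and outer masks overlap")
    if not np.array_equal(inner.grid | outer.grid, cv.mask.grid):
        raise ValueError("partition mismatch: inner + outer must tile the lung mask")

    from .density import BIN_WIDTH

    bw = BIN_WIDTH if bin_width is None else float(bin_width)
    full_values = cv.cv_values()
    full = estimate_density(full_values, bin_width=bw)
    n_total = full.n_values
    edges = full.bin_edges
    components = []
    for part, name in ((inner, "inner"), (outer, "outer")):
        vals = cv.cv_values(part)
        counts, _ = np.histogram(vals, bins=edges)
        density = counts / (n_total * bw) * 100.0
        components.append(
            DensityCurve(
                bin_centers=full.bin_centers,
                density=density,
                n_values=int(vals.size),
                bin_width=bw,
                provenance={
                    "component": name,
                    "volume_fraction": vals.size / n_total if n_total else 0.0,
                },
            )
        )
    return full, components[0], components[1]
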