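"""CV density curves, mode/flank location, and uptake compensation.

A subject's CV values are summarized as a *density curve*: a normalized
histogram on a uniform CV% grid whose total area is 100%, expressed in
percent per CV%. For a uniform tracer distribution the CV values scale
as 1/sqrt(count level), so curves from subjects with different tracer
uptake sit at different positions on the CV axis. Two normalizations
address this:

* ``mode_ratio_transform`` — multiply all CV values by the ratio of the
  density-curve modes (exact for uniform distributions, but distorts the
  heterogeneity tail);
* ``compensate`` — the milder two-step procedure used for subjects:
  (1) shift every CV value so the curve's ascending left flank passes
  through the *fix point* (density 0.5 % per CV% at CV = 3%), then
  (2) rescale the shifted values by M / (M - shift) with the reference
  mode M = 9.5 CV%. The shift is negative for subjects whose healthy
  regions have a lower activity concentration than the reference norm.

A large |shift| signals a count level too low for the compensation to be
meaningful (the heterogeneity tail is lost in noise); such runs are
flagged ``excluded`` but their values are still returned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

#: Default histogram bin width in CV%.
BIN_WIDTH = 0.5

#: Minimum number of finite CV values needed for a density curve.
MIN_SAMPLE = 100


class DensityCurveError(ValueError):
    """Raised when a density curve cannot be built or analysed."""


@dataclass(frozen=True)
class NormConstants:
    """Reference-curve constants anchoring the compensation.

    The fix point (CV = 3%, density = 0.5 % per CV%) is the point the
    left flank of healthy reference curves passes through; ``norm_mode``
    is the mode of the reference mean curve (9.5 CV%).
    """

    fix_point_cv: float = 3.0
    fix_point_density: float = 0.5
    norm_mode: float = 9.5

    def __post_init__(self) -> None:
        if min(self.fix_point_cv, self.fix_point_density, self.norm_mode) <= 0:
            raise ValueError("norm constants must be strictly positive")


#: Reference constants from the healthy-subject mean curve.
NORM = NormConstants()


@dataclass(frozen=True)
class CompensationRecord:
    """Record of one compensation: shift, rescale factor, exclusion flag."""

    shift: float
    scale_factor: float
    flank_crossing: float
    excluded: bool = False
    n_clipped: int = 0

    def as_dict(self) -> dict:
        return {
            "shift_cv_percent": self.shift,
            "scale_factor": self.scale_factor,
            "flank_crossing_cv_percent": self.flank_crossing,
            "excluded": self.excluded,
            "n_clipped": self.n_clipped,
        }


@dataclass
class DensityCurve:
    """Tabulated normalized CV distribution.

    ``bin_centers`` lie on a uniform grid of spacing ``bin_width``
    starting at ``bin_width / 2``; ``density`` is in percent per CV%, so
    that sum(density) * bin_width equals the curve area (100% for a full
    subject curve, the volume fraction x 100 for an inner/outer
    component).
    """

    bin_centers: np.ndarray
    density: np.ndarray
    n_values: int
    bin_width: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if self.bin_centers.shape != self.density.shape:
            raise DensityCurveError("bin_centers and density must have equal length")
        if np.any(self.density < 0):
            raise DensityCurveError("density must be non-negative")

    @property
    def area(self) -> float:
        """Rectangle-rule area: sum(density) * bin_width, in %."""
        return float(self.density.sum() * self.bin_width)

    @property
    def bin_edges(self) -> np.ndarray:
        return np.concatenate(
            [self.bin_centers - self.bin_width / 2, [self.bin_centers[-1] + self.bin_width / 2]]
        )

    def density_at(self, cv: float) -> float:
        """Density linearly interpolated between bin centres."""
        return float(np.interp(cv, self.bin_centers, self.density, left=0.0, right=0.0))


def estimate_density(cv_values: np.ndarray, bin_width: float = BIN_WIDTH) -> DensityCurve:
    """Histogram CV values into a normalized density curve (area 100%).

    Bins run from 0 to the smallest multiple of ``bin_width`` covering
    the largest value; density is counts / (N * bin_width) * 100, so the
    rectangle-rule area is exactly 100%.
    """
    values = np.asarray(cv_values, dtype=float).ravel()
    values = values[np.isfinite(values)]
    if values.size < MIN_SAMPLE:
        raise DensityCurveError(
            f"insufficient CV sample: {values.size} finite values (need >= {MIN_SAMPLE})"
        )
    if np.any(values < 0):
        raise DensityCurveError("CV values must be non-negative")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    vmax = float(values.max())
    n_bins = max(int(np.ceil(vmax / bin_width)), 1)
    if vmax == n_bins * bin_width:  # keep max value interior to the last bin
        n_bins += 1
    edges = np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(values, bins=edges)
    density = counts / (values.size * bin_width) * 100.0
    centers = edges[:-1] + bin_width / 2
    return DensityCurve(
        bin_centers=centers,
        density=density,
        n_values=int(values.size),
        bin_width=float(bin_width),
        provenance={"estimator": "fixed-width histogram", "bin_width": float(bin_width)},
    )


def _smoothed(curve: DensityCurve) -> np.ndarray:
    """3-bin moving average (edges use available bins) for mode finding."""
    d = curve.density
    if d.size < 3:
        return d.copy()
    kernel = np.ones(3) / 3.0
    sm = np.convolve(d, kernel, mode="same")
    # renormalize edge bins where the kernel is truncated
    norm = np.convolve(np.ones_like(d), kernel, mode="same")
    return sm / norm


def find_mode(curve: DensityCurve) -> float:
    """Mode of the curve: bin centre of the smoothed global maximum.

    A 3-bin moving average suppresses single-bin histogram noise before
    the argmax; ties break toward the lower CV. A flat curve has no
    mode and raises.
    """
    sm = _smoothed(curve)
    if np.allclose(sm, sm[0]):
        raise DensityCurveError("flat density curve has no mode")
    idx = int(np.argmax(sm))  # argmax returns the first (lowest-CV) maximum
    return float(curve.bin_centers[idx])


def left_flank_crossing(curve: DensityCurve, level: float = NORM.fix_point_density) -> float:
    """CV where the ascending left flank first attains ``level``.

    Scans bins from zero up to the mode and linearly interpolates between
    the two bin centres bracketing the crossing; crossings after the mode
    are ignored. If the curve is already above ``level`` at the first
    bin, the first bin edge (0) is returned and flagged in the curve's
    provenance.
    """
    sm = _smoothed(curve)
    mode_idx = int(np.argmax(sm))
    d = curve.density
    if d[: mode_idx + 1].max() < level:
        raise DensityCurveError(
            f"no flank crossing: curve never reaches density {level} before its mode"
        )
    idx = int(np.argmax(d[: mode_idx + 1] >= level))
    if idx == 0:
        curve.provenance["flank_at_boundary"] = True
        return float(curve.bin_edges[0])
    d0, d1 = d[idx - 1], d[idx]
    c0 = curve.bin_centers[idx - 1]
    return float(c0 + (level - d0) / (d1 - d0) * curve.bin_width)


def mode_ratio_transform(
    cv_values: np.ndarray, mode_target: float, mode_source: float
) -> np.ndarray:
    """Rescale CV values by the ratio of density-curve modes.

    Exact normalization for uniform activity distributions at different
    count levels: both curves collapse onto the target-mode curve.
    """
    if mode_target <= 0 or mode_source <= 0:
        raise ValueError("density-curve modes must be positive")
    return np.asarray(cv_values, dtype=float) * (mode_target / mode_source)


def compensate(
    cv_values: np.ndarray,
    constants: NormConstants = NORM,
    bin_width: float = BIN_WIDTH,
    exclusion_limit: float = 3.0,
) -> tuple[np.ndarray, CompensationRecord]:
    """Two-step uptake compensation of a subject's CV values.

    1. Build the uncompensated density curve and locate its left-flank
       crossing of the fix-point density; shift every CV value by
       ``shift = fix_point_cv - flank_crossing`` (negative values are
       clipped to 0 and counted).
    2. Rescale the shifted values by ``norm_mode / (norm_mode - shift)``.

    If |shift| exceeds ``exclusion_limit`` the record is flagged
    ``excluded`` — the count level is too low for the compensation to be
    trustworthy — but the compensated values are still returned.
    """
    values = np.asarray(cv_values, dtype=float).ravel()
    curve = estimate_density(values, bin_width=bin_width)
    crossing = left_flank_crossing(curve, level=constants.fix_point_density)
    shift = constants.fix_point_cv - crossing
    if shift >= constants.norm_mode:
        raise DensityCurveError(
            f"shift {shift:.2f} >= norm mode {constants.norm_mode}: rescale undefined"
        )
    shifted = values + shift
    n_clipped = int(np.sum(shifted < 0))
    shifted = np.maximum(shifted, 0.0)
    scale = constants.norm_mode / (constants.norm_mode - shift)
    compensated = shifted * scale
    excluded = abs(shift) > exclusion_limit
    if excluded:
        warnings.warn(
            f"|shift| = {abs(shift):.2f} CV% exceeds the exclusion limit "
            f"({exclusion_limit} CV%): activity concentration too low for a "
            "reliable compensation; result flagged excluded",
            stacklevel=2,
        )
    record = CompensationRecord(
        shift=float(shift),
        scale_factor=float(scale),
        flank_crossing=float(crossing),
        excluded=bool(excluded),
        n_clipped=n_clipped,
    )
    return compensated, record


def mean_curve(curves: list[DensityCurve]) -> DensityCurve:
    """Pointwise average of density curves, renormalized to area 100%.

    Curves must share the bin width; shorter curves are zero-padded to
    the longest grid (all grids start at 0 by construction).
    """
    if not curves:
        raise DensityCurveError("mean_curve requires at least one curve")
    widths = {round(c.bin_width, 12) for c in curves}
    if len(widths) != 1:
        raise DensityCurveError(f"curves must share one bin width, got {sorted(widths)}")
    bw = curves[0].bin_width
    n_bins = max(c.density.size for c in curves)
    stacked = np.zeros((len(curves), n_bins))
    for i, c in enumerate(curves):
        stacked[i, : c.density.size] = c.density
    avg = stacked.mean(axis=0)
    area = avg.sum() * bw
    if area <= 0:
        raise DensityCurveError("mean curve has zero area")
    avg *= 100.0 / area
    centers = (np.arange(n_bins) + 0.5) * bw
    return DensityCurve(
        bin_centers=centers,
        density=avg,
        n_values=int(sum(c.n_values for c in curves)),
        bin_width=bw,
        provenance={"mean_of": len(curves)},
    )


def derive_norm_mode(
    reference_cv_sets: list[np.ndarray],
    constants: NormConstants = NORM,
    bin_width: float = BIN_WIDTH,
    max_iter: int = 50,
    tol: float = 1e-3,
) -> NormConstants:
    """Re-derive ``norm_mode`` from a reference cohort.

    Finds the self-consistent mode: the value M such that compensating
    the reference CV sets with ``norm_mode = M`` yields a mean curve
    whose mode is again M (fixed-point iteration; the fix point itself is
    kept as configured).
    """
    if not reference_cv_sets:
        raise DensityCurveError("need at least one reference CV set")
    mode = constants.norm_mode
    for _ in range(max_iter):
        trial = NormConstants(constants.fix_point_cv, constants.fix_point_density, mode)
        curves = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for values in reference_cv_sets:
                comp, _rec = compensate(
                    values, constants=trial, bin_width=bin_width, exclusion_limit=np.inf
                )
                curves.append(estimate_density(comp, bin_width=bin_width))
        new_mode = find_mode(mean_curve(curves))
        if abs(new_mode - mode) < tol:
            mode = new_mode
            break
        mode = new_mode
    return NormConstants(constants.fix_point_cv, constants.fix_point_density, float(mode))
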