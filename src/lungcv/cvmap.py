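"""Sliding-window coefficient-of-variation mapping of activity volumes.

For every segmented lung voxel, the coefficient of variation
CV = 100 * s / m  [%]
is computed over the cubic window centred on that voxel, where m is the
window mean and s the sample (n-1) standard deviation of the voxel
counts. The default window is 3x3x3 voxels of 3.45 mm, i.e. a 1.04 cm
cube (~1.1 cm^3), the closest odd-sided cube to 1 cm^3.

Windows deliberately include voxels outside the lung mask: at the lung
boundary the window straddles the activity fall-off produced by the
finite system resolution, which is what generates the characteristic
high-CV rim (the periphery or edge effect). Windows truncated by the
image border use only in-grid voxels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .segmentation import LungMask
from .volume import VolumeImage

logger = logging.getLogger(__name__)

#: Default cube side in voxels (3 x 3.45 mm = 1.04 cm).
WINDOW_VOXELS = 3


@dataclass
class CVMatrix:
    """Per-lung-voxel CV values (percent) on the source grid.

    ``values`` is a full-grid float array holding the CV in percent at
    every mask voxel where the window mean is positive, and NaN
    elsewhere (outside the mask, or flagged undefined).
    """

    values: np.ndarray
    mask: LungMask
    window_voxels: int
    n_undefined: int = 0
    provenance: dict = field(default_factory=dict)

    def cv_values(self, submask: np.ndarray | LungMask | None = None) -> np.ndarray:
        """Finite CV values inside the mask (optionally a sub-mask), 1D."""
        grid = self.mask.grid
        if submask is not None:
            sub = submask.grid if isinstance(submask, LungMask) else np.asarray(submask, bool)
            grid = grid & sub
        vals = self.values[grid]
        return vals[np.isfinite(vals)]

    def as_volume(self, sentinel: float = -1.0) -> VolumeImage:
        """CV map as a volume with non-lung/undefined voxels at ``sentinel``."""
        data = np.where(np.isfinite(self.values), self.values, sentinel)
        return VolumeImage(
            data=data,
            voxel_size_mm=self.mask.voxel_size_mm,
            meta={"role": "cv_percent", "sentinel": sentinel, **self.provenance},
        )


def _window_sums(x: np.ndarray, size: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-voxel window count, sum and sum of squares with border truncation."""
    n_full = size**3
    ones = np.ones_like(x, dtype=np.float64)
    n = ndimage.uniform_filter(ones, size=size, mode="constant", cval=0.0) * n_full
    n = np.rint(n)
    s = ndimage.uniform_filter(x, size=size, mode="constant", cval=0.0) * n_full
    ss = ndimage.uniform_filter(x * x, size=size, mode="constant", cval=0.0) * n_full
    return n, s, ss


def compute_cv_matrix(
    counts: VolumeImage,
    mask: LungMask,
    window_voxels: int = WINDOW_VOXELS,
) -> CVMatrix:
    """Compute the 3D CV matrix over overlapping cubic windows.

    Every mask voxel receives the CV of the ``window_voxels``-sided cube
    centred on it, using all in-grid cube voxels regardless of mask
    membership. Voxels whose window mean is <= 0 are flagged undefined
    (NaN) and excluded from downstream density curves; their count is
    logged and recorded in ``n_undefined``.
    """
    if counts.shape != mask.shape:
        raise ValueError("counts volume and mask must share the same grid")
    if window_voxels < 1 or window_voxels % 2 == 0:
        raise ValueError("window_voxels must be a positive odd integer")

    x = np.asarray(counts.data, dtype=np.float64)
    n, s, ss = _window_sums(x, window_voxels)
    with np.errstate(divide="ignore", invalid="ignore"):
        mean = s / n
        var = (ss - s * s / n) / np.maximum(n - 1, 1)
        # clip negative/cancellation residue of the separable box filter
        var = np.maximum(var, 0.0)
        var[var < 1e-12 * mean * mean] = 0.0
        cv = 100.0 * np.sqrt(var) / mean

    values = np.full(mask.shape, np.nan)
    valid = mask.grid & (mean > 0) & (n > 1)
    values[valid] = cv[valid]
    n_undefined = int(mask.grid.sum() - valid.sum())
    if n_undefined:
        logger.info(
            "CV undefined (window mean <= 0) at %d of %d mask voxels",
            n_undefined,
            int(mask.grid.sum()),
        )
    return CVMatrix(
        values=values,
        mask=mask,
        window_voxels=window_voxels,
        n_undefined=n_undefined,
        provenance={
            "window_voxels": int(window_voxels),
            "window_rule": "all in-grid cube voxels, mask-unrestricted",
            "sd_estimator": "sample (n-1)",
        },
    )


def cv_matrix_bruteforce(
    counts: np.ndarray, mask: np.ndarray, window_voxels: int = WINDOW_VOXELS
) -> np.ndarray:
    """Naive triple-loop reference implementation (tests/oracles only)."""
    x = np.asarray(counts, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    half = window_voxels // 2
    out = np.full(x.shape, np.nan)
    ni, nj, nk = x.shape
    for i in range(ni):
        for j in range(nj):
            for k in range(nk):
                if not mask[i, j, k]:
                    continue
                block = x[
                    max(i - half, 0) : i + half + 1,
                    max(j - half, 0) : j + half + 1,
                    max(k - half, 0) : k + half + 1,
                ]
                m = block.mean()
                if m <= 0 or block.size < 2:
                    continue
                out[i, j, k] = 100.0 * block.std(ddof=1) / m
    return out
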