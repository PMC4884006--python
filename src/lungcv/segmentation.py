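"""Lung segmentation from attenuation maps and the inner/outer partition.

The lung is taken to be every voxel that lies inside the body (positive
attenuation) but attenuates less than an empirical threshold of
0.12 cm^-1, which separates aerated lung tissue (~0.05 cm^-1) from soft
tissue (~0.15 cm^-1) at 140 keV. Connected-component cleanup keeps the
one or two largest candidate components (the two lungs may or may not be
connected at the carina). The peripheral shell is obtained by eroding
the mask three voxels deep with a face-connected (6-neighbour)
structuring element; the inner volume is the erosion result, and the
outer volume is the set difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume import VolumeImage

#: Empirical linear-attenuation threshold (cm^-1) separating lung from body.
MU_THRESHOLD = 0.12

#: Default erosion depth (voxels) defining the inner/outer partition.
EROSION_VOXELS = 3


class SegmentationError(ValueError):
    """Raised when no acceptable lung mask can be produced."""


@dataclass
class LungMask:
    """Binary lung mask aligned to a source volume grid."""

    grid: np.ndarray
    voxel_size_mm: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=bool)
        if self.grid.ndim != 3:
            raise ValueError("mask must be 3D")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape

    @property
    def n_voxels(self) -> int:
        return int(self.grid.sum())

    @property
    def volume_mm3(self) -> float:
        return self.n_voxels * float(self.voxel_size_mm) ** 3

    def as_volume(self) -> VolumeImage:
        return VolumeImage(
            data=self.grid.astype(np.float32),
            voxel_size_mm=self.voxel_size_mm,
            meta={"role": "mask", **self.provenance},
        )


def _six_connected() -> np.ndarray:
    return ndimage.generate_binary_structure(3, 1)


def segment_lung(
    attenuation: VolumeImage,
    mu_threshold: float = MU_THRESHOLD,
    max_components: int = 2,
    min_component_fraction: float = 0.25,
) -> LungMask:
    """Threshold-segment the lung from an attenuation map.

    Candidate voxels attenuate strictly below ``mu_threshold`` while lying
    inside the body (attenuation > 0, which excludes the air surrounding
    the subject). Of the connected candidate components, the largest is
    always kept and a second is kept when its size is at least
    ``min_component_fraction`` of the largest, so two disconnected lungs
    survive while small gas pockets are discarded.

    Raises
    ------
    SegmentationError
        If no candidate voxel exists ("no lung found at threshold").
    """
    a = np.asarray(attenuation.data)
    if np.any(a < 0):
        raise ValueError("attenuation map must be non-negative")
    candidate = (a > 0) & (a < mu_threshold)
    if not candidate.any():
        raise SegmentationError(f"no lung found at threshold {mu_threshold} cm^-1")

    labels, n_labels = ndimage.label(candidate, structure=_six_connected())
    sizes = np.bincount(labels.ravel())[1:]  # skip background
    order = np.argsort(sizes)[::-1]
    keep = [order[0]]
    for idx in order[1:max_components]:
        if sizes[idx] >= min_component_fraction * sizes[order[0]]:
            keep.append(idx)
    grid = np.isin(labels, [i + 1 for i in keep])
    if not grid.any():  # pragma: no cover - keep always nonempty here
        raise SegmentationError(f"no lung found at threshold {mu_threshold} cm^-1")
    return LungMask(
        grid=grid,
        voxel_size_mm=attenuation.voxel_size_mm,
        provenance={
            "mu_threshold_cm_inv": float(mu_threshold),
            "components_kept": len(keep),
            "n_candidate_components": int(n_labels),
        },
    )


def candidate_mask(attenuation: VolumeImage, mu_threshold: float = MU_THRESHOLD) -> np.ndarray:
    """Thresholded candidate set before component cleanup (for diagnostics)."""
    a = np.asarray(attenuation.data)
    return (a > 0) & (a < mu_threshold)


def split_inner_outer(
    mask: LungMask, erosion_voxels: int = EROSION_VOXELS
) -> tuple[LungMask, LungMask]:
    """Partition a lung mask into an inner core and an outer shell.

    The inner volume is the mask eroded ``erosion_voxels`` times with the
    6-connected structuring element; the outer volume is the remainder.
    With ``erosion_voxels = 0`` the inner volume is the mask itself.

    Raises
    ------
    SegmentationError
        If the erosion empties the mask ("lung too small").
    """
    if not mask.grid.any():
        raise SegmentationError("mask is empty")
    if erosion_voxels < 0:
        raise ValueError("erosion_voxels must be >= 0")
    if erosion_voxels == 0:
        inner_grid = mask.grid.copy()
    else:
        inner_grid = ndimage.binary_erosion(
            mask.grid, structure=_six_connected(), iterations=erosion_voxels
        )
    if erosion_voxels > 0 and not inner_grid.any():
        raise SegmentationError("lung too small for inner/outer split")
    outer_grid = mask.grid & ~inner_grid
    prov = {**mask.provenance, "erosion_voxels": int(erosion_voxels),
            "structuring_element": "6-connected"}
    inner = LungMask(inner_grid, mask.voxel_size_mm, {**prov, "partition": "inner"})
    outer = LungMask(outer_grid, mask.voxel_size_mm, {**prov, "partition": "outer"})
    return inner, outer


def dice(a: LungMask | np.ndarray, b: LungMask | np.ndarray) -> float:
    """Dice overlap coefficient between two binary masks."""
    ga = a.grid if isinstance(a, LungMask) else np.asarray(a, dtype=bool)
    gb = b.grid if isinstance(b, LungMask) else np.asarray(b, dtype=bool)
    denom = ga.sum() + gb.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(ga, gb).sum() / denom
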