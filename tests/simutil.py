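"""Shared simulation helpers for the test suite."""

from __future__ import annotations

import numpy as np

from lungcv import (
    CVMatrix,
    DensityCurve,
    PhantomSpec,
    VolumeImage,
    compute_cv_matrix,
    make_activity,
    make_anatomy,
    segment_lung,
    simulate_acquisition,
)
from lungcv.phantom import Ellipsoid
from lungcv.segmentation import LungMask


def small_spec(**overrides) -> PhantomSpec:
    """A reduced 48^3 phantom for simulation-heavy tests."""
    defaults = dict(
        grid_shape=(48, 48, 48),
        body=Ellipsoid((0.0, 0.0, 0.0), (75.0, 70.0, 80.0)),
        lung_geometry=(
            Ellipsoid((-36.0, 0.0, 0.0), (26.0, 36.0, 60.0)),
            Ellipsoid((36.0, 0.0, 0.0), (26.0, 36.0, 60.0)),
        ),
    )
    defaults.update(overrides)
    return PhantomSpec(**defaults)


def run_phantom_subject(spec: PhantomSpec, rng=None) -> dict:
    """Full single-subject chain: anatomy -> counts -> mask -> CV matrix."""
    attenuation, truth = make_anatomy(spec)
    activity = make_activity(truth, spec)
    counts = simulate_acquisition(activity, spec, rng=rng)
    mask = segment_lung(attenuation)
    cv = compute_cv_matrix(counts, mask)
    return {
        "attenuation": attenuation,
        "truth": truth,
        "counts": counts,
        "mask": mask,
        "cv": cv,
        "values": cv.cv_values(),
    }


def uniform_cv_values(lam: float, seed: int, n: int = 40, margin: int = 2) -> np.ndarray:
    """CV values of a uniform Poisson field, periphery excluded.

    Emulates the central voxels of a uniform activity distribution: an
    n^3 field of independent Poisson(lam) counts, CV computed everywhere
    and read out on the interior (margin voxels trimmed per side).
    """
    rng = np.random.default_rng(seed)
    field = rng.poisson(lam, size=(n, n, n)).astype(float)
    mask = LungMask(np.ones((n, n, n), dtype=bool), 3.45)
    cv = compute_cv_matrix(VolumeImage(field, 3.45), mask)
    interior = np.zeros((n, n, n), dtype=bool)
    interior[margin:-margin, margin:-margin, margin:-margin] = True
    return cv.cv_values(interior)


def norm_like_sample(rng: np.random.Generator, size: int = 200_000) -> np.ndarray:
    """CV sample whose density curve resembles the reference norm.

    Clipped Normal(9.5, 2.48): mode at 9.5 CV% and density ~0.5 %/CV%
    at 3 CV%, i.e. the curve passes through the fix point.
    """
    vals = rng.normal(9.5, 2.48, size)
    return vals[vals > 0]


def sup_distance(c1: DensityCurve, c2: DensityCurve) -> float:
    """Sup-norm between two density curves on the union bin grid."""
    n = max(c1.density.size, c2.density.size)
    d1 = np.zeros(n)
    d1[: c1.density.size] = c1.density
    d2 = np.zeros(n)
    d2[: c2.density.size] = c2.density
    return float(np.abs(d1 - d2).max())


def interior_mask(cv: CVMatrix, margin: int = 2) -> np.ndarray:
    grid = np.zeros(cv.values.shape, dtype=bool)
    grid[margin:-margin, margin:-margin, margin:-margin] = True
    return grid
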