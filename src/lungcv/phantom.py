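"""Digital two-lung phantom: anatomy, activity, and acquisition emulation.

The phantom places two ellipsoidal lungs inside an ellipsoidal soft-tissue
body on an isotropic voxel grid (default 3.45 mm). Ventilation is modelled
as a uniform tracer concentration in healthy lung, optionally reduced
inside spherical defects. Acquisition is emulated by a stationary Gaussian
point-spread function (resolution loss, which produces the spurious
high-CV rim at the lung boundary) followed by independent Poisson counting
noise per voxel. The per-voxel expected count level stands in for the
administered activity: the study protocol's ~90 MBq deposit maps to a
default of 50 expected counts per lung voxel.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .segmentation import LungMask
from .volume import VolumeImage, coordinate_grids

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


class PhantomValidationError(ValueError):
    """A phantom specification violates a geometric or physical constraint."""


@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned ellipsoid: centre and half-axes in mm."""

    center_mm: tuple[float, float, float]
    half_axes_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        if len(self.center_mm) != 3 or len(self.half_axes_mm) != 3:
            raise PhantomValidationError("ellipsoid needs 3D centre and half-axes")
        if any(a <= 0 for a in self.half_axes_mm):
            raise PhantomValidationError("ellipsoid half-axes must be positive")

    def inside(self, x: np.ndarray, y: np.ndarray, z: np.ndarray) -> np.ndarray:
        cx, cy, cz = self.center_mm
        ax, ay, az = self.half_axes_mm
        return ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2 <= 1.0

    def surface_points(self, n: int = 512) -> np.ndarray:
        """Deterministic quasi-uniform sample of surface points (Fibonacci)."""
        i = np.arange(n) + 0.5
        phi = np.arccos(1 - 2 * i / n)
        theta = np.pi * (1 + 5**0.5) * i
        u = np.stack(
            [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)], axis=1
        )
        return np.asarray(self.center_mm) + u * np.asarray(self.half_axes_mm)

    def contains_points(self, pts: np.ndarray, margin: float = 0.0) -> np.ndarray:
        rel = (pts - np.asarray(self.center_mm)) / np.asarray(self.half_axes_mm)
        return np.sum(rel**2, axis=1) < (1.0 - margin) ** 2

    def contains_sphere(self, center_mm, radius_mm: float) -> bool:
        """Sufficient (slightly conservative) sphere-in-ellipsoid test.

        Uses the bound ||(c-c0)/a||_2 + r/min(a) <= 1, which guarantees the
        whole sphere lies inside (triangle inequality in the scaled norm).
        """
        rel = (np.asarray(center_mm, dtype=float) - np.asarray(self.center_mm)) / np.asarray(
            self.half_axes_mm
        )
        return float(np.linalg.norm(rel)) + radius_mm / min(self.half_axes_mm) <= 1.0


@dataclass(frozen=True)
class DefectSpec:
    """Spherical region of reduced tracer concentration inside a lung.

    ``activity_fraction`` is the concentration relative to the healthy
    background, in [0, 1); a fraction of 0 is a total ventilation defect.
    """

    center_mm: tuple[float, float, float]
    radius_mm: float
    activity_fraction: float

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise PhantomValidationError("defect radius must be positive")
        if not 0.0 <= self.activity_fraction < 1.0 and self.activity_fraction != 1.0:
            # fraction 1.0 is tolerated as an explicit no-op (used in tests)
            raise PhantomValidationError("activity_fraction must lie in [0, 1)")


def default_lung_geometry() -> tuple[Ellipsoid, Ellipsoid]:
    """Two lungs sized to sit well inside the default body ellipsoid."""
    return (
        Ellipsoid(center_mm=(-45.0, 0.0, 0.0), half_axes_mm=(32.0, 45.0, 75.0)),
        Ellipsoid(center_mm=(45.0, 0.0, 0.0), half_axes_mm=(32.0, 45.0, 75.0)),
    )


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of a digital phantom realization.

    Attenuation is two-valued (noiseless): ``body_mu`` in soft tissue and
    ``lung_mu`` in aerated lung, chosen to straddle the 0.12 cm^-1
    segmentation threshold. ``mean_counts_per_lung_voxel`` sets the
    expected reconstructed count level in healthy lung; ``psf_fwhm_mm``
    is the width of the Gaussian resolution model.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size_mm: float = 3.45
    body_mu: float = 0.15
    lung_mu: float = 0.05
    body: Ellipsoid = field(
        default_factory=lambda: Ellipsoid((0.0, 0.0, 0.0), (95.0, 85.0, 105.0))
    )
    lung_geometry: tuple[Ellipsoid, ...] = field(default_factory=default_lung_geometry)
    defects: tuple[DefectSpec, ...] = ()
    mean_counts_per_lung_voxel: float = 50.0
    psf_fwhm_mm: float = 12.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "lung_geometry", tuple(self.lung_geometry))
        object.__setattr__(self, "defects", tuple(self.defects))

    def validate(self) -> None:
        if len(self.lung_geometry) == 0:
            raise PhantomValidationError("no lungs defined in lung_geometry")
        if not (self.lung_mu < 0.12 < self.body_mu):
            raise PhantomValidationError(
                "attenuation must satisfy lung_mu < 0.12 cm^-1 < body_mu "
                f"(got lung_mu={self.lung_mu}, body_mu={self.body_mu})"
            )
        if self.mean_counts_per_lung_voxel <= 0:
            raise PhantomValidationError("mean_counts_per_lung_voxel must be > 0")
        if self.psf_fwhm_mm < 0:
            raise PhantomValidationError("psf_fwhm_mm must be >= 0")
        if self.voxel_size_mm <= 0:
            raise PhantomValidationError("voxel_size_mm must be positive")
        for i, lung in enumerate(self.lung_geometry):
            pts = lung.surface_points()
            if not self.body.contains_points(pts, margin=1e-6).all():
                raise PhantomValidationError(
                    f"lung {i} is not strictly inside the body ellipsoid"
                )
        for j, defect in enumerate(self.defects):
            if not any(
                lung.contains_sphere(defect.center_mm, defect.radius_mm)
                for lung in self.lung_geometry
            ):
                raise PhantomValidationError(
                    f"defect {j} is not fully inside any lung"
                )

    def with_defects(self, defects) -> "PhantomSpec":
        return replace(self, defects=tuple(defects))


def make_anatomy(spec: PhantomSpec) -> tuple[VolumeImage, LungMask]:
    """Voxelize the attenuation map and the truth lung mask.

    The attenuation map holds ``body_mu`` inside the body, ``lung_mu``
    inside the lungs and 0 in the surrounding air; the truth mask marks
    exactly the voxels whose centres fall inside a lung ellipsoid.
    """
    spec.validate()
    x, y, z = coordinate_grids(spec.grid_shape, spec.voxel_size_mm)
    body = spec.body.inside(x, y, z)
    lungs = np.zeros(spec.grid_shape, dtype=bool)
    for lung in spec.lung_geometry:
        lungs |= lung.inside(x, y, z)
    attenuation = np.where(body, spec.body_mu, 0.0)
    attenuation[lungs] = spec.lung_mu
    att = VolumeImage(
        data=attenuation,
        voxel_size_mm=spec.voxel_size_mm,
        meta={"role": "attenuation", "body_mu": spec.body_mu, "lung_mu": spec.lung_mu},
    )
    mask = LungMask(
        grid=lungs,
        voxel_size_mm=spec.voxel_size_mm,
        provenance={"source": "phantom truth"},
    )
    return att, mask


def make_activity(truth_mask: LungMask, spec: PhantomSpec) -> VolumeImage:
    """Noiseless, unblurred expected-activity volume.

    Healthy lung voxels carry ``mean_counts_per_lung_voxel``; voxels inside
    each defect sphere carry that value times the defect's
    ``activity_fraction``; everything outside the lung is zero.
    """
    spec.validate()
    x, y, z = coordinate_grids(truth_mask.shape, truth_mask.voxel_size_mm)
    activity = np.where(truth_mask.grid, float(spec.mean_counts_per_lung_voxel), 0.0)
    for defect in spec.defects:
        cx, cy, cz = defect.center_mm
        inside = ((x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2) <= defect.radius_mm**2
        if not truth_mask.grid[inside].all():
            raise PhantomValidationError("defect voxels extend outside the lung mask")
        activity[inside & truth_mask.grid] *= defect.activity_fraction
    return VolumeImage(
        data=activity,
        voxel_size_mm=truth_mask.voxel_size_mm,
        meta={"role": "activity", "mean_counts": spec.mean_counts_per_lung_voxel},
    )


def apply_psf(activity: VolumeImage, psf_fwhm_mm: float) -> VolumeImage:
    """Gaussian system-resolution blur; count-conserving away from edges."""
    if psf_fwhm_mm < 0:
        raise ValueError("psf_fwhm_mm must be >= 0")
    if psf_fwhm_mm == 0:
        blurred = np.asarray(activity.data, dtype=float).copy()
    else:
        sigma_vox = psf_fwhm_mm * FWHM_TO_SIGMA / activity.voxel_size_mm
        blurred = ndimage.gaussian_filter(
            np.asarray(activity.data, dtype=float), sigma=sigma_vox, mode="constant"
        )
    return VolumeImage(
        data=blurred,
        voxel_size_mm=activity.voxel_size_mm,
        meta={**activity.meta, "psf_fwhm_mm": psf_fwhm_mm},
    )


def simulate_acquisition(
    activity: VolumeImage,
    spec: PhantomSpec,
    rng: np.random.Generator | None = None,
) -> VolumeImage:
    """Emulate acquisition: PSF blur, then Poisson noise per voxel.

    The blurred expected activity is used as the mean of an independent
    Poisson draw in every voxel. Reproducible: the generator is seeded
    from ``spec.seed`` unless an explicit ``rng`` is passed.
    """
    if np.any(np.asarray(activity.data) < 0):
        raise ValueError("activity must be non-negative")
    blurred = apply_psf(activity, spec.psf_fwhm_mm)
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    counts = rng.poisson(blurred.data).astype(np.float64)
    return VolumeImage(
        data=counts,
        voxel_size_mm=activity.voxel_size_mm,
        meta={**blurred.meta, "role": "counts", "seed": spec.seed},
    )


# ---------------------------------------------------------------------------
# Cohorts


@dataclass(frozen=True)
class CohortMember:
    """Per-subject generating parameters plus optional covariates."""

    subject_id: str
    mean_counts: float = 50.0
    defect_volume_fraction: float = 0.0
    defect_activity_fraction: float = 0.3
    age: float | None = None
    height: float | None = None
    gender: str = "M"
    lung_function_abnormal: bool = False


@dataclass(frozen=True)
class CohortSpec:
    """A reproducible list of phantom subjects sharing one geometry."""

    members: tuple[CohortMember, ...]
    base: PhantomSpec = field(default_factory=PhantomSpec)

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", tuple(self.members))

    @staticmethod
    def age_linked_burden(
        n: int,
        age_range: tuple[float, float] = (45.0, 80.0),
        burden_at_min_age: float = 0.0,
        burden_at_max_age: float = 0.12,
        mean_counts: float = 50.0,
        base: PhantomSpec | None = None,
    ) -> "CohortSpec":
        """Cohort whose defect volume fraction rises linearly with age."""
        ages = np.linspace(age_range[0], age_range[1], n)
        lo, hi = burden_at_min_age, burden_at_max_age
        members = tuple(
            CohortMember(
                subject_id=f"S{i + 1}",
                mean_counts=mean_counts,
                defect_volume_fraction=lo + (hi - lo) * (a - ages[0]) / max(ages[-1] - ages[0], 1e-9),
                age=float(a),
            )
            for i, a in enumerate(ages)
        )
        return CohortSpec(members=members, base=base or PhantomSpec())


def defects_for_burden(
    spec: PhantomSpec,
    volume_fraction: float,
    activity_fraction: float = 0.3,
    max_spheres: int = 6,
) -> tuple[DefectSpec, ...]:
    """Place spheres at fixed in-lung sites until the burden is reached.

    Deterministic: candidate sites are interior points of the lung
    ellipsoids on each lung's long axis. The requested ``volume_fraction``
    is the total defect volume relative to the total lung volume.
    """
    if volume_fraction <= 0:
        return ()
    if not 0 <= activity_fraction < 1:
        raise PhantomValidationError("activity_fraction must lie in [0, 1)")
    lung_volume = sum(
        4.0 / 3.0 * np.pi * np.prod(lung.half_axes_mm) for lung in spec.lung_geometry
    )
    target = volume_fraction * lung_volume
    sites: list[tuple[Ellipsoid, np.ndarray]] = []
    for lung in spec.lung_geometry:
        c = np.asarray(lung.center_mm)
        long_axis = np.argmax(lung.half_axes_mm)
        for t in (-0.45, 0.0, 0.45):
            offset = np.zeros(3)
            offset[long_axis] = t * lung.half_axes_mm[long_axis]
            sites.append((lung, c + offset))
    sites = sites[:max_spheres]
    radius = (target / len(sites) * 3.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
    # shrink radius if any sphere would poke out of its lung
    for lung, center in sites:
        while radius > 1.0 and not lung.contains_sphere(center, radius):
            radius *= 0.9
    return tuple(
        DefectSpec(center_mm=tuple(center), radius_mm=radius, activity_fraction=activity_fraction)
        for lung, center in sites
    )


def generate_cohort(
    cohort_spec: CohortSpec, seed: int
) -> list[tuple[VolumeImage, VolumeImage, dict]]:
    """Generate (attenuation, counts, metadata) triples for every member.

    Each member gets an independent, reproducible random stream spawned
    from ``seed``; metadata records the generating parameters so that
    parameter-recovery tests can compare estimates against truth.
    """
    out: list[tuple[VolumeImage, VolumeImage, dict]] = []
    streams = np.random.SeedSequence(seed).spawn(max(len(cohort_spec.members), 1))
    for member, stream in zip(cohort_spec.members, streams):
        spec = replace(
            cohort_spec.base,
            mean_counts_per_lung_voxel=member.mean_counts,
            seed=seed,
        )
        defects = defects_for_burden(
            spec, member.defect_volume_fraction, member.defect_activity_fraction
        )
        spec = spec.with_defects(defects)
        attenuation, truth = make_anatomy(spec)
        activity = make_activity(truth, spec)
        counts = simulate_acquisition(activity, spec, rng=np.random.default_rng(stream))
        meta = {
            "subject_id": member.subject_id,
            "mean_counts": member.mean_counts,
            "defect_volume_fraction": member.defect_volume_fraction,
            "defect_activity_fraction": member.defect_activity_fraction,
            "n_defects": len(defects),
            "age": member.age,
            "height": member.height,
            "gender": member.gender,
            "lung_function_abnormal": member.lung_function_abnormal,
        }
        out.append((attenuation, counts, meta))
    return out
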