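"""Synthetic phantoms and grade-labeled cohorts with known ground truth.

Real FLAIR-derived masks for this problem are clinical data; the phantom
module stands in for them with fully controlled geometry so that every
downstream claim (PV-shell construction, the >60% rule, threshold
learning) can be checked against an analytically known truth.

Two generators are provided:

* :func:`make_phantom` rasterizes an ellipsoidal brain, a pair of
  ellipsoidal lateral-ventricle bodies and spherical lesions placed at
  controlled anisotropic distances from the ventricle surface, returning
  the mask bundle together with per-lesion truth (class and volume).
* :func:`sample_cohort` draws per-grade log-normal volume-ratio samples —
  lesion volume distributions are positive and right-skewed, with SDs of
  the same order as the means — calibrated by default to per-grade mean/SD
  lesion volumes (mL) of a clinical training cohort scaled by a nominal
  1400 mL brain.

All randomness is owned by a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .grading import BRAIN_DOCK, FAZEKAS, GradeScale
from .volume_io import LabelVolume, MaskBundle, ValidationError, voxel_volume_ml

__all__ = [
    "GenerationError",
    "LesionSpec",
    "PhantomSpec",
    "LesionTruth",
    "PhantomTruth",
    "CohortSpec",
    "make_phantom",
    "sample_cohort",
    "default_cohort_spec",
    "lognormal_params",
    "REFERENCE_VOLUME_STATS_ML",
    "NOMINAL_BRAIN_ML",
]

PVH = "PVH"
DWMH = "DWMH"
STRADDLING = "straddling"


class GenerationError(ValueError):
    """A phantom spec cannot be realized (lesion outside brain, overlap...)."""


@dataclass(frozen=True)
class LesionSpec:
    """One spherical lesion, placed by distance from the ventricle surface.

    ``offset_mm`` is the requested anisotropic Euclidean distance from the
    lesion centre to the nearest ventricle voxel centre; ``direction`` is
    the preferred placement direction (mm space) from the ventricle
    centroid, used to disambiguate between equidistant candidate centres.
    """

    offset_mm: float
    radius_mm: float
    intended_class: str
    direction: tuple[float, float, float] = (1.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValidationError("lesion radius must be positive")
        if self.offset_mm <= 0:
            raise ValidationError("lesion offset must be positive")
        if self.intended_class not in (PVH, DWMH, STRADDLING):
            raise ValidationError(
                f"intended_class must be PVH, DWMH or straddling, got {self.intended_class!r}"
            )


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry of one synthetic subject."""

    shape: tuple[int, int, int] = (160, 192, 24)
    spacing: tuple[float, float, float] = (1.0, 1.0, 6.0)
    brain_semiaxes_mm: tuple[float, float, float] = (55.0, 70.0, 52.0)
    ventricle_offset_mm: float = 14.0  # lateral shift of each ventricle body
    ventricle_semiaxes_mm: tuple[float, float, float] = (7.0, 28.0, 10.0)
    lesions: tuple[LesionSpec, ...] = ()
    pv_distance_mm: float = 10.0
    subject_id: str = "phantom"
    seed: int = 0


@dataclass(frozen=True)
class LesionTruth:
    """Ground truth for one generated lesion."""

    intended_class: str
    voxels: np.ndarray  # (n, 3) voxel coordinates
    n_voxels: int
    volume_ml: float
    n_in_pv: int  # voxels within pv_distance of the ventricles


@dataclass(frozen=True)
class PhantomTruth:
    """Per-lesion truth plus aggregate volumes of one phantom."""

    lesions: tuple[LesionTruth, ...]
    pvh_ml: float
    dwmh_ml: float
    brain_ml: float


def _ellipsoid(shape, spacing, center_vox, semiaxes_mm) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    q = sum(
        ((g - c) * sp / ax) ** 2
        for g, c, sp, ax in zip(grids, center_vox, spacing, semiaxes_mm)
    )
    return q <= 1.0


def _sphere(shape, spacing, center_vox, radius_mm) -> np.ndarray:
    return _ellipsoid(shape, spacing, center_vox, (radius_mm,) * 3)


def _place_center(
    dist: np.ndarray,
    brain: np.ndarray,
    brain_margin: np.ndarray,
    spacing,
    centroid_vox: np.ndarray,
    lesion: LesionSpec,
) -> tuple[int, int, int]:
    """Deterministically pick the lesion centre voxel.

    Among brain voxels whose ventricle distance is closest to the
    requested offset (within half the coarsest spacing), take the one
    farthest along the preferred direction from the ventricle centroid.
    Candidates whose brain margin cannot contain the lesion radius are
    dropped when better ones exist.
    """
    err = np.abs(dist - lesion.offset_mm)
    eligible = brain & (dist > 0)
    fitting = eligible & (brain_margin >= lesion.radius_mm)
    if fitting.any():
        eligible = fitting
    if not eligible.any():
        raise GenerationError("no brain voxels available for lesion placement")
    err = np.where(eligible, err, np.inf)
    tol = max(float(err.min()), 0.5 * max(spacing))
    cand = np.argwhere(err <= tol)
    disp = (cand - centroid_vox) * np.asarray(spacing)
    direction = np.asarray(lesion.direction, dtype=float)
    norm = np.linalg.norm(direction)
    if norm == 0:
        raise ValidationError("lesion direction must be a nonzero vector")
    score = disp @ (direction / norm)
    best = cand[int(np.argmax(score))]
    return tuple(int(v) for v in best)


def make_phantom(spec: PhantomSpec) -> tuple[MaskBundle, PhantomTruth]:
    """Rasterize a phantom and derive its ground truth.

    Raises :class:`GenerationError` when a lesion leaves the brain,
    overlaps (or touches) the ventricles or another lesion, or cannot
    realize its intended class relative to the PV distance — touching
    lesions would merge into one in-plane component and break the
    lesion-to-component mapping the truth relies on.
    """
    shape, spacing = spec.shape, spec.spacing
    center = np.array([(s - 1) / 2 for s in shape])
    brain = _ellipsoid(shape, spacing, center, spec.brain_semiaxes_mm)
    if not brain.any():
        raise GenerationError("brain ellipsoid does not intersect the grid")

    off_vox = spec.ventricle_offset_mm / spacing[0]
    vent = _ellipsoid(
        shape, spacing, center + np.array([off_vox, 0, 0]), spec.ventricle_semiaxes_mm
    ) | _ellipsoid(
        shape, spacing, center - np.array([off_vox, 0, 0]), spec.ventricle_semiaxes_mm
    )
    vent &= brain
    if not vent.any():
        raise GenerationError("ventricle ellipsoids do not intersect the brain")

    # anisotropic centre-to-centre distance to the nearest ventricle voxel
    dist = ndimage.distance_transform_edt(~vent, sampling=spacing)
    brain_margin = ndimage.distance_transform_edt(brain, sampling=spacing)
    centroid_vox = np.argwhere(vent).mean(axis=0)

    wmh = np.zeros(shape, dtype=bool)
    occupied = vent.copy()
    lesion_truths: list[LesionTruth] = []
    vv = float(np.prod(spacing)) / 1000.0
    for i, lesion in enumerate(spec.lesions):
        center_vox = _place_center(
            dist, brain, brain_margin, spacing, centroid_vox, lesion
        )
        les = _sphere(shape, spacing, np.array(center_vox), lesion.radius_mm)
        if not les.any():
            raise GenerationError(f"lesion {i}: radius too small to cover any voxel")
        if (les & ~brain).any():
            raise GenerationError(f"lesion {i}: extends outside the brain mask")
        grown = ndimage.binary_dilation(les, structure=np.ones((3, 3, 3), dtype=bool))
        if (grown & occupied).any():
            raise GenerationError(
                f"lesion {i}: overlaps or touches the ventricles or another lesion"
            )
        d = dist[les]
        n_in = int((d <= spec.pv_distance_mm).sum())
        actual = PVH if n_in == les.sum() else DWMH if n_in == 0 else STRADDLING
        if actual != lesion.intended_class:
            raise GenerationError(
                f"lesion {i}: intended {lesion.intended_class} but realized {actual} "
                f"(offset {lesion.offset_mm} mm, radius {lesion.radius_mm} mm)"
            )
        wmh |= les
        occupied |= les
        lesion_truths.append(
            LesionTruth(
                intended_class=lesion.intended_class,
                voxels=np.argwhere(les),
                n_voxels=int(les.sum()),
                volume_ml=float(les.sum()) * vv,
                n_in_pv=n_in,
            )
        )

    axial = int(np.argmax(spacing))
    bundle = MaskBundle(
        brain=LabelVolume(brain, spacing, axial),
        ventricles=LabelVolume(vent, spacing, axial),
        wmh=LabelVolume(wmh, spacing, axial),
        subject_id=spec.subject_id,
    )
    pvh_ml = sum(t.n_in_pv for t in lesion_truths) * vv
    dwmh_ml = sum(t.n_voxels - t.n_in_pv for t in lesion_truths) * vv
    truth = PhantomTruth(
        lesions=tuple(lesion_truths),
        pvh_ml=pvh_ml,
        dwmh_ml=dwmh_ml,
        brain_ml=float(brain.sum()) * vv,
    )
    return bundle, truth


# ---------------------------------------------------------------------------
# grade-labeled volume-ratio cohorts

#: per-grade lesion volume mean (SD) in mL from a clinical training cohort,
#: Brain Dock grades 0..4; Fazekas uses grades 0..3 of the same table.
REFERENCE_VOLUME_STATS_ML: dict[str, tuple[tuple[float, float], ...]] = {
    "PVH": ((0.451, 1.442), (1.535, 1.322), (8.456, 5.443), (13.503, 5.642), (18.632, 10.520)),
    "DWMH": ((0.451, 1.330), (0.790, 0.845), (4.816, 5.420), (20.353, 13.954), (31.411, 13.839)),
}

#: nominal adult total brain volume used to turn mL into volume ratios
NOMINAL_BRAIN_ML = 1400.0


@dataclass(frozen=True)
class CohortSpec:
    """Per-grade log-normal volume-ratio distributions for one scale.

    ``grade_stats[lesion_type][g]`` is the (mean, SD) of the ratio for
    grade g; supports must be ordered by mean.  ``sd = 0`` degenerates to
    a point mass at the mean.
    """

    scale: GradeScale
    grade_stats: dict[str, tuple[tuple[float, float], ...]]
    n_per_grade: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_grade < 1:
            raise ValidationError("n_per_grade must be >= 1")
        for lesion_type, stats in self.grade_stats.items():
            if len(stats) != self.scale.n_grades:
                raise ValidationError(
                    f"{lesion_type}: need {self.scale.n_grades} per-grade stats"
                )
            means = [m for m, _ in stats]
            if any(m <= 0 for m in means):
                raise ValidationError(f"{lesion_type}: grade means must be positive")
            if any(a >= b for a, b in zip(means, means[1:])):
                raise ValidationError(
                    f"{lesion_type}: grade means must be strictly increasing"
                )
            if any(sd < 0 for _, sd in stats):
                raise ValidationError(f"{lesion_type}: SDs must be non-negative")


def default_cohort_spec(
    scale: GradeScale = FAZEKAS,
    n_per_grade: int = 100,
    seed: int = 0,
    brain_ml: float = NOMINAL_BRAIN_ML,
) -> CohortSpec:
    """Cohort spec calibrated to the reference per-grade volume statistics."""
    stats = {
        lt: tuple(
            (m / brain_ml, sd / brain_ml)
            for m, sd in REFERENCE_VOLUME_STATS_ML[lt][: scale.n_grades]
        )
        for lt in ("PVH", "DWMH")
    }
    return CohortSpec(scale=scale, grade_stats=stats, n_per_grade=n_per_grade, seed=seed)


def lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of the log-normal with the given arithmetic mean and SD."""
    if mean <= 0:
        raise ValidationError("log-normal mean must be positive")
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return float(mu), float(np.sqrt(sigma2))


def sample_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a grade-labeled cohort of volume ratios.

    Returns a tidy table with columns subject, lesion_type, grade,
    volume_ratio; fully reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    for lesion_type in sorted(spec.grade_stats):
        stats = spec.grade_stats[lesion_type]
        for grade, (mean, sd) in enumerate(stats):
            if sd == 0:
                draws = np.full(spec.n_per_grade, mean)
            else:
                mu, sigma = lognormal_params(mean, sd)
                draws = rng.lognormal(mu, sigma, size=spec.n_per_grade)
            for j, ratio in enumerate(draws):
                rows.append(
                    {
                        "subject": f"{lesion_type.lower()}-g{grade}-{j:04d}",
                        "lesion_type": lesion_type,
                        "grade": grade,
                        "volume_ratio": float(ratio),
                    }
                )
    return pd.DataFrame(rows)
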