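"""Volume-ratio grading: threshold learning and grade prediction.

The grading feature is the lesion volume ratio — PVH or DWMH volume divided
by total brain volume, which removes inter-individual head-size variation.
Grades on the two clinical scales (Fazekas 0-3; Brain Dock 0-4, which
splits the top Fazekas grade in two) are predicted by comparing a subject's
ratio against a set of ordered boundary thresholds.

Three threshold-learning strategies are provided:

``density``
    fit one kernel density estimate per grade and place each boundary at
    the midpoint between the two adjacent grades' density peaks;
``youden_all``
    treat boundary g|g+1 as a binary problem with grades <= g negative and
    grades >= g+1 positive, and pick the cut maximizing Youden's J
    (sensitivity + specificity - 1);
``youden_neighbor``
    same, but with only the two adjacent grades g and g+1 in the sample.

A set of reference Fazekas thresholds learned with the Youden-neighbor
strategy on a multicenter clinical FLAIR cohort ships as the default, so
grades can be predicted without any training data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.neighbors import KernelDensity

from .volume_io import ValidationError

__all__ = [
    "GradeScale",
    "FAZEKAS",
    "BRAIN_DOCK",
    "VolumeSummary",
    "ThresholdSet",
    "DensityModel",
    "RocAnalysis",
    "DEFAULT_FAZEKAS_THRESHOLDS",
    "fit_thresholds_density",
    "fit_thresholds_youden",
    "predict_grade",
    "predict_grades",
    "braindock_to_fazekas",
]


class FittingError(ValueError):
    """Threshold learning cannot proceed (e.g. a grade has no subjects)."""


@dataclass(frozen=True)
class GradeScale:
    """An ordinal grading scale with contiguous integer grades from 0."""

    name: str
    n_grades: int

    @property
    def grades(self) -> tuple[int, ...]:
        return tuple(range(self.n_grades))

    @property
    def n_boundaries(self) -> int:
        return self.n_grades - 1

    def validate_grades(self, grades) -> np.ndarray:
        arr = np.asarray(grades)
        if arr.size and (
            not np.issubdtype(arr.dtype, np.integer)
            and not np.all(arr == arr.astype(int))
        ):
            raise ValidationError(f"grades must be integers on scale {self.name}")
        arr = arr.astype(int)
        if arr.size and (arr.min() < 0 or arr.max() >= self.n_grades):
            raise ValidationError(
                f"grades out of range for {self.name} (0..{self.n_grades - 1})"
            )
        return arr


FAZEKAS = GradeScale("fazekas", 4)
BRAIN_DOCK = GradeScale("braindock", 5)


def scale_by_name(name: str) -> GradeScale:
    try:
        return {"fazekas": FAZEKAS, "braindock": BRAIN_DOCK}[name.lower()]
    except KeyError:
        raise ValidationError(f"unknown grade scale {name!r}") from None


@dataclass(frozen=True)
class VolumeSummary:
    """Per-subject lesion and brain volumes with brain-normalized ratios."""

    pvh_ml: float
    dwmh_ml: float
    brain_ml: float
    pvh_ratio: float
    dwmh_ratio: float

    def __post_init__(self) -> None:
        for name in ("pvh_ml", "dwmh_ml", "brain_ml", "pvh_ratio", "dwmh_ratio"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")

    def ratio(self, lesion_type: str) -> float:
        return {"PVH": self.pvh_ratio, "DWMH": self.dwmh_ratio}[lesion_type]

    def to_dict(self) -> dict:
        return {
            "pvh_ml": self.pvh_ml,
            "dwmh_ml": self.dwmh_ml,
            "brain_ml": self.brain_ml,
            "pvh_ratio": self.pvh_ratio,
            "dwmh_ratio": self.dwmh_ratio,
        }


@dataclass(frozen=True)
class ThresholdSet:
    """Ordered grade-boundary thresholds on the volume-ratio axis.

    ``thresholds[g]`` is the boundary between grades g and g+1, acting as
    an inclusive lower bound of the upper grade.
    """

    scale: GradeScale
    lesion_type: str
    method: str
    thresholds: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.lesion_type not in ("PVH", "DWMH"):
            raise ValidationError("lesion_type must be 'PVH' or 'DWMH'")
        t = tuple(float(x) for x in self.thresholds)
        if len(t) != self.scale.n_boundaries:
            raise ValidationError(
                f"{self.scale.name} needs {self.scale.n_boundaries} thresholds, got {len(t)}"
            )
        if any(a > b for a, b in zip(t, t[1:])):
            raise ValidationError("thresholds must be sorted non-decreasing")
        object.__setattr__(self, "thresholds", t)

    def to_dict(self) -> dict:
        return {
            "scale": self.scale.name,
            "lesion_type": self.lesion_type,
            "method": self.method,
            "thresholds": list(self.thresholds),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ThresholdSet":
        return cls(
            scale=scale_by_name(d["scale"]),
            lesion_type=d["lesion_type"],
            method=d.get("method", "unspecified"),
            thresholds=tuple(d["thresholds"]),
        )


#: Reference Fazekas thresholds (Youden-neighbor fit on a clinical cohort);
#: used when no training data is supplied.
DEFAULT_FAZEKAS_THRESHOLDS: dict[str, ThresholdSet] = {
    "PVH": ThresholdSet(FAZEKAS, "PVH", "youden_neighbor", (0.00017, 0.00402, 0.00977)),
    "DWMH": ThresholdSet(FAZEKAS, "DWMH", "youden_neighbor", (0.00013, 0.00179, 0.00743)),
}


@dataclass(frozen=True)
class DensityModel:
    """Per-grade KDE of the volume ratio, with peak locations."""

    grid: np.ndarray
    densities: dict[int, np.ndarray]
    peaks: dict[int, float]
    bandwidths: dict[int, float]


@dataclass(frozen=True)
class RocAnalysis:
    """Exhaustive Youden scan of one grade boundary."""

    boundary: int  # boundary between grades boundary and boundary+1
    candidates: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    youden_j: np.ndarray
    chosen: float
    chosen_j: float


def _silverman_bandwidth(x: np.ndarray, floor: float = 1e-6) -> float:
    """Silverman's rule of thumb with a floor for near-constant samples."""
    n = len(x)
    sd = float(np.std(x, ddof=1)) if n > 1 else 0.0
    q75, q25 = np.percentile(x, [75, 25])
    iqr = float(q75 - q25)
    spread_candidates = [s for s in (sd, iqr / 1.34) if s > 0]
    spread = min(spread_candidates) if spread_candidates else 0.0
    return max(0.9 * spread * n ** (-0.2), floor)


def _as_ratio_grade_arrays(ratios, grades, scale: GradeScale):
    r = np.asarray(ratios, dtype=float)
    g = scale.validate_grades(grades)
    if r.shape != g.shape or r.ndim != 1:
        raise ValidationError("ratios and grades must be 1D arrays of equal length")
    if (r < 0).any():
        raise ValidationError("volume ratios must be non-negative")
    return r, g


def _sorted_or_warn(thresholds: list[float], method: str) -> tuple[float, ...]:
    t = list(thresholds)
    if any(a > b for a, b in zip(t, t[1:])):
        warnings.warn(
            f"{method}: fitted thresholds are non-monotone and were sorted",
            stacklevel=3,
        )
        t = sorted(t)
    return tuple(t)


def fit_thresholds_density(
    ratios,
    grades,
    scale: GradeScale,
    lesion_type: str = "PVH",
    grid_points: int = 2048,
) -> tuple[ThresholdSet, DensityModel]:
    """Fit per-grade Gaussian KDEs and set boundaries at peak midpoints.

    Bandwidth per grade follows Silverman's rule (floored at 1e-6 for
    near-constant samples); each peak is the argmax of the density on a
    uniform grid over [0, 1.05 * max ratio].
    """
    r, g = _as_ratio_grade_arrays(ratios, grades, scale)
    for grade in scale.grades:
        n = int((g == grade).sum())
        if n < 2:
            raise FittingError(
                f"grade {grade} has {n} subject(s); density fitting needs >= 2 per grade"
            )
    hi = 1.05 * float(r.max()) if r.max() > 0 else 1.0
    grid = np.linspace(0.0, hi, grid_points)
    densities: dict[int, np.ndarray] = {}
    peaks: dict[int, float] = {}
    bandwidths: dict[int, float] = {}
    for grade in scale.grades:
        x = r[g == grade]
        bw = _silverman_bandwidth(x)
        kde = KernelDensity(kernel="gaussian", bandwidth=bw).fit(x[:, None])
        dens = np.exp(kde.score_samples(grid[:, None]))
        densities[grade] = dens
        peaks[grade] = float(grid[int(np.argmax(dens))])
        bandwidths[grade] = bw
    raw = [
        0.5 * (peaks[grade] + peaks[grade + 1]) for grade in range(scale.n_boundaries)
    ]
    thresholds = _sorted_or_warn(raw, "density")
    ts = ThresholdSet(scale, lesion_type, "density", thresholds)
    return ts, DensityModel(grid=grid, densities=densities, peaks=peaks, bandwidths=bandwidths)


def _youden_scan(neg: np.ndarray, pos: np.ndarray, boundary: int) -> RocAnalysis:
    """Exhaustive Youden-J maximization over midpoint candidates.

    Candidates are the midpoints between consecutive distinct sorted
    pooled ratios plus one sentinel below the minimum; a subject is called
    positive when its ratio >= candidate.  Ties in J are broken by higher
    sensitivity, then by the smaller threshold.
    """
    pooled = np.unique(np.concatenate([neg, pos]))
    if len(pooled) > 1:
        mids = 0.5 * (pooled[:-1] + pooled[1:])
        sentinel = pooled[0] - 0.5 * (pooled[-1] - pooled[0])
    else:
        mids = np.empty(0)
        sentinel = pooled[0] - 1.0
    candidates = np.concatenate([[sentinel], mids])
    sens = (pos[None, :] >= candidates[:, None]).mean(axis=1)
    spec = (neg[None, :] < candidates[:, None]).mean(axis=1)
    j = sens + spec - 1.0
    # lexicographic argmax: J desc, sensitivity desc, threshold asc
    order = np.lexsort((candidates, -sens, -j))
    best = order[0]
    return RocAnalysis(
        boundary=boundary,
        candidates=candidates,
        sensitivity=sens,
        specificity=spec,
        youden_j=j,
        chosen=float(candidates[best]),
        chosen_j=float(j[best]),
    )


def fit_thresholds_youden(
    ratios,
    grades,
    scale: GradeScale,
    strategy: str = "neighbor",
    lesion_type: str = "PVH",
) -> tuple[ThresholdSet, list[RocAnalysis]]:
    """Learn boundary thresholds by Youden-index maximization.

    ``strategy="all"`` pools every grade on each side of a boundary
    (e.g. 0/1 vs 2/3); ``strategy="neighbor"`` uses only the two adjacent
    grades (0 vs 1, 1 vs 2, ...).
    """
    if strategy not in ("all", "neighbor"):
        raise ValidationError("strategy must be 'all' or 'neighbor'")
    r, g = _as_ratio_grade_arrays(ratios, grades, scale)
    analyses: list[RocAnalysis] = []
    raw: list[float] = []
    for boundary in range(scale.n_boundaries):
        if strategy == "all":
            neg, pos = r[g <= boundary], r[g >= boundary + 1]
        else:
            neg, pos = r[g == boundary], r[g == boundary + 1]
        if len(neg) == 0 or len(pos) == 0:
            raise FittingError(
                f"boundary {boundary}|{boundary + 1}: empty class under "
                f"Youden-{strategy} (neg={len(neg)}, pos={len(pos)})"
            )
        analysis = _youden_scan(neg, pos, boundary)
        analyses.append(analysis)
        raw.append(analysis.chosen)
    thresholds = _sorted_or_warn(raw, f"youden_{strategy}")
    ts = ThresholdSet(scale, lesion_type, f"youden_{strategy}", thresholds)
    return ts, analyses


def predict_grade(ratio: float, thresholds: ThresholdSet) -> int:
    """Grade = number of boundary thresholds at or below the ratio.

    Thresholds act as inclusive lower bounds of the upper grade, so a
    ratio exactly at a boundary receives the higher grade.
    """
    if ratio < 0:
        raise ValidationError(f"volume ratio must be non-negative, got {ratio}")
    return int(sum(ratio >= t for t in thresholds.thresholds))


def predict_grades(ratios, thresholds: ThresholdSet) -> np.ndarray:
    """Vectorized :func:`predict_grade`."""
    r = np.asarray(ratios, dtype=float)
    if (r < 0).any():
        raise ValidationError("volume ratios must be non-negative")
    t = np.asarray(thresholds.thresholds)
    return (r[..., None] >= t).sum(axis=-1).astype(int)


def braindock_to_fazekas(grade: int) -> int:
    """Merge Brain Dock grades 3 and 4 into Fazekas grade 3."""
    g = int(grade)
    if not 0 <= g <= 4:
        raise ValidationError(f"Brain Dock grade must be 0..4, got {grade}")
    return min(g, 3)
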