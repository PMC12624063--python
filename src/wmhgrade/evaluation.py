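"""Grading-agreement evaluation: boundary metrics, MAE and kappas.

Ordinal grade predictions are scored three ways, mirroring how automated
WMH grading is judged clinically:

* binary accuracy/F1 at each grade boundary (e.g. Fazekas 0 vs 1/2/3,
  0/1 vs 2/3, 0/1/2 vs 3) — "is the patient above the diagnostic cut?";
* multi-class accuracy, macro F1 and mean absolute error on the full scale;
* chance-corrected agreement: Fleiss' kappa across a panel of raters and
  Cohen's kappa for each rater pair (typically automated vs each human).

Accuracy/F1 and Cohen's kappa delegate to scikit-learn; Fleiss' kappa to
statsmodels.  Conventions: binary F1 takes the upper-grade group as the
positive class and is 0 when precision + recall is 0; macro F1 averages
over the grades present in ground truth or prediction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import accuracy_score, cohen_kappa_score, f1_score
from statsmodels.stats.inter_rater import aggregate_raters
from statsmodels.stats.inter_rater import fleiss_kappa as _sm_fleiss_kappa

from .grading import GradeScale
from .volume_io import ValidationError

__all__ = [
    "RatingMatrix",
    "boundary_split",
    "binary_metrics",
    "multiclass_metrics",
    "cohen_kappa",
    "fleiss_kappa",
    "grading_report",
    "agreement_report",
]


@dataclass(frozen=True)
class RatingMatrix:
    """Complete subjects x raters grid of ordinal grades on one scale."""

    grades: np.ndarray  # (n_subjects, n_raters) integer grades
    raters: tuple[str, ...]
    scale: GradeScale

    def __post_init__(self) -> None:
        g = np.asarray(self.grades)
        if g.ndim != 2:
            raise ValidationError("rating matrix must be 2D (subjects x raters)")
        if g.shape[1] != len(self.raters):
            raise ValidationError("number of rater names must match matrix columns")
        if np.isnan(np.asarray(g, dtype=float)).any():
            raise ValidationError("rating matrix contains missing entries")
        object.__setattr__(self, "grades", self.scale.validate_grades(g))

    @classmethod
    def from_long(cls, table: pd.DataFrame, scale: GradeScale) -> "RatingMatrix":
        """Build from a long table with columns subject, rater, grade."""
        wide = table.pivot(index="subject", columns="rater", values="grade")
        if wide.isna().any().any():
            raise ValidationError("rating table has missing subject/rater entries")
        return cls(wide.to_numpy(), tuple(str(c) for c in wide.columns), scale)


def _aligned(a, b) -> tuple[np.ndarray, np.ndarray]:
    x, y = np.asarray(a), np.asarray(b)
    if x.shape != y.shape or x.ndim != 1 or len(x) == 0:
        raise ValidationError("inputs must be equal-length non-empty 1D sequences")
    return x, y


def boundary_split(grades, boundary: int, scale: GradeScale) -> np.ndarray:
    """Binary labels at boundary g|g+1: positive iff grade >= g+1."""
    g = scale.validate_grades(grades)
    if not 0 <= boundary < scale.n_boundaries:
        raise ValidationError(
            f"boundary must be 0..{scale.n_boundaries - 1} on {scale.name}"
        )
    return g >= boundary + 1


def binary_metrics(gt, pred) -> tuple[float, float]:
    """(accuracy, F1 of the positive class) for binary labels."""
    y, p = _aligned(gt, pred)
    acc = float(accuracy_score(y, p))
    f1 = float(f1_score(y, p, labels=[True], average=None, zero_division=0.0)[0])
    return acc, f1


def multiclass_metrics(gt, pred, scale: GradeScale) -> tuple[float, float, float]:
    """(accuracy, macro F1, MAE) on integer grades.

    Macro F1 averages over the grades present in gt or pred only, so a
    grade absent from both sides cannot drag the mean down.
    """
    y, p = _aligned(scale.validate_grades(gt), scale.validate_grades(pred))
    labels = sorted(set(y.tolist()) | set(p.tolist()))
    acc = float(accuracy_score(y, p))
    f1 = float(f1_score(y, p, labels=labels, average="macro", zero_division=0.0))
    mae = float(np.mean(np.abs(y - p)))
    return acc, f1, mae


def cohen_kappa(ratings_a, ratings_b) -> float:
    """Cohen's kappa between two raters (unweighted).

    Defined as 1.0 in the degenerate perfect-agreement case where both
    raters use a single identical category (chance agreement is then 1 and
    the usual ratio is 0/0).
    """
    a, b = _aligned(ratings_a, ratings_b)
    if np.array_equal(a, b) :
        return 1.0
    return float(cohen_kappa_score(a, b))


def fleiss_kappa(matrix: RatingMatrix | np.ndarray) -> float:
    """Fleiss' kappa for a complete subjects x raters grid.

    Returns NaN (with a warning) when every rater uses one single
    category, where expected agreement is 1 and kappa is undefined.
    """
    grades = matrix.grades if isinstance(matrix, RatingMatrix) else np.asarray(matrix)
    if grades.ndim != 2 or grades.shape[0] < 2 or grades.shape[1] < 2:
        raise ValidationError("Fleiss' kappa needs >= 2 subjects and >= 2 raters")
    if len(np.unique(grades)) == 1:
        warnings.warn(
            "all raters used a single category; Fleiss' kappa is undefined",
            stacklevel=2,
        )
        return float("nan")
    counts, _ = aggregate_raters(grades)
    return float(_sm_fleiss_kappa(counts))


def grading_report(gt, predictions: dict[str, np.ndarray], scale: GradeScale) -> pd.DataFrame:
    """Boundary + multi-class metrics for several prediction sources.

    One row per source (e.g. ``{"AI (youden_neighbor)": ..., "Human expert":
    ...}``), with per-boundary accuracy and F1 columns, multi-class
    accuracy, macro F1 and MAE.
    """
    y = scale.validate_grades(np.asarray(gt))
    rows = {}
    for name, pred in predictions.items():
        p = scale.validate_grades(np.asarray(pred))
        row: dict[str, float] = {}
        for b in range(scale.n_boundaries):
            lo = "".join(str(g) for g in range(b + 1))
            hi = "".join(str(g) for g in range(b + 1, scale.n_grades))
            acc, f1 = binary_metrics(
                boundary_split(y, b, scale), boundary_split(p, b, scale)
            )
            row[f"accuracy_{lo}vs{hi}"] = acc
            row[f"f1_{lo}vs{hi}"] = f1
        acc, f1, mae = multiclass_metrics(y, p, scale)
        row["accuracy_multiclass"] = acc
        row["f1_multiclass"] = f1
        row["mae"] = mae
        rows[name] = row
    report = pd.DataFrame.from_dict(rows, orient="index")
    report.index.name = "source"
    return report


def agreement_report(
    humans: RatingMatrix, ai_grades=None
) -> dict:
    """Inter-rater agreement: Fleiss' kappa over the human panel and, if
    automated grades are given, Cohen's kappa of the automation against
    each human plus their mean."""
    out: dict = {"fleiss_kappa_humans": fleiss_kappa(humans)}
    if ai_grades is not None:
        ai = np.asarray(ai_grades)
        pair = {
            rater: cohen_kappa(ai, humans.grades[:, i])
            for i, rater in enumerate(humans.raters)
        }
        out["cohen_kappa_ai_vs_rater"] = pair
        out["mean_cohen_kappa_ai"] = float(np.mean(list(pair.values())))
    return out
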