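"""Independent naive reference implementations used only by the tests.

Everything here is written the slow, obvious way (explicit loops, direct
formulas, pairwise distances) so that the fast library-backed code paths
in the package can be checked against a genuinely independent route.
"""

from __future__ import annotations

import numpy as np


def brute_force_pv_mask(
    ventricles: np.ndarray, spacing, radius_mm: float
) -> np.ndarray:
    """PV shell by exhaustive pairwise anisotropic distances.

    For every voxel, the minimum centre-to-centre Euclidean distance to
    any ventricle voxel is computed directly; the shell is distance <=
    radius minus the ventricles themselves.
    """
    sp = np.asarray(spacing, dtype=float)
    vent_coords = np.argwhere(ventricles) * sp
    all_coords = (
        np.stack(np.meshgrid(*[np.arange(s) for s in ventricles.shape], indexing="ij"), -1)
        .reshape(-1, 3)
        * sp
    )
    r2 = radius_mm**2
    within = np.zeros(len(all_coords), dtype=bool)
    chunk = 4096
    for start in range(0, len(all_coords), chunk):
        block = all_coords[start : start + chunk]
        d2 = ((block[:, None, :] - vent_coords[None, :, :]) ** 2).sum(-1)
        within[start : start + chunk] = d2.min(axis=1) <= r2
    return within.reshape(ventricles.shape) & ~ventricles


def naive_binary_metrics(gt, pred) -> tuple[float, float]:
    """(accuracy, F1 of the positive class) by direct confusion counts."""
    gt, pred = np.asarray(gt, bool), np.asarray(pred, bool)
    tp = int((gt & pred).sum())
    fp = int((~gt & pred).sum())
    fn = int((gt & ~pred).sum())
    tn = int((~gt & ~pred).sum())
    acc = (tp + tn) / len(gt)
    denom = 2 * tp + fp + fn
    f1 = 2 * tp / denom if denom else 0.0
    return acc, f1


def naive_multiclass_metrics(gt, pred) -> tuple[float, float, float]:
    """(accuracy, macro F1 over present labels, MAE) by loops."""
    gt, pred = np.asarray(gt, int), np.asarray(pred, int)
    acc = float(np.mean(gt == pred))
    labels = sorted(set(gt.tolist()) | set(pred.tolist()))
    f1s = []
    for lab in labels:
        tp = int(((gt == lab) & (pred == lab)).sum())
        fp = int(((gt != lab) & (pred == lab)).sum())
        fn = int(((gt == lab) & (pred != lab)).sum())
        denom = 2 * tp + fp + fn
        f1s.append(2 * tp / denom if denom else 0.0)
    mae = float(np.mean(np.abs(gt - pred)))
    return acc, float(np.mean(f1s)), mae


def naive_cohen_kappa(a, b) -> float:
    """Cohen's kappa from the textbook formula on marginal frequencies."""
    a, b = np.asarray(a), np.asarray(b)
    n = len(a)
    cats = sorted(set(a.tolist()) | set(b.tolist()))
    p_o = float(np.mean(a == b))
    p_e = sum(
        (np.sum(a == c) / n) * (np.sum(b == c) / n) for c in cats
    )
    if p_e == 1.0:
        return 1.0 if p_o == 1.0 else float("nan")
    return (p_o - p_e) / (1.0 - p_e)


def naive_fleiss_kappa(grades: np.ndarray) -> float:
    """Fleiss' kappa from per-subject category counts, by loops."""
    grades = np.asarray(grades, int)
    n_sub, n_rat = grades.shape
    cats = sorted(set(grades.ravel().tolist()))
    counts = np.zeros((n_sub, len(cats)))
    for i in range(n_sub):
        for j, c in enumerate(cats):
            counts[i, j] = np.sum(grades[i] == c)
    p_i = ((counts**2).sum(axis=1) - n_rat) / (n_rat * (n_rat - 1))
    p_bar = p_i.mean()
    p_j = counts.sum(axis=0) / (n_sub * n_rat)
    p_e = float((p_j**2).sum())
    if p_e == 1.0:
        return float("nan")
    return float((p_bar - p_e) / (1.0 - p_e))


def naive_best_youden(neg, pos, candidates) -> float:
    """Maximum Youden J over the given cut candidates, by loops."""
    neg, pos = np.asarray(neg, float), np.asarray(pos, float)
    best = -np.inf
    for t in candidates:
        sens = float(np.mean(pos >= t))
        spec = float(np.mean(neg < t))
        best = max(best, sens + spec - 1.0)
    return best


def gaussian_kde_peak(x, bandwidth: float, grid: np.ndarray) -> float:
    """Argmax of a Gaussian-kernel density written out by hand."""
    x = np.asarray(x, float)
    dens = np.exp(-0.5 * ((grid[:, None] - x[None, :]) / bandwidth) ** 2).sum(axis=1)
    return float(grid[int(np.argmax(dens))])


def bayes_predict_lognormal(ratios, grade_params) -> np.ndarray:
    """Plug-in Bayes grade under known log-normal class densities.

    ``grade_params`` is a list of (mu, sigma) per grade; equal priors.
    Degenerate sigma=0 grades are handled as point masses.
    """
    r = np.asarray(ratios, float)
    logpdfs = []
    for mu, sigma in grade_params:
        if sigma == 0:
            lp = np.where(np.isclose(np.log(r), mu), np.inf, -np.inf)
        else:
            lr = np.log(r)
            lp = -lr - np.log(sigma) - 0.5 * ((lr - mu) / sigma) ** 2
        logpdfs.append(lp)
    return np.argmax(np.stack(logpdfs), axis=0)
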