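"""Quantify grading agreement between an automated grader and a panel.

Simulates a ground-truth grade per subject, three noisy human raters and
an automated prediction, then reports boundary/multi-class metrics plus
Fleiss' kappa (panel consistency) and Cohen's kappa (automation vs each
human).  Kappa is chance-corrected: 0 means chance-level agreement, 1
perfect.
"""

import numpy as np

from wmhgrade import FAZEKAS
from wmhgrade.evaluation import RatingMatrix, agreement_report, grading_report

rng = np.random.default_rng(42)
n = 120
truth = rng.integers(0, 4, n)


def noisy(grades, flip=0.2):
    jitter = rng.choice([-1, 0, 1], size=len(grades), p=[flip / 2, 1 - flip, flip / 2])
    return np.clip(grades + jitter, 0, 3)


humans = np.stack([noisy(truth) for _ in range(3)], axis=1)
ai = noisy(truth, flip=0.15)

report = grading_report(truth, {"AI": ai, "rater 1": humans[:, 0]}, FAZEKAS)
print(report.round(3).to_string())

panel = RatingMatrix(humans, ("rater 1", "rater 2", "rater 3"), FAZEKAS)
agreement = agreement_report(panel, ai)
print(f"\nFleiss' kappa, human panel: {agreement['fleiss_kappa_humans']:.3f}")
for rater, kappa in agreement["cohen_kappa_ai_vs_rater"].items():
    print(f"Cohen's kappa, AI vs {rater}: {kappa:.3f}")
print(f"mean Cohen's kappa, AI vs humans: {agreement['mean_cohen_kappa_ai']:.3f}")
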