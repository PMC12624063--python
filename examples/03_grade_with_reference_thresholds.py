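"""Grade volume ratios with the bundled reference Fazekas thresholds.

No training data needed: the package ships Youden-neighbor thresholds
learned on a clinical cohort.  A ratio is the lesion volume divided by
total brain volume, so 0.005 means the lesion occupies 0.5% of the brain.
"""

from wmhgrade import DEFAULT_FAZEKAS_THRESHOLDS, braindock_to_fazekas, predict_grade

pvh = DEFAULT_FAZEKAS_THRESHOLDS["PVH"]
print(f"PVH thresholds (grade 0|1, 1|2, 2|3): {pvh.thresholds}")
for ratio in (0.0001, 0.002, 0.005, 0.02):
    print(f"  PVH ratio {ratio:.4f} -> Fazekas grade {predict_grade(ratio, pvh)}")

dwmh = DEFAULT_FAZEKAS_THRESHOLDS["DWMH"]
print(f"DWMH thresholds: {dwmh.thresholds}")
print(f"  DWMH ratio 0.0030 -> Fazekas grade {predict_grade(0.003, dwmh)}")

print(f"Brain Dock grade 4 merges to Fazekas {braindock_to_fazekas(4)}")
print(
    "\nGrades count how many boundary thresholds the ratio reaches; ties "
    "at a boundary go to the higher grade."
)
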