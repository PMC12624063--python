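"""Separate a synthetic WMH mask into periventricular and deep parts.

Builds a phantom brain with one lesion hugging the ventricles and one deep
lesion, runs the 10 mm / 60%-rule partition, and prints the resulting
volumes.  With known ground truth, the recovered PVH/DWMH volumes should
match the phantom exactly.
"""

from wmhgrade import separate, summarize_volumes
from wmhgrade.phantom import LesionSpec, PhantomSpec, make_phantom

spec = PhantomSpec(
    lesions=(
        LesionSpec(offset_mm=4.0, radius_mm=3.0, intended_class="PVH"),
        LesionSpec(offset_mm=25.0, radius_mm=6.0, intended_class="DWMH", direction=(0, 1, 0)),
    )
)
bundle, truth = make_phantom(spec)
result = separate(bundle)
summary = summarize_volumes(result, bundle)

print(f"true PVH volume      {truth.pvh_ml:.3f} mL")
print(f"recovered PVH volume {summary.pvh_ml:.3f} mL  (ratio {summary.pvh_ratio:.6f})")
print(f"true DWMH volume      {truth.dwmh_ml:.3f} mL")
print(f"recovered DWMH volume {summary.dwmh_ml:.3f} mL  (ratio {summary.dwmh_ratio:.6f})")
print(f"brain volume          {summary.brain_ml:.1f} mL")
print(
    "\nEach lesion sits entirely on one side of the 10 mm periventricular "
    "shell, so the partition recovers the phantom's truth exactly; the "
    "ratios are the volume fractions grading operates on."
)
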