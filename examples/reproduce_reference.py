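"""Recompute the published validation results from the embedded matrix.

The original validation cohort (206 screen-positive adult eating-disorder
patients) published a 4x4 physician-vs-algorithm confusion matrix plus
per-category sensitivity, specificity, 95% CIs, Youden indices and a
Cohen kappa.  This script recomputes all of them from the matrix alone.
"""

from edscreen import reference_confusion, reproduce_reference

print("Reference confusion matrix (rows physician, columns algorithm):")
print(reference_confusion().to_frame())
print()

check = reproduce_reference()
print(check.report_text)
print()
if check.ok:
    print("Every published value is reproduced within one unit in its last")
    print("printed digit (the published table mixes rounding conventions).")
else:
    print("Mismatches:", *check.mismatches, sep="\n  ")
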