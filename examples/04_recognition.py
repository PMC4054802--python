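"""Six-class facial-color recognition with leave-one-out evaluation.

For every held-out subject the four chromaticity bases are rebuilt from
the remaining subjects, 24-dimensional complexion histograms (4 aggregate
bins + 4 x 5 luminance sub-bins on L* 25-95, interval 14) are re-extracted,
and a one-vs-one RBF-SVM is grid-searched and refit.  White and black share
the normal chromaticity, so only their luminance sub-bins separate them.
"""

import numpy as np

import complexion as cx

fixtures = cx.generate_cohort({l: 5 for l in cx.CLASS_LABELS}, seed=2)
pixels, labels = [], []
for f in fixtures:
    lab, _ = cx.skin_pipeline(f.image, f.mouth_box)
    pixels.append(lab)
    labels.append(f.label)

report = cx.loocv_evaluate(
    pixels,
    labels,
    C_grid=[2.0**e for e in range(-8, 16, 4)],
    gamma_grid=[2.0**e for e in range(-8, 9, 4)],
    inner_folds=3,
    seed=0,
)

print(f"LOOCV accuracy: {report.accuracy:.3f}  "
      f"(micro-F {report.metrics['micro_f']:.3f}, macro-F {report.metrics['macro_f']:.3f})")
print("confusion matrix (rows = actual, cols = predicted):")
print("        " + " ".join(f"{l[:5]:>6s}" for l in report.labels))
for label, row in zip(report.labels, report.confusion_matrix):
    print(f"{label:7s} " + " ".join(f"{v:6d}" for v in row))
# A diagonal matrix means every subject was recognized; off-diagonal counts
# name the confusion (e.g. mild red cases drifting into the normal column).
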