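"""Quantitative analysis: color-degree and gloss-degree ranking.

Both degrees are unsupervised min-max rankings on [0, 1]:

* *color degree* — within each predicted chromatic class, rank subjects by
  their own-base proportion in the 4-bin chromaticity histogram.  White and
  black have no chromaticity base of their own, so no color degree is
  defined for them.
* *gloss degree* — rank the whole cohort by a luminance-weighted histogram
  score; default weights are the bin-center L* values divided by 100, the
  minimal choice satisfying "higher luminance, larger weight".

A constant group maps to the midpoint 0.5 by convention.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .features import ComplexionHistogram, LuminanceBinning, luminance_only_histogram
from .synthetic import BASE_CLASS_LABELS

__all__ = ["color_degree", "gloss_score", "gloss_degree", "ranking_coordinates"]


def _min_max(values: np.ndarray) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    lo, hi = values.min(), values.max()
    if hi - lo < 1e-12:
        return np.full(values.shape, 0.5)
    return (values - lo) / (hi - lo)


def color_degree(cohort) -> np.ndarray:
    """Per-subject color degree from (4-bin histogram, predicted class) pairs.

    Subjects are grouped by predicted class; within each group the subject's
    own-base proportion is min-max normalized.  Raises if a white/black
    subject is passed — those classes carry no color degree.
    """
    hists, classes = zip(*cohort)
    classes = list(classes)
    for c in classes:
        if c not in BASE_CLASS_LABELS:
            raise ValueError(
                f"color degree is undefined for class {c!r}; only "
                f"{BASE_CLASS_LABELS} carry a chromaticity base"
            )
    base_idx = {label: i for i, label in enumerate(BASE_CLASS_LABELS)}
    own = np.array([np.asarray(h, dtype=float)[base_idx[c]] for h, c in zip(hists, classes)])
    degrees = np.empty(len(classes))
    for label in set(classes):
        sel = np.asarray([c == label for c in classes])
        degrees[sel] = _min_max(own[sel])
    return degrees


def gloss_score(
    luminance_histogram,
    binning: LuminanceBinning,
    weights=None,
) -> float:
    """Weighted sum over the K-bin luminance histogram.

    Default weight for bin j is its center L* / 100; custom weights must be
    non-decreasing in bin index (higher luminance never weighs less).
    """
    h = np.asarray(luminance_histogram, dtype=float)
    if h.shape != (binning.n_bins,):
        raise ValueError(f"expected {binning.n_bins} bins, got shape {h.shape}")
    if weights is None:
        w = binning.centers / 100.0
    else:
        w = np.asarray(weights, dtype=float)
        if (np.diff(w) < -1e-12).any():
            raise ValueError("gloss weights must be non-decreasing in bin index")
    return float(w @ h)


def gloss_degree(cohort_scores) -> np.ndarray:
    """Min-max normalization of gloss scores over the whole cohort."""
    scores = np.atleast_1d(np.asarray(cohort_scores, dtype=float))
    return _min_max(scores)


def ranking_coordinates(
    subject_ids,
    predicted_classes,
    fused_histograms: list[ComplexionHistogram],
    gloss_weights=None,
) -> pd.DataFrame:
    """Two-dimensional (color degree, gloss degree) coordinates per subject.

    Region blocks of each fused histogram are summed into a single
    whole-face histogram before degree computation.  White/black rows carry
    an empty (NaN) color degree; gloss covers every class.
    """
    if not (len(subject_ids) == len(predicted_classes) == len(fused_histograms)):
        raise ValueError("ids, classes and histograms must align")
    if len(fused_histograms) == 0:
        raise ValueError("missing features: empty cohort")

    chroma, lum = [], []
    for h in fused_histograms:
        agg = np.zeros(4)
        for region in range(h.n_regions):
            agg += h.aggregate_bins(region)
        chroma.append(agg)
        lum.append(luminance_only_histogram(h))
    binning = fused_histograms[0].binning

    gloss = gloss_degree(
        [gloss_score(l, binning, gloss_weights) for l in lum]
    )

    chromatic = [i for i, c in enumerate(predicted_classes) if c in BASE_CLASS_LABELS]
    color = np.full(len(subject_ids), np.nan)
    if chromatic:
        color[chromatic] = color_degree(
            [(chroma[i], predicted_classes[i]) for i in chromatic]
        )

    return pd.DataFrame(
        {
            "id": list(subject_ids),
            "class": list(predicted_classes),
            "color_degree": color,
            "gloss_degree": gloss,
        }
    )
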