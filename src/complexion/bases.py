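"""Chromaticity-base construction by two-level fuzzy clustering.

A chromaticity base is one (a, b) point standing for a facial color class's
characteristic chromaticity — a codebook word in the bag-of-colors sense.
Bases exist for four classes (normal, cyan, red, yellow); white and black
overlap them in chromaticity and are separated later by luminance.

The construction runs clustering at two levels:

* *pixel level* — per image, fuzzy c-means with c=2 on skin-pixel (a, b)
  yields a dominant and a subdominant chromaticity (ordered by member
  count).  A patient's morbid color may well be the *minor* cluster (mild
  disease on top of the subject's own basic skin tone), which is why the
  subdominant is kept.
* *chromaticity level* — per class, both centers of every image are pooled
  and clustered again with c=2; the cluster with the greater number of
  members becomes the base.  Subjects' basic tones scatter while the class
  color concentrates, so the concentrated cluster collects the votes even
  when it was the minor pixel cluster in every single image.

``single_level_baseline`` is the comparison method: dominant centers only,
averaged — it drifts toward basic skin whenever the morbid color is minor.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .fcm import fcm, largest_cluster
from .synthetic import BASE_CLASS_LABELS

__all__ = [
    "ChromaticityBase",
    "BaseSet",
    "image_dominant_pair",
    "build_base",
    "build_all_bases",
    "single_level_baseline",
    "classify_by_peak",
]


@dataclass
class ChromaticityBase:
    label: str
    a: float
    b: float
    provenance: dict = field(default_factory=dict)

    @property
    def ab(self) -> np.ndarray:
        return np.array([self.a, self.b])


@dataclass
class BaseSet:
    """Exactly four bases in canonical order (normal, cyan, red, yellow)."""

    bases: list[ChromaticityBase]

    def __post_init__(self):
        labels = tuple(b.label for b in self.bases)
        if labels != tuple(BASE_CLASS_LABELS):
            raise ValueError(
                f"bases must appear in canonical order {BASE_CLASS_LABELS}, got {labels}"
            )

    def __iter__(self):
        return iter(self.bases)

    def __len__(self):
        return len(self.bases)

    @property
    def centers(self) -> np.ndarray:
        """(4, 2) array of (a, b) centers in canonical order."""
        return np.array([[b.a, b.b] for b in self.bases])

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(b.label for b in self.bases)

    def to_json(self, path=None) -> str:
        payload = [
            {"label": b.label, "a": b.a, "b": b.b, "provenance": b.provenance}
            for b in self.bases
        ]
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "BaseSet":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        payload = json.loads(text)
        return cls(
            [
                ChromaticityBase(d["label"], d["a"], d["b"], d.get("provenance", {}))
                for d in payload
            ]
        )

    def to_csv(self, path) -> None:
        lines = ["label,a,b"] + [f"{b.label},{b.a:.6f},{b.b:.6f}" for b in self.bases]
        Path(path).write_text("\n".join(lines) + "\n")


def image_dominant_pair(lab_pixels, seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Dominant and subdominant (a, b) of one image's skin pixels (FCM, c=2)."""
    lab = np.asarray(lab_pixels, dtype=float)
    if lab.shape[0] < 10:
        raise ValueError(f"need at least 10 skin pixels, got {lab.shape[0]}")
    result = fcm(lab[:, 1:3], c=2, seed=seed)
    dom = largest_cluster(result)
    other = 1 - int(np.flatnonzero((result.centers == dom).all(axis=1))[0])
    return dom, result.centers[other].copy()


def build_base(class_images, label: str, seed: int = 0) -> ChromaticityBase:
    """Two-level base for one class from its images' lab-pixel sets.

    ``class_images`` may be lab-pixel arrays (pixel-level FCM is run here) or
    precomputed (dominant, subdominant) pairs.
    """
    if len(class_images) < 2:
        raise ValueError(f"need at least 2 images to build the {label!r} base")
    pooled = []
    for i, item in enumerate(class_images):
        arr = np.asarray(item, dtype=float)
        if arr.shape == (2, 2):  # precomputed (dominant, subdominant) pair
            dom, sub = arr[0], arr[1]
        else:
            dom, sub = image_dominant_pair(arr, seed=seed + i)
        pooled.append(dom)
        pooled.append(sub)
    pooled = np.asarray(pooled)
    result = fcm(pooled, c=2, seed=seed)
    center = largest_cluster(result)
    return ChromaticityBase(
        label=label,
        a=float(center[0]),
        b=float(center[1]),
        provenance={
            "n_images": len(class_images),
            "n_pooled_points": int(pooled.shape[0]),
            "hard_counts": [int(v) for v in result.hard_counts],
        },
    )


def build_all_bases(cohort: dict[str, list], seed: int = 0) -> BaseSet:
    """One base per chromatic class, each from that class's images only.

    ``cohort`` maps class label -> list of lab-pixel sets (or dominant
    pairs).  White/black entries, if present, are ignored.
    """
    bases = []
    for k, label in enumerate(BASE_CLASS_LABELS):
        if label not in cohort or len(cohort[label]) < 2:
            raise ValueError(f"cohort is missing class {label!r} (need >= 2 images)")
        bases.append(build_base(cohort[label], label, seed=seed + 1000 * k))
    return BaseSet(bases)


def single_level_baseline(class_images, label: str, seed: int = 0) -> ChromaticityBase:
    """Comparison base: mean of per-image dominant centers (one FCM level)."""
    if len(class_images) < 2:
        raise ValueError(f"need at least 2 images to build the {label!r} base")
    dominants = []
    for i, item in enumerate(class_images):
        arr = np.asarray(item, dtype=float)
        if arr.shape == (2, 2):
            dominants.append(arr[0])
        else:
            dominants.append(image_dominant_pair(arr, seed=seed + i)[0])
    center = np.mean(dominants, axis=0)
    return ChromaticityBase(
        label=label,
        a=float(center[0]),
        b=float(center[1]),
        provenance={"n_images": len(class_images), "method": "single_level"},
    )


def classify_by_peak(four_bin_histogram) -> str:
    """Four-color label from the maximal chromaticity bin (ties: canonical
    order first)."""
    h = np.asarray(four_bin_histogram, dtype=float)
    if h.shape != (4,):
        raise ValueError("expected a 4-bin histogram in canonical base order")
    if (h < 0).any():
        raise ValueError("histogram bins must be non-negative")
    if h.sum() == 0:
        raise ValueError("all-zero histogram")
    return BASE_CLASS_LABELS[int(np.argmax(h))]
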