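"""Complexion histograms: chromaticity bases split by luminance sub-bases.

Each skin pixel is assigned to its nearest chromaticity base by Euclidean
distance in the (a, b) plane, then dropped into a luminance sub-bin by its
L* value.  The resulting vector has, per base (canonical order), an
optional aggregate bin followed by K sub-bins:

* preliminary layout: L* range 0-100, interval 10, no aggregate bins
  -> 4 x 10 = 40 features;
* refined layout: range 25-95, interval 14, aggregate bins on
  -> 4 + 4 x 5 = 24 features (the sweep endpoints give 12 and 284).

Normalization divides every bin by the pixel count, so aggregate bins sum
to 1 and sub-bins sum to 1.  Regional variants segment five facial regions
from the skin mask (morphological close, bounding rectangle, proportional
split) and concatenate the per-region histograms scaled by fixed weights.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .bases import BaseSet

__all__ = [
    "LuminanceBinning",
    "ComplexionHistogram",
    "RegionPartition",
    "REGION_ORDER",
    "DEFAULT_REGION_WEIGHTS",
    "assign_pixels",
    "feature_length",
    "segment_regions",
    "regional_histograms",
    "fuse_features",
    "chromaticity_only_histogram",
    "luminance_only_histogram",
]

REGION_ORDER = ("left_cheek", "right_cheek", "forehead", "nose", "jaw")
DEFAULT_REGION_WEIGHTS = {
    "left_cheek": 0.3,
    "right_cheek": 0.3,
    "forehead": 0.1,
    "nose": 0.1,
    "jaw": 0.2,
}
_N_BASES = 4


@dataclass(frozen=True)
class LuminanceBinning:
    """Even luminance bins on [lo, hi]; K = floor((hi - lo) / interval)."""

    lo: float = 25.0
    hi: float = 95.0
    interval: float = 14.0

    def __post_init__(self):
        if not self.hi > self.lo:
            raise ValueError("need hi > lo")
        if self.interval <= 0 or self.interval > self.hi - self.lo:
            raise ValueError("interval must lie in (0, hi - lo]")

    @property
    def n_bins(self) -> int:
        return int(math.floor((self.hi - self.lo) / self.interval))

    @property
    def edges(self) -> np.ndarray:
        return self.lo + self.interval * np.arange(self.n_bins + 1)

    @property
    def centers(self) -> np.ndarray:
        e = self.edges
        return 0.5 * (e[:-1] + e[1:])

    def bin_index(self, L) -> np.ndarray:
        """Sub-bin index for L* values; out-of-range values clamp to the
        boundary bins."""
        L = np.clip(np.asarray(L, dtype=float), self.lo, self.hi)
        idx = np.floor((L - self.lo) / self.interval).astype(int)
        return np.minimum(idx, self.n_bins - 1)


#: Preliminary binning behind the 40-feature layout.
DEFAULT_COARSE_BINNING = LuminanceBinning(0.0, 100.0, 10.0)
#: Refined binning behind the 24-feature layout.
DEFAULT_REFINED_BINNING = LuminanceBinning(25.0, 95.0, 14.0)


def feature_length(binning: LuminanceBinning, include_base_bins: bool) -> int:
    """Length of the complexion feature vector: 4K (+4 aggregate bins)."""
    return _N_BASES * binning.n_bins + (_N_BASES if include_base_bins else 0)


@dataclass
class ComplexionHistogram:
    """Feature vector plus its layout metadata.

    ``values`` is laid out per base (canonical order): optional aggregate
    bin, then K sub-bins.  For region-fused histograms ``n_regions`` > 1 and
    the whole block repeats per region in REGION_ORDER.
    """

    values: np.ndarray
    binning: LuminanceBinning
    include_base_bins: bool
    n_pixels: int
    normalized: bool = True
    n_regions: int = 1

    @property
    def block_length(self) -> int:
        return feature_length(self.binning, self.include_base_bins)

    def _block(self, region: int) -> np.ndarray:
        L = self.block_length
        return self.values[region * L:(region + 1) * L]

    def aggregate_bins(self, region: int = 0) -> np.ndarray:
        """The four per-base aggregate bins of one region block."""
        if not self.include_base_bins:
            raise ValueError("histogram was built without aggregate base bins")
        per = 1 + self.binning.n_bins
        return self._block(region)[::per][:_N_BASES].copy()

    def sub_bins(self, region: int = 0) -> np.ndarray:
        """(4, K) array of luminance sub-bins of one region block."""
        per = (1 if self.include_base_bins else 0) + self.binning.n_bins
        block = self._block(region).reshape(_N_BASES, per)
        return block[:, 1:].copy() if self.include_base_bins else block.copy()


def assign_pixels(
    lab_pixels,
    bases: BaseSet,
    binning: LuminanceBinning = DEFAULT_REFINED_BINNING,
    include_base_bins: bool = True,
    normalize: bool = True,
) -> ComplexionHistogram:
    """Quantize skin pixels into the complexion histogram."""
    lab = np.asarray(lab_pixels, dtype=float)
    if lab.size == 0:
        raise ValueError("empty pixel set")
    centers = bases.centers  # (4, 2)
    d2 = ((lab[:, None, 1:3] - centers[None, :, :]) ** 2).sum(axis=2)
    base_idx = np.argmin(d2, axis=1)
    sub_idx = binning.bin_index(lab[:, 0])

    K = binning.n_bins
    per = (1 if include_base_bins else 0) + K
    values = np.zeros(_N_BASES * per)
    flat = base_idx * K + sub_idx
    counts = np.bincount(flat, minlength=_N_BASES * K).reshape(_N_BASES, K)
    for i in range(_N_BASES):
        off = i * per
        if include_base_bins:
            values[off] = counts[i].sum()
            values[off + 1: off + 1 + K] = counts[i]
        else:
            values[off: off + K] = counts[i]
    n = lab.shape[0]
    if normalize:
        values = values / n
    return ComplexionHistogram(
        values=values,
        binning=binning,
        include_base_bins=include_base_bins,
        n_pixels=n,
        normalized=normalize,
    )


@dataclass
class RegionPartition:
    """Five disjoint sub-masks of the skin mask plus their weights."""

    regions: dict[str, np.ndarray]
    region_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_REGION_WEIGHTS)
    )

    def __post_init__(self):
        if tuple(self.regions) != REGION_ORDER:
            raise ValueError(f"regions must be keyed in order {REGION_ORDER}")
        if abs(sum(self.region_weights.values()) - 1.0) > 1e-6:
            raise ValueError("region weights must sum to 1")


# Bounding-rectangle split fractions (rows as fraction of height, cols of
# width): forehead on top, cheeks flanking the nose, jaw at the bottom.
_ROW_FOREHEAD = (0.0, 0.33)
_ROW_MID = (0.33, 0.75)
_ROW_JAW = (0.75, 1.0)
_COL_LEFT = (0.0, 0.35)
_COL_NOSE = (0.35, 0.65)
_COL_RIGHT = (0.65, 1.0)


def segment_regions(mask: np.ndarray, region_weights=None) -> RegionPartition:
    """Split a skin mask into the five facial regions.

    The mask is morphologically closed (square element, side ~3% of the
    bounding-box height, minimum 3) to connect fragments, its bounding
    rectangle is split by fixed proportions, and each block is intersected
    with the *original* mask.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    rows = np.flatnonzero(mask.any(axis=1))
    side = max(3, int(round(0.03 * (rows[-1] - rows[0] + 1))))
    closed = ndimage.binary_closing(mask, structure=np.ones((side, side), dtype=bool))
    closed |= mask
    crows = np.flatnonzero(closed.any(axis=1))
    ccols = np.flatnonzero(closed.any(axis=0))
    r0, r1 = crows[0], crows[-1] + 1
    c0, c1 = ccols[0], ccols[-1] + 1
    H, W = r1 - r0, c1 - c0

    def block(rfrac, cfrac):
        rr0 = r0 + int(round(rfrac[0] * H))
        rr1 = r0 + int(round(rfrac[1] * H))
        cc0 = c0 + int(round(cfrac[0] * W))
        cc1 = c0 + int(round(cfrac[1] * W))
        m = np.zeros_like(mask)
        m[rr0:rr1, cc0:cc1] = True
        return m & mask

    regions = {
        "left_cheek": block(_ROW_MID, _COL_LEFT),
        "right_cheek": block(_ROW_MID, _COL_RIGHT),
        "forehead": block(_ROW_FOREHEAD, (0.0, 1.0)),
        "nose": block(_ROW_MID, _COL_NOSE),
        "jaw": block(_ROW_JAW, (0.0, 1.0)),
    }
    weights = dict(region_weights) if region_weights else dict(DEFAULT_REGION_WEIGHTS)
    return RegionPartition(regions=regions, region_weights=weights)


def regional_histograms(
    lab_image: np.ndarray,
    partition: RegionPartition,
    bases: BaseSet,
    binning: LuminanceBinning = DEFAULT_REFINED_BINNING,
) -> dict[str, ComplexionHistogram]:
    """Normalized complexion histogram per facial region.

    ``lab_image`` is the (H, W, 3) CIELAB image aligned with the masks.
    """
    out = {}
    for name in REGION_ORDER:
        m = partition.regions[name]
        if not m.any():
            raise ValueError(f"region {name!r} is empty")
        out[name] = assign_pixels(lab_image[m], bases, binning, include_base_bins=True)
    return out


def fuse_features(
    histograms: dict[str, ComplexionHistogram],
    weights: dict[str, float] | None = None,
) -> ComplexionHistogram:
    """Concatenate weight-scaled regional histograms into one vector.

    With weights summing to 1 the concatenation's total aggregate mass is 1
    by construction; no renormalization is applied.
    """
    weights = dict(weights) if weights else dict(DEFAULT_REGION_WEIGHTS)
    if abs(sum(weights.values()) - 1.0) > 1e-6:
        raise ValueError(f"region weights must sum to 1, got {sum(weights.values())}")
    ref = histograms[REGION_ORDER[0]]
    blocks, n_pixels = [], 0
    for name in REGION_ORDER:
        h = histograms[name]
        if h.binning != ref.binning or h.include_base_bins != ref.include_base_bins:
            raise ValueError("regional histograms have inconsistent layouts")
        blocks.append(weights[name] * h.values)
        n_pixels += h.n_pixels
    return ComplexionHistogram(
        values=np.concatenate(blocks),
        binning=ref.binning,
        include_base_bins=ref.include_base_bins,
        n_pixels=n_pixels,
        normalized=True,
        n_regions=len(REGION_ORDER),
    )


def chromaticity_only_histogram(lab_pixels, bases: BaseSet) -> np.ndarray:
    """Four-bin chromaticity proportion histogram (no luminance split)."""
    lab = np.asarray(lab_pixels, dtype=float)
    if lab.size == 0:
        raise ValueError("empty pixel set")
    d2 = ((lab[:, None, 1:3] - bases.centers[None, :, :]) ** 2).sum(axis=2)
    counts = np.bincount(np.argmin(d2, axis=1), minlength=_N_BASES)
    return counts / lab.shape[0]


def luminance_only_histogram(histogram: ComplexionHistogram) -> np.ndarray:
    """K-bin luminance distribution: sub-bins summed over bases (and, for
    fused input, over regions); aggregate bins excluded."""
    K = histogram.binning.n_bins
    out = np.zeros(K)
    for region in range(histogram.n_regions):
        out += histogram.sub_bins(region).sum(axis=0)
    return out
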