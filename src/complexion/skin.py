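"""Skin detection and fine-tuning.

One image in, one cleaned skin-pixel set out:

1. optional block-average downscale,
2. skin detection in log-opponent chromaticity space — a smoothed 2D
   histogram over (I, By) fused with a Gaussian mixture over (Rg, By),
   everything fit on the input image itself (no training stage),
3. rectangular mouth-box exclusion (lip chromaticity overlaps skin, so the
   box is cut out rather than segmented),
4. removal of extreme-luminance pixels (moles, hair) by cumulative-histogram
   tails.

Both detector branches first find color modes, then decide which modes are
skin.  The histogram branch thresholds the smoothed (I, By) histogram
(relative to its peak) and groups the surviving bins into connected
components; the mixture branch fits ``gmm_components`` diagonal Gaussians
on (I, Rg, By) — five by default, since morbid faces mix two skin
chromaticities on top of background, lips and artifacts.  A mode is
labeled *background* when its pixels are over-represented in a thin frame
around the image border (enrichment >= ``border_enrichment_threshold``
relative to chance): the images are frontal portraits, so the frame
belongs to the backdrop while facial skin never touches it.  All
non-background modes are skin; the two branches are fused with OR
(detection-favoring, the default) or AND.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from sklearn.mixture import GaussianMixture

from .colorspace import rgb_to_lab, rgb_to_log_opponent

__all__ = [
    "SkinDetectorParams",
    "downscale",
    "detect_skin",
    "exclude_mouth",
    "denoise_extremes",
    "extract_skin_pixels",
    "skin_pipeline",
]


@dataclass
class SkinDetectorParams:
    histogram_bins: int = 64
    smoothing_sigma: float = 2.0
    density_threshold: float = 0.1
    gmm_components: int = 5
    gmm_posterior_threshold: float = 0.5
    fusion_rule: str = "OR"
    border_enrichment_threshold: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.histogram_bins < 8:
            raise ValueError("histogram_bins must be >= 8")
        if not 0.0 < self.density_threshold <= 1.0:
            raise ValueError("density_threshold must lie in (0, 1]")
        if not 0.0 < self.gmm_posterior_threshold < 1.0:
            raise ValueError("gmm_posterior_threshold must lie in (0, 1)")
        if self.fusion_rule not in ("OR", "AND"):
            raise ValueError("fusion_rule must be 'OR' or 'AND'")
        if self.border_enrichment_threshold <= 0:
            raise ValueError("border_enrichment_threshold must be positive")


def downscale(image: np.ndarray, factor: int) -> np.ndarray:
    """Reduce each spatial dimension by ``factor`` via block averaging."""
    if factor < 1:
        raise ValueError("factor must be >= 1")
    img = np.asarray(image)
    h, w = img.shape[:2]
    if factor > min(h, w):
        raise ValueError(f"factor {factor} exceeds image size {h}x{w}")
    if factor == 1:
        return img.copy()
    hh, ww = (h // factor) * factor, (w // factor) * factor
    block = img[:hh, :ww].astype(float)
    block = block.reshape(hh // factor, factor, ww // factor, factor, -1)
    out = block.mean(axis=(1, 3))
    if img.ndim == 2:
        out = out[..., 0]
    if np.issubdtype(img.dtype, np.integer):
        out = np.clip(np.round(out), 0, 255).astype(img.dtype)
    return out


def _border_band(shape: tuple[int, int]) -> np.ndarray:
    h, w = shape
    band = max(2, int(round(0.03 * min(h, w))))
    frame = np.zeros((h, w), dtype=bool)
    frame[:band, :] = frame[-band:, :] = True
    frame[:, :band] = frame[:, -band:] = True
    return frame


def _skin_modes_by_border(
    mode_ids: np.ndarray,
    frame_flat: np.ndarray,
    n_modes: int,
    threshold: float,
    fallback: bool = True,
):
    """Split mode indices into skin vs background by border-band enrichment.

    ``mode_ids`` assigns each pixel a mode in 0..n_modes-1 (or -1 for none).
    A mode is background when its pixels are over-represented in the border
    band relative to chance: P(frame | mode) >= threshold * P(frame).  The
    backdrop fills the frame however many modes it splits into, while
    facial skin never touches it.  With ``fallback``, if every mode looks
    like background the least-enriched one is kept as skin so the detector
    degrades gracefully; without it an empty skin set is returned (used for
    the histogram branch, whose modes can merge into one blanket component).
    """
    global_rate = frame_flat.mean()
    enrichment = np.full(n_modes, np.inf)
    for k in range(n_modes):
        sel = mode_ids == k
        n_k = int(sel.sum())
        if n_k:
            enrichment[k] = (frame_flat & sel).sum() / n_k / max(global_rate, 1e-12)
    skin = [k for k in range(n_modes) if enrichment[k] < threshold]
    if not skin and fallback:
        skin = [int(np.argmin(enrichment))]
    return skin, enrichment


def detect_skin(image: np.ndarray, params: SkinDetectorParams | None = None) -> np.ndarray:
    """Boolean skin mask for an 8-bit RGB image.

    All statistics are fit on the input image itself.  Raises on degenerate
    (single-color) input and when the fused mask comes out empty.
    """
    params = params or SkinDetectorParams()
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB image")
    lo = rgb_to_log_opponent(img.reshape(-1, 3))
    I, Rg, By = lo[:, 0], lo[:, 1], lo[:, 2]
    if I.std() < 1e-6 and Rg.std() < 1e-6 and By.std() < 1e-6:
        raise ValueError("degenerate single-color image: zero-variance fit")
    frame_flat = _border_band(img.shape[:2]).reshape(-1)

    # --- histogram branch: smoothed 2D histogram over (I, By) -------------
    nb = params.histogram_bins
    i_edges = np.linspace(I.min(), I.max() + 1e-9, nb + 1)
    b_edges = np.linspace(By.min(), By.max() + 1e-9, nb + 1)
    hist, _, _ = np.histogram2d(I, By, bins=[i_edges, b_edges])
    smooth = ndimage.gaussian_filter(hist, params.smoothing_sigma)
    above = smooth / smooth.max() > params.density_threshold

    hist_skin = np.zeros(I.shape, dtype=bool)
    if above.any():
        comp_map, n_comp = ndimage.label(above)
        i_idx = np.clip(np.searchsorted(i_edges, I, side="right") - 1, 0, nb - 1)
        b_idx = np.clip(np.searchsorted(b_edges, By, side="right") - 1, 0, nb - 1)
        pixel_comp = comp_map[i_idx, b_idx] - 1  # -1 where below threshold
        skin_comps, _ = _skin_modes_by_border(
            pixel_comp, frame_flat, n_comp, params.border_enrichment_threshold,
            fallback=False,
        )
        hist_skin = np.isin(pixel_comp, skin_comps)

    # --- mixture branch: diagonal GMM over (I, Rg, By) --------------------
    # I is included because the log-opponent chroma of dark pixels is noise-
    # dominated; intensity keeps dark backdrop noise out of the skin modes.
    feats = np.column_stack([I, Rg, By])
    gmm = GaussianMixture(
        n_components=params.gmm_components,
        covariance_type="diag",
        random_state=params.seed,
        n_init=1,
        reg_covar=1e-8,
    )
    rng = np.random.default_rng(params.seed)
    fit_idx = (
        rng.choice(len(feats), 20000, replace=False)
        if len(feats) > 20000
        else slice(None)
    )
    gmm.fit(feats[fit_idx])
    resp = gmm.predict_proba(feats)
    hard = np.argmax(resp, axis=1)
    skin_comps, _ = _skin_modes_by_border(
        hard, frame_flat, params.gmm_components, params.border_enrichment_threshold
    )
    gmm_skin = resp[:, skin_comps].sum(axis=1) > params.gmm_posterior_threshold

    if params.fusion_rule == "OR":
        skin = hist_skin | gmm_skin
    else:
        skin = hist_skin & gmm_skin
    mask = skin.reshape(img.shape[:2])
    if not mask.any():
        raise ValueError("skin detection produced an empty mask")
    return mask


def exclude_mouth(mask: np.ndarray, mouth_box) -> np.ndarray:
    """Set all pixels inside the (row0, col0, row1, col1) rectangle to False."""
    r0, c0, r1, c1 = mouth_box
    h, w = mask.shape
    if not (0 <= r0 <= r1 <= h and 0 <= c0 <= c1 <= w):
        raise ValueError(f"mouth box {mouth_box} outside image bounds {h}x{w}")
    out = mask.copy()
    out[r0:r1, c0:c1] = False
    return out


def denoise_extremes(lab_pixels: np.ndarray, low_tail: float = 0.01, high_tail: float = 0.01) -> np.ndarray:
    """Drop pixels in the L* cumulative-distribution tails.

    Removes pixels below the ``low_tail`` quantile or above the
    ``1 - high_tail`` quantile of L*; this is what scrubs moles and stray
    hair from the skin set.
    """
    for t in (low_tail, high_tail):
        if not 0.0 <= t <= 0.2:
            raise ValueError("tail proportions must lie in [0, 0.2]")
    if low_tail + high_tail >= 1.0:
        raise ValueError("tail proportions must sum to < 1")
    lab = np.asarray(lab_pixels, dtype=float)
    L = lab[:, 0]
    lo = np.quantile(L, low_tail)
    hi = np.quantile(L, 1.0 - high_tail)
    keep = (L >= lo) & (L <= hi)
    return lab[keep]


def extract_skin_pixels(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """CIELAB rows (row-major order) of exactly the masked pixels."""
    img = np.asarray(image)
    if img.shape[:2] != mask.shape:
        raise ValueError(f"image {img.shape[:2]} and mask {mask.shape} shapes differ")
    if not mask.any():
        raise ValueError("empty mask: no skin pixels to extract")
    return rgb_to_lab(img[mask])


def skin_pipeline(
    image: np.ndarray,
    mouth_box=None,
    *,
    params: SkinDetectorParams | None = None,
    downscale_factor: int = 1,
    low_tail: float = 0.01,
    high_tail: float = 0.01,
) -> tuple[np.ndarray, np.ndarray]:
    """Run the full chain; returns ``(cleaned lab pixels, skin mask)``.

    ``mouth_box`` coordinates refer to the image *before* downscaling and are
    rescaled along with it.
    """
    img = downscale(np.asarray(image), downscale_factor)
    mask = detect_skin(img, params)
    if mouth_box is not None:
        box = tuple(int(v // downscale_factor) for v in mouth_box)
        mask = exclude_mouth(mask, box)
    lab = extract_skin_pixels(img, mask)
    return denoise_extremes(lab, low_tail, high_tail), mask
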