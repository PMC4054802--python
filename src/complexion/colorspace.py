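"""Color-space transforms used throughout the pipeline.

The chain RGB -> CIEXYZ -> CIELAB separates chromaticity (a*, b*) from
luminance (L*), which is what the complexion features are built on.  The
matrix below is the standard sRGB/D65 primaries matrix applied to *linear*
RGB in [0, 1]; no gamma companding is assumed (``assume_linear_rgb``), since
the acquisition model treats camera output as linear.  Log-opponent
chromaticity (I, Rg, By) feeds the skin detector only.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "RGB_TO_XYZ_MATRIX",
    "WHITE_POINT",
    "rgb_to_xyz",
    "xyz_to_lab",
    "rgb_to_lab",
    "lab_to_xyz",
    "lab_to_rgb",
    "rgb_to_log_opponent",
]

#: Linear RGB -> CIEXYZ matrix (D65 primaries); XYZ scaled x100 downstream.
RGB_TO_XYZ_MATRIX = np.array(
    [
        [0.4124, 0.3576, 0.1805],
        [0.2126, 0.7152, 0.0722],
        [0.0193, 0.1192, 0.9505],
    ]
)

#: D65 reference white (Xn, Yn, Zn) on the 0-100 scale.
WHITE_POINT = np.array([95.047, 100.0, 108.883])

# Branch point of the CIELAB companding function f(t).
_DELTA = 6.0 / 29.0
_DELTA3 = _DELTA**3


def _as_float_pixels(pixels) -> np.ndarray:
    arr = np.asarray(pixels, dtype=float)
    if arr.shape[-1] != 3:
        raise ValueError(f"expected trailing dimension 3, got shape {arr.shape}")
    return arr


def rgb_to_xyz(pixels) -> np.ndarray:
    """Map linear RGB in [0, 1] to CIEXYZ on the 0-100 scale.

    Parameters
    ----------
    pixels : array_like, shape (..., 3)
        Linear RGB with channels in [0, 1].

    Returns
    -------
    ndarray of XYZ tristimulus values, 0-100 scale, same leading shape.
    """
    rgb = _as_float_pixels(pixels)
    if rgb.min() < -1e-9 or rgb.max() > 1 + 1e-9:
        raise ValueError(
            f"RGB channels must lie in [0, 1]; got range "
            f"[{rgb.min():.4g}, {rgb.max():.4g}]"
        )
    return (rgb @ RGB_TO_XYZ_MATRIX.T) * 100.0


def _f(t: np.ndarray) -> np.ndarray:
    """CIELAB companding: cube root above the branch point, linear below."""
    t = np.asarray(t, dtype=float)
    return np.where(t > _DELTA3, np.cbrt(t), t / (3.0 * _DELTA**2) + 4.0 / 29.0)


def _f_inv(ft: np.ndarray) -> np.ndarray:
    ft = np.asarray(ft, dtype=float)
    return np.where(ft > _DELTA, ft**3, 3.0 * _DELTA**2 * (ft - 4.0 / 29.0))


def xyz_to_lab(pixels) -> np.ndarray:
    """Map CIEXYZ (0-100 scale) to CIELAB relative to the D65 white point."""
    xyz = _as_float_pixels(pixels)
    if xyz.min() < -1e-9:
        raise ValueError(f"XYZ tristimulus values must be non-negative; min {xyz.min():.4g}")
    f = _f(xyz / WHITE_POINT)
    lab = np.empty_like(f)
    lab[..., 0] = 116.0 * f[..., 1] - 16.0
    lab[..., 1] = 500.0 * (f[..., 0] - f[..., 1])
    lab[..., 2] = 200.0 * (f[..., 1] - f[..., 2])
    return lab


def rgb_to_lab(pixels, *, assume_linear_rgb: bool = True) -> np.ndarray:
    """RGB to CIELAB.  8-bit input (max > 1 or integer dtype) is scaled by 255.

    ``assume_linear_rgb`` is kept as an explicit switch: when False, sRGB
    gamma decoding is applied before the XYZ matrix.  The default treats the
    camera RGB as already linear.
    """
    rgb = _as_float_pixels(pixels)
    if np.issubdtype(np.asarray(pixels).dtype, np.integer) or rgb.max() > 1.0:
        rgb = rgb / 255.0
    if not assume_linear_rgb:
        rgb = np.where(rgb <= 0.04045, rgb / 12.92, ((rgb + 0.055) / 1.055) ** 2.4)
    return xyz_to_lab(rgb_to_xyz(rgb))


def lab_to_xyz(pixels) -> np.ndarray:
    """Analytic inverse of :func:`xyz_to_lab`."""
    lab = _as_float_pixels(pixels)
    fy = (lab[..., 0] + 16.0) / 116.0
    fx = fy + lab[..., 1] / 500.0
    fz = fy - lab[..., 2] / 200.0
    xyz = np.stack([_f_inv(fx), _f_inv(fy), _f_inv(fz)], axis=-1)
    return xyz * WHITE_POINT


def lab_to_rgb(pixels, *, clip: bool = True) -> tuple[np.ndarray, int]:
    """CIELAB to linear RGB in [0, 1].

    Returns ``(rgb, n_clipped)`` where ``n_clipped`` counts pixels with any
    channel outside [0, 1] before clipping (out-of-gamut samples).
    """
    xyz = lab_to_xyz(pixels)
    rgb = (xyz / 100.0) @ np.linalg.inv(RGB_TO_XYZ_MATRIX).T
    tol = 1e-9
    out_of_gamut = int(np.count_nonzero(
        np.any((rgb < -tol) | (rgb > 1 + tol), axis=-1)
    ))
    if clip:
        rgb = np.clip(rgb, 0.0, 1.0)
    return rgb, out_of_gamut


def rgb_to_log_opponent(pixels) -> np.ndarray:
    """8-bit RGB to log-opponent chromaticity channels (I, Rg, By).

    With l(x) = log(x + 1):  I = (l(R)+l(G)+l(B))/3,  Rg = l(R)-l(G),
    By = l(B) - (l(R)+l(G))/2.  The +1 offset keeps everything finite for
    zero channels.  This is the module's LO dialect; only the (I, By) pair
    drives the skin-detection histogram and (Rg, By) the mixture model.
    """
    rgb = _as_float_pixels(pixels)
    if rgb.min() < 0 or rgb.max() > 255:
        raise ValueError("expected 8-bit channels in [0, 255]")
    l = np.log(rgb + 1.0)
    lo = np.empty_like(l)
    lo[..., 0] = l.mean(axis=-1)
    lo[..., 1] = l[..., 0] - l[..., 1]
    lo[..., 2] = l[..., 2] - 0.5 * (l[..., 0] + l[..., 1])
    return lo
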