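"""Deterministic preprocessing of single-spheroid well images.

The chain standardizes raw phase-contrast photos for the regression
network: percentile contrast stretch (flattens lighting differences between
wells), median + Gaussian denoising, adaptive margin trimming around the
spheroid, small-artifact removal, and resizing to the network input
resolution (224 x 224 by default).  Everything is a pure function of the
input pixels and the config — no randomness — so identical inputs always
produce identical output bytes.

"Contrast maximization" is concretized as a linear percentile stretch and
the artifact threshold as Otsu's criterion; neither step needs a tuned
constant, and both are exposed in :class:`PreprocessConfig` for real data
whose polarity or noise floor differs from the synthetic renders (where
spheroids are darker than background).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
from scipy import ndimage
from skimage import measure, transform
from skimage.filters import threshold_otsu

__all__ = [
    "PreprocessConfig",
    "stretch_contrast",
    "denoise",
    "trim_margins",
    "remove_artifacts",
    "preprocess_image",
    "preprocess_file",
    "preprocess_batch",
    "load_image",
]


@dataclass(frozen=True)
class PreprocessConfig:
    low_pct: float = 1.0
    high_pct: float = 99.0
    median_kernel: int = 3
    blur_sigma: float = 1.0
    crop_margin: float = 0.25  # bounding-box expansion, fraction of its size
    min_crop_frac: float = 0.0  # crop side floor, fraction of the frame side
    output_size: int = 224
    min_area: int = 50  # px^2; smaller foreground components are artifacts
    dark_foreground: bool = True  # spheroid darker than background

    def __post_init__(self) -> None:
        if not (0 <= self.low_pct < self.high_pct <= 100):
            raise ValueError("need 0 <= low_pct < high_pct <= 100")
        if self.median_kernel < 1 or self.median_kernel % 2 == 0:
            raise ValueError("median kernel must be odd and >= 1")
        if self.output_size < 32:
            raise ValueError("output_size must be >= 32")


def load_image(path: str | Path) -> np.ndarray:
    """Read a grayscale image file to float64 in [0, 1]."""
    try:
        arr = iio.imread(path)
    except (OSError, ValueError) as exc:
        raise IOError(f"cannot read image file {path!r}: {exc}") from exc
    arr = np.asarray(arr, dtype=float)
    if arr.ndim == 3:  # collapse any color/alpha channels
        arr = arr[..., :3].mean(axis=-1)
    if arr.max() > 1.0:
        arr = arr / 255.0 if arr.max() <= 255 else arr / 65535.0
    return np.clip(arr, 0.0, 1.0)


def stretch_contrast(img: np.ndarray, low_pct: float = 1.0, high_pct: float = 99.0) -> np.ndarray:
    """Linear stretch mapping the low/high intensity percentiles to 0/1.

    Constant (zero-dynamic-range) images are returned unchanged.
    """
    lo, hi = np.percentile(img, [low_pct, high_pct])
    if hi - lo <= 1e-12:
        return img.copy()
    return np.clip((img - lo) / (hi - lo), 0.0, 1.0)


def denoise(img: np.ndarray, kernel: int = 3, sigma: float = 1.0) -> np.ndarray:
    """Median filter (kills salt-and-pepper pixels) then Gaussian blur."""
    if kernel % 2 == 0:
        raise ValueError("median kernel must be odd")
    out = ndimage.median_filter(img, size=kernel) if kernel > 1 else img
    if sigma > 0:
        out = ndimage.gaussian_filter(out, sigma=sigma)
    return np.clip(out, img.min(), img.max())


def _foreground_mask(img: np.ndarray, dark_foreground: bool) -> np.ndarray:
    vals = img.ravel()
    if vals.max() - vals.min() <= 1e-12:
        return np.zeros_like(img, dtype=bool)
    thr = threshold_otsu(img)
    return img < thr if dark_foreground else img > thr


def _centered_square_crop(img: np.ndarray) -> np.ndarray:
    h, w = img.shape
    side = min(h, w)
    r0 = (h - side) // 2
    c0 = (w - side) // 2
    return img[r0 : r0 + side, c0 : c0 + side]


def trim_margins(img: np.ndarray, cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Crop a square window around the spheroid.

    The spheroid is taken to be the largest foreground connected component
    of the automatically thresholded (Otsu) image; the crop is its bounding
    box expanded by ``cfg.crop_margin`` on each side, squared up, and
    clamped to the frame.  ``cfg.min_crop_frac`` floors the window at a
    fraction of the frame side: a floor of 1.0 keeps a fixed full-frame
    window (appropriate when the source images have no large margins and
    the spheroid's absolute scale is itself informative), while 0 shrinks
    the window fully to the spheroid.  If no component reaches
    ``cfg.min_area`` the well is treated as empty and a centered square
    crop is returned instead.
    """
    cfg = cfg or PreprocessConfig()
    mask = _foreground_mask(img, cfg.dark_foreground)
    labels = measure.label(mask)
    best = None
    for region in measure.regionprops(labels):
        if region.area >= cfg.min_area and (best is None or region.area > best.area):
            best = region
    if best is None:
        return _centered_square_crop(img)

    r0, c0, r1, c1 = best.bbox
    side = max(r1 - r0, c1 - c0)
    pad = cfg.crop_margin * side
    half = side / 2 + pad
    cy, cx = (r0 + r1) / 2, (c0 + c1) / 2
    side_out = min(int(round(2 * half)), min(img.shape))
    side_out = max(side_out, 1, int(round(cfg.min_crop_frac * min(img.shape))))
    side_out = min(side_out, min(img.shape))
    top = int(round(cy - side_out / 2))
    left = int(round(cx - side_out / 2))
    top = min(max(top, 0), img.shape[0] - side_out)
    left = min(max(left, 0), img.shape[1] - side_out)
    return img[top : top + side_out, left : left + side_out]


def remove_artifacts(img: np.ndarray, cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Erase small foreground components, keeping the largest one.

    Components below ``cfg.min_area`` are replaced by the local background
    estimate (a wide median filter of the image), so debris blobs vanish
    into their surroundings.  The largest component is never removed, even
    when it is itself below the area floor — the output is never blank.
    """
    cfg = cfg or PreprocessConfig()
    mask = _foreground_mask(img, cfg.dark_foreground)
    labels = measure.label(mask)
    if labels.max() == 0:
        return img.copy()
    areas = np.bincount(labels.ravel())[1:]
    keep_label = int(np.argmax(areas)) + 1
    small = np.zeros_like(mask)
    for lbl, area in enumerate(areas, start=1):
        if lbl != keep_label and area < cfg.min_area:
            small |= labels == lbl
    if not small.any():
        return img.copy()
    background = ndimage.median_filter(img, size=15)
    out = img.copy()
    out[small] = background[small]
    return out


def _resize(img: np.ndarray, size: int) -> np.ndarray:
    # Area-averaging (anti-aliased) when shrinking, bilinear when growing:
    # both deterministic, documented so outputs are stable across versions.
    downscale = size < min(img.shape)
    out = transform.resize(
        img, (size, size), order=1, anti_aliasing=downscale, mode="reflect"
    )
    return np.clip(out, 0.0, 1.0)


def preprocess_image(img: np.ndarray, cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Full chain: stretch -> denoise -> trim -> remove artifacts -> resize."""
    cfg = cfg or PreprocessConfig()
    out = stretch_contrast(np.asarray(img, dtype=float), cfg.low_pct, cfg.high_pct)
    out = denoise(out, cfg.median_kernel, cfg.blur_sigma)
    out = trim_margins(out, cfg)
    out = remove_artifacts(out, cfg)
    return _resize(out, cfg.output_size)


def preprocess_file(
    path: str | Path, cfg: PreprocessConfig | None = None
) -> np.ndarray:
    return preprocess_image(load_image(path), cfg)


def preprocess_batch(
    paths: Sequence[str | Path],
    cfg: PreprocessConfig | None = None,
    out_dir: str | Path | None = None,
) -> np.ndarray:
    """Preprocess files in order; optionally write PNGs mirroring the names.

    Returns a stack of shape ``(n, output_size, output_size)`` in input
    order.
    """
    cfg = cfg or PreprocessConfig()
    out = np.empty((len(paths), cfg.output_size, cfg.output_size))
    for k, p in enumerate(paths):
        out[k] = preprocess_file(p, cfg)
        if out_dir is not None:
            dest = Path(out_dir)
            dest.mkdir(parents=True, exist_ok=True)
            iio.imwrite(
                dest / Path(p).name, (out[k] * 255).round().astype(np.uint8)
            )
    return out
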