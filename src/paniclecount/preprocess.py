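"""Morphological preprocessing of panicle images.

Turns a raw RGB photograph or scan of a detached rice panicle (bright
panicle on a black light-absorbing background) into a clean, stem-free
binary branch mask:

1. grayscale conversion and Otsu thresholding;
2. connected-component denoising (speckles from fabric contamination);
3. opening (iterated disk erosion then dilation) to suppress thin
   structures, whose residual against the denoised mask isolates the
   stem; the stem is size-filtered and subtracted;
4. the stem-free mask gates the original RGB image.

All masks are 2-D boolean numpy arrays; images are ``(H, W, 3)`` uint8.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi

#: ITU-R 601 luma weights used for grayscale conversion.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)


class DegenerateHistogramError(ValueError):
    """Raised when Otsu thresholding is attempted on a constant image."""


def _binary_structure(connectivity: int) -> np.ndarray:
    if connectivity == 8:
        return ndi.generate_binary_structure(2, 2)
    if connectivity == 4:
        return ndi.generate_binary_structure(2, 1)
    raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")


def disk_element(diameter: int) -> np.ndarray:
    """Discrete disk structuring element inscribed in a ``diameter``² window.

    For ``diameter=5`` this is the 21-pixel element (the 5×5 window with its
    four extreme corners excluded): pixels at Euclidean distance
    ≤ radius + 0.5 from the centre.
    """
    if diameter < 1 or diameter % 2 == 0:
        raise ValueError(f"disk diameter must be odd and >= 1, got {diameter}")
    r = diameter // 2
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return (yy * yy + xx * xx) <= (r + 0.5) ** 2


@dataclass(frozen=True)
class PreprocessConfig:
    """Parameters of the preprocessing chain.

    Defaults correspond to full-resolution scanner frames (2480×3507 px,
    grains 30–50 px wide, stems 5–10 px): speckle noise components are
    < 100 px so a 1000 px area filter is safe, and three openings with a
    5×5 disk remove structures up to ~12 px wide (the stem) while grains
    survive.
    """

    denoise_min_area: int = 1000
    stem_min_area: int = 200
    disk_diameter: int = 5
    erode_iterations: int = 3
    dilate_iterations: int = 3
    remove_stem: bool = True
    connectivity: int = 8
    luma_weights: tuple[float, float, float] = LUMA_WEIGHTS
    invert: bool = False  # foreground darker than background

    def __post_init__(self) -> None:
        if self.denoise_min_area < 0 or self.stem_min_area < 0:
            raise ValueError("area thresholds must be >= 0")
        if self.erode_iterations < 0 or self.dilate_iterations < 0:
            raise ValueError("iteration counts must be >= 0")
        if self.disk_diameter < 1 or self.disk_diameter % 2 == 0:
            raise ValueError("disk_diameter must be odd and >= 1")
        _binary_structure(self.connectivity)

    def at_scale(self, scale: float) -> "PreprocessConfig":
        """Config matched to images shrunk by a linear factor ``scale``.

        Areas scale with ``scale**2``; the opening iteration count scales
        linearly (never below 1) while the 5×5 disk is kept as the smallest
        useful disk element.
        """
        if scale <= 0:
            raise ValueError("scale must be positive")
        return dataclasses.replace(
            self,
            denoise_min_area=max(1, round(self.denoise_min_area * scale**2)),
            stem_min_area=max(1, round(self.stem_min_area * scale**2)),
            erode_iterations=max(1, round(self.erode_iterations * scale)),
            dilate_iterations=max(1, round(self.dilate_iterations * scale)),
        )


@dataclass
class PreprocessResult:
    """All intermediate products of the preprocessing chain."""

    otsu_threshold: int
    raw_mask: np.ndarray        # Otsu foreground
    denoised_mask: np.ndarray   # after the large-area component filter
    opened_mask: np.ndarray     # opening of the denoised mask (stem-free, rough)
    stem_mask: np.ndarray       # size-filtered opening residual
    stemless_mask: np.ndarray   # denoised minus stem
    masked_rgb: np.ndarray      # original RGB gated by stemless_mask

    def stage_pixel_counts(self) -> dict[str, int]:
        """Foreground pixel count per stage (for logging / JSON metadata)."""
        return {
            "raw": int(self.raw_mask.sum()),
            "denoised": int(self.denoised_mask.sum()),
            "opened": int(self.opened_mask.sum()),
            "stem": int(self.stem_mask.sum()),
            "stemless": int(self.stemless_mask.sum()),
        }


def _check_rgb(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) RGB image, got shape {img.shape}")
    if img.shape[0] < 1 or img.shape[1] < 1:
        raise ValueError("empty image")
    return img


def to_grayscale(
    img: np.ndarray, weights: tuple[float, float, float] = LUMA_WEIGHTS
) -> np.ndarray:
    """Weighted-luminance grayscale conversion, rounded to uint8."""
    img = _check_rgb(img)
    gray = img.astype(np.float64) @ np.asarray(weights, dtype=np.float64)
    return np.clip(np.rint(gray), 0, 255).astype(np.uint8)


def otsu_threshold(gray: np.ndarray) -> tuple[int, np.ndarray]:
    """Otsu's threshold over gray levels 0–255 and the foreground mask.

    The threshold maximises the between-class variance of the intensity
    histogram; the mask is ``gray > threshold`` (panicle bright on a dark
    background). Ties take the lowest maximising level.
    """
    gray = np.asarray(gray)
    if gray.size == 0:
        raise ValueError("empty image")
    counts = np.bincount(gray.astype(np.uint8).ravel(), minlength=256).astype(np.float64)
    if np.count_nonzero(counts) < 2:
        raise DegenerateHistogramError("degenerate histogram: fewer than 2 gray levels")
    p = counts / counts.sum()
    levels = np.arange(256, dtype=np.float64)
    omega = np.cumsum(p)              # class weight of {gray <= t}
    mu = np.cumsum(p * levels)        # first moment of {gray <= t}
    mu_total = mu[-1]
    sigma_b = np.zeros(256)
    valid = (omega > 0) & (omega < 1)
    sigma_b[valid] = (mu_total * omega[valid] - mu[valid]) ** 2 / (
        omega[valid] * (1.0 - omega[valid])
    )
    t = int(np.argmax(sigma_b))
    return t, gray > t


def remove_small_components(
    mask: np.ndarray, min_area: int, connectivity: int = 8
) -> np.ndarray:
    """Keep only connected components with pixel area >= ``min_area``."""
    if min_area < 0:
        raise ValueError("min_area must be >= 0")
    mask = np.asarray(mask, dtype=bool)
    if min_area <= 1 or not mask.any():
        return mask.copy()
    labels, n = ndi.label(mask, structure=_binary_structure(connectivity))
    areas = np.bincount(labels.ravel())
    keep = areas >= min_area
    keep[0] = False
    return keep[labels]


def erode(mask: np.ndarray, disk_diameter: int = 5, iterations: int = 3) -> np.ndarray:
    """Iterated binary erosion by a disk element (out-of-image = background)."""
    mask = np.asarray(mask, dtype=bool)
    if iterations == 0:
        return mask.copy()
    return ndi.binary_erosion(
        mask, structure=disk_element(disk_diameter), iterations=iterations, border_value=0
    )


def dilate(mask: np.ndarray, disk_diameter: int = 5, iterations: int = 3) -> np.ndarray:
    """Iterated binary dilation by a disk element (dual of :func:`erode`)."""
    mask = np.asarray(mask, dtype=bool)
    if iterations == 0:
        return mask.copy()
    return ndi.binary_dilation(
        mask, structure=disk_element(disk_diameter), iterations=iterations, border_value=0
    )


def remove_stem(
    denoised: np.ndarray, cfg: PreprocessConfig | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Isolate and subtract the stem from a denoised branch mask.

    The opening (erode×n then dilate×n with the disk element) suppresses
    structures thinner than the accumulated element width — the stem — and
    its residual against the input, size-filtered to drop grain-boundary
    shavings, is the stem. Returns ``(stemless, stem, opened)``; ``stemless``
    and ``stem`` partition a subset of the input and never overlap.
    """
    cfg = cfg or PreprocessConfig()
    denoised = np.asarray(denoised, dtype=bool)
    eroded = erode(denoised, cfg.disk_diameter, cfg.erode_iterations)
    opened = dilate(eroded, cfg.disk_diameter, cfg.dilate_iterations)
    stem_noisy = denoised & ~opened
    stem = remove_small_components(stem_noisy, cfg.stem_min_area, cfg.connectivity)
    stemless = denoised & ~stem
    return stemless, stem, opened


def apply_mask(img: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Keep RGB pixels where ``mask`` is set; black out the rest."""
    img = _check_rgb(img)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != img.shape[:2]:
        raise ValueError(f"mask shape {mask.shape} does not match image {img.shape[:2]}")
    return np.where(mask[..., None], img, 0).astype(img.dtype)


def preprocess_image(
    img: np.ndarray, cfg: PreprocessConfig | None = None
) -> PreprocessResult:
    """Run the full preprocessing chain on one RGB image.

    With ``cfg.remove_stem`` off, the stem mask is empty and the stemless
    mask equals the denoised mask (used for the with/without-stem
    comparison).
    """
    cfg = cfg or PreprocessConfig()
    img = _check_rgb(img)
    gray = to_grayscale(img, cfg.luma_weights)
    threshold, raw = otsu_threshold(gray)
    if cfg.invert:
        raw = gray <= threshold
    denoised = remove_small_components(raw, cfg.denoise_min_area, cfg.connectivity)
    if cfg.remove_stem:
        stemless, stem, opened = remove_stem(denoised, cfg)
    else:
        stemless = denoised.copy()
        stem = np.zeros_like(denoised)
        opened = denoised.copy()
    return PreprocessResult(
        otsu_threshold=threshold,
        raw_mask=raw,
        denoised_mask=denoised,
        opened_mask=opened,
        stem_mask=stem,
        stemless_mask=stemless,
        masked_rgb=apply_mask(img, stemless),
    )
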