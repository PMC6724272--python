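"""Segmentation of the root and its hairs.

Two local adaptive thresholds drive the pipeline: a small-radius Bernsen
threshold captures the root together with its hairs (thin, high-contrast
structures), while a large-radius Phansalkar threshold followed by heavy
morphological opening captures the root body alone. Subtracting the body
from the root+hairs mask leaves the area covered by root hairs only, which
is what the downstream length profiling measures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from scipy.signal import fftconvolve
from skimage.morphology import disk

from .io import IntensityImage

__all__ = [
    "BinaryMask",
    "SegmentationConfig",
    "local_threshold",
    "smooth_mask",
    "build_masks",
]

_SQUARE3 = np.ones((3, 3), dtype=bool)  # 8-connected structuring element


@dataclass
class BinaryMask:
    """A binary mask co-registered with its source image."""

    pixels: np.ndarray  # bool
    px_size_um: float
    role: str = "root_with_hairs"  # root_with_hairs | root_body | hairs_only

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.dtype != bool:
            uniq = np.unique(self.pixels)
            if not np.isin(uniq, (0, 1)).all():
                raise ValueError("mask values must be strictly binary")
            self.pixels = self.pixels.astype(bool)
        if self.pixels.ndim != 2:
            raise ValueError("mask must be 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def area_um2(self) -> float:
        return float(self.pixels.sum()) * self.px_size_um**2


@dataclass
class SegmentationConfig:
    """Parameters of the two-threshold segmentation.

    Defaults suit dense-haired Medicago brightfield images at the original
    acquisition scale:
    Bernsen radius 5 px with 5 smoothing iterations for the root+hairs mask;
    Phansalkar radius 100 px with a closing of 10 iterations and an opening
    of 12 iterations for the root body. The Bernsen contrast threshold (15 on
    the 8-bit scale) and the Phansalkar constants (k=0.25, r=0.5, p=2, q=10)
    are the standard defaults of those methods.
    """

    bernsen_radius: int = 5
    bernsen_contrast: float = 15.0
    phansalkar_radius: int = 100
    phansalkar_k: float = 0.25
    phansalkar_r: float = 0.5
    phansalkar_p: float = 2.0
    phansalkar_q: float = 10.0
    smooth_iters_hairs: int = 5
    smooth_iters_body_close: int = 10
    smooth_iters_body_open: int = 12
    fill_hairs: bool = True
    fill_body: bool = True
    dark_objects: bool = True

    def __post_init__(self) -> None:
        if self.bernsen_radius < 1 or self.phansalkar_radius < 1:
            raise ValueError("threshold radii must be >= 1")
        for name in ("smooth_iters_hairs", "smooth_iters_body_close", "smooth_iters_body_open"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def _disk_mean_std(x: np.ndarray, radius: int) -> tuple[np.ndarray, np.ndarray]:
    """Local mean and standard deviation in a disk, reflect-padded borders."""
    fp = disk(radius).astype(np.float64)
    area = fp.sum()
    xp = np.pad(x, radius, mode="reflect")
    m = fftconvolve(xp, fp, mode="valid") / area
    m2 = fftconvolve(xp * xp, fp, mode="valid") / area
    var = np.clip(m2 - m * m, 0.0, None)
    return m, np.sqrt(var)


def _bernsen(img: np.ndarray, radius: int, contrast: float, half_range: float) -> np.ndarray:
    """Bernsen local threshold, bright-object convention.

    With local min m and max M in a disk of radius ``radius``: where the
    local contrast M - m reaches ``contrast`` a pixel is foreground iff it
    lies above the local midgrey (m + M) / 2; in flat neighbourhoods the
    whole region is classed by whether the midgrey exceeds half the dynamic
    range.
    """
    fp = disk(radius).astype(bool)
    mn = ndi.minimum_filter(img, footprint=fp, mode="nearest")
    mx = ndi.maximum_filter(img, footprint=fp, mode="nearest")
    mid = (mn.astype(np.float64) + mx) / 2.0
    has_contrast = (mx.astype(np.float64) - mn) >= contrast
    return np.where(has_contrast, img > mid, mid > half_range)


def _phansalkar(
    img01: np.ndarray, radius: int, k: float, r: float, p: float, q: float
) -> np.ndarray:
    """Phansalkar local threshold on [0, 1] intensities, bright-object convention.

    t = mean * (1 + p * exp(-q * mean) + k * (std / r - 1)); foreground iff
    the pixel exceeds t. Tuned for low-contrast bright objects.
    """
    mean, std = _disk_mean_std(img01, radius)
    t = mean * (1.0 + p * np.exp(-q * mean) + k * (std / r - 1.0))
    return img01 > t


def local_threshold(
    img: IntensityImage, method: str, cfg: SegmentationConfig | None = None
) -> BinaryMask:
    """Threshold an image with the Bernsen or Phansalkar local method.

    ``cfg.dark_objects`` selects the object polarity: when True (the default,
    matching brightfield images of dark structures on a bright background)
    both methods are applied to the photometric inverse of the image, which
    makes inverting the image and toggling the flag an exact symmetry.
    """
    cfg = cfg or SegmentationConfig()
    maxval = 2**img.bit_depth - 1
    pixels = img.pixels.astype(np.float64)
    if cfg.dark_objects:
        pixels = maxval - pixels

    if method == "bernsen":
        r = cfg.bernsen_radius
        if r >= min(img.shape) / 2:
            raise ValueError(f"bernsen_radius {r} too large for image {img.shape}")
        fg = _bernsen(pixels, r, cfg.bernsen_contrast, maxval / 2.0)
        role = "root_with_hairs"
    elif method == "phansalkar":
        r = cfg.phansalkar_radius
        if r >= min(img.shape) / 2:
            raise ValueError(f"phansalkar_radius {r} too large for image {img.shape}")
        fg = _phansalkar(
            pixels / maxval,
            r,
            cfg.phansalkar_k,
            cfg.phansalkar_r,
            cfg.phansalkar_p,
            cfg.phansalkar_q,
        )
        role = "root_body"
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    return BinaryMask(fg, img.px_size_um, role)


def smooth_mask(
    mask: BinaryMask, n_dilate: int, n_erode: int, fill: bool = False
) -> BinaryMask:
    """Dilate, then erode, then optionally fill interior holes.

    Uses a fixed 3x3 square (8-connected) structuring element throughout.
    Hole filling sets to foreground every background component that does not
    touch the image border (4-connected background flood).
    """
    px = mask.pixels
    if n_dilate:
        px = ndi.binary_dilation(px, structure=_SQUARE3, iterations=n_dilate)
    if n_erode:
        px = ndi.binary_erosion(px, structure=_SQUARE3, iterations=n_erode)
    if fill:
        px = ndi.binary_fill_holes(px)
    return BinaryMask(px, mask.px_size_um, mask.role)


def build_masks(
    img: IntensityImage, cfg: SegmentationConfig | None = None
) -> tuple[BinaryMask, BinaryMask, BinaryMask]:
    """Run the full segmentation: (root_with_hairs, root_body, hairs_only).

    root_with_hairs: Bernsen threshold, closed (dilate/erode
    ``smooth_iters_hairs`` times) and hole-filled.
    root_body: Phansalkar threshold, closed and hole-filled
    (``smooth_iters_body_close``), then opened (``smooth_iters_body_open``
    erosions followed by the same number of dilations, which removes the
    thin hairs), then restricted to root_with_hairs and reduced to its
    largest connected object (the root).
    hairs_only: root_with_hairs minus root_body.

    By construction hairs_only is disjoint from root_body and contained in
    root_with_hairs.
    """
    cfg = cfg or SegmentationConfig()

    rwh = local_threshold(img, "bernsen", cfg)
    rwh = smooth_mask(rwh, cfg.smooth_iters_hairs, cfg.smooth_iters_hairs, fill=cfg.fill_hairs)

    body = local_threshold(img, "phansalkar", cfg)
    body = smooth_mask(
        body, cfg.smooth_iters_body_close, cfg.smooth_iters_body_close, fill=cfg.fill_body
    )
    bp = body.pixels
    n = cfg.smooth_iters_body_open
    if n:
        bp = ndi.binary_erosion(bp, structure=_SQUARE3, iterations=n)
        bp = ndi.binary_dilation(bp, structure=_SQUARE3, iterations=n)
    bp = bp & rwh.pixels  # clear body pixels falling outside the root+hairs mask
    if not bp.any():
        raise ValueError("no root body detected (empty root_body mask)")
    lab, n_comp = ndi.label(bp, structure=_SQUARE3)
    if n_comp > 1:  # the root is the largest remaining object
        sizes = ndi.sum_labels(bp, lab, index=np.arange(1, n_comp + 1))
        bp = lab == (1 + int(np.argmax(sizes)))
    bp = ndi.binary_fill_holes(bp)  # the body is solid; pinholes break its skeleton
    body = BinaryMask(bp, img.px_size_um, "root_body")

    hairs = BinaryMask(rwh.pixels & ~bp, img.px_size_um, "hairs_only")
    return rwh, body, hairs
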