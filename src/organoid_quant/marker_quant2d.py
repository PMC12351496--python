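"""2D fluorescence-marker quantification.

The coverage chain mirrors the acquisition protocol for nuclear/cytoplasmic
markers (PAX6, CTIP2, TBR1, GFAP): mean z-projection over a block of planes,
then median filtering → background removal → H-minima transform → CLAHE,
Otsu binarization, and finally area fraction plus integrated density of the
foreground. The same primitives serve the synaptic-marker measurements
(threshold + area/integrated density, mask colocalization) and the
mitochondria readout (object count and per-object length restricted to a
neurite path mask, replacing manual freehand tracing).

Integrated density is always computed on the *raw* image under the final
mask: CLAHE destroys intensity linearity, and integrated signal density is
conventionally a sum of raw intensities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import exposure, measure
from skimage.filters import threshold_otsu, threshold_triangle
from skimage.morphology import reconstruction

from organoid_quant.core_io import Image2D, ImageStack3D, ValidationError

OTSU_NBINS = 256


@dataclass
class Preprocess2DParams:
    """Tunables of the 2D preprocessing chain.

    ``median_size_px`` is the side of the square median window (odd, ≥ 1).
    ``hminima_depth`` is the depth H of the H-minima transform on the
    normalized [0, 1] scale. Background removal subtracts a scalar
    background level estimated from the intensity histogram (see
    :func:`estimate_background`).
    """

    median_size_px: int = 5
    hminima_depth: float = 0.05
    clahe_clip: float = 0.01
    clahe_tile_px: int = 64
    background_method: str = "histogram_peak_offset"
    background_peak_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.median_size_px < 1 or self.median_size_px % 2 == 0:
            raise ValidationError("median_size_px must be odd and >= 1")
        if not 0.0 <= self.hminima_depth <= 1.0:
            raise ValidationError("hminima_depth must lie in [0, 1]")
        if not 0.0 < self.background_peak_fraction < 1.0:
            raise ValidationError("background_peak_fraction must lie in (0, 1)")
        if self.background_method not in ("histogram_peak_offset", "triangle"):
            raise ValidationError(f"unknown background method {self.background_method!r}")


@dataclass
class CoverageResult:
    """Foreground coverage of a field of view."""

    area_fraction: float
    integrated_density: float
    n_foreground_px: int


@dataclass
class ObjectStats:
    """Connected-object statistics inside a region of interest."""

    n_objects: int
    lengths_um: list[float] = field(default_factory=list)
    mean_length_um: float = 0.0
    empty: bool = False


def zproject_mean(stack: ImageStack3D, n_planes: int) -> Image2D:
    """Mean z-projection over ``n_planes`` planes centered on the stack midpoint."""
    z = stack.voxels.shape[0]
    if n_planes < 1:
        raise ValidationError("n_planes must be >= 1")
    if n_planes > z:
        raise ValidationError(f"n_planes={n_planes} exceeds stack depth Z={z}")
    start = (z - n_planes) // 2
    proj = stack.voxels[start : start + n_planes].mean(axis=0)
    return Image2D(proj, pixel_size_um=stack.voxel_size_um[2])


def estimate_background(
    pixels: np.ndarray,
    method: str = "histogram_peak_offset",
    peak_fraction: float = 0.5,
    nbins: int = OTSU_NBINS,
) -> float:
    """Estimate a scalar background level from the intensity histogram.

    ``histogram_peak_offset`` locates the histogram mode (the background
    peak) and walks toward higher intensities until the bin count first falls
    below ``peak_fraction`` of the mode count; the center of that bin is the
    background level. ``triangle`` uses the triangle threshold instead.
    """
    if method == "triangle":
        return float(threshold_triangle(pixels, nbins=nbins))
    hist, edges = np.histogram(pixels, bins=nbins, range=(0.0, 1.0))
    centers = 0.5 * (edges[:-1] + edges[1:])
    mode = int(np.argmax(hist))
    cutoff = peak_fraction * hist[mode]
    for i in range(mode + 1, nbins):
        if hist[i] < cutoff:
            return float(centers[i])
    return float(centers[-1])


def hminima_transform(pixels: np.ndarray, depth: float) -> np.ndarray:
    """Suppress local minima shallower than ``depth``.

    Implemented as morphological reconstruction by erosion of ``f + depth``
    over ``f``; regional minima whose depth is below ``depth`` are filled.
    """
    if depth == 0:
        return pixels.copy()
    return reconstruction(pixels + depth, pixels, method="erosion")


def preprocess2d(img: Image2D, params: Preprocess2DParams | None = None) -> Image2D:
    """Denoise and equalize a normalized 2D image.

    Applies, in order: square median filtering, scalar background
    subtraction (clamped at 0), the H-minima transform, and CLAHE. Input and
    output are on the [0, 1] scale. A constant image maps to all zeros (the
    background equals the constant).
    """
    p = params or Preprocess2DParams()
    a = img.pixels
    if a.min() < 0 or a.max() > 1:
        raise ValidationError("preprocess2d expects intensities normalized to [0, 1]")

    a = ndi.median_filter(a, size=p.median_size_px)
    bg = estimate_background(a, p.background_method, p.background_peak_fraction)
    a = np.clip(a - bg, 0.0, None)
    if a.max() == a.min():
        # all background (flat field): nothing to equalize or threshold
        return Image2D(
            np.zeros_like(a), pixel_size_um=img.pixel_size_um, channel_names=list(img.channel_names)
        )
    a = np.clip(hminima_transform(a, p.hminima_depth), 0.0, 1.0)
    if a.max() > a.min():
        a = exposure.equalize_adapthist(
            a, kernel_size=p.clahe_tile_px, clip_limit=p.clahe_clip, nbins=OTSU_NBINS
        )
    return Image2D(a, pixel_size_um=img.pixel_size_um, channel_names=list(img.channel_names))


def binarize_otsu(img: Image2D | ImageStack3D | np.ndarray) -> np.ndarray:
    """Binarize by Otsu's method (256-bin histogram, maximum between-class variance).

    Foreground is strictly above the threshold, so ties go to background. A
    constant image yields an empty foreground with a warning rather than an
    error, so degenerate fields do not abort a batch.
    """
    if isinstance(img, Image2D):
        arr = img.pixels
    elif isinstance(img, ImageStack3D):
        arr = img.voxels
    else:
        arr = np.asarray(img, dtype=float)
    if arr.min() == arr.max():
        warnings.warn("constant image: Otsu undefined, returning empty foreground")
        return np.zeros(arr.shape, dtype=bool)
    thresh = threshold_otsu(arr, nbins=OTSU_NBINS)
    return arr > thresh


def coverage(mask: np.ndarray, raw_img: Image2D | np.ndarray) -> CoverageResult:
    """Area fraction and integrated density of ``mask`` over the raw image."""
    raw = raw_img.pixels if isinstance(raw_img, Image2D) else np.asarray(raw_img, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != raw.shape:
        raise ValidationError(f"mask shape {mask.shape} != image shape {raw.shape}")
    n_fg = int(mask.sum())
    return CoverageResult(
        area_fraction=n_fg / mask.size,
        integrated_density=float(raw[mask].sum()) if n_fg else 0.0,
        n_foreground_px=n_fg,
    )


def colocalize(
    mask_a: np.ndarray, mask_b: np.ndarray, raw_img_a: Image2D | np.ndarray
) -> CoverageResult:
    """Coverage of the pixelwise overlap of two marker masks.

    Measures how much of the field carries both signals (e.g. pre- and
    post-synaptic puncta); symmetric in area terms.
    """
    mask_a = np.asarray(mask_a, dtype=bool)
    mask_b = np.asarray(mask_b, dtype=bool)
    if mask_a.shape != mask_b.shape:
        raise ValidationError(f"mask shapes differ: {mask_a.shape} vs {mask_b.shape}")
    return coverage(mask_a & mask_b, raw_img_a)


def objects_in_path(
    mask: np.ndarray, path_mask: np.ndarray, pixel_size_um: float
) -> ObjectStats:
    """Count and measure connected objects restricted to a path mask.

    The path mask marks the neurite region of interest (e.g. an axon,
    excluding the soma); the object mask is intersected with it before
    8-connected labeling. Object length is the major-axis length of the
    labeled region in µm, with a floor of one pixel so isolated single-pixel
    objects report ``pixel_size_um`` rather than zero.
    """
    mask = np.asarray(mask, dtype=bool)
    path_mask = np.asarray(path_mask, dtype=bool)
    if mask.shape != path_mask.shape:
        raise ValidationError("mask and path_mask shapes differ")
    if not path_mask.any():
        raise ValidationError("path_mask is empty")
    labels = measure.label(mask & path_mask, connectivity=2)
    lengths = [
        max(prop.axis_major_length, 1.0) * pixel_size_um
        for prop in measure.regionprops(labels)
    ]
    if not lengths:
        warnings.warn("no objects inside path mask; mean length reported as 0")
        return ObjectStats(n_objects=0, lengths_um=[], mean_length_um=0.0, empty=True)
    return ObjectStats(
        n_objects=len(lengths),
        lengths_um=lengths,
        mean_length_um=float(np.mean(lengths)),
    )
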