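"""Micrograph loading and ridge-based segmentation of curvilinear structures.

Turns a raw fluorescence image into a clean one-pixel-wide skeleton of
candidate dendritic branches: grayscale conversion, multi-scale Frangi
vesselness enhancement, slider-style intensity thresholding, small-object
removal, and topology-preserving skeletonization.

Conventions used throughout the package: pixel coordinates are row-major and
0-based with the origin at the top-left corner (x rightward = columns,
y downward = rows); connected components and skeleton neighborhoods use
8-connectivity.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
from skimage import color as _color
from skimage import filters as _filters
from skimage import morphology as _morphology

__all__ = [
    "RawImage",
    "SegmentationParams",
    "load_image",
    "to_grayscale",
    "frangi_enhance",
    "map_threshold_slider",
    "binarize",
    "remove_small_objects",
    "skeletonize_mask",
    "segment_image",
]

#: Minimum admissible image side, in pixels.
MIN_IMAGE_SIDE = 16


@dataclass(frozen=True)
class RawImage:
    """A grayscale micrograph with intensities on the 0-255 scale."""

    pixels: np.ndarray
    source_path: str = "<memory>"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise ValueError("RawImage requires a 2D grayscale array")
        if min(px.shape) < MIN_IMAGE_SIDE:
            raise ValueError(
                f"image {self.source_path!r} is {px.shape[0]}x{px.shape[1]}; "
                f"both sides must be >= {MIN_IMAGE_SIDE} px"
            )
        if px.min() < 0 or px.max() > 255:
            raise ValueError("grayscale intensities must lie within [0, 255]")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable knobs of the segmentation stage.

    ``sigma_min``/``sigma_max``/``sigma_step`` span the vesselness scales in
    pixels (defaults cover branch widths up to ~7 px with 14 scales);
    ``threshold_slider`` and ``length_slider`` are the 1-10 integer sliders
    mapped onto the 0-255 intensity range and the 5-200 px length range.
    ``frangi_beta``/``frangi_gamma`` are the conventional blobness and
    structureness constants of the vesselness measure, applied to the image
    rescaled to [0, 1].
    """

    sigma_min: float = 0.25
    sigma_max: float = 3.5
    sigma_step: float = 0.25
    threshold_slider: int = 2
    min_object_px: int = 20
    length_slider: int | None = None
    min_length_px: float | None = None
    frangi_beta: float = 0.5
    frangi_gamma: float = 15.0

    def __post_init__(self) -> None:
        if self.sigma_min > self.sigma_max:
            raise ValueError("sigma_min must not exceed sigma_max")
        if self.sigma_step <= 0:
            raise ValueError("sigma_step must be positive")
        if not (1 <= int(self.threshold_slider) <= 10):
            raise ValueError("threshold_slider must be an integer in 1..10")
        if self.min_object_px < 0:
            raise ValueError("min_object_px must be non-negative")
        if self.length_slider is not None and not (1 <= int(self.length_slider) <= 10):
            raise ValueError("length_slider must be an integer in 1..10 or None")

    @property
    def sigmas(self) -> np.ndarray:
        """The vesselness scale ladder (inclusive of sigma_max)."""
        return np.arange(self.sigma_min, self.sigma_max + 1e-9, self.sigma_step)


def to_grayscale(pixels: np.ndarray) -> np.ndarray:
    """Collapse an image array to a float grayscale grid on the 0-255 scale.

    RGB(A) input is converted by the standard luma weighting; integer inputs
    of any bit depth are rescaled so that the dtype maximum maps to 255.
    """
    px = np.asarray(pixels)
    if px.ndim == 3:
        if px.shape[2] == 4:  # drop alpha
            px = px[:, :, :3]
        if px.shape[2] != 3:
            raise ValueError(f"cannot interpret image with {px.shape[2]} channels")
        if np.issubdtype(px.dtype, np.integer):
            px = px.astype(float) / np.iinfo(px.dtype).max
        gray = _color.rgb2gray(px)  # luma-weighted, range [0, 1]
        return gray * 255.0
    if px.ndim != 2:
        raise ValueError(f"expected a 2D or 3D image array, got shape {px.shape}")
    if np.issubdtype(px.dtype, np.integer):
        info = np.iinfo(px.dtype)
        if info.max > 255:  # e.g. 16-bit microscopy TIFF
            return px.astype(float) * (255.0 / info.max)
        return px.astype(float)
    return px.astype(float)


def load_image(path: str) -> RawImage:
    """Read a raster image (PNG/TIFF/JPG/BMP) as a grayscale :class:`RawImage`."""
    if not os.path.isfile(path):
        raise FileNotFoundError(f"image file not found: {path}")
    import imageio.v3 as iio

    try:
        raw = iio.imread(path)
    except Exception as exc:  # decoder-specific error classes vary by plugin
        raise ValueError(f"cannot decode image file {path}: {exc}") from exc
    return RawImage(to_grayscale(raw), source_path=str(path))


def frangi_enhance(img: RawImage, params: SegmentationParams | None = None) -> np.ndarray:
    """Multi-scale vesselness response, max-pooled over scales, in [0, 1].

    Bright curvilinear structures on a dark background score high.  The image
    is rescaled to [0, 1] before filtering so the structureness constant
    ``frangi_gamma`` acts on a normalized Hessian.
    """
    params = params or SegmentationParams()
    resp = _filters.frangi(
        img.pixels / 255.0,
        sigmas=params.sigmas,
        beta=params.frangi_beta,
        gamma=params.frangi_gamma,
        black_ridges=False,
    )
    peak = resp.max()
    if peak > 0:
        resp = resp / peak
    return np.clip(resp, 0.0, 1.0)


def map_threshold_slider(s: int) -> int:
    """Map the 1-10 intensity slider linearly onto the 0-255 grayscale range.

    ``t = round(25.5 * s)`` with half-up rounding, so slider 10 gives 255.
    """
    if int(s) != s or not (1 <= int(s) <= 10):
        raise ValueError(f"threshold slider must be an integer in 1..10, got {s!r}")
    return int(np.floor(25.5 * int(s) + 0.5))


def binarize(response: np.ndarray, threshold_slider: int) -> np.ndarray:
    """Threshold a [0, 1] ridge map: keep pixels with response*255 >= t(slider).

    Lower slider values admit fainter structures (mask monotonically shrinks
    as the slider rises).
    """
    response = np.asarray(response, dtype=float)
    t = map_threshold_slider(threshold_slider)
    return response * 255.0 >= t


def remove_small_objects(mask: np.ndarray, min_object_px: int = 20) -> np.ndarray:
    """Drop 8-connected components with area below ``min_object_px`` pixels."""
    mask = np.asarray(mask, dtype=bool)
    if min_object_px <= 1:
        return mask.copy()
    # skimage's threshold is exclusive-upper: max_size removes areas <= value.
    return _morphology.remove_small_objects(mask, max_size=min_object_px - 1, connectivity=2)


def skeletonize_mask(mask: np.ndarray) -> np.ndarray:
    """Thin a binary mask to its one-pixel-wide, topology-preserving skeleton."""
    return _morphology.skeletonize(np.asarray(mask, dtype=bool))


def segment_image(img: RawImage, params: SegmentationParams | None = None):
    """Run the full segmentation stage.

    Returns ``(ridge_map, binary_mask, skeleton)`` where the binary mask has
    already had sub-threshold small objects removed.
    """
    params = params or SegmentationParams()
    ridge = frangi_enhance(img, params)
    mask = binarize(ridge, params.threshold_slider)
    mask = remove_small_objects(mask, params.min_object_px)
    skeleton = skeletonize_mask(mask)
    return ridge, mask, skeleton
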