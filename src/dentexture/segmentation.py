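"""Front-face tooth segmentation.

Raw captures are binarized, cleaned with a morphological opening (erosion
followed by dilation with a 10x10 all-ones structuring element), and the
largest surviving contour's bounding box is used to crop the original
grayscale image. The opening removes isolated bright outliers smaller than
the structuring element while leaving the dominant tooth region intact.

Conventions: row-major 0-based coordinates; bounding boxes are half-open
``(row_min, col_min, row_max, col_max)``; for both morphological operators
anything outside the image grid counts as background.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage import measure
from skimage.filters import threshold_otsu

from .errors import NoForegroundError, ParameterError


@dataclass(frozen=True)
class StructuringElement:
    """Binary neighborhood mask with an anchor offset inside its extent."""

    mask: np.ndarray  # 2D {0,1}
    anchor: tuple[int, int]

    def __post_init__(self):
        m = np.asarray(self.mask)
        if m.ndim != 2 or not m.any():
            raise ParameterError("structuring element needs at least one active cell")
        ar, ac = self.anchor
        if not (0 <= ar < m.shape[0] and 0 <= ac < m.shape[1]):
            raise ParameterError("anchor must lie inside the mask extent")

    @classmethod
    def square(cls, size: int) -> "StructuringElement":
        """All-ones size x size element anchored at the center cell."""
        if size < 1:
            raise ParameterError("structuring element size must be >= 1")
        return cls(np.ones((size, size), dtype=bool), (size // 2, size // 2))


#: Default kernel of the cleaning stage.
DEFAULT_SE = StructuringElement.square(10)


def _as_binary(img: np.ndarray) -> np.ndarray:
    a = np.asarray(img)
    if a.ndim != 2:
        raise ParameterError("binary image must be 2D")
    if a.dtype != bool and not np.isin(a, (0, 1)).all():
        raise ParameterError("binary image must contain only {0,1}")
    return a.astype(bool)


def binarize(img, threshold_method: str = "otsu", fixed_value: float | None = None):
    """Threshold a [0,1] grayscale image; pixel = 1 iff intensity >= threshold.

    A constant image defeats Otsu's between-class-variance criterion; in that
    case the mid-range threshold 0.5 is used and a warning is emitted.
    """
    a = np.asarray(img, dtype=np.float64)
    if threshold_method == "fixed":
        if fixed_value is None or not 0 < fixed_value < 1:
            raise ParameterError("fixed threshold must lie in (0, 1)")
        t = fixed_value
    elif threshold_method == "otsu":
        if np.ptp(a) == 0:
            warnings.warn("constant image: Otsu undefined, using mid-range 0.5")
            t = 0.5
        else:
            t = threshold_otsu(a)
    else:
        raise ParameterError(f"unknown threshold method {threshold_method!r}")
    return a >= t


def _shift(img: np.ndarray, dr: int, dc: int) -> np.ndarray:
    """Translate a boolean grid by (dr, dc), filling with background."""
    out = np.zeros_like(img)
    h, w = img.shape
    rs, re = max(dr, 0), min(h + dr, h)
    cs, ce = max(dc, 0), min(w + dc, w)
    if rs < re and cs < ce:
        out[rs:re, cs:ce] = img[rs - dr : re - dr, cs - dc : ce - dc]
    return out


def erode(img, se: StructuringElement = DEFAULT_SE) -> np.ndarray:
    """Set-definition erosion: output z is 1 iff the element translated to z
    fits entirely inside the foreground (out-of-bounds = background)."""
    a = _as_binary(img)
    ar, ac = se.anchor
    out = np.ones_like(a)
    for i, j in zip(*np.nonzero(np.asarray(se.mask))):
        out &= _shift(a, -(int(i) - ar), -(int(j) - ac))
    return out


def dilate(img, se: StructuringElement = DEFAULT_SE) -> np.ndarray:
    """Minkowski-sum dilation: union of element translates over foreground
    pixels; contributions falling outside the grid are discarded."""
    a = _as_binary(img)
    ar, ac = se.anchor
    out = np.zeros_like(a)
    for i, j in zip(*np.nonzero(np.asarray(se.mask))):
        out |= _shift(a, int(i) - ar, int(j) - ac)
    return out


def opening(img, se: StructuringElement = DEFAULT_SE) -> np.ndarray:
    return dilate(erode(img, se), se)


@dataclass(frozen=True)
class ContourRegion:
    """One 8-connected foreground component."""

    boundary: np.ndarray  # ordered (row, col) coordinates, closed
    bounding_box: tuple[int, int, int, int]  # half-open (r0, c0, r1, c1)
    area: int


def find_contours(img) -> list[ContourRegion]:
    """Regions of an 8-connected component labeling, largest area first."""
    a = _as_binary(img)
    if not a.any():
        return []
    labels = measure.label(a, connectivity=2)
    regions = []
    for prop in measure.regionprops(labels):
        comp = labels == prop.label
        padded = np.pad(comp.astype(float), 1)
        contours = measure.find_contours(padded, 0.5)
        boundary = max(contours, key=len) - 1.0  # undo padding offset
        regions.append(
            ContourRegion(
                boundary=boundary,
                bounding_box=tuple(int(v) for v in prop.bbox),
                area=int(prop.area),
            )
        )
    regions.sort(key=lambda r: r.area, reverse=True)
    return regions


def extract_front_face(
    img,
    se_size: int = 10,
    pad: int = 2,
    threshold_method: str = "otsu",
    fixed_value: float | None = None,
) -> np.ndarray:
    """Crop the front-facing tooth region from a grayscale image.

    Pipeline: binarize -> opening (``se_size`` square element) ->
    contours -> crop the original image to the largest region's bounding
    box expanded by ``pad`` and clipped to the image bounds.
    """
    a = np.asarray(img, dtype=np.float64)
    if a.size == 0:
        raise ParameterError("empty image")
    binary = binarize(a, threshold_method, fixed_value)
    cleaned = opening(binary, StructuringElement.square(se_size))
    regions = find_contours(cleaned)
    if not regions:
        raise NoForegroundError("no foreground found after morphological cleaning")
    r0, c0, r1, c1 = regions[0].bounding_box
    r0 = max(r0 - pad, 0)
    c0 = max(c0 - pad, 0)
    r1 = min(r1 + pad, a.shape[0])
    c1 = min(c1 + pad, a.shape[1])
    return a[r0:r1, c0:c1]
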