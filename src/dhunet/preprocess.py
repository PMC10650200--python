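"""Region-of-interest preprocessing for wound photographs.

The pipeline turns a raw photo/mask pair into a standardised network
input: grayscale conversion with a smoothing filter, intensity
thresholding, detection of the largest bright contour, cropping both
rasters to its bounding box, and resizing to the model input size
(128 x 128 by default) with [0, 1] image values and a re-binarised mask.
Its practical job is to discard the all-black bands some photographs
carry while keeping every content pixel.

Coordinate conventions, stated once: pixels are 0-based with x = column
and y = row; crop boxes are half-open ``[x0, x1) x [y0, y1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure, transform

from .config import BlurConfig, PreprocessConfig
from .exceptions import ValidationError

LUMA_WEIGHTS = (0.299, 0.587, 0.114)  # ITU-R 601


# ---------------------------------------------------------------------
# blur + grayscale
# ---------------------------------------------------------------------

def gaussian_kernel(kernel: int, sigma_x: float, sigma_y: float) -> np.ndarray:
    """Discrete 2-D Gaussian on a ``kernel x kernel`` support, normalised
    to unit sum.

    The window is centred (mu at the middle tap) and the amplitude drops
    out under normalisation, so only the two standard deviations matter.
    """
    half = kernel // 2
    x = np.arange(-half, half + 1, dtype=float)
    gx = np.exp(-(x ** 2) / (2.0 * sigma_x ** 2))
    gy = np.exp(-(x ** 2) / (2.0 * sigma_y ** 2))
    k = np.outer(gy, gx)
    return k / k.sum()


def blur_gray(image: np.ndarray, cfg: BlurConfig) -> np.ndarray:
    """Luminance conversion followed by the configured blur; 8-bit output."""
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValidationError(f"expected H x W x 3 image, got shape {image.shape}")
    r, g, b = LUMA_WEIGHTS
    gray = r * image[..., 0] + g * image[..., 1] + b * image[..., 2]
    if cfg.mode == "median":
        # replicate ("nearest") borders: a 1-pixel black band must stay
        # black under the median rather than absorb reflected content
        out = ndimage.median_filter(
            np.rint(gray).astype(np.uint8), size=cfg.kernel, mode="nearest")
        return out
    k = gaussian_kernel(cfg.kernel, cfg.sigma_x, cfg.sigma_y)
    out = ndimage.convolve(gray, k, mode="nearest")
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def binarize(gray: np.ndarray, threshold: int) -> np.ndarray:
    """Map pixels strictly above ``threshold`` to 255, the rest to 0."""
    if not 0 <= threshold <= 255:
        raise ValidationError(f"threshold must be in [0, 255], got {threshold}")
    return np.where(gray > threshold, 255, 0).astype(np.uint8)


# ---------------------------------------------------------------------
# contours
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class Contour:
    """Closed outer boundary of a bright region, as ordered pixel vertices.

    ``vertices`` is an (n, 2) integer array of (x, y) boundary-pixel
    coordinates; ``area`` is the shoelace area of that pixel-centre
    polygon.  ``approx`` is the Douglas-Peucker simplification and
    ``far_point`` its vertex farthest from the contour centroid.
    """

    vertices: np.ndarray
    area: float
    approx: np.ndarray = field(repr=False, default=None)

    @property
    def centroid(self) -> tuple[float, float]:
        return tuple(self.vertices.mean(axis=0))

    @property
    def far_point(self) -> tuple[int, int]:
        pts = self.approx if self.approx is not None and len(self.approx) else self.vertices
        c = np.asarray(self.centroid)
        d = ((pts - c) ** 2).sum(axis=1)
        return tuple(int(v) for v in pts[int(d.argmax())])

    @property
    def max_x(self) -> int:
        return int(self.vertices[:, 0].max())

    @property
    def max_y(self) -> int:
        return int(self.vertices[:, 1].max())


def _shoelace(pts: np.ndarray) -> float:
    x, y = pts[:, 0].astype(float), pts[:, 1].astype(float)
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def _snap_to_region(poly_rc: np.ndarray, region: np.ndarray) -> np.ndarray:
    """Snap marching-squares vertices (sub-pixel) onto region boundary pixels."""
    h, w = region.shape
    snapped = []
    for r, c in poly_rc:
        found = None
        for rr in (int(np.floor(r)), int(np.ceil(r))):
            for cc in (int(np.floor(c)), int(np.ceil(c))):
                if 0 <= rr < h and 0 <= cc < w and region[rr, cc]:
                    found = (cc, rr)  # (x, y)
                    break
            if found:
                break
        if found and (not snapped or snapped[-1] != found):
            snapped.append(found)
    if len(snapped) > 1 and snapped[0] == snapped[-1]:
        snapped.pop()
    return np.asarray(snapped, dtype=int)


def extract_largest_contour(binary: np.ndarray,
                            dp_tolerance_frac: float = 0.01) -> Contour | None:
    """Trace outer boundaries of 255-regions and return the largest by area.

    Areas follow the pixel-centre shoelace convention (a filled ``w x h``
    rectangle scores ``(w-1)*(h-1)``).  Returns ``None`` when the raster
    holds no foreground.
    """
    fg = binary > 0
    if not fg.any():
        return None
    labels = measure.label(fg, connectivity=2)
    best: Contour | None = None
    for region_label in range(1, labels.max() + 1):
        region = labels == region_label
        padded = np.pad(region, 1).astype(float)
        polys = measure.find_contours(padded, 0.5)
        if not polys:
            continue
        outer = max(polys, key=lambda p: _shoelace(p))
        verts = _snap_to_region(outer - 1.0, region)
        if len(verts) < 3:
            # tiny region (single pixel / thin line): keep it with zero area
            verts = np.asarray([(c, r) for r, c in np.argwhere(region)][:3], dtype=int)
            if len(verts) < 3:
                verts = np.vstack([verts] * 3)[:3]
        area = _shoelace(verts)
        if best is None or area > best.area:
            perimeter = np.abs(np.diff(verts, axis=0, append=verts[:1])).sum()
            tol = dp_tolerance_frac * perimeter
            approx_rc = measure.approximate_polygon(
                verts[:, ::-1].astype(float), tolerance=tol)
            best = Contour(vertices=verts, area=float(area),
                           approx=approx_rc[:, ::-1].astype(int))
    return best


# ---------------------------------------------------------------------
# cropping and standardisation
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class CropBox:
    """Half-open pixel window ``[x0, x1) x [y0, y1)``."""

    x0: int
    y0: int
    x1: int
    y1: int

    def __post_init__(self):
        if self.x1 <= self.x0 or self.y1 <= self.y0:
            raise ValidationError(f"degenerate crop box {self}")

    @property
    def width(self) -> int:
        return self.x1 - self.x0

    @property
    def height(self) -> int:
        return self.y1 - self.y0


def compute_crop_box(contour: Contour, bounds: tuple[int, int]) -> CropBox:
    """Axis-aligned bounding box of the contour, clamped to ``(H, W)``."""
    h, w = bounds
    x0 = max(int(contour.vertices[:, 0].min()), 0)
    y0 = max(int(contour.vertices[:, 1].min()), 0)
    x1 = min(int(contour.vertices[:, 0].max()) + 1, w)
    y1 = min(int(contour.vertices[:, 1].max()) + 1, h)
    return CropBox(x0, y0, x1, y1)


def apply_crop(image: np.ndarray, mask: np.ndarray, box: CropBox
               ) -> tuple[np.ndarray, np.ndarray]:
    """Crop image and mask with the identical window."""
    if image.shape[:2] != mask.shape:
        raise ValidationError(
            f"image/mask shape mismatch: {image.shape[:2]} vs {mask.shape}")
    h, w = mask.shape
    if not (0 <= box.x0 < box.x1 <= w and 0 <= box.y0 < box.y1 <= h):
        raise ValidationError(f"crop box {box} outside {h}x{w} raster")
    return (image[box.y0:box.y1, box.x0:box.x1].copy(),
            mask[box.y0:box.y1, box.x0:box.x1].copy())


@dataclass(frozen=True)
class PreprocessedSample:
    """Standardised network input: image in [0, 1], binary mask, provenance."""

    image: np.ndarray
    mask: np.ndarray
    crop_box: CropBox | None = None
    source: tuple[str, str] | None = None


def standardize(image: np.ndarray, mask: np.ndarray,
                target_size: int = 128) -> PreprocessedSample:
    """Resize to ``target_size`` squared; image bilinear then scaled to
    [0, 1], mask nearest-neighbour then re-binarised at 0.5."""
    if target_size < 8:
        raise ValidationError(f"target_size must be >= 8, got {target_size}")
    if image.size == 0 or mask.size == 0:
        raise ValidationError("empty input")
    img = transform.resize(image.astype(float), (target_size, target_size),
                           order=1, preserve_range=True, anti_aliasing=False)
    msk = transform.resize(mask.astype(float), (target_size, target_size),
                           order=0, preserve_range=True, anti_aliasing=False)
    img = np.clip(img / 255.0, 0.0, 1.0)
    return PreprocessedSample(image=img, mask=(msk >= 0.5).astype(np.uint8))


def preprocess_sample(image: np.ndarray, mask: np.ndarray,
                      cfg: PreprocessConfig | None = None,
                      source: tuple[str, str] | None = None
                      ) -> PreprocessedSample:
    """Full pipeline: blur/gray -> threshold -> largest contour -> crop ->
    standardise.  Falls back to the identity crop when no contour exists,
    so no sample is ever discarded."""
    cfg = cfg or PreprocessConfig()
    gray = blur_gray(image, cfg.blur)
    binary = binarize(gray, cfg.threshold)
    contour = extract_largest_contour(binary, cfg.dp_tolerance_frac)
    h, w = mask.shape
    box = CropBox(0, 0, w, h) if contour is None else compute_crop_box(contour, (h, w))
    img_c, msk_c = apply_crop(image, mask, box)
    std = standardize(img_c, msk_c, cfg.target_size)
    return PreprocessedSample(image=std.image, mask=std.mask,
                              crop_box=box, source=source)
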