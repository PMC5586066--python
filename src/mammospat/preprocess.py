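"""Breast-region extraction and enhancement for MLO mammograms.

The preprocessing chain separates the breast from the background, labels and
tags, and from the pectoral muscle, and enhances the image for tissue
clustering.  The fixed stage order is: intensity rescale + adaptive Wiener
denoising (digitised film only), logarithmic contrast enhancement, three-class
Otsu multi-thresholding (keep the two brightest classes), largest connected
component + morphological smoothing, then pectoral-muscle removal.

Pectoral removal here is a simplified straight-line, gradient-guided cut:
high-intensity pixels in the pectoral corner are bounded by a least-squares
line through the muscle edge and removed.  It is not a faithful texture
gradient pectoral segmentation; downstream analysis only needs a
pectoral-free mask.

Coordinates are row-major, origin at the top-left, 0-based.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage import measure, morphology

from .errors import (
    DegenerateHistogramError,
    InvalidImageError,
    NoBreastFoundError,
)

logger = logging.getLogger(__name__)

DEFAULT_WIENER_WINDOW = 5
DEFAULT_LOG_C = 9.0
N_HIST_BINS = 256


@dataclass
class MammogramImage:
    """Grayscale mammogram with intensities in [0, 1] and physical spacing."""

    pixels: np.ndarray
    pixel_spacing_mm: float
    source_kind: str = "digitised"  # or "digital-raw"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise InvalidImageError("image must be 2-D grayscale")
        if not np.all(np.isfinite(self.pixels)):
            raise InvalidImageError("image contains non-finite pixels")
        if self.pixels.min() < -1e-9 or self.pixels.max() > 1 + 1e-9:
            raise InvalidImageError("intensities must lie in [0, 1]")
        if self.pixel_spacing_mm <= 0:
            raise InvalidImageError("pixel_spacing_mm must be > 0")
        if self.source_kind not in ("digitised", "digital-raw"):
            raise InvalidImageError(f"unknown source_kind {self.source_kind!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class BreastMask:
    """Binary breast-region mask aligned with its image."""

    mask: np.ndarray
    pixel_spacing_mm: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def breast_area_px(self) -> int:
        return int(self.mask.sum())

    @property
    def breast_area_mm2(self) -> float:
        return self.breast_area_px * self.pixel_spacing_mm**2


def load_image(
    path: str | Path, pixel_spacing_mm: float, source_kind: str = "digitised"
) -> MammogramImage:
    """Read an 8/16-bit grayscale PNG/TIFF (or DICOM) and rescale to [0, 1]."""
    path = Path(path)
    if path.suffix.lower() in (".dcm", ".dicom"):
        import pydicom

        arr = pydicom.dcmread(path).pixel_array.astype(float)
    else:
        import imageio.v3 as iio

        arr = iio.imread(path)
        if arr.ndim == 3:  # luminance of an already-gray RGB export
            arr = arr[..., :3].mean(axis=-1)
        if arr.dtype == np.uint8:
            arr = arr / 255.0
        elif arr.dtype == np.uint16:
            arr = arr / 65535.0
        arr = arr.astype(float)
    lo, hi = float(arr.min()), float(arr.max())
    if hi > 1.0 or lo < 0.0:
        arr = (arr - lo) / (hi - lo) if hi > lo else np.zeros_like(arr)
    return MammogramImage(arr, pixel_spacing_mm, source_kind)


def save_mask(path: str | Path, mask: BreastMask) -> None:
    """Write a mask as an 8-bit 0/255 PNG."""
    import imageio.v3 as iio

    iio.imwrite(Path(path), (mask.mask.astype(np.uint8) * 255))


def rescale_and_denoise(
    image: MammogramImage, window: int = DEFAULT_WIENER_WINDOW
) -> MammogramImage:
    """Pixelwise adaptive (Wiener) denoising of a digitised mammogram.

    Local means and variances over a ``window x window`` neighbourhood drive a
    signal-dependent linear minimum-mean-square-error smoother,
    ``out = mu + max(var - noise, 0) / var * (x - mu)``, with the noise
    variance estimated as the mean of the local variances.  Digital raw
    images pass through unchanged (their signal-to-noise ratio is high enough
    that denoising is unnecessary).
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be an odd positive integer")
    if image.source_kind == "digital-raw":
        return image
    x = image.pixels
    mu = ndimage.uniform_filter(x, size=window)
    var = np.maximum(ndimage.uniform_filter(x * x, size=window) - mu * mu, 0.0)
    noise = float(var.mean())
    with np.errstate(invalid="ignore", divide="ignore"):
        gain = np.where(var > noise, (var - noise) / np.maximum(var, 1e-300), 0.0)
    out = np.clip(mu + gain * (x - mu), 0.0, 1.0)
    return MammogramImage(out, image.pixel_spacing_mm, image.source_kind)


def enhance_contrast(image: MammogramImage, c: float = DEFAULT_LOG_C) -> MammogramImage:
    """Logarithmic contrast enhancement ``log(1 + c*x) / log(1 + c)``.

    A strictly increasing map of [0, 1] onto [0, 1] that brightens
    low-intensity pixels near the skin line.
    """
    if c <= 0:
        raise ValueError("log-transform constant c must be > 0")
    out = np.log1p(c * image.pixels) / np.log1p(c)
    return MammogramImage(np.clip(out, 0.0, 1.0), image.pixel_spacing_mm, image.source_kind)


def otsu_multithreshold(histogram: np.ndarray, n_classes: int = 3) -> tuple[int, int]:
    """Two Otsu thresholds (bin indices) maximising between-class variance.

    All ``(t1 < t2)`` bin pairs are searched exhaustively; classes are
    ``bins <= t1``, ``t1 < bins <= t2`` and ``bins > t2``.  Ties are broken
    towards the lexicographically smallest ``(t1, t2)``.
    """
    if n_classes != 3:
        raise ValueError("only the three-class (two-threshold) case is supported")
    h = np.asarray(histogram, dtype=float)
    if h.ndim != 1 or h.sum() <= 0:
        raise DegenerateHistogramError("histogram must be 1-D with positive total")
    if int(np.count_nonzero(h)) < n_classes:
        raise DegenerateHistogramError(
            f"need >= {n_classes} occupied bins, got {int(np.count_nonzero(h))}"
        )
    nbins = h.size
    p = h / h.sum()
    bins = np.arange(nbins, dtype=float)
    w = np.concatenate(([0.0], np.cumsum(p)))  # w[t] = P(bin < t)
    s = np.concatenate(([0.0], np.cumsum(p * bins)))
    # class (lo..hi] in threshold space: weight w[hi+1]-w[lo+1], sum s[hi+1]-s[lo+1]
    t1 = np.arange(nbins)[:, None]
    t2 = np.arange(nbins)[None, :]
    w1 = w[t1 + 1]
    w2 = w[t2 + 1] - w[t1 + 1]
    w3 = 1.0 - w[t2 + 1]
    s1 = s[t1 + 1]
    s2 = s[t2 + 1] - s[t1 + 1]
    s3 = s[nbins] - s[t2 + 1]
    with np.errstate(invalid="ignore", divide="ignore"):
        between = (
            np.where(w1 > 0, s1**2 / np.maximum(w1, 1e-300), 0.0)
            + np.where(w2 > 0, s2**2 / np.maximum(w2, 1e-300), 0.0)
            + np.where(w3 > 0, s3**2 / np.maximum(w3, 1e-300), 0.0)
        )
    between = np.where(t1 < t2, between, -np.inf)
    flat = int(np.argmax(between))  # first max: lexicographically smallest pair
    return flat // nbins, flat % nbins


def _intensity_bins(pixels: np.ndarray) -> np.ndarray:
    return np.minimum((pixels * N_HIST_BINS).astype(int), N_HIST_BINS - 1)


def segment_breast(image: MammogramImage, morph_radius: int | None = None) -> BreastMask:
    """Extract the breast mask from an enhanced mammogram.

    The 256-bin intensity histogram is split into three Otsu classes; the two
    brightest form the candidate foreground (breast plus tags/artefacts).
    The largest 8-connected component is kept, smoothed by morphological
    closing and opening with a disk (radius defaults to 1% of image width)
    and hole filling, and reduced to a single component.
    """
    binned = _intensity_bins(image.pixels)
    hist = np.bincount(binned.ravel(), minlength=N_HIST_BINS)
    try:
        t1, _ = otsu_multithreshold(hist)
    except DegenerateHistogramError as exc:
        raise NoBreastFoundError(f"image too flat to threshold: {exc}") from exc
    candidate = binned > t1
    if not candidate.any():
        raise NoBreastFoundError("no foreground pixels above the Otsu threshold")
    mask = _largest_component(candidate)
    if morph_radius is None:
        morph_radius = max(1, int(round(0.01 * image.pixels.shape[1])))
    selem = morphology.disk(morph_radius)
    mask = morphology.closing(mask, selem)
    mask = morphology.opening(mask, selem)
    mask = ndimage.binary_fill_holes(mask)
    if not mask.any():
        raise NoBreastFoundError("morphological smoothing removed all foreground")
    mask = _largest_component(mask)
    return BreastMask(mask, image.pixel_spacing_mm)


def _largest_component(binary: np.ndarray) -> np.ndarray:
    lab = measure.label(binary, connectivity=2)
    if lab.max() == 0:
        raise NoBreastFoundError("empty foreground")
    counts = np.bincount(lab.ravel())
    counts[0] = 0
    return lab == int(np.argmax(counts))


def detect_pectoral_corner(image: MammogramImage, mask: BreastMask) -> str:
    """Guess whether the pectoral muscle sits in the top-left or top-right.

    The brighter of the two top-corner windows (within the mask) wins.
    """
    h, w = image.shape
    win = image.pixels[: h // 4, :]
    m = mask.mask[: h // 4, :]
    left = win[:, : w // 4][m[:, : w // 4]]
    right = win[:, -w // 4 :][m[:, -w // 4 :]]
    lmean = left.mean() if left.size else 0.0
    rmean = right.mean() if right.size else 0.0
    return "left" if lmean >= rmean else "right"


def remove_pectoral(
    image: MammogramImage,
    mask: BreastMask,
    corner: str | None = None,
) -> BreastMask:
    """Cut the pectoral muscle out of the breast mask with a straight line.

    High-intensity pixels in the pectoral corner (components touching both
    the top edge and the chest wall) are located by a two-class Otsu split of
    the corner window; the muscle edge — the outermost candidate pixel per
    row, i.e. the strongest oriented intensity gradient — is fit by least
    squares and everything on the corner side of that line is removed.  If no
    candidate is found the mask is returned unchanged with a warning.
    The result never has more pixels than the input mask.
    """
    if corner is None:
        corner = detect_pectoral_corner(image, mask)
    if corner == "right":
        flipped = remove_pectoral(
            MammogramImage(image.pixels[:, ::-1], image.pixel_spacing_mm, image.source_kind),
            BreastMask(mask.mask[:, ::-1], mask.pixel_spacing_mm),
            corner="left",
        )
        return BreastMask(flipped.mask[:, ::-1], mask.pixel_spacing_mm)
    if corner != "left":
        raise ValueError("corner must be 'left' or 'right'")

    h, w = image.shape
    window = np.zeros((h, w), dtype=bool)
    window[: h // 2, : w // 2] = True
    region = window & mask.mask
    vals = image.pixels[region]
    if vals.size < 16 or np.ptp(vals) < 1e-6:
        logger.warning("no pectoral candidate found; mask unchanged")
        return BreastMask(mask.mask.copy(), mask.pixel_spacing_mm)
    from skimage.filters import threshold_otsu

    thr = threshold_otsu(vals)
    candidate = region & (image.pixels > thr)
    lab = measure.label(candidate, connectivity=2)
    keep = np.zeros_like(candidate)
    for comp in measure.regionprops(lab):
        rmin, cmin, _, _ = comp.bbox
        if rmin == 0 and cmin == 0:
            keep[lab == comp.label] = True
    if not keep.any():
        logger.warning("no pectoral candidate found; mask unchanged")
        return BreastMask(mask.mask.copy(), mask.pixel_spacing_mm)

    # muscle edge: outermost candidate column per row; least-squares line
    rows = np.nonzero(keep.any(axis=1))[0]
    edge_cols = np.array([keep[r].nonzero()[0].max() for r in rows], dtype=float)
    if rows.size >= 2 and np.ptp(rows) > 0:
        a, b = np.polyfit(rows.astype(float), edge_cols, 1)
    else:
        a, b = 0.0, float(edge_cols.max())
    rr = np.arange(h, dtype=float)
    cut_col = a * rr + b
    col_idx = np.arange(w, dtype=float)
    cut = (col_idx[None, :] <= cut_col[:, None]) & (rr[:, None] <= rows.max() + 1)
    new_mask = mask.mask & ~(cut | keep)
    if not new_mask.any():
        logger.warning("pectoral cut removed the whole mask; mask unchanged")
        return BreastMask(mask.mask.copy(), mask.pixel_spacing_mm)
    new_mask = _largest_component(new_mask)
    return BreastMask(new_mask, mask.pixel_spacing_mm)


@dataclass
class PreprocessedImage:
    """Output of the full preprocessing chain."""

    denoised: MammogramImage
    enhanced: MammogramImage
    mask: BreastMask


def preprocess_image(
    image: MammogramImage,
    wiener_window: int = DEFAULT_WIENER_WINDOW,
    log_c: float = DEFAULT_LOG_C,
    morph_radius: int | None = None,
    pectoral: bool = True,
) -> PreprocessedImage:
    """Full preprocessing chain: denoise, enhance, mask, pectoral removal.

    The enhanced image drives breast-profile segmentation (it brightens the
    dim skin-line pixels); tissue clustering downstream uses the denoised,
    un-enhanced intensities.
    """
    den = rescale_and_denoise(image, wiener_window)
    enh = enhance_contrast(den, log_c)
    mask = segment_breast(enh, morph_radius=morph_radius)
    if pectoral:
        mask = remove_pectoral(enh, mask)
    return PreprocessedImage(denoised=den, enhanced=enh, mask=mask)
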