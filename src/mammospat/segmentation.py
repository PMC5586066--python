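"""Four-class tissue segmentation of the breast region by fuzzy C-means.

The breast is partitioned into fatty (1), semi-fatty (2), semi-dense (3) and
dense (4) tissue by clustering pixel intensities with fuzzy C-means (FCM) and
hardening memberships to the arg-max class, with class indices assigned in
ascending centroid intensity.  Label maps can be resampled (nearest
neighbour) to a coarser physical grid before spatial-relation analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateInputError, InvalidTargetError
from .preprocess import BreastMask

logger = logging.getLogger(__name__)

#: label semantics: 0 outside breast, then ascending density
LABEL_NAMES = {0: "outside", 1: "fatty", 2: "semi-fatty", 3: "semi-dense", 4: "dense"}

#: display palette for the four tissue classes (dark blue, light blue, yellow, red)
LABEL_PALETTE = {
    0: (0, 0, 0),
    1: (8, 48, 107),
    2: (107, 174, 214),
    3: (254, 217, 42),
    4: (203, 24, 29),
}


@dataclass
class FCMResult:
    """Converged (or truncated) state of a fuzzy C-means run on intensities."""

    centroids: np.ndarray  # (c,) ascending
    memberships: np.ndarray  # (n_pixels, c), rows sum to 1
    fuzzifier_m: float
    n_iterations: int
    converged: bool
    objective_trace: np.ndarray = field(default_factory=lambda: np.array([]))


@dataclass
class RegionLabelMap:
    """Per-pixel hard tissue labels {0..4} with physical pixel spacing."""

    labels: np.ndarray  # (rows, cols) integer labels
    pixel_spacing_mm: float
    pectoral_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("labels must be 2-D")
        if self.pixel_spacing_mm <= 0:
            raise ValueError("pixel_spacing_mm must be > 0")

    @property
    def breast_mask(self) -> np.ndarray:
        return self.labels > 0

    def class_areas(self) -> dict[int, int]:
        """Pixel counts per tissue class 1..4."""
        return {k: int(np.sum(self.labels == k)) for k in (1, 2, 3, 4)}

    def percentage_density(self) -> float:
        """Percent of breast pixels in the two densest classes (3 and 4)."""
        n_breast = int(np.sum(self.labels > 0))
        if n_breast == 0:
            return 0.0
        return 100.0 * float(np.sum(self.labels >= 3)) / n_breast


def fuzzy_cmeans(
    intensities: np.ndarray,
    c: int = 4,
    m: float = 2.0,
    tol: float = 1e-6,
    max_iter: int = 300,
    seed: int | None = None,
    init: str = "percentile",
) -> FCMResult:
    """Fuzzy C-means on a 1-D intensity sample.

    Alternates the membership update ``u_pk = 1 / sum_q (d_pk/d_pq)^(2/(m-1))``
    and the centroid update ``v_k = sum_p u_pk^m x_p / sum_p u_pk^m`` until the
    largest centroid shift falls below ``tol`` or ``max_iter`` is reached.
    Points coinciding with a centroid get full membership in that class.
    Centroids are returned sorted ascending; the objective trace
    ``sum u^m d^2`` is recorded per iteration (it is non-increasing).

    Initialisation defaults to deterministic intensity percentiles
    (12.5/37.5/62.5/87.5 for c=4); ``init='random'`` samples c distinct data
    points with ``seed``.
    """
    x = np.asarray(intensities, dtype=float).ravel()
    if m <= 1:
        raise ValueError("fuzzifier m must be > 1")
    uniq = np.unique(x)
    if uniq.size < c:
        raise DegenerateInputError(
            f"need >= {c} distinct intensity values, got {uniq.size}"
        )
    if init == "percentile":
        qs = (np.arange(c) + 0.5) / c * 100.0
        v = np.percentile(x, qs)
        # percentiles of heavily discrete data may coincide; nudge apart
        if np.unique(v).size < c:
            v = uniq[np.linspace(0, uniq.size - 1, c).astype(int)].astype(float)
    elif init == "random":
        rng = np.random.default_rng(seed)
        v = np.sort(rng.choice(uniq, size=c, replace=False).astype(float))
    else:
        raise ValueError(f"unknown init {init!r}")

    expo = 2.0 / (m - 1.0)
    trace = []
    converged = False
    u = np.empty((x.size, c))
    for it in range(1, max_iter + 1):
        d2 = (x[:, None] - v[None, :]) ** 2
        zero = d2 <= 1e-300
        any_zero = zero.any(axis=1)
        with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
            inv = d2 ** (-expo / 2.0)
            u = inv / inv.sum(axis=1, keepdims=True)
        if np.any(any_zero):
            u[any_zero] = zero[any_zero] / zero[any_zero].sum(axis=1, keepdims=True)
        um = u**m
        trace.append(float(np.sum(um * d2)))
        v_new = (um * x[:, None]).sum(axis=0) / um.sum(axis=0)
        shift = float(np.max(np.abs(v_new - v)))
        v = v_new
        if shift < tol:
            converged = True
            break
    if not converged:
        logger.warning("FCM did not converge in %d iterations", max_iter)
    order = np.argsort(v)
    return FCMResult(
        centroids=v[order],
        memberships=u[:, order],
        fuzzifier_m=m,
        n_iterations=len(trace),
        converged=converged,
        objective_trace=np.asarray(trace),
    )


def harden_labels(fcm: FCMResult, mask: BreastMask) -> RegionLabelMap:
    """Arg-max memberships to hard labels 1..4 inside the breast mask.

    ``fcm`` must have been fit on the masked pixels in row-major order.
    Class indices follow ascending centroid intensity; membership ties go to
    the lower class.
    """
    inside = mask.mask
    if fcm.memberships.shape[0] != int(inside.sum()):
        raise ValueError("FCM memberships do not match the number of mask pixels")
    hard = np.argmax(fcm.memberships, axis=1) + 1  # argmax takes first max: lower class
    labels = np.zeros(inside.shape, dtype=np.uint8)
    labels[inside] = hard.astype(np.uint8)
    for k in range(1, fcm.centroids.size + 1):
        if not np.any(hard == k):
            logger.warning("hardened class %d (%s) is empty", k, LABEL_NAMES.get(k))
    return RegionLabelMap(labels=labels, pixel_spacing_mm=mask.pixel_spacing_mm)


def segment_tissue(
    image: np.ndarray,
    mask: BreastMask,
    c: int = 4,
    m: float = 2.0,
    tol: float = 1e-6,
    max_iter: int = 300,
    seed: int | None = None,
) -> tuple[RegionLabelMap, FCMResult]:
    """Convenience: FCM on the masked pixels of ``image``, then harden."""
    fcm = fuzzy_cmeans(image[mask.mask], c=c, m=m, tol=tol, max_iter=max_iter, seed=seed)
    return harden_labels(fcm, mask), fcm


def save_labelmap(path, labelmap: RegionLabelMap, colorized: bool = False) -> None:
    """Write labels as an 8-bit PNG (raw values 0..4, or the display palette)."""
    import imageio.v3 as iio

    if colorized:
        rgb = np.zeros((*labelmap.labels.shape, 3), dtype=np.uint8)
        for k, col in LABEL_PALETTE.items():
            rgb[labelmap.labels == k] = col
        iio.imwrite(path, rgb)
    else:
        iio.imwrite(path, labelmap.labels.astype(np.uint8))


def load_labelmap(path, pixel_spacing_mm: float) -> RegionLabelMap:
    """Read a raw-value label PNG written by :func:`save_labelmap`."""
    import imageio.v3 as iio

    labels = np.asarray(iio.imread(path))
    if labels.ndim == 3:
        labels = labels[..., 0]
    return RegionLabelMap(labels=labels.astype(np.uint8), pixel_spacing_mm=pixel_spacing_mm)


def rescale_labelmap(
    labelmap: RegionLabelMap, target_spacing_mm: float = 0.25
) -> RegionLabelMap:
    """Nearest-neighbour downsampling of a label map to a coarser grid.

    Preserves the label set exactly (no interpolated classes).  Upsampling
    requests are rejected.
    """
    src = labelmap.pixel_spacing_mm
    if target_spacing_mm < src - 1e-12:
        raise InvalidTargetError(
            f"target spacing {target_spacing_mm} mm finer than source {src} mm"
        )
    factor = target_spacing_mm / src
    if abs(factor - 1.0) < 1e-12:
        return RegionLabelMap(
            labels=labelmap.labels.copy(),
            pixel_spacing_mm=target_spacing_mm,
            pectoral_mask=labelmap.pectoral_mask,
        )
    rows, cols = labelmap.labels.shape
    new_r = max(1, int(round(rows / factor)))
    new_c = max(1, int(round(cols / factor)))
    ri = np.clip(np.round((np.arange(new_r) + 0.5) * factor - 0.5).astype(int), 0, rows - 1)
    ci = np.clip(np.round((np.arange(new_c) + 0.5) * factor - 0.5).astype(int), 0, cols - 1)
    labels = labelmap.labels[np.ix_(ri, ci)]
    pect = None
    if labelmap.pectoral_mask is not None:
        pect = labelmap.pectoral_mask[np.ix_(ri, ci)]
    return RegionLabelMap(labels=labels, pixel_spacing_mm=target_spacing_mm, pectoral_mask=pect)
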