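"""Forces histograms: directional spatial-relation descriptors of region pairs.

A forces histogram (FH) describes the relative position of two pixel regions
A and B.  For a direction ``theta`` the image is swept by a family of parallel
digital lines oriented along ``theta``; on each line, every ordered pixel pair
(p in A strictly ahead of q in B along the sweep direction) contributes the
inverse squared Euclidean distance ``1/d^2``, and the per-line weights are
summed into the histogram bin for ``theta``.  Repeating over a directions
evenly spaced on [0, 360) yields the histogram.  A breast image segmented
into four tissue classes is described by the six FHs of its region pairs.

Angles are measured counter-clockwise from the +x (column) axis with +y
pointing up (i.e. against the row index).  Distances are in pixel units of
the (rescaled) grid.

The production path (:func:`compute_fh_set`) runs a numba kernel that
accumulates all ordered label pairs in a single sweep; :func:`fh_oracle` is a
deliberately naive pure-Python evaluation of the same definition, kept for
testing only.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .errors import InvalidLabelMapError, InvalidPairError
from .segmentation import RegionLabelMap

logger = logging.getLogger(__name__)

DEFAULT_N_ANGLES = 180

#: the six unordered tissue-class pairs, stored with i < j
REGION_PAIRS = ((1, 2), (1, 3), (1, 4), (2, 3), (2, 4), (3, 4))


@dataclass
class ForcesHistogram:
    """FH of one ordered region pair over ``n_angles`` directions."""

    pair: tuple[int, int]
    values: np.ndarray  # (n_angles,) non-negative forces
    pixel_spacing_mm: float
    n_angles: int = DEFAULT_N_ANGLES

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.n_angles,):
            raise ValueError("values length must equal n_angles")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("FH values must be finite and non-negative")

    @property
    def angles(self) -> np.ndarray:
        """Bin angles in degrees: k * 360 / n_angles."""
        return np.arange(self.n_angles) * (360.0 / self.n_angles)

    def normalised(self) -> "ForcesHistogram":
        """Optional sum-to-one normalisation (off by default downstream)."""
        total = self.values.sum()
        vals = self.values / total if total > 0 else self.values
        return ForcesHistogram(self.pair, vals, self.pixel_spacing_mm, self.n_angles)


@dataclass
class FHSet:
    """The six pairwise FHs of a four-class label map (stored with i < j)."""

    histograms: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.histograms) != set(REGION_PAIRS):
            raise ValueError("FHSet requires exactly the six pairs (i < j)")

    def __getitem__(self, pair: tuple[int, int]) -> ForcesHistogram:
        return self.histograms[pair]

    def __iter__(self):
        return iter(REGION_PAIRS)

    def as_matrix(self) -> np.ndarray:
        """Stack to (6, n_angles) in REGION_PAIRS order."""
        return np.stack([self.histograms[p].values for p in REGION_PAIRS])


def _direction(theta_deg: float) -> tuple[float, float]:
    """Unit sweep direction as (dcol, drow); tiny components snapped to 0."""
    th = math.radians(theta_deg)
    dcol, drow = math.cos(th), -math.sin(th)
    if abs(dcol) < 1e-12:
        dcol = 0.0
    if abs(drow) < 1e-12:
        drow = 0.0
    return dcol, drow


def sweep_lines(grid_shape: tuple[int, int], theta_deg: float) -> list[list[tuple[int, int]]]:
    """Family of digital lines with direction ``theta_deg`` covering the grid.

    Every pixel belongs to exactly one line.  Near-horizontal directions
    (|drow| <= |dcol|) index lines by the rounded row intercept and sample one
    pixel per column; near-vertical directions are handled transposed.  Pixels
    on a line are ordered by increasing projection onto the direction vector.
    """
    rows, cols = grid_shape
    if rows <= 0 or cols <= 0:
        raise ValueError("grid must be non-empty")
    dcol, drow = _direction(theta_deg % 360.0)
    lines: dict[int, list[tuple[int, int]]] = {}
    if abs(drow) <= abs(dcol):
        m = drow / dcol
        c_order = range(cols) if dcol > 0 else range(cols - 1, -1, -1)
        for c in c_order:
            off = math.floor(c * m + 0.5)
            for r in range(rows):
                lines.setdefault(r - off, []).append((r, c))
    else:
        m = dcol / drow
        r_order = range(rows) if drow > 0 else range(rows - 1, -1, -1)
        for r in r_order:
            off = math.floor(r * m + 0.5)
            for c in range(cols):
                lines.setdefault(c - off, []).append((r, c))
    return [lines[k] for k in sorted(lines)]


def line_positions(line, theta_deg: float) -> np.ndarray:
    """Scalar positions of a line's pixels along the sweep direction."""
    dcol, drow = _direction(theta_deg % 360.0)
    return np.array([c * dcol + r * drow for r, c in line], dtype=float)


def line_force(positions_a, positions_b) -> float:
    """Force of ordered pairs (p in A strictly ahead of q in B) on one line.

    ``positions_*`` are scalar positions (pixel units) along the line.  Pairs
    with p behind or level with q belong to the opposite direction's line and
    contribute nothing here.
    """
    pos_a = np.asarray(positions_a, dtype=float)
    pos_b = np.asarray(positions_b, dtype=float)
    if pos_a.size == 0 or pos_b.size == 0:
        return 0.0
    diff = pos_a[:, None] - pos_b[None, :]
    if np.any(diff == 0.0):
        raise InvalidLabelMapError("coincident pixels: regions overlap on the line")
    ahead = diff > 0
    return float(np.sum(1.0 / diff[ahead] ** 2))


@njit(cache=True)
def _fh_kernel(rr, cc, lab, n_angles, n_labels):  # pragma: no cover - numba
    """Accumulate forces for all ordered label pairs over all sweep angles.

    Returns out[label_ahead, label_behind, angle_index]; the diagonal is
    accumulated but never read.
    """
    n = rr.shape[0]
    out = np.zeros((n_labels + 1, n_labels + 1, n_angles))
    key = np.empty(n, np.int64)
    ordv = np.empty(n, np.int64)
    t = np.empty(n)
    for k in range(n_angles):
        th = k * (360.0 / n_angles) * math.pi / 180.0
        dcol = math.cos(th)
        drow = -math.sin(th)
        if abs(dcol) < 1e-12:
            dcol = 0.0
        if abs(drow) < 1e-12:
            drow = 0.0
        if abs(drow) <= abs(dcol):
            m = drow / dcol
            for p in range(n):
                key[p] = rr[p] - np.int64(math.floor(cc[p] * m + 0.5))
                ordv[p] = cc[p] if dcol > 0 else -cc[p]
                t[p] = cc[p] * dcol + rr[p] * drow
        else:
            m = dcol / drow
            for p in range(n):
                key[p] = cc[p] - np.int64(math.floor(rr[p] * m + 0.5))
                ordv[p] = rr[p] if drow > 0 else -rr[p]
                t[p] = cc[p] * dcol + rr[p] * drow
        if n == 0:
            continue
        kmin = key.min()
        omin = ordv.min()
        span = np.int64(ordv.max() - omin + 1)
        combo = (key - kmin) * span + (ordv - omin)
        idx = np.argsort(combo)
        key_s = key[idx]
        t_s = t[idx]
        lab_s = lab[idx]
        s = 0
        while s < n:
            e = s + 1
            ks = key_s[s]
            while e < n and key_s[e] == ks:
                e += 1
            for u in range(s + 1, e):
                tu = t_s[u]
                lu = lab_s[u]
                for v in range(s, u):
                    d = tu - t_s[v]
                    out[lu, lab_s[v], k] += 1.0 / (d * d)
            s = e
    return out


def _all_pair_forces(labels: np.ndarray, n_angles: int) -> np.ndarray:
    """(5, 5, a) ordered-pair force table for a 4-class label map."""
    rr, cc = np.nonzero(labels > 0)
    lab = labels[rr, cc].astype(np.int64)
    return _fh_kernel(rr.astype(np.int64), cc.astype(np.int64), lab, n_angles, 4)


def compute_fh(
    labelmap: RegionLabelMap, i: int, j: int, n_angles: int = DEFAULT_N_ANGLES
) -> ForcesHistogram:
    """FH of the ordered region pair (i, j) by angular line sweeping.

    Bin k (angle ``k * 360/a``) sums, over the family of parallel digital
    lines at that angle, the inverse squared distances of all pairs with the
    region-i pixel strictly ahead of the region-j pixel.  An empty region
    yields an all-zero histogram (logged).
    """
    if i == j:
        raise InvalidPairError(f"region pair requires i != j, got ({i}, {j})")
    labels = labelmap.labels
    if not np.any(labels == i) or not np.any(labels == j):
        logger.warning("empty region in pair (%d, %d): returning zero FH", i, j)
        return ForcesHistogram(
            (i, j), np.zeros(n_angles), labelmap.pixel_spacing_mm, n_angles
        )
    table = _all_pair_forces(labels, n_angles)
    return ForcesHistogram((i, j), table[i, j], labelmap.pixel_spacing_mm, n_angles)


def compute_fh_set(labelmap: RegionLabelMap, n_angles: int = DEFAULT_N_ANGLES) -> FHSet:
    """The six pairwise FHs of a four-class map, in one sweep.

    All ordered label pairs share the same line sweep, so the six histograms
    (stored with the i < j convention) come from a single kernel pass.
    """
    table = _all_pair_forces(labelmap.labels, n_angles)
    hists = {
        (i, j): ForcesHistogram(
            (i, j), table[i, j], labelmap.pixel_spacing_mm, n_angles
        )
        for i, j in REGION_PAIRS
    }
    return FHSet(hists)


def fh_oracle(
    labelmap: RegionLabelMap, i: int, j: int, n_angles: int = DEFAULT_N_ANGLES
) -> ForcesHistogram:
    """Reference FH by explicit enumeration of every line and pixel pair.

    Same definition as :func:`compute_fh`, evaluated without any of the
    shared-sweep machinery.  Intended for small maps (<= 64 x 64) in tests.
    """
    if i == j:
        raise InvalidPairError(f"region pair requires i != j, got ({i}, {j})")
    labels = labelmap.labels
    values = np.zeros(n_angles)
    for k in range(n_angles):
        theta = k * (360.0 / n_angles)
        total = 0.0
        for line in sweep_lines(labels.shape, theta):
            pos = line_positions(line, theta)
            labs = np.array([labels[r, c] for r, c in line])
            total += line_force(pos[labs == i], pos[labs == j])
        values[k] = total
    return ForcesHistogram((i, j), values, labelmap.pixel_spacing_mm, n_angles)


def fhset_to_row(fhset: FHSet) -> dict[str, float]:
    """Flatten a six-FH set to ``fh{i}{j}_deg{angle}`` -> value."""
    row: dict[str, float] = {}
    for (i, j) in REGION_PAIRS:
        fh = fhset[(i, j)]
        for angle, val in zip(fh.angles, fh.values):
            row[f"fh{i}{j}_deg{int(round(angle))}"] = float(val)
    return row
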