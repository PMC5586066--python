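"""Synthetic MLO-like phantoms, functional curves and case-control cohorts.

Real mammograms from the underlying case-control studies are not publicly
available, so every downstream stage is exercised on synthetic data with
known ground truth.  The phantom idealises an MLO view as a breast
half-ellipse flush with the chest-wall (left) edge, a bright right-triangle
pectoral region in the top-left corner, a skin-line intensity fall-off, and
four tissue classes (fatty, semi-fatty, semi-dense, dense) arranged by a
small set of interpretable spatial parameters:

* ``dense_blob_centers`` place Gaussian islands of dense tissue (with a
  semi-dense halo) at polar positions inside the breast;
* ``lower_quadrant_fat_weight`` tilts the fatty-class probability towards
  the lower quadrants, making "fatty tissue low in the breast" a
  recoverable ground-truth parameter;
* fatty tissue also concentrates along the breast edge (the fatty skin-line
  rim seen on real images).

The cohort generator draws risk-factor covariates, latent spatial
parameters (a dense-location angle and the lower-quadrant fat weight) and
case status from a logistic model whose intercept is auto-calibrated to the
requested case fraction, then emits one phantom specification per subject.
Percentage density (PD) for synthetic subjects is defined from ground truth
as the percentage of breast pixels in the two densest classes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import truncnorm

from .errors import CalibrationFailureError, InvalidSpecError
from .preprocess import MammogramImage
from .segmentation import RegionLabelMap

PECTORAL_INTENSITY = 0.95

HRT_LEVELS = ("Never", "Past", "Current")
PARITY_LEVELS = (
    "Nulliparous",
    "P<=2_AFB<=25",
    "P<=2_AFB>25",
    "P>2_AFB<=25",
    "P>2_AFB>25",
)

#: covariate distributions matching the key characteristics of the main
#: case-control study (pooled cases and controls)
DEFAULT_COVARIATE_DISTRIBUTIONS: dict = {
    "age": (63.1, 6.5),
    "bmi": (25.1, 3.7),
    "hrt_probs": (0.73, 0.06, 0.21),
    "parity_afb_probs": (0.117, 0.287, 0.295, 0.230, 0.071),
    "pd": (16.7, 14.0, 0.5, 85.0),  # mean, sd, truncation lo/hi (percent)
}

#: log-odds coefficients; covariate effects follow the adjusted estimates of
#: the main analysis, latent spatial effects default to zero (null cohort)
DEFAULT_BETA: dict = {
    "age": -0.008,
    "bmi": 0.066,
    "sqrt_pd": 0.199,
    "parity:P<=2_AFB<=25": -0.186,
    "parity:P<=2_AFB>25": -0.139,
    "parity:P>2_AFB<=25": -0.666,
    "parity:P>2_AFB>25": -0.393,
    "hrt:Past": 0.737,
    "hrt:Current": 0.270,
    "z_dense_angle": 0.0,
    "z_lq_fat": 0.0,
}


@dataclass
class PhantomSpec:
    """Geometry, tissue layout and noise of one synthetic MLO phantom."""

    canvas_size: tuple[int, int] = (128, 128)
    pixel_spacing_mm: float = 0.25
    breast_axes: tuple[float, float] | None = None  # (row semi-axis, col semi-axis)
    pectoral_fraction: float = 0.28
    tissue_levels: tuple[float, float, float, float] = (0.25, 0.45, 0.65, 0.85)
    dense_blob_centers: tuple = ((0.45, 30.0), (0.55, 330.0))
    dense_blob_sigma: float = 8.0
    lower_quadrant_fat_weight: float = 1.0
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        rows, cols = self.canvas_size
        if rows < 8 or cols < 8:
            raise InvalidSpecError("canvas too small")
        if self.pixel_spacing_mm <= 0:
            raise InvalidSpecError("pixel_spacing_mm must be > 0")
        if self.breast_axes is None:
            self.breast_axes = (0.45 * rows, 0.82 * (cols - 1))
        ar, ac = self.breast_axes
        if ar <= 0 or ac <= 0 or ar > (rows - 1) / 2 or ac > cols - 1:
            raise InvalidSpecError("breast half-ellipse does not fit the canvas")
        if not 0 <= self.pectoral_fraction <= 0.5:
            raise InvalidSpecError("pectoral_fraction must be in [0, 0.5]")
        lv = np.asarray(self.tissue_levels, dtype=float)
        if lv.size != 4 or np.any(np.diff(lv) <= 0) or lv.min() < 0 or lv.max() > 1:
            raise InvalidSpecError("tissue_levels must be 4 ascending values in [0,1]")
        for rho, ang in self.dense_blob_centers:
            if not 0 <= rho <= 1:
                raise InvalidSpecError("blob radius fraction must be in [0, 1]")
            if math.cos(math.radians(ang)) < -1e-9:
                raise InvalidSpecError(
                    f"blob at angle {ang} deg lies outside the breast half-ellipse"
                )
        if self.dense_blob_sigma <= 0:
            raise InvalidSpecError("dense_blob_sigma must be > 0")
        if self.lower_quadrant_fat_weight < 0 or self.noise_sd < 0:
            raise InvalidSpecError("weights and noise_sd must be >= 0")

    def blob_centers_px(self) -> list[tuple[float, float]]:
        """Blob centers as (row, col) pixel coordinates."""
        rows, _ = self.canvas_size
        r0 = (rows - 1) / 2.0
        ar, ac = self.breast_axes
        out = []
        for rho, ang in self.dense_blob_centers:
            th = math.radians(ang)
            out.append((r0 - rho * math.sin(th) * ar, rho * math.cos(th) * ac))
        return out


def generate_phantom(spec: PhantomSpec) -> tuple[MammogramImage, RegionLabelMap]:
    """Render a phantom image and its ground-truth tissue label map.

    Background is ~0 intensity; the pectoral triangle is bright
    (:data:`PECTORAL_INTENSITY`); each breast tissue pixel is drawn from a
    Gaussian centred at its class's ``tissue_levels`` entry, attenuated near
    the skin line.  Labels cover every breast (non-pectoral) pixel; the
    pectoral mask is returned on the label map.  Deterministic given
    ``spec.seed``.
    """
    rows, cols = spec.canvas_size
    rng = np.random.default_rng(spec.seed)
    r0 = (rows - 1) / 2.0
    ar, ac = spec.breast_axes

    rr, cc = np.mgrid[0:rows, 0:cols]
    ny = (rr - r0) / ar
    nx = cc / ac
    rho = np.sqrt(nx**2 + ny**2)
    in_ellipse = rho <= 1.0

    pect = np.zeros((rows, cols), dtype=bool)
    if spec.pectoral_fraction > 0:
        ph = spec.pectoral_fraction * rows
        pw = 0.45 * ac
        pect = (rr < ph) & (cc < pw * (1.0 - rr / ph))
    tissue = in_ellipse & ~pect

    # class scores: fatty rim + lower-quadrant tilt, semi-fatty background,
    # dense blobs with a semi-dense halo
    phi = np.arctan2(-(rr - r0), cc)  # image polar angle, +y up
    s1 = 0.30 * np.exp(-((1.0 - rho) ** 2) / (2 * 0.15**2))
    s1 = s1 + 0.5 * spec.lower_quadrant_fat_weight * np.maximum(0.0, -np.sin(phi))
    s2 = np.full((rows, cols), 0.35)
    s3 = np.zeros((rows, cols))
    s4 = np.zeros((rows, cols))
    sig = spec.dense_blob_sigma
    for br, bc in spec.blob_centers_px():
        d2 = (rr - br) ** 2 + (cc - bc) ** 2
        s4 += np.exp(-d2 / (2 * sig**2))
        s3 += 0.55 * np.exp(-d2 / (2 * (2 * sig) ** 2))
    scores = np.stack([s1, s2, s3, s4])
    labels = np.zeros((rows, cols), dtype=np.uint8)
    labels[tissue] = (np.argmax(scores, axis=0) + 1)[tissue].astype(np.uint8)

    levels = np.asarray(spec.tissue_levels)
    img = np.zeros((rows, cols))
    noise = rng.normal(0.0, spec.noise_sd, size=(rows, cols)) if spec.noise_sd > 0 else 0.0
    img = img + 0.5 * np.where(tissue | pect, 0.0, 1.0) * noise  # faint background noise
    img[tissue] = levels[labels[tissue] - 1]
    img[pect] = PECTORAL_INTENSITY
    img = img + np.where(tissue | pect, 1.0, 0.0) * noise
    falloff = np.where(rho > 0.985, 0.55 + 0.45 * (1.0 - rho) / 0.015, 1.0)
    falloff = np.clip(falloff, 0.55, 1.0)
    img = np.where(tissue, img * falloff, img)
    img = np.clip(img, 0.0, 1.0)

    image = MammogramImage(img, spec.pixel_spacing_mm, source_kind="digitised")
    labelmap = RegionLabelMap(
        labels=labels, pixel_spacing_mm=spec.pixel_spacing_mm, pectoral_mask=pect
    )
    return image, labelmap


@dataclass
class CohortSpec:
    """Distributions and effect sizes of a synthetic case-control cohort."""

    n_cases: int = 100
    n_controls: int = 100
    covariate_distributions: dict = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_DISTRIBUTIONS)
    )
    beta: dict = field(default_factory=lambda: dict(DEFAULT_BETA))
    seed: int = 0
    canvas_size: tuple[int, int] = (128, 128)
    pixel_spacing_mm: float = 0.25
    noise_sd: float = 0.02

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1:
            raise InvalidSpecError("n_cases and n_controls must be >= 1")
        dists = dict(DEFAULT_COVARIATE_DISTRIBUTIONS)
        dists.update(self.covariate_distributions)
        self.covariate_distributions = dists
        for key, k in (("hrt_probs", 3), ("parity_afb_probs", 5)):
            p = np.asarray(dists[key], dtype=float)
            if p.size != k or abs(p.sum() - 1.0) > 1e-12 or np.any(p < 0):
                raise InvalidSpecError(f"{key} must be {k} probabilities summing to 1")
        full_beta = dict(DEFAULT_BETA)
        full_beta.update(self.beta)
        self.beta = full_beta


def _linear_predictor(df: pd.DataFrame, beta: dict) -> np.ndarray:
    lin = (
        beta["age"] * df["age"].to_numpy()
        + beta["bmi"] * df["bmi"].to_numpy()
        + beta["sqrt_pd"] * df["sqrt_pd"].to_numpy()
        + beta["z_dense_angle"] * df["z_dense_angle"].to_numpy()
        + beta["z_lq_fat"] * df["z_lq_fat"].to_numpy()
    )
    for lvl in PARITY_LEVELS[1:]:
        lin = lin + beta[f"parity:{lvl}"] * (df["parity_afb"] == lvl).to_numpy()
    for lvl in HRT_LEVELS[1:]:
        lin = lin + beta[f"hrt:{lvl}"] * (df["hrt"] == lvl).to_numpy()
    return lin


def _draw_pool(spec: CohortSpec, rng: np.random.Generator, n: int) -> pd.DataFrame:
    d = spec.covariate_distributions
    age = rng.normal(*d["age"], size=n)
    bmi = rng.normal(*d["bmi"], size=n)
    mu, sd, lo, hi = d["pd"]
    pd_vals = truncnorm.rvs((lo - mu) / sd, (hi - mu) / sd, loc=mu, scale=sd, size=n, random_state=rng)
    hrt = rng.choice(HRT_LEVELS, size=n, p=d["hrt_probs"])
    parity = rng.choice(PARITY_LEVELS, size=n, p=d["parity_afb_probs"])
    return pd.DataFrame(
        {
            "age": age,
            "bmi": bmi,
            "pd": pd_vals,
            "sqrt_pd": np.sqrt(pd_vals),
            "hrt": pd.Categorical(hrt, categories=HRT_LEVELS),
            "parity_afb": pd.Categorical(parity, categories=PARITY_LEVELS),
            "z_dense_angle": rng.normal(size=n),
            "z_lq_fat": rng.normal(size=n),
        }
    )


def _phantom_for_subject(spec: CohortSpec, row: pd.Series, seed: int) -> PhantomSpec:
    """Map a subject's latent parameters to a phantom specification."""
    rows, cols = spec.canvas_size
    ar, ac = 0.45 * rows, 0.82 * (cols - 1)
    breast_area = math.pi * ar * ac / 2.0
    # dense+semi-dense footprint per blob is ~11.3 sigma^2 (argmax geometry)
    n_blobs = 2
    sigma = math.sqrt(max(row["pd"], 0.5) / 100.0 * breast_area / (11.3 * n_blobs))
    angle = float(np.clip(315.0 + 20.0 * row["z_dense_angle"], 272.0, 358.0))
    lqw = float(math.exp(0.5 * row["z_lq_fat"]))
    return PhantomSpec(
        canvas_size=spec.canvas_size,
        pixel_spacing_mm=spec.pixel_spacing_mm,
        dense_blob_centers=((0.40, 35.0), (0.55, angle)),
        dense_blob_sigma=max(sigma, 1.5),
        lower_quadrant_fat_weight=lqw,
        noise_sd=spec.noise_sd,
        seed=seed,
    )


def generate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, list[PhantomSpec]]:
    """Draw a case-control cohort and one phantom specification per subject.

    Covariates and latent spatial parameters are drawn from the stated
    distributions; case status is Bernoulli with logit
    ``intercept + beta . (covariates, latents)``, the intercept calibrated by
    root finding so the expected case fraction matches ``n_cases /
    (n_cases + n_controls)``.  Subjects are then sampled by status to the
    exact requested counts.  Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n_total = spec.n_cases + spec.n_controls
    target = spec.n_cases / n_total
    pool_n = max(4 * n_total, 2000)
    for _attempt in range(5):
        pool = _draw_pool(spec, rng, pool_n)
        lin = _linear_predictor(pool, spec.beta)
        if not np.all(np.isfinite(lin)):
            raise CalibrationFailureError("non-finite linear predictor")

        def case_frac(b0: float) -> float:
            return float(np.mean(expit(b0 + lin))) - target

        try:
            b0 = brentq(case_frac, -60.0, 60.0)
        except ValueError as exc:
            raise CalibrationFailureError(
                f"cannot calibrate intercept to case fraction {target:.3f}"
            ) from exc
        status = rng.random(pool_n) < expit(b0 + lin)
        if status.sum() >= spec.n_cases and (~status).sum() >= spec.n_controls:
            break
        pool_n *= 2
    else:
        raise CalibrationFailureError("could not realise the requested case/control counts")

    case_idx = np.nonzero(status)[0][: spec.n_cases]
    ctrl_idx = np.nonzero(~status)[0][: spec.n_controls]
    idx = np.concatenate([case_idx, ctrl_idx])
    cohort = pool.iloc[idx].reset_index(drop=True)
    cohort.insert(0, "status", np.r_[np.ones(spec.n_cases), np.zeros(spec.n_controls)].astype(int))
    cohort.insert(0, "subject_id", [f"S{k:05d}" for k in range(n_total)])

    seeds = rng.integers(0, 2**31 - 1, size=n_total)
    phantoms = [
        _phantom_for_subject(spec, cohort.iloc[k], int(seeds[k])) for k in range(n_total)
    ]
    return cohort, phantoms


@dataclass
class CurveSample:
    """Synthetic functional sample: curves = mean + sum_k xi_k phi_k + noise."""

    curves: np.ndarray  # (n, grid)
    scores: np.ndarray  # (n, K) latent component scores xi
    grid: np.ndarray  # angles in degrees


def generate_curves(
    n: int,
    grid,
    mean_fn,
    eigenfunctions,
    eigenvalues,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> CurveSample:
    """Draw curves from a Karhunen-Loeve expansion on a common angle grid.

    ``curve_i = mean + sum_k xi_ik phi_k + eps`` with ``xi_ik ~ N(0,
    lambda_k)`` and iid ``eps ~ N(0, noise_sd^2)``.  ``grid`` may be an
    integer (that many angles evenly spaced on [0, 360)) or an explicit array;
    ``mean_fn`` and the eigenfunctions may be callables of the angle (in
    degrees) or arrays on the grid.  Eigenfunctions must be orthonormal under
    the plain grid inner product.
    """
    if n < 1:
        raise InvalidSpecError("n must be >= 1")
    grid = (
        np.arange(int(grid)) * (360.0 / int(grid))
        if np.isscalar(grid)
        else np.asarray(grid, dtype=float)
    )
    mu = np.asarray(mean_fn(grid) if callable(mean_fn) else mean_fn, dtype=float)
    phis = np.stack(
        [np.asarray(f(grid) if callable(f) else f, dtype=float) for f in eigenfunctions]
    )
    lam = np.asarray(eigenvalues, dtype=float)
    if mu.shape != grid.shape or phis.shape[1] != grid.size or lam.size != phis.shape[0]:
        raise InvalidSpecError("mean/eigenfunction/eigenvalue shapes do not match the grid")
    gram = phis @ phis.T
    if not np.allclose(gram, np.eye(phis.shape[0]), atol=1e-8):
        raise InvalidSpecError("eigenfunctions are not orthonormal on the grid")
    if np.any(lam < 0):
        raise InvalidSpecError("eigenvalues must be non-negative")
    rng = np.random.default_rng(seed)
    xi = rng.normal(size=(n, lam.size)) * np.sqrt(lam)
    curves = mu[None, :] + xi @ phis
    if noise_sd > 0:
        curves = curves + rng.normal(0.0, noise_sd, size=curves.shape)
    return CurveSample(curves=curves, scores=xi, grid=grid)
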