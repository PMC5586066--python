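"""End-to-end orchestration: images -> FH curves -> fPCA -> association.

``run_pipeline`` executes the full workflow on either a directory of real
mammograms plus a covariate table, or a synthetic cohort generated on the
fly: preprocessing (denoise, enhance, breast mask, pectoral removal),
four-class fuzzy C-means tissue segmentation, rescaling to a common physical
grid, the six pairwise forces histograms per image, per-family functional
PCA, and the adjusted case-control association analysis with
optimism-corrected validation.  All randomness flows from one seed and
outputs are reproducible bit-for-bit for a fixed configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import association as assoc
from . import fpca as fpca_mod
from .errors import JoinError
from .forces import DEFAULT_N_ANGLES, REGION_PAIRS, compute_fh_set
from .phantom import CohortSpec, generate_cohort, generate_phantom
from .preprocess import MammogramImage, load_image, preprocess_image
from .segmentation import RegionLabelMap, rescale_labelmap, segment_tissue

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one pipeline run (synthetic or real-image)."""

    # input: either a synthetic cohort spec, or an image directory + CSV
    cohort_spec: CohortSpec | None = None
    image_dir: str | None = None
    covariates_csv: str | None = None
    image_pixel_spacing_mm: float = 0.05
    source_kind: str = "digitised"
    # stages
    n_angles: int = DEFAULT_N_ANGLES
    target_spacing_mm: float = 0.25
    fcm_m: float = 2.0
    fcm_tol: float = 1e-6
    fcm_max_iter: int = 300
    cluster_on: str = "denoised"  # or "enhanced"
    variance_threshold: float = 0.85
    pd_scale: str = "sqrt"
    pd_from_ground_truth: bool = True  # synthetic runs only
    use_ground_truth_masks: bool = False  # skip preprocessing on phantoms
    bootstrap_B: int = 200
    do_stepwise: bool = True
    make_plots: bool = False
    seed: int = 0
    output_dir: str | None = None

    def config_hash(self) -> str:
        payload = {k: v for k, v in asdict(self).items()}
        return hashlib.sha1(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


@dataclass
class PipelineResult:
    """Everything the pipeline computed, plus where it was written."""

    cohort: pd.DataFrame
    fh_matrix: np.ndarray  # (n_images, 6, n_angles)
    fpc_models: dict
    global_test: tuple[float, int, float]
    full_fit: assoc.LogisticFit
    validation: assoc.ValidationReport | None
    selected_fpcs: list[str] = field(default_factory=list)
    config_hash: str = ""
    output_dir: str | None = None


def _image_to_labelmap(
    image: MammogramImage, config: RunConfig, truth: RegionLabelMap | None = None
) -> RegionLabelMap:
    """Preprocess + segment one image down to a rescaled 4-class label map."""
    if config.use_ground_truth_masks and truth is not None:
        labelmap = truth
    else:
        pre = preprocess_image(image)
        cluster_img = pre.enhanced if config.cluster_on == "enhanced" else pre.denoised
        labelmap, _ = segment_tissue(
            cluster_img.pixels,
            pre.mask,
            m=config.fcm_m,
            tol=config.fcm_tol,
            max_iter=config.fcm_max_iter,
        )
    return rescale_labelmap(labelmap, config.target_spacing_mm)


def compute_fh_curves(labelmaps, n_angles: int = DEFAULT_N_ANGLES) -> np.ndarray:
    """Stack the six-FH description of each label map into (n, 6, a)."""
    out = []
    for lm in labelmaps:
        out.append(compute_fh_set(lm, n_angles).as_matrix())
    return np.stack(out)


def attach_fpc_scores(
    cohort: pd.DataFrame,
    fh_matrix: np.ndarray,
    variance_threshold: float = 0.85,
) -> tuple[pd.DataFrame, dict]:
    """Fit fPCA per FH family and append standardised score columns.

    Columns are named ``fpc{i}{j}_{k}`` with k = 1..K for each of the six
    region pairs.
    """
    models: dict = {}
    score_cols: dict[str, np.ndarray] = {}
    for p_idx, (i, j) in enumerate(REGION_PAIRS):
        model = fpca_mod.fit_fpca(
            fh_matrix[:, p_idx, :], variance_threshold=variance_threshold
        )
        models[(i, j)] = model
        for k in range(model.K):
            score_cols[f"fpc{i}{j}_{k + 1}"] = model.scores[:, k]
    scores_df = pd.DataFrame(score_cols, index=cohort.index)
    return pd.concat([cohort.copy(), scores_df], axis=1), models


def _load_real_images(config: RunConfig):
    cov = pd.read_csv(config.covariates_csv)
    image_dir = Path(config.image_dir)
    paths = {p.stem: p for p in sorted(image_dir.iterdir()) if p.suffix.lower() in (".png", ".tif", ".tiff", ".dcm")}
    ids = list(cov["subject_id"].astype(str))
    missing = [s for s in ids if s not in paths]
    extra = [s for s in paths if s not in set(ids)]
    if missing or extra:
        raise JoinError(
            f"unmatched image/covariate identifiers: missing images {missing[:5]}, "
            f"unmatched images {extra[:5]}"
        )
    images = (
        load_image(paths[s], config.image_pixel_spacing_mm, config.source_kind) for s in ids
    )
    return cov, images, [None] * len(ids)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _stage(name: str):
    from contextlib import contextmanager

    @contextmanager
    def ctx():
        try:
            yield
        except Exception as exc:
            raise StageError(f"pipeline stage '{name}' failed: {exc}") from exc

    return ctx()


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run the full analysis and (optionally) write the results bundle.

    A failure in any stage is re-raised as :class:`StageError` naming the
    stage (identifier joins raise :class:`~mammospat.errors.JoinError`
    directly, listing the offenders).
    """
    t0 = time.time()
    if config.cohort_spec is not None:
        with _stage("synthetic cohort generation"):
            cohort, phantom_specs = generate_cohort(config.cohort_spec)
        logger.info("generated synthetic cohort of %d subjects", len(cohort))
        with _stage("preprocessing/segmentation"):
            labelmaps = []
            gt_pd = []
            for ps in phantom_specs:
                image, truth = generate_phantom(ps)
                gt_pd.append(truth.percentage_density())
                labelmaps.append(_image_to_labelmap(image, config, truth))
        if config.pd_from_ground_truth:
            cohort = cohort.copy()
            cohort["pd"] = np.asarray(gt_pd)
            cohort["sqrt_pd"] = np.sqrt(cohort["pd"])
    else:
        cohort, images, truths = _load_real_images(config)
        with _stage("preprocessing/segmentation"):
            labelmaps = [_image_to_labelmap(img, config) for img in images]
    logger.info("segmented %d images (%.1f s)", len(labelmaps), time.time() - t0)

    with _stage("forces histograms"):
        fh_matrix = compute_fh_curves(labelmaps, config.n_angles)
    logger.info("forces histograms done (%.1f s)", time.time() - t0)

    with _stage("functional PCA"):
        cohort, models = attach_fpc_scores(cohort, fh_matrix, config.variance_threshold)
    fpc_cols = tuple(assoc.fpc_columns(cohort))

    with _stage("association"):
        global_test = assoc.global_spatial_test(cohort, fpc_cols, pd_scale=config.pd_scale)
        y, X = assoc.build_design(cohort, fpc_cols, pd_scale=config.pd_scale)
        full_fit = assoc.fit_logistic(y, X, "adjusted + fPCs")
        cohort["spatial_score"] = assoc.build_score(full_fit, cohort, fpc_cols)

    validation = None
    if config.bootstrap_B >= 1:
        with _stage("bootstrap validation"):
            validation = assoc.optimism_bootstrap(
                cohort,
                B=config.bootstrap_B,
                seed=config.seed,
                fpc_cols=fpc_cols,
                pd_scale=config.pd_scale,
            )
    selected = []
    if config.do_stepwise:
        with _stage("stepwise selection"):
            selected = assoc.stepwise_select(cohort, fpc_cols, pd_scale=config.pd_scale)
    logger.info("association done (%.1f s); global p=%.3g", time.time() - t0, global_test[2])

    result = PipelineResult(
        cohort=cohort,
        fh_matrix=fh_matrix,
        fpc_models=models,
        global_test=global_test,
        full_fit=full_fit,
        validation=validation,
        selected_fpcs=selected,
        config_hash=config.config_hash(),
    )
    if config.output_dir is not None:
        write_results(result, config)
        result.output_dir = config.output_dir
    return result


def write_results(result: PipelineResult, config: RunConfig) -> None:
    """Serialise the results bundle (CSV/JSON, optional plots) to disk."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"config_hash": result.config_hash, "seed": config.seed}

    result.cohort.to_csv(out / "cohort_with_scores.csv", index=False)

    n, _, a = result.fh_matrix.shape
    cols = [
        f"fh{i}{j}_deg{int(round(k * 360 / a))}"
        for (i, j) in REGION_PAIRS
        for k in range(a)
    ]
    fh_df = pd.DataFrame(result.fh_matrix.reshape(n, -1), columns=cols)
    fh_df.insert(0, "subject_id", result.cohort["subject_id"].to_numpy())
    fh_df.to_csv(out / "forces_histograms.csv", index=False)

    models_json = {
        f"fh{i}{j}": m.to_dict() for (i, j), m in result.fpc_models.items()
    }
    (out / "fpc_models.json").write_text(json.dumps({**meta, "models": models_json}))

    coef = pd.DataFrame(
        {
            "coef": result.full_fit.params,
            "se": result.full_fit.bse,
            "p": result.full_fit.pvalues,
        }
    )
    coef.to_csv(out / "logistic_coefficients.csv")

    stat, df, p = result.global_test
    summary = {
        **meta,
        "global_lrt": {"statistic": stat, "df": df, "p": p},
        "selected_fpcs": result.selected_fpcs,
    }
    if result.validation is not None:
        summary["validation"] = result.validation.to_dict()
    (out / "association_summary.json").write_text(json.dumps(summary, indent=2))

    if config.make_plots:
        _plot_modes(result, out)


def _plot_modes(result: PipelineResult, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for (i, j), model in result.fpc_models.items():
        fig, axes = plt.subplots(1, model.K, figsize=(4 * model.K, 3), squeeze=False)
        for k in range(1, model.K + 1):
            mov = fpca_mod.mode_of_variation(model, k, alpha=2.0)
            ax = axes[0][k - 1]
            ax.plot(model.grid, model.mean_fn, "k-", label="mean")
            ax.plot(mov.grid, mov.plus, "r--", label="+2sd")
            ax.plot(mov.grid, mov.minus, "b--", label="-2sd")
            ax.set_title(f"FH{i}{j} component {k}")
            ax.set_xlabel("angle (deg)")
        axes[0][0].legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(out / f"modes_fh{i}{j}.png", dpi=90)
        plt.close(fig)


@dataclass
class TransferReport:
    """Cross-study check that selected components mean the same thing."""

    angle_match: dict  # fpc name -> (train angle, new angle)
    coefficients: pd.DataFrame  # adjusted logistic fit on the new cohort
    global_p: float


def validate_transfer(
    train: PipelineResult,
    new_cohort: pd.DataFrame,
    new_fh_matrix: np.ndarray,
    selected: list[str] | None = None,
    pd_scale: str = "sqrt",
) -> TransferReport:
    """Score a second study with the training fPC models and re-test.

    New FH curves are projected onto the selected training components
    (training standardisation), the dominant angles of independently refit
    components are compared between studies, and the adjusted logistic model
    with the selected fPCs is fit on the new cohort.
    """
    selected = selected if selected is not None else train.selected_fpcs
    if not selected:
        raise ValueError("no selected fPCs to transfer")
    new_cohort = new_cohort.copy()
    angle_match = {}
    pair_index = {pair: idx for idx, pair in enumerate(REGION_PAIRS)}
    for name in selected:
        m = assoc.FPC_COLUMN_RE.match(name)
        i, j, k = int(m.group(1)), int(m.group(2)), int(m.group(3))
        model = train.fpc_models[(i, j)]
        curves = new_fh_matrix[:, pair_index[(i, j)], :]
        scores = fpca_mod.project(model, curves)
        new_cohort[name] = scores[:, k - 1]
        refit = fpca_mod.fit_fpca(curves, variance_threshold=model.variance_threshold)
        k_new = min(k, refit.K)
        train_angle = fpca_mod.dominant_angles(model, k, top_m=1)[0][0]
        new_angle = fpca_mod.dominant_angles(refit, k_new, top_m=1)[0][0]
        angle_match[name] = (train_angle, new_angle)
    y, X = assoc.build_design(new_cohort, tuple(selected), pd_scale=pd_scale)
    fit = assoc.fit_logistic(y, X, "transfer")
    _, _, p = assoc.global_spatial_test(new_cohort, tuple(selected), pd_scale=pd_scale)
    coefs = pd.DataFrame({"coef": fit.params, "se": fit.bse, "p": fit.pvalues})
    return TransferReport(angle_match=angle_match, coefficients=coefs, global_p=p)
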