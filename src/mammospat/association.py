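"""Case-control association analysis of spatial-relation components.

The standardised functional principal component (fPC) scores of the six FH
families enter adjusted logistic regression models of case-control status.
The primary inference is a global likelihood-ratio test of the model with
all fPCs against the adjusted model without any (degrees of freedom = number
of fPC columns); the adjustment set is age, BMI, square-root percentage
density, the combined parity / age-at-first-birth category and HRT use.
A spatial-relations score is built as the coefficient-weighted sum of the
fPCs, its per-standard-deviation odds ratio and the model AUCs are
validated by Harrell's optimism-correction bootstrap, apparent AUCs of
nested models are compared with DeLong's correlated-ROC test, and the most
important fPCs can be located by bidirectional AIC stepwise selection with
the adjustments forced in.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.metrics import roc_auc_score

from .errors import (
    DesignError,
    InvalidComparisonError,
    SeparationError,
    UndefinedAUCError,
)
from .phantom import HRT_LEVELS, PARITY_LEVELS

try:  # statsmodels signals separation as an error or (newer) a warning
    from statsmodels.tools.sm_exceptions import PerfectSeparationError
except ImportError:  # pragma: no cover
    PerfectSeparationError = ()
try:
    from statsmodels.tools.sm_exceptions import PerfectSeparationWarning
except ImportError:  # pragma: no cover
    PerfectSeparationWarning = None

FPC_COLUMN_RE = re.compile(r"^fpc(\d)(\d)_(\d+)$")

#: percentage-density category bins for the categorical PD coding
PD_BINS = (0.0, 5.0, 10.0, 20.0, 40.0, 100.0)


def fpc_columns(df: pd.DataFrame) -> list[str]:
    """Columns named ``fpc{i}{j}_{k}`` in stable (column) order."""
    return [c for c in df.columns if FPC_COLUMN_RE.match(c)]


def build_design(
    df: pd.DataFrame,
    fpc_cols: tuple[str, ...] = (),
    pd_scale: str = "sqrt",
    extra_terms: tuple[str, ...] = (),
    include_adjustments: bool = True,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Assemble (y, X) with an intercept and the standard adjustment set.

    ``pd_scale`` selects square-root (default), raw, or five-category coded
    percentage density.  Categorical covariates use reference levels Never
    (HRT) and Nulliparous (parity/AFB).
    """
    y = df["status"].to_numpy(dtype=float)
    X = pd.DataFrame(index=df.index)
    X["const"] = 1.0
    if include_adjustments:
        X["age"] = df["age"].astype(float)
        X["bmi"] = df["bmi"].astype(float)
        if pd_scale == "sqrt":
            X["sqrt_pd"] = np.sqrt(df["pd"].astype(float))
        elif pd_scale == "raw":
            X["pd"] = df["pd"].astype(float)
        elif pd_scale == "categorical":
            cat = pd.cut(df["pd"].astype(float), PD_BINS, right=False, include_lowest=True)
            for iv in cat.cat.categories[1:]:
                X[f"pd_cat:{iv}"] = (cat == iv).astype(float)
        else:
            raise ValueError(f"unknown pd_scale {pd_scale!r}")
        for lvl in PARITY_LEVELS[1:]:
            X[f"parity:{lvl}"] = (df["parity_afb"] == lvl).astype(float)
        for lvl in HRT_LEVELS[1:]:
            X[f"hrt:{lvl}"] = (df["hrt"] == lvl).astype(float)
        for term in extra_terms:
            if term == "breastfeeding":
                X["breastfeeding"] = (df["breastfeeding"] == "yes").astype(float)
            else:
                X[term] = df[term].astype(float)
    # drop dummies of category levels absent from this sample
    empty = [c for c in X.columns if (":" in c) and not X[c].any()]
    X = X.drop(columns=empty)
    for c in fpc_cols:
        X[c] = df[c].astype(float)
    return y, X


@dataclass
class LogisticFit:
    """Maximum-likelihood logistic regression fit."""

    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    llf: float
    n: int
    design_cols: tuple[str, ...]
    description: str = ""

    @property
    def aic(self) -> float:
        return 2 * len(self.design_cols) - 2 * self.llf


def fit_logistic(y, X: pd.DataFrame, description: str = "") -> LogisticFit:
    """Fit a logistic regression by Newton/IRLS via statsmodels.

    Raises :class:`DesignError` for rank-deficient designs and
    :class:`SeparationError` for complete/quasi-complete separation
    (diverging coefficients).
    """
    y = np.asarray(y, dtype=float)
    Xv = X.to_numpy(dtype=float)
    n, p = Xv.shape
    if n <= p:
        raise DesignError(f"n={n} must exceed number of columns p={p}")
    if np.linalg.matrix_rank(Xv) < p:
        raise DesignError("design matrix is rank deficient")
    try:
        with warnings.catch_warnings():
            if PerfectSeparationWarning is not None:
                warnings.simplefilter("error", PerfectSeparationWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            from statsmodels.tools.sm_exceptions import ConvergenceWarning

            warnings.simplefilter("ignore", ConvergenceWarning)
            res = sm.Logit(y, Xv).fit(method="newton", tol=1e-10, maxiter=200, disp=0)
    except np.linalg.LinAlgError as exc:
        raise SeparationError(f"singular Hessian (likely separation): {exc}") from exc
    except Exception as exc:
        if isinstance(exc, PerfectSeparationError) or (
            PerfectSeparationWarning is not None
            and isinstance(exc, PerfectSeparationWarning)
        ):
            raise SeparationError("perfect separation detected") from exc
        raise
    if np.any(np.abs(res.params) > 30):
        raise SeparationError("diverging coefficients indicate separation")
    if not res.mle_retvals.get("converged", True):
        raise SeparationError("Newton did not converge (possible quasi-separation)")
    cols = tuple(X.columns)
    return LogisticFit(
        params=pd.Series(res.params, index=cols),
        bse=pd.Series(res.bse, index=cols),
        pvalues=pd.Series(res.pvalues, index=cols),
        llf=float(res.llf),
        n=n,
        design_cols=cols,
        description=description,
    )


def likelihood_ratio_test(full: LogisticFit, reduced: LogisticFit) -> tuple[float, int, float]:
    """LRT of nested logistic fits: ``(2 delta-loglik, df, chi2 upper tail)``."""
    if full.n != reduced.n:
        raise InvalidComparisonError("models fit on different numbers of observations")
    if not set(reduced.design_cols) <= set(full.design_cols):
        raise InvalidComparisonError("reduced model is not nested in the full model")
    df = len(full.design_cols) - len(reduced.design_cols)
    stat = max(2.0 * (full.llf - reduced.llf), 0.0)
    p = 1.0 if df == 0 else float(stats.chi2.sf(stat, df))
    return stat, df, p


def categorical_lrt_from_counts(
    case_counts, control_counts, levels=None
) -> tuple[float, int, float]:
    """Unadjusted categorical LRT from a printed case/control count table.

    Expands the counts to per-subject rows, fits a logistic regression of
    status on the category dummies against the intercept-only model, and
    returns the likelihood-ratio test (equivalently the contingency-table
    G-statistic).
    """
    case_counts = np.asarray(case_counts, dtype=int)
    control_counts = np.asarray(control_counts, dtype=int)
    k = case_counts.size
    if levels is None:
        levels = [f"cat{i}" for i in range(k)]
    rows = []
    for lvl, nc, nn in zip(levels, case_counts, control_counts):
        rows += [(1, lvl)] * int(nc) + [(0, lvl)] * int(nn)
    tab = pd.DataFrame(rows, columns=["status", "category"])
    X = pd.DataFrame({"const": np.ones(len(tab))})
    for lvl in levels[1:]:
        X[f"cat:{lvl}"] = (tab["category"] == lvl).astype(float)
    y = tab["status"].to_numpy(dtype=float)
    full = fit_logistic(y, X, "category")
    reduced = fit_logistic(y, X[["const"]], "intercept-only")
    return likelihood_ratio_test(full, reduced)


def contingency_g_statistic(table) -> tuple[float, int, float]:
    """Closed-form G-statistic ``2 sum O ln(O/E)``; oracle for the LRT identity."""
    tab = np.asarray(table, dtype=float)
    E = tab.sum(axis=1, keepdims=True) * tab.sum(axis=0, keepdims=True) / tab.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(tab > 0, tab * np.log(tab / E), 0.0)
    G = 2.0 * terms.sum()
    df = (tab.shape[0] - 1) * (tab.shape[1] - 1)
    return float(G), df, float(stats.chi2.sf(G, df))


def global_spatial_test(
    df: pd.DataFrame,
    fpc_cols: tuple[str, ...] | None = None,
    pd_scale: str = "sqrt",
    extra_terms: tuple[str, ...] = (),
) -> tuple[float, int, float]:
    """Global LRT of all fPC columns against the adjusted model without them."""
    cols = tuple(fpc_columns(df)) if fpc_cols is None else tuple(fpc_cols)
    if not cols:
        raise InvalidComparisonError("no fPC columns to test")
    y, X_full = build_design(df, cols, pd_scale=pd_scale, extra_terms=extra_terms)
    _, X_red = build_design(df, (), pd_scale=pd_scale, extra_terms=extra_terms)
    full = fit_logistic(y, X_full, "adjusted + fPCs")
    reduced = fit_logistic(y, X_red, "adjusted")
    return likelihood_ratio_test(full, reduced)


def build_score(fit: LogisticFit, df: pd.DataFrame, fpc_cols=None) -> np.ndarray:
    """Spatial-relations score: coefficient-weighted sum of the fPC values."""
    cols = fpc_columns(df) if fpc_cols is None else list(fpc_cols)
    missing = [c for c in cols if c not in fit.params.index]
    if missing:
        raise KeyError(f"fit does not contain fPC terms {missing}")
    beta = fit.params[cols].to_numpy()
    return df[cols].to_numpy(dtype=float) @ beta


def per_sd_odds_ratio(fit: LogisticFit, term: str, sd: float) -> float:
    """``exp(beta_term * sd)``: the odds ratio per one SD of the term."""
    if sd <= 0:
        raise ValueError("sd must be > 0")
    return float(np.exp(fit.params[term] * sd))


def auc(scores, labels) -> float:
    """AUC as the Mann-Whitney statistic with half credit for ties."""
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise UndefinedAUCError("both classes must be present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def _midrank(x: np.ndarray) -> np.ndarray:
    order = np.argsort(x, kind="mergesort")
    xs = x[order]
    n = x.size
    mid = np.empty(n)
    i = 0
    while i < n:
        j = i
        while j < n and xs[j] == xs[i]:
            j += 1
        mid[i:j] = 0.5 * (i + j - 1) + 1.0
        i = j
    out = np.empty(n)
    out[order] = mid
    return out


def _delong_cov(predictions: np.ndarray, labels: np.ndarray):
    """AUCs and their covariance for k correlated models (placement values)."""
    pos = predictions[:, labels == 1]
    neg = predictions[:, labels == 0]
    m, n = pos.shape[1], neg.shape[1]
    k = predictions.shape[0]
    v01 = np.empty((k, m))
    v10 = np.empty((k, n))
    aucs = np.empty(k)
    for r in range(k):
        all_r = np.concatenate([pos[r], neg[r]])
        tx = _midrank(pos[r])
        ty = _midrank(neg[r])
        tz = _midrank(all_r)
        aucs[r] = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
        v01[r] = (tz[:m] - tx) / n
        v10[r] = 1.0 - (tz[m:] - ty) / m
    s01 = np.cov(v01) if k > 1 else np.atleast_2d(np.var(v01, ddof=1))
    s10 = np.cov(v10) if k > 1 else np.atleast_2d(np.var(v10, ddof=1))
    cov = np.atleast_2d(s01) / m + np.atleast_2d(s10) / n
    return aucs, cov


def delong_variance(scores, labels) -> float:
    """DeLong variance of a single AUC."""
    labels = np.asarray(labels)
    aucs, cov = _delong_cov(np.asarray(scores, float)[None, :], labels)
    return float(cov[0, 0])


def delong_test(scores_model1, scores_model2, labels) -> tuple[float, float]:
    """DeLong's two-sided z-test comparing two correlated AUCs.

    Both score vectors must be predictions for the same subjects.
    """
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise UndefinedAUCError("both classes must be present")
    preds = np.stack([np.asarray(scores_model1, float), np.asarray(scores_model2, float)])
    aucs, cov = _delong_cov(preds, labels)
    var = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    diff = aucs[0] - aucs[1]
    if var <= 0:
        return 0.0, 1.0
    z = diff / np.sqrt(var)
    return float(z), float(2.0 * stats.norm.sf(abs(z)))


@dataclass
class ValidationReport:
    """Apparent vs optimism-corrected (honest) performance of the score."""

    apparent: dict = field(default_factory=dict)  # per index
    optimism: dict = field(default_factory=dict)
    honest: dict = field(default_factory=dict)
    B: int = 0
    seed: int = 0
    n_failed_resamples: int = 0

    @property
    def apparent_per_sd_or(self) -> float:
        return float(np.exp(self.apparent["per_sd_effect"]))

    @property
    def honest_per_sd_or(self) -> float:
        return float(np.exp(self.honest["per_sd_effect"]))

    def to_dict(self) -> dict:
        return {
            "apparent": dict(self.apparent),
            "optimism": dict(self.optimism),
            "honest": dict(self.honest),
            "apparent_per_sd_or": self.apparent_per_sd_or,
            "honest_per_sd_or": self.honest_per_sd_or,
            "B": self.B,
            "seed": self.seed,
            "n_failed_resamples": self.n_failed_resamples,
        }


def _score_indices(
    fit_df: pd.DataFrame,
    eval_df: pd.DataFrame,
    cols,
    pd_scale: str,
    include_adjustments: bool = True,
) -> dict:
    """Train the score pipeline on ``fit_df`` and measure it on ``eval_df``.

    Indices: per-SD effect of the spatial score (coefficient of the trained
    score, refit on the evaluation data with adjustments, times the score SD
    there) and AUCs of the trained full / adjustment-only linear predictors.
    Linear predictors are aligned by column name so a category level absent
    from a resample cannot shift the coefficients.
    """
    adj = include_adjustments
    y_fit, X_fit = build_design(fit_df, cols, pd_scale=pd_scale, include_adjustments=adj)
    full = fit_logistic(y_fit, X_fit, "full")
    y_ev, X_ev = build_design(eval_df, cols, pd_scale=pd_scale, include_adjustments=adj)
    score_ev = build_score(full, eval_df, cols)
    Xs = X_ev.drop(columns=list(cols))
    Xs["score"] = score_ev
    sfit = fit_logistic(y_ev, Xs, "score model")
    sd = float(np.std(score_ev, ddof=1))
    eta_full = X_ev[list(full.design_cols)].to_numpy(float) @ full.params.to_numpy()
    y_r, X_r_fit = build_design(fit_df, (), pd_scale=pd_scale, include_adjustments=adj)
    reduced = fit_logistic(y_r, X_r_fit, "reduced")
    _, X_r_ev = build_design(eval_df, (), pd_scale=pd_scale, include_adjustments=adj)
    eta_red = X_r_ev[list(reduced.design_cols)].to_numpy(float) @ reduced.params.to_numpy()
    return {
        "per_sd_effect": float(sfit.params["score"] * sd),
        "auc_full": auc(eta_full, y_ev),
        "auc_reduced": auc(eta_red, y_ev),
    }


def optimism_bootstrap(
    df: pd.DataFrame,
    B: int = 1000,
    seed: int = 0,
    fpc_cols: tuple[str, ...] | None = None,
    pd_scale: str = "sqrt",
    resample=None,
    include_adjustments: bool = True,
) -> ValidationReport:
    """Harrell's optimism-corrected validation of the spatial-relations score.

    For each bootstrap resample the supervised steps (logistic fit, score,
    index computation) are refit; optimism is the mean excess of the
    resample-apparent index over the same trained score measured on the
    original data, and honest = apparent - optimism per index.  The fPC
    basis is treated as fixed (it is fit without outcome labels).
    Deterministic given ``seed``.  ``resample`` may override the index
    drawing (callable ``(rng, n) -> indices``), e.g. to force the identity
    resample.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    cols = tuple(fpc_columns(df)) if fpc_cols is None else tuple(fpc_cols)
    rng = np.random.default_rng(seed)
    if resample is None:
        resample = lambda r, n: r.integers(0, n, size=n)  # noqa: E731
    apparent = _score_indices(df, df, cols, pd_scale, include_adjustments)
    sums = {k: 0.0 for k in apparent}
    failed = 0
    done = 0
    for _b in range(B):
        idx = resample(rng, len(df))
        boot = df.iloc[idx].reset_index(drop=True)
        try:
            app_b = _score_indices(boot, boot, cols, pd_scale, include_adjustments)
            test_b = _score_indices(boot, df, cols, pd_scale, include_adjustments)
        except SeparationError:
            failed += 1
            continue
        for k in sums:
            sums[k] += app_b[k] - test_b[k]
        done += 1
    if failed > 0.05 * B:
        raise SeparationError(
            f"separation in {failed}/{B} bootstrap resamples; cohort too small "
            "or covariates too sparse for validation"
        )
    optimism = {k: (sums[k] / done if done else 0.0) for k in sums}
    honest = {k: apparent[k] - optimism[k] for k in apparent}
    return ValidationReport(
        apparent=apparent,
        optimism=optimism,
        honest=honest,
        B=B,
        seed=seed,
        n_failed_resamples=failed,
    )


def stepwise_select(
    df: pd.DataFrame,
    candidate_fpcs,
    pd_scale: str = "sqrt",
) -> list[str]:
    """Bidirectional AIC stepwise selection over fPC terms.

    The adjustment set is always retained; candidates are scanned in column
    order and a move is taken only if it strictly lowers the AIC (ties keep
    the current model).
    """
    candidates = list(candidate_fpcs)
    selected: list[str] = []

    def aic_of(cols) -> float:
        y, X = build_design(df, tuple(cols), pd_scale=pd_scale)
        return fit_logistic(y, X).aic

    current = aic_of(selected)
    improved = True
    while improved:
        improved = False
        best_move, best_aic = None, current
        for c in candidates:
            trial = selected + [c] if c not in selected else [s for s in selected if s != c]
            a = aic_of(trial)
            if a < best_aic - 1e-10:
                best_move, best_aic = trial, a
        if best_move is not None:
            selected, current = best_move, best_aic
            improved = True
    return [c for c in candidates if c in selected]


def fpc_determinant_regression(
    df: pd.DataFrame,
    fpc_col: str,
    pd_scale: str = "raw",
    include_adjustments: bool = True,
):
    """OLS of a standardised fPC on the breast cancer risk factors.

    Returns the coefficient table plus Pearson correlations (r, p) of the
    fPC with age, BMI and PD.  ``include_adjustments=False`` fits the
    intercept-only model.
    """
    _, X = build_design(df, (), pd_scale=pd_scale, include_adjustments=include_adjustments)
    yv = df[fpc_col].to_numpy(dtype=float)
    Xv = X.to_numpy(dtype=float)
    if np.linalg.matrix_rank(Xv) < Xv.shape[1]:
        raise DesignError("design matrix is rank deficient")
    res = sm.OLS(yv, Xv).fit()
    res_named = pd.DataFrame(
        {"coef": res.params, "se": res.bse, "p": res.pvalues}, index=X.columns
    )
    corr = {
        var: stats.pearsonr(df[var].to_numpy(float), yv) for var in ("age", "bmi", "pd")
    }
    return res_named, {k: (float(v.statistic), float(v.pvalue)) for k, v in corr.items()}
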