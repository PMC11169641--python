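"""Cohort-level statistics for the acoustic feature battery.

Implements the study-level analysis chain: sex-stratified z-normalization
against healthy controls, two-sample group comparisons with Hedge's g
effect sizes, effect-size-based feature ranking with a correlation
demotion rule, covariate-adjusted partial correlations,
Benjamini-Hochberg FDR, disease-stage ANOVA with Bonferroni/LSD pairwise
tests, ordinary-least-squares prediction of clinical motor scores, and a
Gaussian Naive Bayes classifier evaluated by stratified 5-fold
cross-validation with ROC/AUC.

A cohort is a plain :class:`pandas.DataFrame` with one row per subject:
``subject_id``, ``group`` (HC/PD), ``sex`` (M/F), the clinical covariates,
and the acoustic feature columns (see :data:`FEATURE_COLUMNS`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from statsmodels.stats.multitest import multipletests

from .errors import (
    ArgumentError,
    CollinearityError,
    NormalizationError,
    StratificationError,
)
from .synth import SELECTED_FEATURES, reference_feature_params

#: The 29 acoustic feature columns, in canonical order.
FEATURE_COLUMNS: list[str] = list(reference_feature_params()["feature"])


def _feature_cols(cohort: pd.DataFrame, features=None) -> list[str]:
    if features is None:
        features = [c for c in FEATURE_COLUMNS if c in cohort.columns]
    missing = [f for f in features if f not in cohort.columns]
    if missing:
        raise ArgumentError(f"cohort lacks feature columns: {missing}")
    return list(features)


# ---------------------------------------------------------------------------
# Normalization and group comparison

def znormalize(cohort: pd.DataFrame, features=None) -> pd.DataFrame:
    """Z-score features per sex using healthy-control statistics of that sex.

    Every subject's feature x becomes (x - mean_HC,sex) / SD_HC,sex.  A sex
    stratum with fewer than two controls, or a zero-variance control feature,
    raises :class:`NormalizationError` naming the stratum and feature.
    """
    features = _feature_cols(cohort, features)
    out = cohort.copy()
    for sex in out["sex"].unique():
        stratum = (out["sex"] == sex)
        hc = out[stratum & (out["group"] == "HC")]
        if len(hc) < 2:
            raise NormalizationError(f"sex stratum {sex!r} has {len(hc)} HC subjects; need >= 2")
        mean = hc[features].mean()
        sd = hc[features].std(ddof=1)
        zero = sd[sd == 0]
        if len(zero):
            raise NormalizationError(
                f"zero HC variance in stratum {sex!r} for feature(s) {list(zero.index)}"
            )
        out.loc[stratum, features] = (out.loc[stratum, features] - mean) / sd
    return out


def hedges_g(m1: float, s1: float, n1: int, m2: float, s2: float, n2: int) -> float:
    """Hedge's g: bias-corrected standardized mean difference.

    g = J * (m1 - m2) / s_pooled, with the pooled SD over both groups and the
    small-sample correction J = 1 - 3 / (4*(n1+n2-2) - 1).
    """
    if n1 < 2 or n2 < 2:
        raise ArgumentError("need n >= 2 in both groups")
    if s1 < 0 or s2 < 0:
        raise ArgumentError("SDs must be nonnegative")
    df = n1 + n2 - 2
    s_pooled = np.sqrt(((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / df)
    if s_pooled == 0:
        raise ArgumentError("degenerate pooled SD: both groups have zero variance")
    correction = 1.0 - 3.0 / (4.0 * df - 1.0)
    return float(correction * (m1 - m2) / s_pooled)


def compare_groups(
    cohort: pd.DataFrame, features=None, welch: bool = False
) -> pd.DataFrame:
    """Per-feature HC-vs-PD comparison: group summaries, t-test, Hedge's g.

    Uses the pooled-variance (Student) two-sample t-test by default, two
    tailed; set ``welch`` for unequal variances.  The sign convention is
    HC minus PD.  Returns a DataFrame indexed by feature.
    """
    features = _feature_cols(cohort, features)
    hc = cohort[cohort["group"] == "HC"]
    pd_grp = cohort[cohort["group"] == "PD"]
    rows = {}
    for f in features:
        x = hc[f].dropna().to_numpy(dtype=float)
        y = pd_grp[f].dropna().to_numpy(dtype=float)
        if x.size < 2 or y.size < 2:
            warnings.warn(f"feature {f!r}: fewer than 2 observations per group; skipped")
            continue
        t, p = stats.ttest_ind(x, y, equal_var=not welch)
        try:
            g = hedges_g(x.mean(), x.std(ddof=1), x.size, y.mean(), y.std(ddof=1), y.size)
        except ArgumentError:
            g = 0.0 if x.mean() == y.mean() else np.nan
            t, p = (0.0, 1.0) if x.mean() == y.mean() else (t, p)
        rows[f] = {
            "mean_HC": x.mean(),
            "sd_HC": x.std(ddof=1),
            "mean_PD": y.mean(),
            "sd_PD": y.std(ddof=1),
            "t_statistic": float(t),
            "p_value": float(p),
            "hedges_g": g,
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def rank_features(
    comparison: pd.DataFrame,
    feature_matrix: pd.DataFrame | None = None,
    max_abs_corr: float = 0.9,
) -> list[str]:
    """Order features by |Hedge's g|, demoting redundant (highly correlated) ones.

    Features are visited in descending |g|; a feature whose absolute Pearson
    correlation with an already-kept feature exceeds ``max_abs_corr`` is
    demoted below all non-redundant features.  The six features used in the
    published classifier are available as :data:`pdspeech.synth.SELECTED_FEATURES`.
    """
    order = comparison["hedges_g"].abs().sort_values(ascending=False).index.tolist()
    if feature_matrix is None:
        return order
    corr = feature_matrix[order].corr().abs()
    kept: list[str] = []
    demoted: list[str] = []
    for f in order:
        if any(corr.loc[f, s] > max_abs_corr for s in kept):
            demoted.append(f)
        else:
            kept.append(f)
    return kept + demoted


# ---------------------------------------------------------------------------
# Correlation and multiple testing

def partial_correlation(
    x: np.ndarray, y: np.ndarray, covariates: np.ndarray | None = None
) -> tuple[float, float]:
    """Pearson correlation of x and y after regressing out covariates.

    Both variables are residualized on [1, covariates] by OLS; the p-value
    uses the t distribution with n - n_covariates - 2 degrees of freedom.
    With no covariates this reduces exactly to the plain Pearson correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if covariates is None or (hasattr(covariates, "size") and np.size(covariates) == 0):
        cov = np.empty((x.size, 0))
    else:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != x.size:
            cov = cov.T
    mask = np.isfinite(x) & np.isfinite(y) & np.all(np.isfinite(cov), axis=1)
    x, y, cov = x[mask], y[mask], cov[mask]
    n, k = x.size, cov.shape[1]
    if n <= k + 2:
        raise ArgumentError(f"need n > n_covariates + 2; got n={n}, k={k}")
    design = np.column_stack([np.ones(n), cov])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise CollinearityError("covariate matrix is rank deficient")
    beta_x, *_ = np.linalg.lstsq(design, x, rcond=None)
    beta_y, *_ = np.linalg.lstsq(design, y, rcond=None)
    rx = x - design @ beta_x
    ry = y - design @ beta_y
    denom = np.sqrt(np.sum(rx**2) * np.sum(ry**2))
    if denom == 0:
        raise ArgumentError("a variable is constant after residualization")
    r = float(np.clip(np.sum(rx * ry) / denom, -1.0, 1.0))
    dof = n - k - 2
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt(dof / (1.0 - r**2))
    p = float(2.0 * stats.t.sf(abs(t), dof))
    return r, p


def fdr_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ArgumentError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Stage comparison and regression

_STAGE_BINS = (
    ("HY1.5-2.0", 1.5, 2.0),
    ("HY2.5", 2.5, 2.5),
    ("HY3.0", 3.0, 3.0),
    ("HY4-5", 4.0, 5.0),
)


def stage_labels(cohort: pd.DataFrame) -> pd.Series:
    """Label each subject HC or an H-Y stage bin (HY1.5-2.0, HY2.5, HY3.0, HY4-5)."""
    labels = pd.Series(index=cohort.index, dtype=object)
    labels[cohort["group"] == "HC"] = "HC"
    hy = cohort["HY_stage"]
    for name, lo, hi in _STAGE_BINS:
        labels[(cohort["group"] == "PD") & (hy >= lo) & (hy <= hi)] = name
    return labels


def stage_comparison(cohort: pd.DataFrame, feature: str) -> dict:
    """One-way ANOVA of a feature across HC and H-Y stage bins, plus pairwise tests.

    Stage-vs-HC contrasts are Bonferroni-corrected two-sample t-tests;
    between-stage contrasts use Fisher's LSD (t on the ANOVA's pooled
    within-group variance, uncorrected — valid after a significant omnibus F).
    Stages with fewer than two subjects are dropped with a warning.
    """
    labels = stage_labels(cohort)
    values = cohort[feature]
    groups: dict[str, np.ndarray] = {}
    for name in ["HC"] + [b[0] for b in _STAGE_BINS]:
        vals = values[labels == name].dropna().to_numpy(dtype=float)
        if vals.size < 2:
            if vals.size:
                warnings.warn(f"stage {name}: only {vals.size} subject(s); dropped")
            continue
        groups[name] = vals
    if len(groups) < 2:
        raise ArgumentError("need >= 2 stages with >= 2 subjects each")
    names = list(groups)
    arrays = [groups[n] for n in names]
    f_stat, p_omnibus = stats.f_oneway(*arrays)
    if all(np.allclose(a, arrays[0][0]) for a in arrays):
        f_stat, p_omnibus = 0.0, 1.0

    n_total = sum(a.size for a in arrays)
    k = len(arrays)
    mse = sum(((a.size - 1) * a.var(ddof=1)) for a in arrays) / (n_total - k)

    vs_hc = []
    if "HC" in groups:
        pd_stages = [n for n in names if n != "HC"]
        for name in pd_stages:
            t, p = stats.ttest_ind(groups["HC"], groups[name])
            vs_hc.append(
                {
                    "stage": name,
                    "t_statistic": float(t),
                    "p_value": float(p),
                    "p_bonferroni": min(1.0, float(p) * len(pd_stages)),
                }
            )
    lsd = []
    pd_names = [n for n in names if n != "HC"]
    for i, a_name in enumerate(pd_names):
        for b_name in pd_names[i + 1 :]:
            a, b = groups[a_name], groups[b_name]
            se = np.sqrt(mse * (1.0 / a.size + 1.0 / b.size))
            t = (a.mean() - b.mean()) / se if se > 0 else 0.0
            p = 2.0 * stats.t.sf(abs(t), n_total - k)
            lsd.append(
                {"stage_a": a_name, "stage_b": b_name, "t_statistic": float(t), "p_value": float(p)}
            )
    return {
        "F": float(f_stat),
        "p_value": float(p_omnibus),
        "group_sizes": {n: int(groups[n].size) for n in names},
        "vs_hc": pd.DataFrame(vs_hc),
        "lsd": pd.DataFrame(lsd),
    }


def linear_updrs_model(features: np.ndarray, target: np.ndarray) -> dict:
    """OLS prediction of a clinical motor score from acoustic features.

    Returns intercept-first coefficients, in-sample R^2, and per-subject
    predictions.  Rows with missing values are dropped; a rank-deficient
    design raises :class:`CollinearityError`.
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if X.shape[0] == 1 and X.shape[1] > 1 and np.asarray(target).size == X.shape[1]:
        X = X.T
    y = np.asarray(target, dtype=float)
    mask = np.all(np.isfinite(X), axis=1) & np.isfinite(y)
    X, y = X[mask], y[mask]
    n, k = X.shape
    if n <= k + 1:
        raise ArgumentError(f"need n > n_features + 1; got n={n}, k={k}")
    design = np.column_stack([np.ones(n), X])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise CollinearityError("design matrix is rank deficient")
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    pred = design @ beta
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return {"coefficients": beta, "r_squared": r2, "predictions": pred}


# ---------------------------------------------------------------------------
# Classification

def roc_auc(scores, labels) -> float:
    """AUC as the Mann-Whitney probability that a patient outscores a control.

    Computed from average ranks, so ties contribute 1/2; equals the
    fraction of (negative, positive) pairs ordered correctly.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise ArgumentError("both classes must be present")
    ranks = stats.rankdata(scores)
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


@dataclass
class ClassifierReport:
    """Out-of-fold Gaussian Naive Bayes results with ROC/AUC."""

    fold_assignments: np.ndarray
    scores: np.ndarray  # posterior probability of the positive (PD) class
    labels: np.ndarray
    roc_points: pd.DataFrame  # fpr, tpr, threshold
    auc: float  # pooled over folds (primary)
    fold_aucs: list[float]
    seed: int

    def to_json_dict(self) -> dict:
        return {
            "auc": self.auc,
            "fold_aucs": self.fold_aucs,
            "seed": self.seed,
            "n": int(self.labels.size),
        }


def nb_classify_cv(
    features: np.ndarray,
    labels,
    k: int = 5,
    seed: int = 0,
) -> ClassifierReport:
    """Gaussian Naive Bayes with stratified k-fold cross-validation.

    Per fold the classifier (class priors and per-feature Gaussians with a
    small variance floor) is fit on the training subjects only and scores
    the held-out subjects by posterior probability of the patient class;
    scores are pooled across folds for the primary ROC/AUC, with per-fold
    AUCs reported alongside.  Fully deterministic given ``seed``.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels).astype(int)
    classes = np.unique(y)
    if classes.size != 2:
        raise ArgumentError(f"need exactly 2 classes, got {classes.size}")
    if X.shape[0] < k:
        raise ArgumentError(f"need at least k={k} subjects")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    scores = np.empty(y.size)
    folds = np.empty(y.size, dtype=int)
    fold_aucs = []
    for fold_idx, (train, test) in enumerate(skf.split(X, y)):
        if np.unique(y[train]).size < 2:
            raise StratificationError(f"fold {fold_idx}: single class in training data")
        model = GaussianNB()  # var_smoothing floors variances at 1e-9 * max variance
        model.fit(X[train], y[train])
        pos_col = int(np.where(model.classes_ == 1)[0][0])
        scores[test] = model.predict_proba(X[test])[:, pos_col]
        folds[test] = fold_idx
        if np.unique(y[test]).size == 2:
            fold_aucs.append(roc_auc(scores[test], y[test]))
    fpr, tpr, thresh = roc_curve(y, scores)
    return ClassifierReport(
        fold_assignments=folds,
        scores=scores,
        labels=y,
        roc_points=pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thresh}),
        auc=roc_auc(scores, y),
        fold_aucs=fold_aucs,
        seed=seed,
    )
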