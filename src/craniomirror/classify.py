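"""Genotype classification and feature selection.

Classification follows the two-stage recipe standard for cohort data with
nuisance covariates: each feature is first residualized on the covariates
alone (never on genotype), optionally with a family random intercept when
a variance test supports one; linear discriminant analysis is then run on
the residual matrix, with accuracy assessed both by resubstitution and by
leave-one-out cross-validation (per-genotype sensitivity and specificity).

Feature selection is L1-penalized (lasso) logistic regression over a
descending penalty path, with the penalty chosen either by 10-fold
cross-validated deviance (human analysis) or by AIC along the path
(rodent analysis).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
import statsmodels.api as sm

from .association import _ml_fit

logger = logging.getLogger(__name__)

__all__ = [
    "ClassificationResult",
    "SelectionResult",
    "residualize",
    "lda_fit_predict",
    "loocv_lda",
    "lasso_select",
]


@dataclass
class ClassificationResult:
    """LDA outcome: confusion matrix (rows = true class), overall correct
    classification rate, per-class sensitivity/specificity, and the first
    two discriminant scores per subject."""

    confusion: pd.DataFrame
    total_correct_rate: float
    sensitivity: dict[str, float]
    specificity: dict[str, float]
    scores: pd.DataFrame
    method: str  # "resubstitution" or "loocv"


@dataclass
class SelectionResult:
    """Lasso selection outcome with the penalty-path summary."""

    selected: tuple[str, ...]
    rule: str
    chosen_penalty: float
    path: pd.DataFrame = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# residualization
# ---------------------------------------------------------------------------

def _covariate_matrix(covariates: pd.DataFrame | None, index) -> tuple[np.ndarray, list[str]]:
    if covariates is None or covariates.shape[1] == 0:
        return np.ones((len(index), 1)), ["intercept"]
    cov = covariates.loc[index].copy()
    for c in cov.columns:
        if not np.issubdtype(cov[c].dtype, np.number):
            cov[c] = pd.factorize(cov[c])[0].astype(float)
    X = np.column_stack([np.ones(len(cov))] + [cov[c].to_numpy(dtype=float) for c in cov.columns])
    names = ["intercept"] + list(cov.columns)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the columns whose removal restores full rank
        collinear = []
        for j in range(1, X.shape[1]):
            others = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(others) == rank:
                collinear.append(names[j])
        raise ValueError(f"rank-deficient covariates; collinear columns: {collinear}")
    return X, names


def _variance_lrt_p(y: np.ndarray, X: np.ndarray, groups: np.ndarray) -> float:
    """LRT p for the random-intercept variance (boundary-corrected: the
    null distribution is an equal mixture of a point mass at 0 and chi2_1)."""
    ols = sm.OLS(y, X).fit()
    mm = _ml_fit(y, X, groups)
    stat = max(0.0, 2.0 * (mm.llf - ols.llf))
    return 0.5 * float(stats.chi2.sf(stat, 1)) if stat > 0 else 1.0


def residualize(
    features: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    groups: pd.Series | None = None,
    random_intercept: str = "auto",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Residuals of each feature on the covariates (genotype never enters).

    Rows with any missing feature or covariate are dropped (count logged).
    With ``groups`` (family ids) and ``random_intercept='auto'``, a family
    random intercept is included per feature when its variance LRT is
    significant at ``alpha``; residuals then also subtract the predicted
    family effect so within-family correlation is removed. ``'always'`` and
    ``'never'`` force the choice. Without covariates the residuals are the
    mean-centered features.
    """
    if random_intercept not in ("auto", "always", "never"):
        raise ValueError("random_intercept must be 'auto', 'always' or 'never'")
    keep = features.notna().all(axis=1)
    if covariates is not None:
        keep &= covariates.reindex(features.index).notna().all(axis=1)
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("residualize: dropped %d subjects with missing data", n_drop)
    feats = features.loc[keep]
    X, _ = _covariate_matrix(
        covariates.reindex(features.index).loc[keep] if covariates is not None else None,
        feats.index,
    )
    g = groups.reindex(feats.index).to_numpy() if groups is not None else None
    out = {}
    for col in feats.columns:
        y = feats[col].to_numpy(dtype=float)
        use_mixed = False
        if g is not None and random_intercept != "never" and len(np.unique(g)) >= 2:
            if random_intercept == "always":
                use_mixed = True
            else:
                use_mixed = _variance_lrt_p(y, X, g) < alpha
        if use_mixed:
            mm = _ml_fit(y, X, g)
            if hasattr(mm, "random_effects"):
                fitted = X @ mm.fe_params
                ranef = mm.random_effects
                fam_eff = np.array([float(np.asarray(ranef[gi]).ravel()[0]) for gi in g])
                out[col] = y - fitted - fam_eff
            else:  # variance hit the zero boundary; mm is the OLS fit
                out[col] = mm.resid
        else:
            res = sm.OLS(y, X).fit()
            out[col] = res.resid
    return pd.DataFrame(out, index=feats.index)


# ---------------------------------------------------------------------------
# LDA
# ---------------------------------------------------------------------------

def _rates(confusion: pd.DataFrame) -> tuple[float, dict, dict]:
    total = confusion.to_numpy().sum()
    correct = np.trace(confusion.to_numpy())
    sens, spec = {}, {}
    for cls in confusion.index:
        n_cls = confusion.loc[cls].sum()
        tp = confusion.loc[cls, cls]
        fp = confusion[cls].sum() - tp
        tn = total - n_cls - fp
        sens[cls] = float(tp / n_cls) if n_cls else float("nan")
        spec[cls] = float(tn / (total - n_cls)) if total > n_cls else float("nan")
    return float(correct / total), sens, spec


def _confusion(true_labels, pred_labels, classes) -> pd.DataFrame:
    conf = pd.DataFrame(0, index=list(classes), columns=list(classes), dtype=int)
    for t, p in zip(true_labels, pred_labels):
        conf.loc[t, p] += 1
    conf.index.name = "true"
    conf.columns.name = "predicted"
    return conf


def lda_fit_predict(residuals: pd.DataFrame, labels: pd.Series) -> ClassificationResult:
    """LDA with proportional priors, scored by resubstitution.

    Deterministic given its input. Errors if there are fewer subjects than
    features + classes (advising feature selection first) or if the pooled
    covariance is singular.
    """
    y = labels.reindex(residuals.index)
    classes = sorted(y.unique())
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    n, k = residuals.shape
    if n <= k + len(classes):
        raise ValueError(
            f"n={n} subjects with {k} features and {len(classes)} classes: "
            "too few subjects; reduce features (e.g. by selection) first"
        )
    lda = LinearDiscriminantAnalysis()  # priors default to class frequencies
    X = residuals.to_numpy(dtype=float)
    try:
        lda.fit(X, y.to_numpy())
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"singular pooled covariance ({exc}); consider feature reduction"
        ) from exc
    pred = lda.predict(X)
    conf = _confusion(y, pred, classes)
    total, sens, spec = _rates(conf)
    Z = lda.transform(X)[:, :2]
    scores = pd.DataFrame(Z, index=residuals.index,
                          columns=[f"LD{i+1}" for i in range(Z.shape[1])])
    return ClassificationResult(conf, total, sens, spec, scores, "resubstitution")


def loocv_lda(residuals: pd.DataFrame, labels: pd.Series) -> ClassificationResult:
    """Leave-one-out cross-validated LDA.

    Each subject is predicted by a model trained without it. A left-out fit
    that fails (singularity) flags the subject as misclassified with a
    warning. Sensitivity(g) = TP_g / n_g; specificity(g) = TN_g / (n - n_g).
    """
    y = labels.reindex(residuals.index)
    classes = sorted(y.unique())
    X = residuals.to_numpy(dtype=float)
    yv = y.to_numpy()
    preds = []
    for i in range(len(X)):
        mask = np.ones(len(X), bool)
        mask[i] = False
        lda = LinearDiscriminantAnalysis()
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                lda.fit(X[mask], yv[mask])
            preds.append(lda.predict(X[i: i + 1])[0])
        except (np.linalg.LinAlgError, ValueError) as exc:
            warnings.warn(f"LOOCV fold {i} failed ({exc}); counting as misclassified")
            wrong = [c for c in classes if c != yv[i]]
            preds.append(wrong[0] if wrong else yv[i])
    conf = _confusion(yv, preds, classes)
    total, sens, spec = _rates(conf)
    scores = pd.DataFrame(index=residuals.index)
    return ClassificationResult(conf, total, sens, spec, scores, "loocv")


# ---------------------------------------------------------------------------
# lasso selection
# ---------------------------------------------------------------------------

def _deviance(model, X, y) -> float:
    p = np.clip(model.predict_proba(X)[:, 1], 1e-12, 1 - 1e-12)
    return float(-2.0 * np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))


def lasso_select(
    features: pd.DataFrame,
    labels,
    rule: str = "cv_min_deviance",
    folds: int = 10,
    seed: int = 0,
    n_penalties: int = 40,
) -> SelectionResult:
    """L1-penalized logistic regression feature selection on a binary label.

    Features are standardized to unit variance before penalization (the
    selection is reported on the original names). The penalty descends on a
    log grid from just above the value that zeroes every coefficient.
    ``rule='cv_min_deviance'`` picks the penalty minimizing mean held-out
    deviance over seeded stratified k-folds; ``rule='aic'`` minimizes
    AIC = deviance + 2 x (number of nonzero coefficients) along the
    full-data path. Ties break toward the sparser (larger-penalty) model.
    """
    if rule not in ("cv_min_deviance", "aic"):
        raise ValueError("rule must be 'cv_min_deviance' or 'aic'")
    y = np.asarray(pd.Series(labels).reindex(features.index) if hasattr(labels, "reindex") else labels)
    uniq = np.unique(y)
    if len(uniq) != 2:
        raise ValueError(f"label must be binary, got classes {list(uniq)}")
    y01 = (y == uniq[1]).astype(float)
    Xdf = features.dropna(axis=0)
    y01 = y01[[i in set(Xdf.index) for i in features.index]] if len(Xdf) != len(features) else y01
    mu = Xdf.mean()
    sd = Xdf.std(ddof=0).replace(0, 1.0)
    X = ((Xdf - mu) / sd).to_numpy(dtype=float)
    n = len(X)
    # lambda_max: smallest penalty with all-zero coefficients (KKT bound)
    lam_max = float(np.max(np.abs(X.T @ (y01 - y01.mean()))) / n)
    lams = np.geomspace(lam_max * 1.05, lam_max * 1e-3, n_penalties)

    def fit(Xtr, ytr, lam):
        C = 1.0 / max(lam * len(Xtr), 1e-12)
        m = LogisticRegression(l1_ratio=1.0, C=C, solver="liblinear",
                               max_iter=2000, random_state=0)
        m.fit(Xtr, ytr)
        return m

    records = []
    if rule == "cv_min_deviance":
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        splits = list(skf.split(X, y01))
        for lam in lams:
            dev = 0.0
            for tr, te in splits:
                m = fit(X[tr], y01[tr], lam)
                dev += _deviance(m, X[te], y01[te])
            m_full = fit(X, y01, lam)
            records.append((lam, int(np.sum(m_full.coef_ != 0)), dev / n))
        path = pd.DataFrame(records, columns=["penalty", "n_nonzero", "criterion"])
    else:
        for lam in lams:
            m_full = fit(X, y01, lam)
            nz = int(np.sum(m_full.coef_ != 0))
            aic = _deviance(m_full, X, y01) + 2.0 * nz
            records.append((lam, nz, aic))
        path = pd.DataFrame(records, columns=["penalty", "n_nonzero", "criterion"])

    # minimum criterion; ties toward the sparser model = larger penalty = earlier row
    best_idx = int(path["criterion"].round(10).idxmin())
    lam_best = float(path.loc[best_idx, "penalty"])
    m_best = fit(X, y01, lam_best)
    nz_mask = m_best.coef_.ravel() != 0
    if path["criterion"].max() < 1e-8:  # complete separation along the whole path
        warnings.warn("complete separation at all penalties; returning the "
                      "largest-penalty separating set")
        lam_best = float(path.loc[0, "penalty"])
        m_best = fit(X, y01, lam_best)
        nz_mask = m_best.coef_.ravel() != 0
    selected = tuple(np.asarray(Xdf.columns)[nz_mask])
    return SelectionResult(selected=selected, rule=rule,
                           chosen_penalty=lam_best, path=path)
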