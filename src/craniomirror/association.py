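"""Per-feature genotype association.

Human cohort: linear mixed-effects models with a family random intercept,
fixed covariates (age, head circumference, BMI, sex, ancestry PCs), an
optional genotype-by-sex interaction screened per feature, and a
likelihood-ratio test of the genotype terms on nested maximum-likelihood
fits. Deletion and duplication are each contrasted against controls in
separate models. Multiplicity is controlled per contrast by Holm (FWER)
and Benjamini-Hochberg (FDR), both always reported.

Rodent cohorts: univariate linear models per feature (equivalent to a
pooled-variance two-sample t-test).

Also implements the ancestry-PC imputation rule used for subjects missing
genotype-derived principal components: copy the PCs of the sibling nearest
in age, else of a randomly chosen parent.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests
import statsmodels.api as sm

logger = logging.getLogger(__name__)

__all__ = [
    "EffectRow",
    "RandomInterceptML",
    "fit_random_intercept_ml",
    "impute_ancestry_pcs",
    "fit_feature_model",
    "fit_univariate_lm",
    "adjust_holm",
    "adjust_bh",
    "effect_table",
    "univariate_effect_table",
    "add_adjustments",
]

GENOTYPES = ("DEL", "CTRL", "DUP")


@dataclass
class EffectRow:
    """One feature-by-contrast genotype effect."""

    feature: str
    contrast: str
    coef: float
    se: float
    lrt_stat: float
    df: int
    p: float
    n_used: int
    n_dropped: int
    interaction_included: bool = False
    converged: bool = True
    note: str = ""


# ---------------------------------------------------------------------------
# multiplicity adjustments
# ---------------------------------------------------------------------------

def _check_pvalues(pvalues) -> np.ndarray:
    p = np.asarray(pvalues, dtype=float)
    if p.size and ((p < 0).any() or (p > 1).any()):
        raise ValueError("p-values must lie in [0, 1]")
    return p


def adjust_holm(pvalues) -> np.ndarray:
    """Holm step-down adjusted p-values (FWER control), original order."""
    p = _check_pvalues(pvalues)
    if p.size == 0:
        return p
    return multipletests(p, method="holm")[1]


def adjust_bh(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (FDR control), original order."""
    p = _check_pvalues(pvalues)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# ancestry PC imputation
# ---------------------------------------------------------------------------

def _pc_columns(covariates: pd.DataFrame) -> list[str]:
    return [c for c in covariates.columns if c.lower().startswith("pc")]


def impute_ancestry_pcs(
    covariates: pd.DataFrame,
    pedigree: pd.DataFrame,
    seed: int = 0,
) -> pd.DataFrame:
    """Fill missing ancestry PCs from relatives.

    A subject with missing PCs receives the PCs of the sibling (same two
    parents) nearest in age that has PCs; failing that, of a parent with
    PCs chosen uniformly at random (seeded). Subjects with no eligible
    relative stay missing and are flagged, not dropped.

    ``pedigree`` needs columns subject_id, father_id, mother_id (empty/NaN
    for founders). Returns a copy with PCs filled and a ``pc_imputed``
    column in {``observed``, ``sibling``, ``parent``, ``missing``}.
    """
    pcs = _pc_columns(covariates)
    out = covariates.copy()
    if not pcs:
        out["pc_imputed"] = "observed"
        return out
    ped = pedigree.set_index("subject_id")
    has_pcs = out[pcs].notna().all(axis=1)
    ages = out.set_index("subject_id")["age"] if "age" in out.columns else None
    by_id = out.set_index("subject_id")
    rng = np.random.default_rng(seed)
    status = []
    for i, row in out.iterrows():
        sid = row["subject_id"]
        if has_pcs.loc[i]:
            status.append("observed")
            continue
        father = ped["father_id"].get(sid)
        mother = ped["mother_id"].get(sid)
        sibs = []
        if pd.notna(father) and pd.notna(mother):
            mask = (ped["father_id"] == father) & (ped["mother_id"] == mother)
            sibs = [s for s in ped.index[mask] if s != sid and s in by_id.index]
        donors = [
            s for s in sibs if by_id.loc[s, pcs].notna().all()
        ]
        if donors and ages is not None:
            gaps = {s: abs(float(ages.loc[s]) - float(row["age"])) for s in donors}
            donor = min(sorted(donors), key=gaps.__getitem__)
            out.loc[i, pcs] = by_id.loc[donor, pcs].to_numpy(dtype=float)
            status.append("sibling")
            continue
        if donors:  # siblings but no ages: deterministic first by id
            donor = sorted(donors)[0]
            out.loc[i, pcs] = by_id.loc[donor, pcs].to_numpy(dtype=float)
            status.append("sibling")
            continue
        parents = [
            p for p in (father, mother)
            if pd.notna(p) and p in by_id.index and by_id.loc[p, pcs].notna().all()
        ]
        if parents:
            donor = parents[int(rng.integers(len(parents)))]
            out.loc[i, pcs] = by_id.loc[donor, pcs].to_numpy(dtype=float)
            status.append("parent")
            continue
        status.append("missing")
    out["pc_imputed"] = status
    return out


# ---------------------------------------------------------------------------
# mixed-model association (human)
# ---------------------------------------------------------------------------

def _design(
    covariates: pd.DataFrame,
    contrast: str,
    control: str,
    n_pcs: int,
    use_pcs: bool,
) -> tuple[pd.DataFrame, list[str]]:
    """Covariate design for one contrast-vs-control subset (no intercept
    column; added by the fitter). Returns (frame, covariate column names)."""
    df = covariates[covariates["genotype"].isin([contrast, control])].copy()
    df["geno"] = (df["genotype"] == contrast).astype(float)
    df["sex_m"] = (df["sex"].astype(str).str.upper().str.startswith("M")).astype(float)
    cols = ["age", "head_circumference", "bmi", "sex_m"]
    if use_pcs:
        pcs = _pc_columns(covariates)[:n_pcs]
        cols += pcs
    return df, cols


@dataclass
class RandomInterceptML:
    """Exact maximum-likelihood fit of a linear model with one random
    intercept (``y = X b + u_group + e``).

    The likelihood is profiled down to the single variance ratio
    theta = sigma^2_group / sigma^2_resid, for which the marginal
    covariance inverts in closed form per group (Sherman-Morrison), and
    maximized by bounded scalar optimization with an explicit check of
    the theta = 0 boundary. This makes nested log-likelihoods exactly
    comparable — generic gradient optimizers on this surface routinely
    stop short near the boundary, which breaks likelihood-ratio tests.
    """

    params: np.ndarray
    bse: np.ndarray
    llf: float
    sigma2_resid: float
    sigma2_group: float
    random_effects: dict
    converged: bool = True

    @property
    def fe_params(self) -> np.ndarray:
        return self.params


def fit_random_intercept_ml(y, X, groups) -> RandomInterceptML:
    """Exact ML fit of a single-random-intercept linear mixed model.

    Returns coefficient estimates with GLS standard errors, the exact ML
    log-likelihood, both variance components, and per-group predicted
    (BLUP) intercepts. At the boundary (group variance 0) the fit reduces
    to OLS.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    uniq, inv = np.unique(np.asarray(groups), return_inverse=True)
    ns = np.bincount(inv).astype(float)
    GX = np.zeros((len(uniq), p))
    np.add.at(GX, inv, X)
    Gy = np.zeros(len(uniq))
    np.add.at(Gy, inv, y)
    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)

    def profile(theta):
        """(negative llf, beta, sigma2_resid, XtVinvX) at a variance ratio."""
        w = theta / (1.0 + ns * theta)
        XtVX = XtX - (GX * w[:, None]).T @ GX
        XtVy = Xty - (GX * w[:, None]).T @ Gy
        beta = np.linalg.solve(XtVX, XtVy)
        Gr = Gy - GX @ beta
        rss = yty - 2.0 * beta @ Xty + beta @ XtX @ beta - w @ (Gr ** 2)
        s2 = rss / n
        nll = 0.5 * n * np.log(2.0 * np.pi * s2) \
            + 0.5 * float(np.sum(np.log(1.0 + ns * theta))) + 0.5 * n
        return nll, beta, s2, XtVX

    theta_hat = 0.0
    if np.max(ns) > 1:
        res = optimize.minimize_scalar(
            lambda lt: profile(np.exp(lt))[0],
            bounds=(-12.0, 8.0), method="bounded",
            options={"xatol": 1e-10},
        )
        if -res.fun > -profile(0.0)[0]:
            theta_hat = float(np.exp(res.x))
    nll, beta, s2, XtVX = profile(theta_hat)
    cov = s2 * np.linalg.inv(XtVX)
    bse = np.sqrt(np.diag(cov))
    Gr = Gy - GX @ beta
    shrink = theta_hat / (1.0 + ns * theta_hat)
    blups = shrink * Gr
    return RandomInterceptML(
        params=beta, bse=bse, llf=-nll,
        sigma2_resid=float(s2), sigma2_group=float(theta_hat * s2),
        random_effects={g: float(b) for g, b in zip(uniq, blups)},
    )


def _ml_fit(y, X, groups):
    return fit_random_intercept_ml(y, X, groups)


def _lrt(llf_full: float, llf_reduced: float, df: int) -> tuple[float, float]:
    stat = max(0.0, 2.0 * (llf_full - llf_reduced))
    return stat, float(stats.chi2.sf(stat, df))


def fit_feature_model(
    feature: pd.Series,
    covariates: pd.DataFrame,
    contrast: str,
    control: str = "CTRL",
    n_pcs: int = 2,
    use_pcs: bool = True,
    sex_interaction: str = "screen",
    feature_name: str | None = None,
) -> EffectRow:
    """Mixed-model genotype effect on one feature for one contrast.

    Mean model: feature ~ genotype + age + head_circumference + bmi + sex
    (+ ancestry PCs) (+ genotype:sex when ``sex_interaction='screen'`` finds
    it significant at 5%, or when ``'always'``), with a family random
    intercept. The genotype terms are tested by a likelihood-ratio test of
    nested maximum-likelihood fits (df = 1, or 2 with the interaction).

    ``feature`` is indexed like ``covariates`` rows; rows with missing
    response or predictors are dropped and counted. Cohorts with fewer than
    two families fall back to a fixed-effects-only model with a warning.
    Singular or non-convergent fits return a flagged row, not an exception.
    """
    if sex_interaction not in ("screen", "always", "never"):
        raise ValueError("sex_interaction must be 'screen', 'always' or 'never'")
    name = feature_name or (feature.name if feature.name is not None else "feature")
    df, covcols = _design(covariates, contrast, control, n_pcs, use_pcs)
    df = df.assign(_y=np.asarray(feature.reindex(df.index), dtype=float))
    n0 = len(df)
    df = df.dropna(subset=["_y", "geno", "family_id"] + covcols)
    n_dropped = n0 - len(df)
    if n_dropped:
        logger.info("%s/%s: dropped %d rows with missing data", name, contrast, n_dropped)
    groups = df["family_id"].to_numpy()
    n_fam = len(np.unique(groups))
    y = df["_y"].to_numpy()
    if df["geno"].nunique() < 2:
        raise ValueError(f"{name}/{contrast}: contrast and control groups both required")
    X_cov = np.column_stack([np.ones(len(df))] + [df[c].to_numpy(dtype=float) for c in covcols])
    geno = df["geno"].to_numpy()
    inter = geno * df["sex_m"].to_numpy()

    mixed = n_fam >= 2
    if not mixed:
        warnings.warn("fewer than 2 families: falling back to fixed-effects-only model")

    def fit(X):
        if mixed:
            return _ml_fit(y, X, groups)
        return sm.OLS(y, X).fit()

    def llf(res):
        return float(res.llf)

    try:
        X_main = np.column_stack([X_cov, geno])
        res_main = fit(X_main)
        include_inter = sex_interaction == "always"
        if sex_interaction == "screen":
            X_int = np.column_stack([X_cov, geno, inter])
            res_int = fit(X_int)
            _, p_screen = _lrt(llf(res_int), llf(res_main), 1)
            include_inter = p_screen < 0.05
        if include_inter:
            X_full = np.column_stack([X_cov, geno, inter])
            res_full = fit(X_full) if sex_interaction != "screen" else res_int
            df_lrt = 2
        else:
            X_full = X_main
            res_full = res_main
            df_lrt = 1
        res_red = fit(X_cov)
        stat, p = _lrt(llf(res_full), llf(res_red), df_lrt)
        geno_idx = X_cov.shape[1]  # genotype main effect column
        coef = float(res_full.params[geno_idx])
        se = float(res_full.bse[geno_idx])
        converged = bool(getattr(res_full, "converged", True)) and bool(
            getattr(res_red, "converged", True)
        )
        note = "" if converged else "non-convergent fit"
        if not mixed:
            note = (note + "; " if note else "") + "fixed-effects fallback (<2 families)"
        return EffectRow(
            feature=name, contrast=contrast, coef=coef, se=se,
            lrt_stat=stat, df=df_lrt, p=p, n_used=len(df), n_dropped=n_dropped,
            interaction_included=include_inter, converged=converged, note=note,
        )
    except (np.linalg.LinAlgError, ValueError) as exc:
        logger.warning("%s/%s: fit failed (%s)", name, contrast, exc)
        return EffectRow(
            feature=name, contrast=contrast, coef=float("nan"), se=float("nan"),
            lrt_stat=float("nan"), df=0, p=float("nan"), n_used=len(df),
            n_dropped=n_dropped, converged=False, note=f"fit failed: {exc}",
        )


def fit_univariate_lm(
    feature,
    genotype,
    contrast: str,
    control: str = "CTRL",
    feature_name: str = "feature",
) -> EffectRow:
    """Two-group linear model of one feature on genotype (rodent analysis).

    Equivalent to a pooled-variance two-sample t-test: the coefficient is
    mean(contrast) - mean(control).
    """
    y = np.asarray(feature, dtype=float)
    g = np.asarray(genotype)
    keep = ~np.isnan(y) & np.isin(g, [contrast, control])
    y, g = y[keep], g[keep]
    y1, y0 = y[g == contrast], y[g == control]
    if len(y1) < 2 or len(y0) < 2:
        raise ValueError(f"{feature_name}/{contrast}: both groups need n >= 2")
    if np.var(y1) == 0 and np.var(y0) == 0:
        if np.mean(y1) == np.mean(y0):
            return EffectRow(feature=feature_name, contrast=contrast, coef=0.0,
                             se=0.0, lrt_stat=0.0, df=1, p=1.0,
                             n_used=len(y), n_dropped=int((~keep).sum()))
        raise ValueError(f"{feature_name}/{contrast}: zero variance in both groups")
    X = np.column_stack([np.ones(len(y)), (g == contrast).astype(float)])
    res = sm.OLS(y, X).fit()
    return EffectRow(
        feature=feature_name, contrast=contrast,
        coef=float(res.params[1]), se=float(res.bse[1]),
        lrt_stat=float(res.tvalues[1] ** 2), df=1, p=float(res.pvalues[1]),
        n_used=len(y), n_dropped=int((~keep).sum()),
    )


# ---------------------------------------------------------------------------
# effect tables
# ---------------------------------------------------------------------------

_ROW_COLS = [
    "feature", "contrast", "coef", "se", "lrt_stat", "df", "p",
    "n_used", "n_dropped", "interaction_included", "converged", "note",
]


def _rows_to_frame(rows: list[EffectRow]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in rows], columns=_ROW_COLS)


def add_adjustments(table: pd.DataFrame) -> pd.DataFrame:
    """Holm and BH columns per contrast, over converged rows only.

    Non-converged rows get NaN adjusted values and are excluded from the
    multiplicity family (their count is logged).
    """
    out = table.copy()
    out["p_holm"] = np.nan
    out["q_bh"] = np.nan
    for contrast, idx in out.groupby("contrast").groups.items():
        sub = out.loc[idx]
        ok = sub["converged"] & sub["p"].notna()
        n_bad = int((~ok).sum())
        if n_bad:
            logger.info("contrast %s: %d non-converged fits excluded from adjustment", contrast, n_bad)
        p = sub.loc[ok, "p"].to_numpy()
        if len(p):
            out.loc[sub.index[ok], "p_holm"] = adjust_holm(p)
            out.loc[sub.index[ok], "q_bh"] = adjust_bh(p)
    return out


def effect_table(
    features: pd.DataFrame,
    covariates: pd.DataFrame,
    contrasts=("DEL", "DUP"),
    control: str = "CTRL",
    **fit_kwargs,
) -> pd.DataFrame:
    """Mixed-model effect table: one row per (feature, contrast), with Holm
    and BH adjusted columns per contrast."""
    cov = covariates.set_index("subject_id") if "subject_id" in covariates.columns else covariates
    cov = cov.loc[cov.index.intersection(features.index)]
    rows = []
    for contrast in contrasts:
        for col in features.columns:
            rows.append(
                fit_feature_model(
                    features.loc[cov.index, col], cov, contrast,
                    control=control, feature_name=col, **fit_kwargs,
                )
            )
    return add_adjustments(_rows_to_frame(rows))


def univariate_effect_table(
    features: pd.DataFrame,
    genotype: pd.Series,
    contrasts=("DEL", "DUP"),
    control: str = "CTRL",
) -> pd.DataFrame:
    """Univariate linear-model effect table (rodent), with adjustments."""
    g = genotype.reindex(features.index)
    rows = []
    for contrast in contrasts:
        for col in features.columns:
            rows.append(
                fit_univariate_lm(features[col], g, contrast, control=control,
                                  feature_name=col)
            )
    return add_adjustments(_rows_to_frame(rows))
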