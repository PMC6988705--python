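"""Statistics for larval zebrafish craniofacial phenotypes.

The phenotype of interest is the ceratohyal arch angle (CHA) measured on
ventral images of 3 dpf larvae; a smaller angle means a more protrusive
lower jaw. Within each experimental batch, raw angles are anchored to the
uninjected controls: every larva's angle is rescaled so the control-group
mean sits at exactly 100. Group comparisons use one-way ANOVA followed by
Tukey's HSD; the across-gene direction pattern uses an exact binomial sign
test; and double/triple gene-combination experiments are tested for
synergy by comparing an additive main-effects model to the fully
parameterized cell-means model with an F-test. Additional head measures
(frontonasal area FNA, interocular distance IOD) and body length run
through the identical machinery via the ``response`` argument.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .mirror import direction_sign_test

__all__ = [
    "normalize_to_controls",
    "anova_tukey",
    "majority_direction_test",
    "synergy_test",
    "group_compare",
    "summarize_conditions",
    "AnovaTukeyResult",
    "SynergyResult",
]

CONTROL_CONDITION = "uninjected"


@dataclass
class AnovaTukeyResult:
    f_stat: float
    p_value: float
    pairwise: pd.DataFrame  # group1, group2, diff, p_adj, ci_low, ci_high

    def vs_control(self, control: str = CONTROL_CONDITION) -> pd.DataFrame:
        """The Tukey rows against the control, as condition-minus-control."""
        rows = []
        for _, r in self.pairwise.iterrows():
            if r["group1"] == control:
                rows.append({"condition": r["group2"], "diff": -r["diff"],
                             "p_adj": r["p_adj"],
                             "ci_low": -r["ci_high"], "ci_high": -r["ci_low"]})
            elif r["group2"] == control:
                rows.append({"condition": r["group1"], "diff": r["diff"],
                             "p_adj": r["p_adj"],
                             "ci_low": r["ci_low"], "ci_high": r["ci_high"]})
        return pd.DataFrame(rows)


@dataclass
class SynergyResult:
    genes: tuple[str, ...]
    interaction_coefs: pd.DataFrame  # term, coef, se, t, p
    f_stat: float
    p_additive_vs_full: float
    df_num: int
    df_den: int
    additive_fit: object = field(repr=False, default=None)
    full_fit: object = field(repr=False, default=None)


def normalize_to_controls(
    batch: pd.DataFrame,
    response: str = "cha_deg",
    out: str = "cha_norm",
    control: str = CONTROL_CONDITION,
) -> pd.DataFrame:
    """Anchor a batch to its uninjected controls at 100.

    Every larva's raw measurement is multiplied by 100 / (control mean), so
    the normalized control mean is exactly 100 and the operation is
    invariant to any common rescaling of the raw values. Idempotent when
    re-applied to its own output column.
    """
    ctrl = batch.loc[batch["condition"] == control, response]
    ctrl = ctrl.dropna()
    if len(ctrl) == 0:
        raise ValueError(f"no {control!r} control larvae in batch")
    mean_ctrl = float(ctrl.mean())
    if mean_ctrl <= 0:
        raise ValueError("control mean must be positive")
    result = batch.copy()
    result[out] = batch[response] * (100.0 / mean_ctrl)
    return result


def anova_tukey(groups: dict[str, np.ndarray] | pd.DataFrame,
                group_col: str = "condition",
                value_col: str = "cha_norm") -> AnovaTukeyResult:
    """One-way ANOVA with Tukey's HSD all-pairs comparisons.

    Accepts either a mapping condition -> values or a long DataFrame.
    Tukey adjusted p-values come from the studentized-range distribution
    with the pooled within-group variance.
    """
    if isinstance(groups, pd.DataFrame):
        groups = {
            k: v[value_col].dropna().to_numpy()
            for k, v in groups.groupby(group_col, sort=True)
        }
    names = sorted(groups)
    arrays = [np.asarray(groups[k], dtype=float) for k in names]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    for name, arr in zip(names, arrays):
        if len(arr) < 2:
            raise ValueError(f"group {name!r} needs n >= 2")
    f_stat, p = stats.f_oneway(*arrays)
    res = stats.tukey_hsd(*arrays)
    ci = res.confidence_interval()
    rows = []
    for i, j in itertools.combinations(range(len(names)), 2):
        rows.append({
            "group1": names[i], "group2": names[j],
            "diff": float(np.mean(arrays[i]) - np.mean(arrays[j])),
            "p_adj": float(res.pvalue[i, j]),
            "ci_low": float(ci.low[i, j]), "ci_high": float(ci.high[i, j]),
        })
    return AnovaTukeyResult(float(f_stat), float(p), pd.DataFrame(rows))


def majority_direction_test(
    gene_effects: dict[str, float] | pd.Series,
    direction: str = "negative",
) -> tuple[int, int, float]:
    """Exact sign test on the direction of per-gene mean effects vs control.

    Success is an effect in the stated ``direction`` (default negative: a
    lower mean CHA than controls, i.e. a more protrusive jaw). Returns
    (n_success, n, one-sided binomial p) via the same exact-tail machinery
    as the mirror direction test; zero effects are excluded.
    """
    eff = pd.Series(gene_effects, dtype=float)
    signed = eff.to_numpy()
    if direction == "negative":
        a = -signed
    elif direction == "positive":
        a = signed
    else:
        raise ValueError("direction must be 'negative' or 'positive'")
    # success when sign(a) differs from sign of a constant -1 vector iff a>0:
    # delegate with the reference vector of -1s so "opposite" means a > 0.
    ref = -np.ones_like(a)
    n_succ, n, p = direction_sign_test(a, ref)
    return n_succ, n, p


def _condition_genes(cond: str) -> frozenset[str]:
    if cond == CONTROL_CONDITION:
        return frozenset()
    return frozenset(g for g in cond.split("+") if g)


def synergy_test(
    batch: pd.DataFrame,
    genes,
    response: str = "cha_norm",
    control: str = CONTROL_CONDITION,
) -> SynergyResult:
    """Additive-vs-full model comparison for 2- or 3-gene combinations.

    Conditions are "GENE", "GENE1+GENE2", ... plus the uninjected control.
    The additive model regresses the response on gene main-effect
    indicators; the fully parameterized model fits one mean per design
    cell. Their F-test asks whether combination effects depart from
    additivity (a low p indicates synergy/epistasis). Interaction
    coefficients with t-tests come from the full-factorial parameterization.
    """
    genes = tuple(genes)
    if len(genes) < 2:
        raise ValueError("synergy test needs at least 2 genes; single-gene "
                         "sets have no interaction terms")
    if len(genes) > 3:
        raise ValueError("at most 3 genes supported")
    required = [frozenset()]
    for r in range(1, len(genes) + 1):
        required += [frozenset(c) for c in itertools.combinations(genes, r)]
    cond_sets = {c: _condition_genes(c) for c in batch["condition"].unique()}
    present = set(cond_sets.values())
    absent = [s for s in required if s not in present]
    if absent:
        names = ["+".join(sorted(s)) if s else control for s in absent]
        raise ValueError(f"missing design cells: {names}")
    sub = batch[[s in set(required) for s in batch["condition"].map(cond_sets)]].copy()
    y = sub[response].to_numpy(dtype=float)
    ind = {g: sub["condition"].map(lambda c: float(g in cond_sets[c])).to_numpy()
           for g in genes}

    terms, cols = [], []
    for r in range(1, len(genes) + 1):
        for combo in itertools.combinations(genes, r):
            col = np.prod([ind[g] for g in combo], axis=0)
            terms.append(":".join(combo))
            cols.append(col)
    X_full = np.column_stack([np.ones(len(y))] + cols)
    X_add = np.column_stack([np.ones(len(y))] + cols[: len(genes)])
    fit_full = sm.OLS(y, X_full).fit()
    fit_add = sm.OLS(y, X_add).fit()

    df_num = X_full.shape[1] - X_add.shape[1]
    df_den = len(y) - X_full.shape[1]
    rss_f, rss_a = float(fit_full.ssr), float(fit_add.ssr)
    f_stat = ((rss_a - rss_f) / df_num) / (rss_f / df_den)
    p = float(stats.f.sf(f_stat, df_num, df_den))

    inter_rows = []
    for k, term in enumerate(terms, start=1):
        if ":" not in term:
            continue
        inter_rows.append({
            "term": term,
            "coef": float(fit_full.params[k]),
            "se": float(fit_full.bse[k]),
            "t": float(fit_full.tvalues[k]),
            "p": float(fit_full.pvalues[k]),
        })
    return SynergyResult(
        genes=genes, interaction_coefs=pd.DataFrame(inter_rows),
        f_stat=float(f_stat), p_additive_vs_full=p,
        df_num=df_num, df_den=df_den,
        additive_fit=fit_add, full_fit=fit_full,
    )


def group_compare(a, b) -> tuple[float, float, float]:
    """Generic two-group pooled-variance comparison (e.g. body length of
    edited vs control larvae). Returns (mean difference, t, p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(np.mean(a) - np.mean(b)), float(t), float(p)


def summarize_conditions(
    batch: pd.DataFrame,
    value_col: str = "cha_norm",
    group_col: str = "condition",
) -> pd.DataFrame:
    """Mean, SEM and n per condition (bar-chart quantities)."""
    g = batch.groupby(group_col)[value_col]
    out = pd.DataFrame({
        "mean": g.mean(),
        "sem": g.sem(ddof=1),
        "n": g.count(),
    })
    out.index.name = group_col
    return out.reset_index()
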