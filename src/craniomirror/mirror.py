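"""Mirror-effect statistics for reciprocal copy-number variants.

A reciprocal deletion/duplication pair shows a "mirror effect" on a
quantitative feature when the two genotypes shift the feature in opposite
directions relative to controls. Across a panel of features this is
quantified two ways: the Pearson correlation between the deletion and
duplication effect vectors (strongly negative under mirroring), and an
exact one-sided binomial sign test on the count of features whose effects
have opposite signs. The same machinery, with agreement instead of
opposition as the success, measures cross-species concordance of effect
maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MirrorResult",
    "effect_vector_correlation",
    "direction_sign_test",
    "cross_species_concordance",
    "mirror_result",
]


@dataclass
class MirrorResult:
    """Mirror/concordance statistics over a feature subset."""

    n_features: int
    pearson_r: float
    r_pvalue: float
    n_success: int          # opposite-direction (mirror) or same-direction (concordance) count
    sign_p_one_sided: float
    mode: str               # "opposite" or "concordant"
    features: tuple[str, ...] = field(default_factory=tuple)
    n_excluded_zero: int = 0
    sign_p_two_sided: float = float("nan")


def effect_vector_correlation(del_effects, dup_effects) -> tuple[float, float]:
    """Pearson correlation between matched effect vectors, with its
    two-sided p-value from the t-distribution on n-2 df."""
    a = np.asarray(del_effects, dtype=float)
    b = np.asarray(dup_effects, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("effect vectors must be 1D and of equal length")
    if len(a) < 3:
        raise ValueError("need at least 3 matched features")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero-variance effect vector")
    res = stats.pearsonr(a, b)
    return float(res.statistic), float(res.pvalue)


def direction_sign_test(
    del_effects, dup_effects
) -> tuple[int, int, float]:
    """Count of opposite-sign effect pairs and its exact binomial tail.

    Success is strict sign disagreement: sign(del) != sign(dup). Pairs in
    which either effect is exactly zero are excluded (and their count is
    recoverable from n). The one-sided p-value is P(X >= n_opposite) for
    X ~ Binomial(n, 1/2), computed by exact tail summation.
    """
    a = np.asarray(del_effects, dtype=float)
    b = np.asarray(dup_effects, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) == 0:
        raise ValueError("effect vectors must be matched, 1D and non-empty")
    keep = (a != 0) & (b != 0)
    a, b = a[keep], b[keep]
    n = len(a)
    if n == 0:
        raise ValueError("all effect pairs contain a zero effect")
    n_opposite = int(np.sum(np.sign(a) != np.sign(b)))
    p = float(stats.binomtest(n_opposite, n, 0.5, alternative="greater").pvalue)
    return n_opposite, n, p


def mirror_result(
    del_effects: pd.Series | dict,
    dup_effects: pd.Series | dict,
    features=None,
) -> MirrorResult:
    """Full mirror-effect summary on an explicit feature subset.

    ``features`` selects the subset to analyse (e.g. the FWER-significant
    set); ``None`` uses all features shared by name. The subset is always
    an explicit choice of the caller, never inferred.
    """
    return _paired_result(del_effects, dup_effects, features, mode="opposite")


def cross_species_concordance(
    effects_a: pd.Series | dict,
    effects_b: pd.Series | dict,
    features=None,
) -> MirrorResult:
    """Concordance of two species' effect maps on shared features.

    Pearson correlation plus a sign test in which success is sign
    *agreement* (same-direction effects across species).
    """
    return _paired_result(effects_a, effects_b, features, mode="concordant")


def _paired_result(ea, eb, features, mode: str) -> MirrorResult:
    sa = pd.Series(ea, dtype=float)
    sb = pd.Series(eb, dtype=float)
    if features is None:
        features = [f for f in sa.index if f in set(sb.index)]
    features = list(features)
    missing = [f for f in features if f not in sa.index or f not in sb.index]
    if missing:
        raise KeyError(f"features absent from an effect table: {missing}")
    if len(features) < 3:
        raise ValueError("need at least 3 shared features")
    a = sa.loc[features].to_numpy()
    b = sb.loc[features].to_numpy()
    r, rp = effect_vector_correlation(a, b)
    keep = (a != 0) & (b != 0)
    n_zero = int((~keep).sum())
    av, bv = a[keep], b[keep]
    n = len(av)
    if n == 0:
        raise ValueError("all effect pairs contain a zero effect")
    disagree = int(np.sum(np.sign(av) != np.sign(bv)))
    k = disagree if mode == "opposite" else n - disagree
    p1 = float(stats.binomtest(k, n, 0.5, alternative="greater").pvalue)
    p2 = float(stats.binomtest(k, n, 0.5, alternative="two-sided").pvalue)
    return MirrorResult(
        n_features=n, pearson_r=r, r_pvalue=rp, n_success=k,
        sign_p_one_sided=p1, mode=mode, features=tuple(features),
        n_excluded_zero=n_zero, sign_p_two_sided=p2,
    )
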