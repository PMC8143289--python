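"""Reduction of the 84 radiomic features to one uncorrelated feature couple.

The selection chain, fitted on training rows only:

1. min-max scaling to [0, 1] followed by z-scoring (constant features are
   dropped with a warning);
2. L1-penalized logistic regression (LASSO) over a log-spaced penalty grid,
   with the penalty chosen by the minimum mean cross-validated deviance;
   nonzero coefficients are ranked by absolute value;
3. all unordered pairs of the LASSO-selected features with absolute Pearson
   correlation below ``rho_max`` (default 0.15) become candidate couples;
4. each feature's two-sided Wilcoxon rank-sum p-value between classes is
   computed; a couple's p-value is the larger of its members' (both features
   must discriminate); Holm-Bonferroni step-down over the candidate couples
   determines significance; the significant couple with the smallest p-value
   wins (ties: larger summed absolute LASSO coefficient, then name order).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss
from sklearn.model_selection import StratifiedKFold

from .errors import (
    NoSignificantCoupleError,
    NoUncorrelatedPairError,
    ValidationError,
)
from .io import CohortTable

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

@dataclass
class NormalizationParams:
    """Per-feature (min, max, mean, sd) learned on training rows.

    ``mean``/``sd`` refer to the min-max-scaled training values; ``sd`` is
    the sample standard deviation (ddof = 1). ``dropped`` lists constant
    training features excluded from the transform.
    """

    params: dict[str, tuple[float, float, float, float]]
    dropped: tuple[str, ...] = ()

    @property
    def features(self) -> tuple[str, ...]:
        return tuple(self.params)

    def to_dict(self) -> dict:
        return {
            "params": {k: list(v) for k, v in self.params.items()},
            "dropped": list(self.dropped),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NormalizationParams":
        return cls(
            params={k: tuple(v) for k, v in d["params"].items()},
            dropped=tuple(d["dropped"]),
        )


def fit_normalization(X_train: pd.DataFrame) -> NormalizationParams:
    """Learn min-max + z-score parameters per feature on training rows."""
    if len(X_train) < 2:
        raise ValidationError("need at least 2 training rows to fit normalization")
    params: dict[str, tuple[float, float, float, float]] = {}
    dropped: list[str] = []
    for name in X_train.columns:
        col = X_train[name].to_numpy(dtype=float)
        lo, hi = col.min(), col.max()
        if hi == lo:
            dropped.append(name)
            continue
        scaled = (col - lo) / (hi - lo)
        params[name] = (float(lo), float(hi), float(scaled.mean()), float(scaled.std(ddof=1)))
    if dropped:
        logger.warning("dropping %d constant feature(s): %s", len(dropped), dropped)
    return NormalizationParams(params=params, dropped=tuple(dropped))


def apply_normalization(X: pd.DataFrame, norm: NormalizationParams) -> pd.DataFrame:
    """Apply learned parameters unchanged to any rows (train or test)."""
    out = {}
    for name, (lo, hi, mean, sd) in norm.params.items():
        scaled = (X[name].to_numpy(dtype=float) - lo) / (hi - lo)
        out[name] = (scaled - mean) / sd
    return pd.DataFrame(out, index=X.index)


def normalize_standardize(table: CohortTable) -> tuple[CohortTable, NormalizationParams]:
    """Normalize a partitioned cohort table, fitting on its training rows."""
    norm = fit_normalization(table.X("train"))
    transformed = apply_normalization(table.X(), norm)
    df = table.data[["patient_id", "label", "partition"]].copy()
    df = df.join(transformed.reset_index(drop=True))
    return CohortTable(df, norm.features), norm


# ---------------------------------------------------------------------------
# LASSO ranking
# ---------------------------------------------------------------------------

def lasso_rank(
    X: pd.DataFrame,
    y: np.ndarray,
    n_folds: int = 10,
    seed: int = 0,
    n_lambda: int = 100,
    lambda_min_ratio: float = 1e-4,
) -> dict[str, float]:
    """Nonzero LASSO-logistic coefficients at the minimum-CV-deviance penalty.

    The penalty grid is ``n_lambda`` log-spaced values from the smallest
    penalty that zeroes every coefficient down to ``lambda_min_ratio`` times
    it. Cross-validation folds are stratified and seeded; if the smaller
    class has fewer members than ``n_folds`` the fold count is reduced with
    a warning. Returns ``{feature: coefficient}`` ordered by decreasing
    absolute coefficient (ties broken by feature name).
    """
    y = np.asarray(y, dtype=int)
    Xv = X.to_numpy(dtype=float)
    n = len(y)
    if set(np.unique(y)) != {0, 1}:
        raise ValidationError("lasso_rank requires both classes present")

    min_class = int(np.bincount(y).min())
    if min_class < n_folds:
        logger.warning("reducing LASSO CV folds from %d to %d (small class)", n_folds, min_class)
        n_folds = max(2, min_class)

    # smallest penalty with an all-zero solution (gradient bound at w = 0)
    p0 = y.mean()
    lam_max = np.max(np.abs(Xv.T @ (y - p0))) / n
    lambdas = np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambda)

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed % (2**31))
    folds = list(skf.split(Xv, y))

    deviance = np.zeros(n_lambda)
    for tr, va in folds:
        for i, lam in enumerate(lambdas):
            model = _l1_logistic(lam, n, seed)
            model.fit(Xv[tr], y[tr])
            proba = model.predict_proba(Xv[va])[:, 1]
            deviance[i] += 2.0 * log_loss(y[va], proba, labels=[0, 1], normalize=False)
    deviance /= n

    best = int(np.argmin(deviance))  # argmin returns the largest-penalty tie
    final = _l1_logistic(lambdas[best], n, seed)
    final.fit(Xv, y)
    coefs = final.coef_.ravel()

    nonzero = [(X.columns[j], float(coefs[j])) for j in np.flatnonzero(coefs)]
    nonzero.sort(key=lambda kv: (-abs(kv[1]), kv[0]))
    return dict(nonzero)


def _l1_logistic(lam: float, n: int, seed: int) -> LogisticRegression:
    # sklearn objective: C * sum(loss) + |w|_1  <=>  glmnet lambda = 1 / (C n);
    # fixed random_state pins liblinear's internal shuffling; the large
    # intercept_scaling leaves the intercept effectively unpenalized
    return LogisticRegression(
        l1_ratio=1.0, C=1.0 / (lam * n), solver="liblinear", max_iter=2000,
        tol=1e-7, random_state=seed % (2**31), intercept_scaling=100.0,
    )


# ---------------------------------------------------------------------------
# couple filtering and testing
# ---------------------------------------------------------------------------

def uncorrelated_pairs(
    X: pd.DataFrame, features: list[str], rho_max: float = 0.15
) -> list[tuple[str, str]]:
    """Unordered feature pairs with |Pearson rho| < ``rho_max`` on these rows."""
    if len(features) < 2:
        return []
    corr = X[features].corr().to_numpy()
    pairs = []
    for (i, fi), (j, fj) in combinations(enumerate(features), 2):
        if abs(corr[i, j]) < rho_max:
            pairs.append((fi, fj))
    return pairs


def wilcoxon_rank_sum(x, y) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact permutation null when the smaller group has <= 10 members and the
    pooled data are tie-free; otherwise the normal approximation with tie
    and continuity corrections. Two identical constant groups give p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both groups must be nonempty")
    pooled = np.concatenate([x, y])
    if np.unique(pooled).size == 1:
        return 1.0
    has_ties = np.unique(pooled).size < pooled.size
    if min(x.size, y.size) <= 10 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    return float(min(res.pvalue, 1.0))


def holm_bonferroni(pvalues, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Holm-Bonferroni step-down procedure.

    Sorts the m p-values ascending and rejects while
    ``p_(i) <= alpha / (m - i + 1)`` (1-based rank i), stopping at the first
    failure. Returns ``(rejected, thresholds)`` where ``rejected`` flags the
    p-values in their *input* order and ``thresholds[i - 1]`` is the rank-i
    threshold ``alpha / (m - i + 1)``.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    thresholds = alpha / (m - np.arange(m))
    order = np.argsort(p, kind="stable")
    rejected = np.zeros(m, dtype=bool)
    for rank, idx in enumerate(order):
        if p[idx] <= thresholds[rank]:
            rejected[idx] = True
        else:
            break
    return rejected, thresholds


# ---------------------------------------------------------------------------
# couple selection
# ---------------------------------------------------------------------------

@dataclass
class SelectionResult:
    """Outcome of the 84 -> 2 feature reduction."""

    lasso_coefficients: dict[str, float]
    normalization: NormalizationParams | None
    uncorrelated_couples: list[tuple[str, str]]
    couple_pvalues: dict[tuple[str, str], float]
    significant_couples: list[tuple[str, str]]
    selected_couple: tuple[str, str]
    feature_pvalues: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "lasso_coefficients": self.lasso_coefficients,
            "normalization": None if self.normalization is None else self.normalization.to_dict(),
            "uncorrelated_couples": [list(c) for c in self.uncorrelated_couples],
            "couple_pvalues": {f"{a}|{b}": p for (a, b), p in self.couple_pvalues.items()},
            "significant_couples": [list(c) for c in self.significant_couples],
            "selected_couple": list(self.selected_couple),
            "feature_pvalues": self.feature_pvalues,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SelectionResult":
        return cls(
            lasso_coefficients=dict(d["lasso_coefficients"]),
            normalization=(
                None if d.get("normalization") is None
                else NormalizationParams.from_dict(d["normalization"])
            ),
            uncorrelated_couples=[tuple(c) for c in d["uncorrelated_couples"]],
            couple_pvalues={
                tuple(k.split("|")): float(p) for k, p in d["couple_pvalues"].items()
            },
            significant_couples=[tuple(c) for c in d["significant_couples"]],
            selected_couple=tuple(d["selected_couple"]),
            feature_pvalues=dict(d.get("feature_pvalues", {})),
        )


def select_couple(
    X: pd.DataFrame,
    y: np.ndarray,
    lasso_coefficients: dict[str, float],
    rho_max: float = 0.15,
    alpha: float = 0.05,
) -> SelectionResult:
    """Choose the most discriminant uncorrelated couple of LASSO features.

    ``X`` must contain training rows only. Raises
    :class:`NoUncorrelatedPairError` / :class:`NoSignificantCoupleError`
    when the candidate set collapses.
    """
    y = np.asarray(y, dtype=int)
    features = list(lasso_coefficients)
    couples = uncorrelated_pairs(X, features, rho_max=rho_max)
    if not couples:
        raise NoUncorrelatedPairError(
            f"no pair of the {len(features)} LASSO features has |rho| < {rho_max}"
        )

    feat_p = {
        f: wilcoxon_rank_sum(X[f].to_numpy()[y == 0], X[f].to_numpy()[y == 1])
        for f in sorted({f for c in couples for f in c})
    }
    couple_p = {(a, b): max(feat_p[a], feat_p[b]) for a, b in couples}

    pvals = np.array([couple_p[c] for c in couples])
    rejected, _ = holm_bonferroni(pvals, alpha=alpha)
    significant = [c for c, r in zip(couples, rejected) if r]
    if not significant:
        diag = sorted(couple_p.items(), key=lambda kv: kv[1])[:5]
        raise NoSignificantCoupleError(
            f"no couple significant after Holm-Bonferroni at alpha={alpha}; "
            f"smallest couple p-values: {[(list(c), round(p, 5)) for c, p in diag]}"
        )

    def sort_key(c):
        weight = abs(lasso_coefficients[c[0]]) + abs(lasso_coefficients[c[1]])
        return (couple_p[c], -weight, c)

    selected = min(significant, key=sort_key)
    return SelectionResult(
        lasso_coefficients=dict(lasso_coefficients),
        normalization=None,
        uncorrelated_couples=couples,
        couple_pvalues=couple_p,
        significant_couples=significant,
        selected_couple=selected,
        feature_pvalues=feat_p,
    )


def select_features(
    table: CohortTable,
    rho_max: float = 0.15,
    alpha: float = 0.05,
    seed: int = 0,
    n_folds: int = 10,
    n_lambda: int = 100,
) -> SelectionResult:
    """Full selection chain on a partitioned cohort table (training rows only)."""
    if not table.has_partition:
        raise ValidationError("selection requires a train/test partition")
    normalized, norm = normalize_standardize(table)
    X_train = normalized.X("train")
    y_train = normalized.y("train")
    coefs = lasso_rank(X_train, y_train, n_folds=n_folds, seed=seed, n_lambda=n_lambda)
    if len(coefs) < 2:
        raise NoUncorrelatedPairError(
            f"LASSO retained {len(coefs)} feature(s); need at least 2"
        )
    result = select_couple(X_train, y_train, coefs, rho_max=rho_max, alpha=alpha)
    result.normalization = norm
    return result
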