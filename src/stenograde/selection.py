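"""Per-task feature processing: scaling, the three-step selection chain, SMOTE.

The selection chain, run independently for each cascade sub-task on training
rows only:

1. **Redundancy filter** — of any feature pair with |Spearman rho| > 0.95, the
   member with the higher mean absolute correlation to all other features is
   dropped (pairs processed in descending |rho|, lexicographic tie-break, so
   the result is deterministic).
2. **Rank-sum filter** — a two-sided Wilcoxon rank-sum (Mann-Whitney) test per
   feature; only features with p < alpha (default 0.05, uncorrected) survive.
3. **LASSO** — an L1-penalized logistic model with the penalty chosen by
   seeded 5-fold cross-validation at one-standard-error parsimony; features
   with nonzero coefficients are the final set.

Class balancing uses SMOTE: synthetic minority rows interpolated between a
minority sample and one of its k nearest minority neighbors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import NearestNeighbors
from sklearn.preprocessing import StandardScaler

__all__ = [
    "SelectionReport",
    "fit_scaler",
    "apply_scaler",
    "correlation_filter",
    "wilcoxon_filter",
    "lasso_select",
    "smote_balance",
    "select_features",
]


@dataclass
class SelectionReport:
    """Outcome of the three-step chain for one sub-task; sets are nested."""

    task: str
    kept_after_correlation: list[str]
    kept_after_wilcoxon: list[str]
    wilcoxon_pvalues: dict[str, float]
    kept_after_lasso: list[str]
    lasso_coefficients: dict[str, float]
    thresholds: dict[str, float] = field(
        default_factory=lambda: {"rho_max": 0.95, "alpha": 0.05}
    )

    def __post_init__(self) -> None:
        a, b, c = (
            set(self.kept_after_lasso),
            set(self.kept_after_wilcoxon),
            set(self.kept_after_correlation),
        )
        if not (a <= b <= c):
            raise ValueError("selection sets must be nested (lasso ⊆ wilcoxon ⊆ correlation)")

    def to_dict(self) -> dict:
        return {
            "task": self.task,
            "thresholds": self.thresholds,
            "kept_after_correlation": self.kept_after_correlation,
            "kept_after_wilcoxon": self.kept_after_wilcoxon,
            "wilcoxon_pvalues": self.wilcoxon_pvalues,
            "kept_after_lasso": self.kept_after_lasso,
            "lasso_coefficients": self.lasso_coefficients,
        }


def fit_scaler(x_train: pd.DataFrame) -> StandardScaler:
    """Per-feature z-score scaler fitted on training rows only.

    Zero-variance features are centered but not divided (sklearn sets their
    scale to 1), so constant columns pass through as zeros.
    """
    return StandardScaler().fit(x_train.to_numpy())


def apply_scaler(scaler: StandardScaler, x: pd.DataFrame) -> pd.DataFrame:
    return pd.DataFrame(
        scaler.transform(x.to_numpy()), index=x.index, columns=x.columns
    )


def correlation_filter(x: pd.DataFrame, rho_max: float = 0.95) -> list[str]:
    """Drop one member of every feature pair with |Spearman rho| > rho_max.

    Pairs are processed in descending |rho| (ties broken by the lexicographic
    order of the name pair); the dropped member is the one with the higher mean
    absolute Spearman correlation to all other features, computed once on the
    full input matrix. Returns surviving names in original column order.
    """
    if len(x) < 2:
        raise ValueError("need at least 2 rows")
    names = list(x.columns)
    ranks = np.apply_along_axis(stats.rankdata, 0, x.to_numpy())
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = np.corrcoef(ranks, rowvar=False)
    rho = np.nan_to_num(np.atleast_2d(rho), nan=0.0)  # constant columns: rho 0
    np.fill_diagonal(rho, 0.0)
    abs_rho = np.abs(rho)
    mean_abs = abs_rho.sum(axis=1) / max(len(names) - 1, 1)

    iu, ju = np.triu_indices(len(names), k=1)
    over = abs_rho[iu, ju] > rho_max
    pairs = sorted(
        zip(abs_rho[iu, ju][over], iu[over], ju[over]),
        key=lambda t: (-t[0], names[t[1]], names[t[2]]),
    )
    dropped: set[int] = set()
    for _, i, j in pairs:
        if i in dropped or j in dropped:
            continue
        if mean_abs[i] > mean_abs[j]:
            dropped.add(i)
        elif mean_abs[j] > mean_abs[i]:
            dropped.add(j)
        else:  # exact tie: drop the lexicographically later name
            dropped.add(i if names[i] > names[j] else j)
    return [n for k, n in enumerate(names) if k not in dropped]


def wilcoxon_filter(
    x: pd.DataFrame, y: np.ndarray, alpha: float = 0.05
) -> tuple[list[str], dict[str, float]]:
    """Keep features whose two-sided rank-sum p-value is below alpha.

    Uses exact enumeration when both groups have <= 20 samples and the feature
    has no cross-group ties, and the tie-corrected normal approximation
    otherwise.
    """
    y = np.asarray(y)
    groups = np.unique(y)
    if len(groups) != 2:
        raise ValueError("y must be binary")
    mask = y == groups[0]
    n0, n1 = int(mask.sum()), int((~mask).sum())
    if min(n0, n1) < 3:
        raise ValueError(f"each group needs >= 3 samples, got {n0} and {n1}")
    small = max(n0, n1) <= 20
    pvalues: dict[str, float] = {}
    for name in x.columns:
        col = x[name].to_numpy()
        a, b = col[mask], col[~mask]
        if np.all(col == col[0]):
            pvalues[name] = 1.0
            continue
        method = "exact" if small and len(np.unique(col)) == len(col) else "asymptotic"
        pvalues[name] = float(
            stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue
        )
    kept = [n for n in x.columns if pvalues[n] < alpha]
    return kept, pvalues


def lasso_select(
    x: pd.DataFrame,
    y: np.ndarray,
    seed: int = 0,
    n_folds: int = 5,
    cs: np.ndarray | None = None,
) -> tuple[list[str], dict[str, float]]:
    """Final selection by L1-penalized logistic regression.

    The inverse penalty C is chosen over a log grid by stratified ``n_folds``
    cross-validated deviance at one-standard-error parsimony: the strongest
    penalty whose mean score is within one SE of the best. Features with
    nonzero coefficients are returned ordered by |coefficient|, descending.
    Falls back to the minimum-deviance penalty if the parsimonious fit keeps
    nothing, then to the single best univariate feature.
    """
    y = np.asarray(y)
    if len(np.unique(y)) != 2:
        raise ValueError("y must be binary")
    if cs is None:
        cs = np.logspace(-3, 0.5, 8)
    xv = x.to_numpy()
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    scores = np.zeros((n_folds, len(cs)))
    for f, (tr, te) in enumerate(cv.split(xv, y)):
        for k, c in enumerate(cs):
            clf = LogisticRegression(
                l1_ratio=1.0, C=c, solver="liblinear", random_state=seed,
                max_iter=200, tol=1e-3,
            ).fit(xv[tr], y[tr])
            prob = np.clip(clf.predict_proba(xv[te])[:, 1], 1e-12, 1 - 1e-12)
            yb = (y[te] == clf.classes_[1]).astype(float)
            scores[f, k] = float(
                np.mean(yb * np.log(prob) + (1 - yb) * np.log(1 - prob))
            )
    mean = scores.mean(axis=0)
    se = scores.std(axis=0, ddof=1) / np.sqrt(n_folds)
    best = int(np.argmax(mean))
    within = np.flatnonzero(mean >= mean[best] - se[best])
    pick = int(within.min())  # smallest C = strongest penalty within 1 SE

    def _nonzero(c: float) -> tuple[list[str], dict[str, float]]:
        clf = LogisticRegression(
            l1_ratio=1.0, C=c, solver="liblinear", random_state=seed, max_iter=500
        ).fit(xv, y)
        coef = clf.coef_.ravel()
        idx = np.flatnonzero(coef)
        order = idx[np.argsort(-np.abs(coef[idx]))]
        return [x.columns[k] for k in order], {
            str(x.columns[k]): float(coef[k]) for k in order
        }

    names, coefs = _nonzero(cs[pick])
    if not names and pick != best:
        names, coefs = _nonzero(cs[best])
    if not names:
        warnings.warn(
            "LASSO kept no features; falling back to the best univariate feature"
        )
        _, pvals = wilcoxon_filter(x, y, alpha=1.1)
        top = min(pvals, key=pvals.get)
        names, coefs = [top], {top: 0.0}
    return names, coefs


def smote_balance(
    x: np.ndarray | pd.DataFrame,
    y: np.ndarray,
    k_neighbors: int = 5,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Equalize class counts by synthetic minority oversampling.

    Each synthetic row is ``s + u * (nb - s)`` with u ~ U(0, 1), where ``s`` is
    a minority sample and ``nb`` one of its ``k_neighbors`` nearest minority
    neighbors. Original rows are preserved verbatim, in order, ahead of the
    synthetic ones.
    """
    xv = x.to_numpy() if isinstance(x, pd.DataFrame) else np.asarray(x, dtype=float)
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    classes, counts = np.unique(y, return_counts=True)
    target = counts.max()
    new_x = [xv]
    new_y = [y]
    for cls, cnt in zip(classes, counts):
        deficit = int(target - cnt)
        if deficit == 0:
            continue
        if cnt < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 samples")
        k = k_neighbors
        if cnt <= k:
            k = int(cnt - 1)
            warnings.warn(
                f"minority class {cls!r} has only {cnt} samples; "
                f"reducing k_neighbors to {k}"
            )
        pool = xv[y == cls]
        nn = NearestNeighbors(n_neighbors=k + 1).fit(pool)
        neighbors = nn.kneighbors(pool, return_distance=False)[:, 1:]
        seeds = rng.integers(0, cnt, size=deficit)
        picks = neighbors[seeds, rng.integers(0, k, size=deficit)]
        gaps = rng.random((deficit, 1))
        synth = pool[seeds] + gaps * (pool[picks] - pool[seeds])
        new_x.append(synth)
        new_y.append(np.full(deficit, cls, dtype=y.dtype))
    return np.vstack(new_x), np.concatenate(new_y)


def select_features(
    x_train: pd.DataFrame,
    y_train: np.ndarray,
    task: str = "a",
    rho_max: float = 0.95,
    alpha: float = 0.05,
    seed: int = 0,
) -> SelectionReport:
    """Run the full three-step chain on (already scaled) training rows."""
    kept_corr = correlation_filter(x_train, rho_max=rho_max)
    kept_wilcoxon, pvalues = wilcoxon_filter(x_train[kept_corr], y_train, alpha=alpha)
    if kept_wilcoxon:
        kept_lasso, coefs = lasso_select(x_train[kept_wilcoxon], y_train, seed=seed)
    else:
        warnings.warn(f"task {task}: no feature passed the rank-sum filter")
        kept_lasso, coefs = [], {}
    return SelectionReport(
        task=task,
        kept_after_correlation=kept_corr,
        kept_after_wilcoxon=kept_wilcoxon,
        wilcoxon_pvalues={k: pvalues[k] for k in kept_wilcoxon},
        kept_after_lasso=kept_lasso,
        lasso_coefficients=coefs,
        thresholds={"rho_max": rho_max, "alpha": alpha},
    )
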