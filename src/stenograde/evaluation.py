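"""Patient-stratified splitting, metrics, and clinical association analysis.

Splits are always by patient: all images of a patient follow the patient, so
no image of a test patient can leak into training. The outer split holds out
15% of patients (label-stratified); robustness is assessed over 30 further
stratified 80/20 train/validation splits of the training pool.

Metrics follow the macro conventions: balanced accuracy is the unweighted mean
of per-class recall; sensitivity/specificity/F1/AUC are one-vs-rest,
unweighted class means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import confusion_matrix, roc_auc_score
from sklearn.model_selection import StratifiedShuffleSplit

from .synthetic import CLASS_LABELS

__all__ = [
    "SplitPlan",
    "Splits",
    "make_splits",
    "EvaluationReport",
    "compute_metrics",
    "associate_clinical",
    "compare_models",
]


@dataclass(frozen=True)
class SplitPlan:
    """Patient- and label-stratified split configuration."""

    test_fraction: float = 0.15
    inner_repeats: int = 30
    inner_val_fraction: float = 0.20
    seed: int = 0


@dataclass
class Splits:
    """Outer test set plus repeated inner (train, validation) partitions."""

    test_patients: list[str]
    inner: list[tuple[list[str], list[str]]]
    train_pool: list[str]


def make_splits(
    patients: list[str], labels: pd.Series | dict, plan: SplitPlan
) -> Splits:
    """Deterministic stratified patient partitions.

    Every inner (train, validation) pair partitions the training pool exactly;
    class proportions are preserved within rounding. A class with fewer than 2
    patients cannot be stratified and raises.
    """
    patients = list(patients)
    y = np.array([labels[p] for p in patients])
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < 2:
        bad = classes[counts.argmin()]
        raise ValueError(f"class {bad!r} has fewer than 2 patients; cannot stratify")
    outer = StratifiedShuffleSplit(
        n_splits=1, test_size=plan.test_fraction, random_state=plan.seed
    )
    (train_idx, test_idx), = outer.split(np.zeros(len(patients)), y)
    pool = [patients[i] for i in train_idx]
    test = sorted(patients[i] for i in test_idx)
    y_pool = y[train_idx]
    inner_splitter = StratifiedShuffleSplit(
        n_splits=plan.inner_repeats,
        test_size=plan.inner_val_fraction,
        random_state=plan.seed + 1,
    )
    inner = [
        (sorted(pool[i] for i in tr), sorted(pool[i] for i in va))
        for tr, va in inner_splitter.split(np.zeros(len(pool)), y_pool)
    ]
    return Splits(test_patients=test, inner=inner, train_pool=sorted(pool))


@dataclass
class EvaluationReport:
    """Patient-level confusion matrix and macro metrics for one split."""

    confusion: np.ndarray
    class_order: tuple[str, ...]
    balanced_accuracy: float
    macro_sensitivity: float
    macro_specificity: float
    macro_f1: float
    macro_auc: float | None = None
    n_patients: int = 0

    def to_dict(self) -> dict:
        return {
            "class_order": list(self.class_order),
            "confusion": self.confusion.tolist(),
            "balanced_accuracy": self.balanced_accuracy,
            "macro_sensitivity": self.macro_sensitivity,
            "macro_specificity": self.macro_specificity,
            "macro_f1": self.macro_f1,
            "macro_auc": self.macro_auc,
            "n_patients": self.n_patients,
        }


def compute_metrics(
    y_true,
    y_pred,
    scores: pd.DataFrame | np.ndarray | None = None,
    class_order: tuple[str, ...] = CLASS_LABELS,
) -> EvaluationReport:
    """Macro metrics over patients.

    ``scores`` (optional, one column per class in ``class_order``) enables
    macro one-vs-rest AUC; without it AUC is None with a warning. Classes
    absent from ``y_true`` are excluded from the class means with a warning.
    """
    y_true = np.asarray(list(y_true))
    y_pred = np.asarray(list(y_pred))
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    cm = confusion_matrix(y_true, y_pred, labels=list(class_order))
    present = cm.sum(axis=1) > 0
    if not present.all():
        absent = [c for c, ok in zip(class_order, present) if not ok]
        warnings.warn(f"classes absent from y_true excluded from macro means: {absent}")

    recalls, specs, f1s = [], [], []
    total = cm.sum()
    for k, ok in enumerate(present):
        if not ok:
            continue
        tp = cm[k, k]
        fn = cm[k].sum() - tp
        fp = cm[:, k].sum() - tp
        tn = total - tp - fn - fp
        recalls.append(tp / (tp + fn))
        specs.append(tn / (tn + fp) if tn + fp > 0 else 1.0)
        f1s.append(2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn > 0 else 0.0)

    auc = None
    if scores is not None:
        s = np.asarray(scores, dtype=float)
        if present.all():
            y_idx = np.array([list(class_order).index(c) for c in y_true])
            auc = float(
                roc_auc_score(y_idx, s / s.sum(axis=1, keepdims=True),
                              multi_class="ovr", average="macro")
            )
        else:
            aucs = []
            for k, ok in enumerate(present):
                if ok and cm[k].sum() < total:
                    aucs.append(
                        float(roc_auc_score((y_true == class_order[k]).astype(int), s[:, k]))
                    )
            auc = float(np.mean(aucs)) if aucs else None
    else:
        warnings.warn("no scores given; AUC skipped")

    return EvaluationReport(
        confusion=cm,
        class_order=tuple(class_order),
        balanced_accuracy=float(np.mean(recalls)),
        macro_sensitivity=float(np.mean(recalls)),
        macro_specificity=float(np.mean(specs)),
        macro_f1=float(np.mean(f1s)),
        macro_auc=auc,
        n_patients=int(total),
    )


BINARY_CLINICAL = (
    "sex",
    "hypertension",
    "smoking",
    "hyperlipidemia",
    "diabetes",
    "family_history",
)


def associate_clinical(
    ae_features: pd.DataFrame,
    clinical: pd.DataFrame,
    aggregate: str = "mean",
) -> pd.DataFrame:
    """Association of selected AE features with clinical variables.

    AE features (rows = images or patients) are aggregated per patient (mean
    by default, median optionally). For each binary clinical column a
    two-sided Mann-Whitney U p-value is computed per feature; numeric ``age``
    yields Spearman rho and its p-value. No multiplicity correction is
    applied. Cells that cannot be assessed (subgroup n < 3, constant feature)
    are reported with NaN statistics and ``assessable=False``.
    """
    if aggregate not in ("mean", "median"):
        raise ValueError("aggregate must be 'mean' or 'median'")
    if isinstance(ae_features.index, pd.MultiIndex):
        grouped = ae_features.groupby(level="patient_id")
        per_patient = grouped.mean() if aggregate == "mean" else grouped.median()
    else:
        per_patient = ae_features
    joined = per_patient.join(clinical, how="inner")
    rows = []
    for feat in per_patient.columns:
        x = joined[feat].to_numpy(dtype=float)
        constant = np.all(x == x[0])
        for var in BINARY_CLINICAL:
            if var not in clinical.columns:
                continue
            g = joined[var].to_numpy()
            x0, x1 = x[g == 0], x[g == 1]
            if constant or min(len(x0), len(x1)) < 3:
                rows.append(
                    {"feature": feat, "variable": var, "statistic": np.nan,
                     "p_value": np.nan, "assessable": False}
                )
                continue
            res = stats.mannwhitneyu(x0, x1, alternative="two-sided")
            rows.append(
                {"feature": feat, "variable": var, "statistic": float(res.statistic),
                 "p_value": float(res.pvalue), "assessable": True}
            )
        if "age" in clinical.columns:
            if constant:
                rows.append(
                    {"feature": feat, "variable": "age", "statistic": np.nan,
                     "p_value": np.nan, "assessable": False}
                )
            else:
                rho, p = stats.spearmanr(x, joined["age"].to_numpy(dtype=float))
                rows.append(
                    {"feature": feat, "variable": "age", "statistic": float(rho),
                     "p_value": float(p), "assessable": True}
                )
    return pd.DataFrame(rows)


def compare_models(metric_a: np.ndarray, metric_b: np.ndarray) -> float:
    """Paired Wilcoxon signed-rank p-value over repeated splits."""
    metric_a = np.asarray(metric_a, dtype=float)
    metric_b = np.asarray(metric_b, dtype=float)
    if metric_a.shape != metric_b.shape:
        raise ValueError("paired metric arrays must have equal length")
    if np.allclose(metric_a, metric_b):
        return 1.0
    return float(stats.wilcoxon(metric_a, metric_b).pvalue)
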