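"""Utility metrics and statistical machinery for classifier audits.

AUROC is computed in its Mann–Whitney formulation (ties count half);
operating thresholds follow Youden's criterion (maximize TPR − FPR);
uncertainty is quantified by record-level bootstrap, and AUROC differences
between two models are tested with the Hanley & McNeil normal approximation.

The interchange object between training and auditing is the
:class:`PredictionTable`: one row per record with subgroup attributes and
paired truth/score columns per label.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

__all__ = [
    "UndefinedMetricError",
    "PredictionTable",
    "BootstrapResult",
    "auroc",
    "youden_threshold",
    "confusion_metrics",
    "bootstrap",
    "hanley_mcneil_test",
    "pearson_r",
    "macro_average",
    "metric_report",
]


class UndefinedMetricError(ValueError):
    """A metric has no defined value on the given data (e.g. one class only)."""


@dataclass
class PredictionTable:
    """Per-record scores and truths with subgroup metadata.

    ``frame`` holds columns ``record_id``, ``patient_id``, ``sex``,
    ``age_group`` plus ``y_true_<label>`` (in {0,1}) and ``y_score_<label>``
    (in [0,1]) for each entry of ``labels``.
    """

    frame: pd.DataFrame
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        if not self.labels:
            raise ValueError("PredictionTable needs at least one label")
        if self.frame["record_id"].duplicated().any():
            raise ValueError("duplicate record_ids in PredictionTable")
        for label in self.labels:
            for col in (f"y_true_{label}", f"y_score_{label}"):
                if col not in self.frame.columns:
                    raise ValueError(f"missing column {col}")
            scores = self.frame[f"y_score_{label}"].to_numpy()
            if np.any((scores < 0) | (scores > 1)):
                raise ValueError(f"scores for {label} outside [0, 1]")

    def __len__(self) -> int:
        return len(self.frame)

    def truths(self, label: str) -> np.ndarray:
        return self.frame[f"y_true_{label}"].to_numpy(dtype=int)

    def scores(self, label: str) -> np.ndarray:
        return self.frame[f"y_score_{label}"].to_numpy(dtype=float)

    def subset(self, mask: np.ndarray) -> "PredictionTable":
        return PredictionTable(self.frame.loc[mask].reset_index(drop=True), self.labels)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PredictionTable":
        frame = pd.read_csv(path)
        labels = tuple(
            c[len("y_true_"):] for c in frame.columns if c.startswith("y_true_")
        )
        return cls(frame, labels)


def auroc(scores: np.ndarray, truths: np.ndarray) -> float:
    """Area under the ROC curve, Mann–Whitney style.

    Equals (wins + 0.5·ties) / (n_pos · n_neg) over all positive–negative
    pairs, computed from midranks in O(n log n).
    """
    scores = np.asarray(scores, dtype=float)
    truths = np.asarray(truths, dtype=int)
    n_pos = int(truths.sum())
    n_neg = truths.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("AUROC needs both classes present")
    ranks = rankdata(scores)  # midranks handle ties as half-wins
    rank_sum = ranks[truths == 1].sum()
    return float((rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def youden_threshold(scores: np.ndarray, truths: np.ndarray) -> float:
    """Observed score maximizing TPR − FPR with ≥-threshold positivity.

    Ties in the criterion are broken toward the smallest maximizing threshold.
    """
    scores = np.asarray(scores, dtype=float)
    truths = np.asarray(truths, dtype=int)
    n_pos = int(truths.sum())
    n_neg = truths.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("Youden threshold needs both classes present")
    candidates = np.unique(scores)  # ascending
    # counts of records with score >= t for each candidate t
    order_pos = np.sort(scores[truths == 1])
    order_neg = np.sort(scores[truths == 0])
    tpr = (n_pos - np.searchsorted(order_pos, candidates, side="left")) / n_pos
    fpr = (n_neg - np.searchsorted(order_neg, candidates, side="left")) / n_neg
    j = tpr - fpr
    return float(candidates[int(np.argmax(j))])  # argmax takes first (smallest) max


def confusion_metrics(
    scores: np.ndarray, truths: np.ndarray, threshold: float
) -> tuple[float, float, float]:
    """(sensitivity, specificity, accuracy) at a ≥-threshold decision rule."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    scores = np.asarray(scores, dtype=float)
    truths = np.asarray(truths, dtype=int)
    pred = (scores >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (truths == 1)))
    tn = int(np.sum((pred == 0) & (truths == 0)))
    fp = int(np.sum((pred == 1) & (truths == 0)))
    fn = int(np.sum((pred == 0) & (truths == 1)))
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    acc = (tp + tn) / truths.size
    return sens, spec, acc


@dataclass(frozen=True)
class BootstrapResult:
    mean: float
    std: float
    ci_low: float
    ci_high: float
    n_redraws: int
    n_skipped: int


def bootstrap(
    table: PredictionTable,
    metric: Callable[[PredictionTable], float],
    n_redraws: int = 1000,
    seed: int | np.random.Generator = 0,
    patient_level: bool = False,
) -> BootstrapResult:
    """Resample records (or patients) with replacement and summarize a metric.

    Redraws on which the metric is undefined (e.g. a single-class resample)
    are skipped and counted; more than 50% undefined redraws raise.
    """
    if n_redraws < 1:
        raise ValueError("n_redraws must be >= 1")
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    values: list[float] = []
    skipped = 0
    if patient_level:
        patients = table.frame["patient_id"].to_numpy()
        unique_patients = np.unique(patients)
    for _ in range(n_redraws):
        if patient_level:
            chosen = rng.choice(unique_patients, size=unique_patients.size, replace=True)
            parts = [table.frame[patients == p] for p in chosen]
            frame = pd.concat(parts, ignore_index=True)
            frame["record_id"] = np.arange(len(frame))  # resampled rows duplicate ids
            resampled = PredictionTable(frame, table.labels)
        else:
            idx = rng.integers(0, len(table), size=len(table))
            frame = table.frame.iloc[idx].reset_index(drop=True)
            frame["record_id"] = np.arange(len(frame))
            resampled = PredictionTable(frame, table.labels)
        try:
            values.append(float(metric(resampled)))
        except UndefinedMetricError:
            skipped += 1
    if skipped > n_redraws / 2:
        raise UndefinedMetricError(
            f"metric undefined on {skipped}/{n_redraws} bootstrap redraws"
        )
    arr = np.asarray(values)
    lo, hi = np.percentile(arr, [2.5, 97.5])
    return BootstrapResult(
        float(arr.mean()), float(arr.std(ddof=0)), float(lo), float(hi),
        n_redraws, skipped,
    )


def _hanley_mcneil_se(auc: float, n_pos: int, n_neg: int) -> float:
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (
        auc * (1.0 - auc)
        + (n_pos - 1) * (q1 - auc**2)
        + (n_neg - 1) * (q2 - auc**2)
    ) / (n_pos * n_neg)
    return float(np.sqrt(max(var, 0.0)))


def hanley_mcneil_test(
    auc1: float, n_pos1: int, n_neg1: int,
    auc2: float, n_pos2: int, n_neg2: int,
) -> tuple[float, float]:
    """Two-sided z-test for a difference of two independent AUROCs.

    Standard errors follow Hanley & McNeil with Q1 = A/(2−A) and
    Q2 = 2A²/(1+A); returns (z, two-sided p).
    """
    for n in (n_pos1, n_neg1, n_pos2, n_neg2):
        if n < 2:
            raise ValueError("Hanley–McNeil test needs >= 2 records per class")
    se1 = _hanley_mcneil_se(auc1, n_pos1, n_neg1)
    se2 = _hanley_mcneil_se(auc2, n_pos2, n_neg2)
    denom = np.sqrt(se1**2 + se2**2)
    if denom == 0.0:
        z = 0.0 if auc1 == auc2 else float("inf") * np.sign(auc1 - auc2)
    else:
        z = (auc1 - auc2) / denom
    p = 2.0 * (1.0 - norm.cdf(abs(z)))
    return float(z), float(p)


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation; raises on degenerate input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("pearson_r needs two equal-length vectors of length >= 2")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise UndefinedMetricError("pearson_r undefined for zero-variance input")
    return float(np.corrcoef(x, y)[0, 1])


def macro_average(per_label_values: Sequence[float]) -> float:
    """Unweighted mean over labels."""
    values = np.asarray(per_label_values, dtype=float)
    if values.size == 0:
        raise ValueError("macro_average of an empty sequence")
    return float(values.mean())


def macro_auroc(table: PredictionTable) -> float:
    """Macro (label-averaged) AUROC of a prediction table."""
    return macro_average([auroc(table.scores(l), table.truths(l)) for l in table.labels])


def metric_report(
    table: PredictionTable,
    thresholds: dict[str, float] | None = None,
    n_redraws: int = 1000,
    seed: int = 0,
) -> dict:
    """Per-label and macro AUROC/sensitivity/specificity/accuracy with bootstrap.

    Thresholds default to per-label Youden thresholds computed on ``table``;
    pass precomputed ones to reuse a global operating point on subgroups.
    """
    if thresholds is None:
        thresholds = {
            l: youden_threshold(table.scores(l), table.truths(l)) for l in table.labels
        }
    per_label: dict[str, dict] = {}
    for label in table.labels:
        s, t = table.scores(label), table.truths(label)
        sens, spec, acc = confusion_metrics(s, t, thresholds[label])
        per_label[label] = {
            "auroc": auroc(s, t),
            "sensitivity": sens,
            "specificity": spec,
            "accuracy": acc,
            "threshold": thresholds[label],
        }
    report = {
        "per_label": per_label,
        "macro": {
            m: macro_average([per_label[l][m] for l in table.labels])
            for m in ("auroc", "sensitivity", "specificity", "accuracy")
        },
        "thresholds": thresholds,
    }
    report["macro_bootstrap"] = _bootstrap_macro_metrics(
        table, thresholds, n_redraws, seed
    )
    return report


def _bootstrap_macro_metrics(
    table: PredictionTable,
    thresholds: dict[str, float],
    n_redraws: int,
    seed: int,
) -> dict:
    """One record-level resampling pass evaluating all four macro metrics.

    Thresholds stay fixed at the full-split operating points; redraws on
    which AUROC is undefined (single-class resample) are skipped for all
    metrics and counted.
    """
    rng = np.random.default_rng(seed)
    truths = np.column_stack([table.truths(l) for l in table.labels])
    scores = np.column_stack([table.scores(l) for l in table.labels])
    thr = np.array([thresholds[l] for l in table.labels])
    n = truths.shape[0]
    draws: dict[str, list[float]] = {
        m: [] for m in ("auroc", "sensitivity", "specificity", "accuracy")
    }
    skipped = 0
    for _ in range(n_redraws):
        idx = rng.integers(0, n, size=n)
        t, s = truths[idx], scores[idx]
        try:
            aurocs = [auroc(s[:, j], t[:, j]) for j in range(t.shape[1])]
        except UndefinedMetricError:
            skipped += 1
            continue
        pred = s >= thr
        pos = t == 1
        sens = np.array([
            pred[pos[:, j], j].mean() if pos[:, j].any() else np.nan
            for j in range(t.shape[1])
        ])
        spec = np.array([
            (~pred[~pos[:, j], j]).mean() if (~pos[:, j]).any() else np.nan
            for j in range(t.shape[1])
        ])
        acc = (pred == pos).mean(axis=0)
        draws["auroc"].append(float(np.mean(aurocs)))
        draws["sensitivity"].append(float(np.nanmean(sens)))
        draws["specificity"].append(float(np.nanmean(spec)))
        draws["accuracy"].append(float(np.mean(acc)))
    if skipped > n_redraws / 2:
        raise UndefinedMetricError(
            f"macro metrics undefined on {skipped}/{n_redraws} redraws"
        )
    out: dict = {"n_redraws": n_redraws, "skipped": skipped}
    for m, vals in draws.items():
        arr = np.asarray(vals)
        lo, hi = np.percentile(arr, [2.5, 97.5])
        out[m] = {
            "mean": float(arr.mean()), "std": float(arr.std(ddof=0)),
            "ci": [float(lo), float(hi)],
        }
    return out
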