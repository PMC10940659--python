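"""Subgroup disparity statistics and their trends across privacy levels.

The central quantity is the statistical parity difference

    PtD = P(correct | minority) − P(correct | majority),

where "correct" means the thresholded prediction matches the truth.  PtD is
optimally zero; negative values mean the minority group is discriminated
against.  The complementary underdiagnosis rate is the per-group false
negative rate.  Trends across a privacy-budget grid are summarized by
Pearson's r of the disparity against ln ε.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .evaluation import PredictionTable, UndefinedMetricError, pearson_r

__all__ = [
    "GroupAssignment",
    "assign_groups",
    "correctness_indicator",
    "statistical_parity_difference",
    "underdiagnosis_rate",
    "disparity_trend",
    "fairness_report",
]


@dataclass(frozen=True)
class GroupAssignment:
    """Per-record group labels with designated minority and majority groups."""

    attribute: str
    group_of_record: tuple
    minority: str
    majority: str

    def __post_init__(self) -> None:
        if self.minority == self.majority:
            raise ValueError("minority and majority must differ")
        groups = np.asarray(self.group_of_record)
        for g in (self.minority, self.majority):
            if not np.any(groups == g):
                raise ValueError(f"group {g!r} is empty in the evaluated split")


def assign_groups(
    metadata: pd.DataFrame,
    attribute: str,
    focus_group: str | None = None,
    reference_counts: Mapping[str, int] | None = None,
) -> GroupAssignment:
    """Designate minority/majority groups for a metadata attribute.

    The minority is the smaller group by record count — counted on
    ``reference_counts`` (e.g. the training split) when given, else on
    ``metadata`` itself; ties break toward the lexicographically first label.
    For multi-valued attributes such as age bins, ``focus_group`` selects one
    bin which is compared against the complement ("rest").
    """
    if attribute not in metadata.columns:
        raise ValueError(f"attribute {attribute!r} missing from metadata")
    values = metadata[attribute].astype(str).to_numpy()
    if focus_group is not None:
        groups = np.where(values == focus_group, focus_group, "rest")
        if reference_counts is not None:
            n_focus = reference_counts.get(focus_group, 0)
            n_rest = sum(v for k, v in reference_counts.items() if k != focus_group)
        else:
            n_focus = int(np.sum(groups == focus_group))
            n_rest = int(np.sum(groups == "rest"))
        counts = {focus_group: n_focus, "rest": n_rest}
    else:
        uniques = sorted(set(values))
        if len(uniques) != 2:
            raise ValueError(
                f"attribute {attribute!r} has {len(uniques)} levels; pass "
                "focus_group to compare one level against the rest"
            )
        groups = values
        if reference_counts is not None:
            counts = {u: reference_counts.get(u, 0) for u in uniques}
        else:
            counts = {u: int(np.sum(values == u)) for u in uniques}
    ordered = sorted(counts, key=lambda g: (counts[g], g))
    minority, majority = ordered[0], ordered[-1]
    return GroupAssignment(attribute, tuple(groups), minority, majority)


def correctness_indicator(
    table: PredictionTable, thresholds: Mapping[str, float]
) -> np.ndarray:
    """Binary correctness per record and label: (score >= threshold) == truth."""
    out = np.empty((len(table), len(table.labels)), dtype=int)
    for j, label in enumerate(table.labels):
        if label not in thresholds:
            raise ValueError(f"missing threshold for label {label!r}")
        pred = (table.scores(label) >= thresholds[label]).astype(int)
        out[:, j] = (pred == table.truths(label)).astype(int)
    return out


def statistical_parity_difference(
    correctness: np.ndarray, groups: GroupAssignment
) -> float:
    """Minority mean correctness minus majority mean correctness.

    Multi-label correctness matrices are averaged over labels per record
    first, so every record contributes equally regardless of label count.
    """
    correctness = np.asarray(correctness, dtype=float)
    if correctness.ndim == 2:
        correctness = correctness.mean(axis=1)
    labels = np.asarray(groups.group_of_record)
    if correctness.shape[0] != labels.shape[0]:
        raise ValueError("correctness and group assignment lengths differ")
    minority_mask = labels == groups.minority
    majority_mask = labels == groups.majority
    if not minority_mask.any() or not majority_mask.any():
        raise ValueError("both groups must be non-empty")
    return float(correctness[minority_mask].mean() - correctness[majority_mask].mean())


def underdiagnosis_rate(
    table: PredictionTable,
    groups: GroupAssignment,
    thresholds: Mapping[str, float],
) -> dict[str, float]:
    """Per-group false-negative rate FN/(FN+TP), pooled over labels.

    Groups without any positive label are reported as NaN (flagged undefined).
    """
    labels = np.asarray(groups.group_of_record)
    rates: dict[str, float] = {}
    for g in sorted(set(labels.tolist())):
        mask = labels == g
        fn = tp = 0
        for label in table.labels:
            if label not in thresholds:
                raise ValueError(f"missing threshold for label {label!r}")
            truth = table.truths(label)[mask]
            pred = (table.scores(label)[mask] >= thresholds[label]).astype(int)
            tp += int(np.sum((truth == 1) & (pred == 1)))
            fn += int(np.sum((truth == 1) & (pred == 0)))
        rates[g] = fn / (fn + tp) if (fn + tp) > 0 else float("nan")
    return rates


def disparity_trend(
    parity_differences: Sequence[float],
    epsilons: Sequence[float],
    infinity_factor: float = 10.0,
) -> dict:
    """Pearson r of parity difference against ln ε plus a direction summary.

    ε = ∞ (the non-private run) is placed on the log axis at
    ``infinity_factor`` times the largest finite grid point.  Zero-variance
    disparities have no defined correlation and are reported as "no trend".
    """
    parity = np.asarray(parity_differences, dtype=float)
    eps = np.asarray(epsilons, dtype=float)
    if parity.size != eps.size or parity.size < 3:
        raise ValueError("disparity_trend needs >= 3 matched privacy levels")
    finite = eps[np.isfinite(eps)]
    if finite.size == 0:
        raise ValueError("at least one finite epsilon required")
    axis = np.where(np.isfinite(eps), eps, infinity_factor * finite.max())
    log_axis = np.log(axis)
    diffs = np.diff(parity[np.argsort(log_axis)])
    if np.all(diffs == 0):
        direction = "no trend"
    elif np.all(diffs >= 0):
        direction = "increasing"
    elif np.all(diffs <= 0):
        direction = "decreasing"
    else:
        direction = "mixed"
    try:
        r = pearson_r(log_axis, parity)
    except UndefinedMetricError:
        return {"pearson_r": float("nan"), "direction": "no trend"}
    return {"pearson_r": r, "direction": direction}


def fairness_report(
    table: PredictionTable,
    thresholds: Mapping[str, float],
    attributes: Sequence[str] = ("sex", "age_group"),
    reference_counts: Mapping[str, Mapping[str, int]] | None = None,
) -> dict:
    """Parity difference and underdiagnosis rate per subgroup attribute.

    Binary attributes (sex) are compared minority-vs-majority directly; the
    multi-valued age attribute is handled pairwise, each bin against its
    complement.  ``reference_counts`` optionally supplies training-split
    counts per attribute for the minority designation.
    """
    correct = correctness_indicator(table, thresholds)
    report: dict = {}
    for attribute in attributes:
        ref = reference_counts.get(attribute) if reference_counts else None
        values = sorted(set(table.frame[attribute].astype(str)))
        entry: dict = {}
        if len(values) == 2:
            groups = assign_groups(table.frame, attribute, reference_counts=ref)
            entry["parity_difference"] = {
                groups.minority: statistical_parity_difference(correct, groups)
            }
            entry["minority"] = groups.minority
            entry["underdiagnosis_rate"] = underdiagnosis_rate(
                table, groups, thresholds
            )
        else:
            entry["parity_difference"] = {}
            entry["underdiagnosis_rate"] = {}
            for v in values:
                groups = assign_groups(
                    table.frame, attribute, focus_group=v, reference_counts=ref
                )
                # report each bin as the "group in question" vs the rest
                ptd = statistical_parity_difference(correct, groups)
                entry["parity_difference"][v] = ptd if groups.minority == v else -ptd
                entry["underdiagnosis_rate"][v] = underdiagnosis_rate(
                    table, groups, thresholds
                )[v]
        report[attribute] = entry
    return report
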