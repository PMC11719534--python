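"""Diagnostic-performance evaluation with non-diagnostic results.

Implements confusion-matrix construction, the five standard metrics
(sensitivity, specificity, PPV, NPV, accuracy), one-vs-rest per-class
metrics, a method-comparison table, and the group-difference tests
(chi-square for categorical findings, one-way ANOVA for continuous
features).

Non-diagnostic results -- e.g. fine-needle aspiration samples that yield no
interpretable cytology -- are handled with the intention-to-diagnose
convention: they count against sensitivity, specificity and accuracy (a
non-diagnostic test failed to deliver the diagnosis) but not against PPV
or NPV (predictive values condition on a definite test result).  Percents
are reported as half-up-rounded integers alongside the exact fraction.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import stats

__all__ = [
    "BinaryConfusion",
    "Metric",
    "PerfMetrics",
    "REFERENCE_METHOD_CONFUSIONS",
    "confusion_from_predictions",
    "metrics_from_confusion",
    "per_class_metrics",
    "chi_square_table",
    "anova_by_group",
    "assemble_comparison_table",
]

METRIC_NAMES = ("sens", "spec", "ppv", "npv", "acc")


@dataclass(frozen=True)
class BinaryConfusion:
    """Binary confusion counts, with non-diagnostic results kept separate.

    ``nd_pos`` / ``nd_neg`` count non-diagnostic test results among truly
    positive / truly negative cases; both are 0 for methods that always
    return a definite result.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    nd_pos: int = 0
    nd_neg: int = 0

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn", "nd_pos", "nd_neg"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn + self.nd_pos + self.nd_neg


@dataclass(frozen=True)
class Metric:
    """One diagnostic metric as an exact fraction plus rounded percent.

    ``percent`` is None when the denominator is zero (undefined metric,
    never reported as 0).
    """

    numerator: int
    denominator: int

    @property
    def defined(self) -> bool:
        return self.denominator > 0

    @property
    def value(self) -> float | None:
        return self.numerator / self.denominator if self.defined else None

    @property
    def percent(self) -> int | None:
        """Half-up-rounded integer percent (62.5% -> 63)."""
        if not self.defined:
            return None
        # half-up on the exact fraction: floor(p + 1/2); avoids float ties
        return int(Fraction(100 * self.numerator, self.denominator) + Fraction(1, 2))

    def __str__(self) -> str:
        if not self.defined:
            return "undefined"
        return f"{self.percent}% ({self.numerator} of {self.denominator})"


@dataclass(frozen=True)
class PerfMetrics:
    """The five diagnostic metrics of one method."""

    sens: Metric
    spec: Metric
    ppv: Metric
    npv: Metric
    acc: Metric

    def percents(self) -> dict[str, int | None]:
        return {name: getattr(self, name).percent for name in METRIC_NAMES}


#: Confusion counts of the three diagnostic approaches on the original
#: 36-patient cohort (malignant vs benign).  The MRI decision tree found all
#: 8 malignant tumors with 2 benign false positives; the DCE+DWI comparator
#: missed 2 malignant tumors and called 4 benign lesions malignant; FNAC was
#: performed in 31 patients, 4 of which (all with benign lesions) were
#: non-diagnostic.  Note the comparator's sensitivity is 6/8 = 75%, although
#: it is printed elsewhere as 76% -- an internal rounding inconsistency in
#: the source; this module always reports the exact fraction.
REFERENCE_METHOD_CONFUSIONS: dict[str, BinaryConfusion] = {
    "MRI algorithm": BinaryConfusion(tp=8, fp=2, tn=26, fn=0),
    "DCE + DWI": BinaryConfusion(tp=6, fp=4, tn=24, fn=2),
    "FNAC": BinaryConfusion(tp=5, fp=1, tn=18, fn=3, nd_pos=0, nd_neg=4),
}


def confusion_from_predictions(
    truth,
    predicted,
    positive_label="malignant",
    nd_label: str | None = None,
) -> BinaryConfusion:
    """Cross-tabulate binary truth against predictions.

    ``truth`` must contain exactly two labels (positive_label and one
    other); ``predicted`` may additionally contain ``nd_label``, routed to
    the non-diagnostic counts by the true status.
    """
    truth = list(truth)
    predicted = list(predicted)
    if len(truth) != len(predicted):
        raise ValueError("truth and predicted must have equal length")
    # the label universe (truth plus predictions, minus the nd marker) must
    # be binary: the positive label and at most one negative label
    universe = set(truth) | set(predicted)
    if nd_label is not None:
        universe -= {nd_label}
    extra = universe - {positive_label}
    if len(extra) > 1:
        raise ValueError(f"unknown labels beyond a binary scheme: "
                         f"{sorted(map(str, universe))}")

    tp = fp = tn = fn = nd_pos = nd_neg = 0
    for t, p in zip(truth, predicted):
        t_pos = t == positive_label
        if nd_label is not None and p == nd_label:
            if t_pos:
                nd_pos += 1
            else:
                nd_neg += 1
        elif p == positive_label:
            if t_pos:
                tp += 1
            else:
                fp += 1
        else:
            if t_pos:
                fn += 1
            else:
                tn += 1
    return BinaryConfusion(tp=tp, fp=fp, tn=tn, fn=fn,
                           nd_pos=nd_pos, nd_neg=nd_neg)


def metrics_from_confusion(c: BinaryConfusion) -> PerfMetrics:
    """The five metrics under the intention-to-diagnose convention.

    sens = tp / (tp + fn + nd_pos), spec = tn / (tn + fp + nd_neg),
    ppv = tp / (tp + fp), npv = tn / (tn + fn), acc = (tp + tn) / total.
    A metric with zero denominator is undefined (``percent is None``).
    """
    return PerfMetrics(
        sens=Metric(c.tp, c.tp + c.fn + c.nd_pos),
        spec=Metric(c.tn, c.tn + c.fp + c.nd_neg),
        ppv=Metric(c.tp, c.tp + c.fp),
        npv=Metric(c.tn, c.tn + c.fn),
        acc=Metric(c.tp + c.tn, c.total),
    )


def per_class_metrics(truth, predicted, target_class: str) -> PerfMetrics:
    """One-vs-rest metrics for one diagnosis in a multi-class prediction."""
    truth = np.asarray(truth)
    predicted = np.asarray(predicted)
    if truth.shape != predicted.shape:
        raise ValueError("truth and predicted must have equal length")
    bin_truth = np.where(truth == target_class, target_class, "rest")
    bin_pred = np.where(predicted == target_class, target_class, "rest")
    c = confusion_from_predictions(bin_truth, bin_pred,
                                   positive_label=target_class)
    return metrics_from_confusion(c)


def chi_square_table(table) -> tuple[float, float]:
    """Pearson chi-square test on an R x C contingency table.

    No continuity correction is applied.  Raises when any expected cell
    count is zero (a zero row or column margin), since the statistic is
    undefined there.
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("need an R x C table with R, C >= 2")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero row or column margin: expected counts are 0")
    res = stats.chi2_contingency(table, correction=False)
    return float(res.statistic), float(res.pvalue)


def anova_by_group(values, groups) -> tuple[float, float]:
    """One-way ANOVA of a continuous feature across >= 2 groups."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if labels.size < 2:
        raise ValueError("need at least 2 groups")
    samples = [values[groups == g] for g in labels]
    stat, p = stats.f_oneway(*samples)
    return float(stat), float(p)


def assemble_comparison_table(confusions: dict[str, BinaryConfusion]):
    """Method-comparison report: one row per method, five percent columns.

    Undefined metrics appear as missing values.  Pass
    :data:`REFERENCE_METHOD_CONFUSIONS` to reproduce the original cohort's
    method comparison.
    """
    import pandas as pd

    if not confusions:
        raise ValueError("need at least one method")
    rows = {}
    for name, conf in confusions.items():
        m = metrics_from_confusion(conf)
        rows[name] = {k.upper(): v for k, v in m.percents().items()}
    df = pd.DataFrame.from_dict(rows, orient="index",
                                columns=[n.upper() for n in METRIC_NAMES])
    df = df.astype("Int64")
    df.index.name = "method"
    return df
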