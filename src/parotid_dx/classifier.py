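"""Rule-based diagnostic classification of parotid tumors.

The diagnostic algorithm maps three MRI features -- the ghosting sign on
late post-contrast fat-saturated T1 images, the normalized late T1
post-contrast SI, and the normalized T2 SI -- to one of four diagnoses:

1. ghosting sign present                  -> Warthin tumor (WT)
2. else normalized late T1 SI < 2.0      -> other benign tumor (OBT)
3. else normalized T2 SI >= 3.5          -> pleomorphic adenoma (PA)
4. else                                   -> malignant tumor (MT)

The ghosting sign is treated as pathognomonic for Warthin tumors; low late
T1 enhancement without ghosting points to a benign non-Warthin lesion; high
T2 signal identifies pleomorphic adenomas; what remains (low T2, substantial
late enhancement, no ghosting) is called malignant.  Boundary conventions
are strict: T1 SI exactly 2.0 does not fire rule 2, T2 SI exactly 3.5 does
fire rule 3.  Only MT is malignant under binarization.

Thresholds default to the established 2.0 / 3.5 cuts but can be re-derived
from labelled data by Youden-J maximisation (:func:`derive_thresholds`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .features import QualitativeFindings, QuantitativeFeatures

__all__ = [
    "DxThresholds",
    "DxPrediction",
    "classify_lesion",
    "classify_values",
    "binarize",
    "derive_thresholds",
]

DX_CLASSES = ("PA", "WT", "OBT", "MT")


@dataclass(frozen=True)
class DxThresholds:
    """Signal-intensity cut-points of the decision tree.

    ``t1_cut`` applies to the normalized late post-contrast T1 SI (rule:
    below the cut is benign-low-enhancing); ``t2_cut`` to the normalized T2
    SI (at or above the cut is pleomorphic adenoma).
    """

    t1_cut: float = 2.0
    t2_cut: float = 3.5

    def __post_init__(self) -> None:
        if not (self.t1_cut > 0 and self.t2_cut > 0):
            raise ValueError("thresholds must be > 0")


@dataclass(frozen=True)
class DxPrediction:
    """Decision-tree output: diagnosis, malignancy flag, and audit trail."""

    dx_class: str
    malignant: bool
    rule_path: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.dx_class not in DX_CLASSES:
            raise ValueError(f"unknown class {self.dx_class!r}")
        if self.malignant != (self.dx_class == "MT"):
            raise ValueError("malignant flag must equal (dx_class == 'MT')")


def classify_values(
    ghosting: bool,
    norm_t1_si: float,
    norm_t2_si: float,
    thresholds: DxThresholds = DxThresholds(),
) -> DxPrediction:
    """Apply the decision tree to raw feature values.

    Rules fire in fixed order (ghosting -> T1 -> T2); ``rule_path`` records
    every test evaluated and the branch taken, so each prediction is
    auditable.
    """
    if ghosting is None:
        raise ValueError("missing required feature: ghosting")
    for name, v in (("norm_t1_si", norm_t1_si), ("norm_t2_si", norm_t2_si)):
        if v is None or (isinstance(v, float) and math.isnan(v)):
            raise ValueError(f"missing required feature: {name}")

    path: list[str] = []
    if ghosting:
        path.append("ghosting present -> WT")
        dx = "WT"
    else:
        path.append("ghosting absent")
        if norm_t1_si < thresholds.t1_cut:
            path.append(f"norm_t1_si {norm_t1_si:g} < {thresholds.t1_cut:g} -> OBT")
            dx = "OBT"
        else:
            path.append(f"norm_t1_si {norm_t1_si:g} >= {thresholds.t1_cut:g}")
            if norm_t2_si >= thresholds.t2_cut:
                path.append(f"norm_t2_si {norm_t2_si:g} >= {thresholds.t2_cut:g} -> PA")
                dx = "PA"
            else:
                path.append(f"norm_t2_si {norm_t2_si:g} < {thresholds.t2_cut:g} -> MT")
                dx = "MT"
    return DxPrediction(dx_class=dx, malignant=dx == "MT", rule_path=tuple(path))


def classify_lesion(
    findings: QualitativeFindings,
    features: QuantitativeFeatures,
    thresholds: DxThresholds = DxThresholds(),
) -> DxPrediction:
    """Classify one lesion from its qualitative findings and SI ratios."""
    return classify_values(findings.ghosting, features.norm_t1_si,
                           features.norm_t2_si, thresholds)


def binarize(prediction: DxPrediction) -> str:
    """Collapse a four-class diagnosis to 'malignant' / 'benign'."""
    return "malignant" if prediction.dx_class == "MT" else "benign"


def _youden_cut(values: np.ndarray, positive: np.ndarray,
                direction: str) -> tuple[float, float]:
    """Cut maximizing Youden's J = sens + spec - 1 for a one-sided rule.

    ``direction='below'`` tests ``value < cut`` as positive, ``'above'``
    tests ``value >= cut``.  Candidate cuts are midpoints between
    consecutive unique values; ties in J are broken toward the midpoint of
    the two class means.  Returns (cut, J).
    """
    uniq = np.unique(values)
    if uniq.size < 2:
        raise ValueError("need at least two distinct feature values")
    candidates = (uniq[:-1] + uniq[1:]) / 2.0
    n_pos = positive.sum()
    n_neg = (~positive).sum()
    best_j = -np.inf
    best_cuts: list[float] = []
    for c in candidates:
        pred = values < c if direction == "below" else values >= c
        sens = (pred & positive).sum() / n_pos
        spec = (~pred & ~positive).sum() / n_neg
        j = sens + spec - 1.0
        if j > best_j + 1e-12:
            best_j, best_cuts = j, [float(c)]
        elif abs(j - best_j) <= 1e-12:
            best_cuts.append(float(c))
    mid = (values[positive].mean() + values[~positive].mean()) / 2.0
    cut = min(best_cuts, key=lambda c: abs(c - mid))
    return cut, float(best_j)


def derive_thresholds(
    norm_t1_si,
    norm_t2_si,
    groups,
) -> tuple[DxThresholds, dict[str, float]]:
    """Re-derive the SI thresholds from a labelled cohort.

    The T1 cut separates Warthin tumors (low late enhancement) from all
    other groups with the rule ``norm_t1_si < cut``; the T2 cut separates
    pleomorphic adenomas (high T2 signal) with ``norm_t2_si >= cut``.  Each
    cut maximizes Youden's J over midpoints between observed values.

    Returns the thresholds and a diagnostics dict with the achieved J per
    feature; a J near 0 means the feature does not separate the classes and
    the corresponding cut is arbitrary.
    """
    t1 = np.asarray(norm_t1_si, dtype=float)
    t2 = np.asarray(norm_t2_si, dtype=float)
    groups = np.asarray(groups)
    if not (t1.shape == t2.shape == groups.shape):
        raise ValueError("feature and label vectors must have equal length")
    for cls, label in (("WT", "t1"), ("PA", "t2")):
        n_in = (groups == cls).sum()
        n_out = (groups != cls).sum()
        if n_in < 2 or n_out < 2:
            raise ValueError(
                f"need >= 2 lesions inside and outside class {cls} to derive "
                f"the {label} cut (got {n_in} / {n_out})"
            )
    t1_cut, j_t1 = _youden_cut(t1, groups == "WT", "below")
    t2_cut, j_t2 = _youden_cut(t2, groups == "PA", "above")
    return DxThresholds(t1_cut=t1_cut, t2_cut=t2_cut), {"j_t1": j_t1, "j_t2": j_t2}
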