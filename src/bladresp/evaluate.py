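"""ROC analysis, operating-point selection, confusion counts and
multi-method agreement regions.

Scores are likelihoods of complete response (post-treatment stage T0); the
convention throughout is that a higher score means more likely complete
response, and at a decision threshold a score greater than or equal to the
threshold predicts complete response.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, List, Sequence, Tuple

import numpy as np
from sklearn.metrics import roc_curve

from .types import ResponseLabel


def _to_binary(labels: Sequence) -> np.ndarray:
    out = []
    for l in labels:
        if isinstance(l, ResponseLabel):
            out.append(1 if l.is_complete else 0)
        else:
            out.append(int(l))
    return np.asarray(out, dtype=int)


@dataclass
class ROCResult:
    auc: float
    se: float
    fpr: np.ndarray
    tpr: np.ndarray

    @property
    def points(self) -> List[Tuple[float, float]]:
        return list(zip(self.fpr.tolist(), self.tpr.tolist()))


def _delong_se(pos: np.ndarray, neg: np.ndarray) -> float:
    """DeLong's nonparametric standard error of the empirical AUC."""
    m, n = len(pos), len(neg)
    # placement values via midranks
    psi = (pos[:, None] > neg[None, :]).astype(float) \
        + 0.5 * (pos[:, None] == neg[None, :])
    v10 = psi.mean(axis=1)          # per-positive
    v01 = psi.mean(axis=0)          # per-negative
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return float(np.sqrt(s10 / m + s01 / n))


def roc_auc(scores: Sequence[float], labels: Sequence) -> ROCResult:
    """Empirical (trapezoid / Mann–Whitney, midrank ties) ROC and AUC
    with the DeLong standard error."""
    y = _to_binary(labels)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present for ROC analysis")
    fpr, tpr, _ = roc_curve(y, s, drop_intermediate=False)
    if fpr[0] != 0 or tpr[0] != 0:
        fpr, tpr = np.r_[0.0, fpr], np.r_[0.0, tpr]
    if fpr[-1] != 1 or tpr[-1] != 1:
        fpr, tpr = np.r_[fpr, 1.0], np.r_[tpr, 1.0]
    auc = float(np.trapezoid(tpr, fpr))
    se = _delong_se(s[y == 1], s[y == 0])
    return ROCResult(auc=auc, se=se, fpr=fpr, tpr=tpr)


@dataclass
class OperatingPoint:
    threshold: float
    sensitivity: float
    specificity: float


def operating_point(train_scores: Sequence[float], train_labels: Sequence,
                    target_sensitivity: float) -> OperatingPoint:
    """Largest threshold whose training sensitivity reaches the target.

    Candidate thresholds are the observed scores (score ≥ threshold
    predicts complete response), so a target of 1.0 lands at or below the
    smallest positive score.
    """
    if not 0.0 < target_sensitivity <= 1.0:
        raise ValueError("target sensitivity must lie in (0, 1]")
    y = _to_binary(train_labels)
    s = np.asarray(train_scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    pos, neg = s[y == 1], s[y == 0]
    best = None
    for t in np.unique(s)[::-1]:  # descending: first hit is the largest
        sens = float(np.mean(pos >= t))
        if sens >= target_sensitivity:
            best = t
            break
    if best is None:  # cannot happen for target <= 1: min(pos) attains 1.0
        best = float(pos.min())
    sens = float(np.mean(pos >= best))
    spec = float(np.mean(neg < best))
    return OperatingPoint(threshold=float(best), sensitivity=sens, specificity=spec)


def _pct(numer: int, denom: int) -> float:
    """Percentage rounded half-up to one decimal (report formatting)."""
    if denom == 0:
        return 0.0
    return float(Decimal(100.0 * numer / denom).quantize(
        Decimal("0.1"), rounding=ROUND_HALF_UP))


def confusion_at(scores: Sequence[float], labels: Sequence,
                 threshold: float) -> Dict[str, float]:
    """Confusion counts and percentages at a fixed threshold.

    Score ≥ threshold predicts complete response. Sensitivity is the
    fraction of complete responders called correctly, specificity the
    fraction of non-complete responders called correctly; both reported
    as percentages rounded half-up to one decimal.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    y = _to_binary(labels)
    pred = np.asarray(scores, dtype=float) >= threshold
    tp = int(np.sum(pred & (y == 1)))
    fn = int(np.sum(~pred & (y == 1)))
    tn = int(np.sum(~pred & (y == 0)))
    fp = int(np.sum(pred & (y == 0)))
    return {"tp": tp, "fn": fn, "tn": tn, "fp": fp,
            "sensitivity_pct": _pct(tp, tp + fn),
            "specificity_pct": _pct(tn, tn + fp)}


@dataclass
class AgreementTable:
    """Per-pattern correctness counts for m methods over n cases.

    ``counts`` maps each boolean correctness pattern (one flag per method)
    to its case count; the all-False pattern is the outer 'every method
    wrong' region of a Venn diagram.
    """

    counts: Dict[Tuple[bool, ...], int]
    n_methods: int
    n_cases: int

    @property
    def all_correct(self) -> int:
        return self.counts.get((True,) * self.n_methods, 0)

    @property
    def none_correct(self) -> int:
        return self.counts.get((False,) * self.n_methods, 0)

    @property
    def all_correct_fraction_pct(self) -> float:
        return _pct(self.all_correct, self.n_cases)


def agreement_regions(correctness: Sequence[Sequence[bool]]) -> AgreementTable:
    """Tabulate which methods were simultaneously correct per case.

    ``correctness[i][k]`` says whether method k called case i correctly.
    """
    rows = [tuple(bool(v) for v in row) for row in correctness]
    if not rows:
        raise ValueError("no cases")
    m = len(rows[0])
    if m < 1 or any(len(r) != m for r in rows):
        raise ValueError("correctness matrix is ragged or empty")
    counts: Dict[Tuple[bool, ...], int] = {}
    for r in rows:
        counts[r] = counts.get(r, 0) + 1
    return AgreementTable(counts=counts, n_methods=m, n_cases=len(rows))
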