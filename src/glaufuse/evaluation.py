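"""Diagnostic-performance evaluation: ROC/AROC, DeLong's paired AROC test,
McNemar's paired-accuracy test, sensitivity-specificity cutoff selection,
agreement odds ratios, and the two instrument-native comparator rules
(Glaucoma Hemifield Test label, quadrant-wise RNFLT depression).

All operations are pure functions of their inputs.  The classification
convention throughout is *abnormal when score >= threshold*.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve

from .cohort import GHTLabel, N_ASCANS, OCTTest, SAPTest
from .normative import NormativeDB, correct_ascan

__all__ = [
    "ROCResult",
    "PairedTestResult",
    "roc",
    "delong_test",
    "delong_auc_variance",
    "mcnemar_test",
    "select_cutoff",
    "agreement_odds_ratio",
    "classify_oct_quadrant",
    "classify_ght",
    "QUADRANTS",
]


@dataclass
class ROCResult:
    """ROC sweep: thresholds with sensitivity/specificity, and the AROC."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auroc: float


@dataclass
class PairedTestResult:
    statistic: float
    p_value: float
    method: str
    aux: dict


def roc(outputs: Sequence[float], labels: Sequence[int]) -> ROCResult:
    """ROC curve over the observed scores; AROC by trapezoid.

    The trapezoidal area equals the Mann-Whitney pairwise concordance with
    ties counted one half.
    """
    outputs = np.asarray(outputs, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) != 2:
        raise ValueError("both classes must be present")
    fpr, tpr, thresholds = roc_curve(labels, outputs)
    return ROCResult(
        thresholds=thresholds,
        sensitivity=tpr,
        specificity=1.0 - fpr,
        auroc=float(roc_auc_score(labels, outputs)),
    )


# ---------------------------------------------------------------------------
# DeLong's method


def _placements(scores: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """AROC with the per-case placement values of DeLong's estimator.

    ``V10[i]`` is the fraction of controls a diseased case outranks (ties
    half), ``V01[j]`` the fraction of cases a control is outranked by.
    """
    x = scores[labels == 1]
    y = scores[labels == 0]
    # pairwise psi via broadcasting; cohort sizes here keep this cheap
    gt = (x[:, None] > y[None, :]).astype(float)
    eq = (x[:, None] == y[None, :]).astype(float)
    psi = gt + 0.5 * eq
    v10 = psi.mean(axis=1)
    v01 = psi.mean(axis=0)
    return float(psi.mean()), v10, v01


def delong_auc_variance(outputs: Sequence[float], labels: Sequence[int]) -> tuple[float, float]:
    """(AROC, variance) of a single AROC by DeLong's placement estimator."""
    outputs = np.asarray(outputs, dtype=float)
    labels = np.asarray(labels, dtype=int)
    auc, v10, v01 = _placements(outputs, labels)
    m, n = v10.size, v01.size
    var = float(np.var(v10, ddof=1) / m + np.var(v01, ddof=1) / n)
    return auc, var


def delong_test(
    outputs_a: Sequence[float],
    outputs_b: Sequence[float],
    labels: Sequence[int],
) -> PairedTestResult:
    """DeLong's nonparametric comparison of two correlated AROCs.

    Uses the placement-value covariance estimate of
    ``var(AROC_a - AROC_b)``; the statistic is the normal z-score and the
    p-value two-sided.
    """
    a = np.asarray(outputs_a, dtype=float)
    b = np.asarray(outputs_b, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if a.shape != b.shape or a.shape[0] != labels.shape[0]:
        raise ValueError("both classifiers must score the same records")
    if len(np.unique(labels)) != 2:
        raise ValueError("both classes must be present")

    auc_a, v10_a, v01_a = _placements(a, labels)
    auc_b, v10_b, v01_b = _placements(b, labels)
    m, n = v10_a.size, v01_a.size
    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1)
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1)
    cov = s10 / m + s01 / n
    var_diff = float(cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1])

    diff = auc_a - auc_b
    aux = {"auc_a": auc_a, "auc_b": auc_b, "var_diff": var_diff, "cov": cov}
    if var_diff <= 0:
        if np.isclose(diff, 0.0):
            return PairedTestResult(0.0, 1.0, "delong", aux)
        raise ZeroDivisionError(
            "degenerate DeLong comparison: zero estimated variance with unequal AROCs"
        )
    z = diff / np.sqrt(var_diff)
    p = float(2.0 * stats.norm.sf(abs(z)))
    return PairedTestResult(float(z), p, "delong", aux)


# ---------------------------------------------------------------------------
# McNemar


def mcnemar_test(b: int, c: int, method: str = "exact") -> PairedTestResult:
    """McNemar's test for correlated proportions on discordant counts.

    ``b`` counts records the first classifier got right and the second
    wrong; ``c`` the reverse.  The default exact form is the two-sided
    binomial ``p = min(1, 2 P(X <= min(b, c)))`` with ``X ~ Bin(b+c, 1/2)``;
    ``method="chi2"`` gives the asymptotic chi-square variant.
    """
    if b < 0 or c < 0 or b != int(b) or c != int(c):
        raise ValueError("discordant counts must be non-negative integers")
    b, c = int(b), int(c)
    n = b + c
    if n == 0:
        return PairedTestResult(0.0, 1.0, f"mcnemar_{method}", {"b": b, "c": c})
    if method == "exact":
        p = min(1.0, 2.0 * float(stats.binom.cdf(min(b, c), n, 0.5)))
        return PairedTestResult(float(min(b, c)), p, "mcnemar_exact", {"b": b, "c": c})
    if method == "chi2":
        statistic = (b - c) ** 2 / n
        p = float(stats.chi2.sf(statistic, df=1))
        return PairedTestResult(float(statistic), p, "mcnemar_chi2", {"b": b, "c": c})
    raise ValueError(f"unknown method {method!r}")


def select_cutoff(roc_result: ROCResult) -> float:
    """Threshold maximizing sensitivity x specificity (ties -> higher specificity)."""
    prod = roc_result.sensitivity * roc_result.specificity
    best = np.flatnonzero(prod == prod.max())
    # among maxima prefer the highest specificity, then the higher threshold
    order = sorted(
        best, key=lambda i: (roc_result.specificity[i], roc_result.thresholds[i]), reverse=True
    )
    return float(roc_result.thresholds[order[0]])


def agreement_odds_ratio(
    class_a: Sequence[int], class_b: Sequence[int]
) -> tuple[float, np.ndarray]:
    """Odds ratio of classification agreement between two binary raters.

    Returns the OR and the 2x2 table ``[[n11, n10], [n01, n00]]``; the
    Haldane-Anscombe +0.5 correction is applied to every cell when any
    cell is empty.
    """
    a = np.asarray(class_a, dtype=int)
    b = np.asarray(class_b, dtype=int)
    if a.shape != b.shape:
        raise ValueError("classification vectors must align")
    n11 = int(np.sum((a == 1) & (b == 1)))
    n10 = int(np.sum((a == 1) & (b == 0)))
    n01 = int(np.sum((a == 0) & (b == 1)))
    n00 = int(np.sum((a == 0) & (b == 0)))
    table = np.array([[n11, n10], [n01, n00]], dtype=float)
    cells = table.copy()
    if (cells == 0).any():
        cells += 0.5
    odds = float((cells[0, 0] * cells[1, 1]) / (cells[0, 1] * cells[1, 0]))
    return odds, table


# ---------------------------------------------------------------------------
# instrument-native comparator rules

#: TSNIT quadrants: 64 consecutive (circularly) A-scans centred on the
#: temporal, superior, nasal and inferior meridians.
QUADRANTS: dict[str, np.ndarray] = {
    "temporal": np.concatenate([np.arange(224, 256), np.arange(0, 32)]),
    "superior": np.arange(32, 96),
    "nasal": np.arange(96, 160),
    "inferior": np.arange(160, 224),
}


def classify_oct_quadrant(test: OCTTest, db: NormativeDB) -> str:
    """Quadrant-level normative comparison: ABNORMAL if any quadrant mean is
    strictly below the normative 5th percentile of that quadrant's mean.

    Quadrant normative distributions are the per-subject quadrant means of
    the stored residuals; the boundary case (exactly at the 5th percentile)
    is NORMAL.
    """
    corrected = correct_ascan(test, db)
    for idx in QUADRANTS.values():
        test_resid = float(np.mean(corrected[idx] - db.intercept_um[idx]))
        norm_means = db.residuals[:, idx].mean(axis=1)
        if test_resid < float(np.percentile(norm_means, 5.0)):
            return "ABNORMAL"
    return "NORMAL"


def classify_ght(sap: SAPTest) -> str:
    """GHT comparator: borderline results count as abnormal."""
    return "NORMAL" if sap.ght_label is GHTLabel.WNL else "ABNORMAL"
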