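"""Evaluation statistics for biomarker studies.

Implements the ranking metrics and hypothesis tests used throughout the
pipeline: AUROC with a DeLong confidence interval, AUPRC (step-wise,
interpolation-free), the paired DeLong test for correlated AUROCs, a paired
bootstrap test for arbitrary metrics (used for AUPRC), the Wilcoxon
signed-rank test with the r = Z/sqrt(N) effect size, Spearman correlation,
and the Bonferroni gate for the four-detector comparison family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from sklearn.metrics import average_precision_score

__all__ = [
    "EvalResult",
    "auroc",
    "auprc",
    "delong_test",
    "bootstrap_paired_test",
    "wilcoxon_effect",
    "spearman",
    "bonferroni_gate",
    "prevalence_percent",
    "permutation_p",
]

BONFERRONI_FAMILY = 4  # STE, SLL, HIL, MNI
BONFERRONI_ALPHA = 0.05


@dataclass
class EvalResult:
    """A single evaluation metric with its 95% CI and comparison p-values."""

    metric: str
    value: float
    ci95: tuple[float, float]
    p_values: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lo, hi = self.ci95
        if not (lo - 1e-12 <= self.value <= hi + 1e-12):
            raise ValueError("ci95 must contain the point estimate")


def _check_binary(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels).astype(float)
    uniq = np.unique(labels)
    if not np.isin(uniq, [0.0, 1.0]).all():
        raise ValueError("labels must be binary 0/1")
    if uniq.size < 2:
        raise ValueError("both classes must be present")
    return labels.astype(int)


def _delong_components(scores: np.ndarray, labels: np.ndarray):
    """Structural components of the DeLong estimator for k correlated scorers.

    scores: (k, n); labels: (n,) with both classes present.
    Returns (aucs, covariance matrix S of the AUC vector).
    Ties receive half credit via midranks.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    labels = _check_binary(labels)
    pos = scores[:, labels == 1]
    neg = scores[:, labels == 0]
    m, n = pos.shape[1], neg.shape[1]
    k = scores.shape[0]
    v01 = np.empty((k, m))
    v10 = np.empty((k, n))
    aucs = np.empty(k)
    for r in range(k):
        tx = sps.rankdata(pos[r])
        ty = sps.rankdata(neg[r])
        tz = sps.rankdata(np.concatenate([pos[r], neg[r]]))
        v01[r] = (tz[:m] - tx) / n
        v10[r] = 1.0 - (tz[m:] - ty) / m
        aucs[r] = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    s01 = np.atleast_2d(np.cov(v01)) if m > 1 else np.zeros((k, k))
    s10 = np.atleast_2d(np.cov(v10)) if n > 1 else np.zeros((k, k))
    S = s01 / m + s10 / n
    return aucs, S


def auroc(scores, labels) -> EvalResult:
    """AUROC as the Mann-Whitney pair probability (half credit for ties).

    The 95% CI uses the DeLong asymptotic variance of the same rank
    construction, clipped to [0, 1].
    """
    aucs, S = _delong_components(np.asarray(scores, dtype=float), labels)
    se = float(np.sqrt(max(S[0, 0], 0.0)))
    value = float(aucs[0])
    lo = max(0.0, value - 1.959963984540054 * se)
    hi = min(1.0, value + 1.959963984540054 * se)
    return EvalResult("AUROC", value, (min(lo, value), max(hi, value)))


def auprc(scores, labels) -> EvalResult:
    """Area under the precision-recall step curve (no interpolation).

    For a random scorer the expectation is approximately the positive
    prevalence. A bootstrap CI is not attached here; paired comparisons go
    through :func:`bootstrap_paired_test`.
    """
    labels = _check_binary(labels)
    if labels.sum() == 0:
        raise ValueError("at least one positive label required")
    value = float(average_precision_score(labels, np.asarray(scores, float)))
    return EvalResult("AUPRC", value, (value, value))


def delong_test(scores_a, scores_b, labels) -> float:
    """Two-sided DeLong test for a paired AUROC difference.

    Both scorers must be evaluated on the same rows/labels. Identical
    scores give p = 1 (zero difference by construction).
    """
    scores_a = np.asarray(scores_a, float)
    scores_b = np.asarray(scores_b, float)
    if scores_a.shape != scores_b.shape:
        raise ValueError("paired scores must have identical shape")
    aucs, S = _delong_components(np.vstack([scores_a, scores_b]), labels)
    diff = aucs[0] - aucs[1]
    var = S[0, 0] + S[1, 1] - 2.0 * S[0, 1]
    if diff == 0.0 or var <= 0.0:
        return 1.0 if diff == 0.0 else 0.0
    z = diff / np.sqrt(var)
    return float(2.0 * sps.norm.sf(abs(z)))


def bootstrap_paired_test(
    metric_fn,
    scores_a,
    scores_b,
    labels,
    n_boot: int = 2000,
    seed: int = 0,
    max_redraw_factor: int = 10,
) -> float:
    """Two-sided paired bootstrap test for a metric difference.

    Rows (score_a, score_b, label) are resampled with replacement; the
    metric difference is recomputed per replicate and the p-value is the
    two-sided add-one percentile of zero in the replicate distribution.
    Replicates that drop one class entirely are redrawn, up to
    ``max_redraw_factor * n_boot`` total draws.
    """
    scores_a = np.asarray(scores_a, float)
    scores_b = np.asarray(scores_b, float)
    labels = _check_binary(labels)
    n = labels.size
    if scores_a.shape != scores_b.shape or scores_a.size != n:
        raise ValueError("inputs must be paired and aligned with labels")
    if np.array_equal(scores_a, scores_b):
        return 1.0
    rng = np.random.default_rng(seed)
    diffs = np.empty(n_boot)
    got, draws, cap = 0, 0, max_redraw_factor * n_boot
    while got < n_boot:
        if draws >= cap:
            warnings.warn(
                "bootstrap redraw cap reached; p-value based on "
                f"{got} replicates",
                RuntimeWarning,
            )
            diffs = diffs[:got]
            break
        idx = rng.integers(0, n, size=n)
        draws += 1
        lab = labels[idx]
        if lab.min() == lab.max():
            continue
        diffs[got] = metric_fn(scores_a[idx], lab) - metric_fn(scores_b[idx], lab)
        got += 1
    b = diffs.size
    p_lo = (1 + np.sum(diffs <= 0)) / (b + 1)
    p_hi = (1 + np.sum(diffs >= 0)) / (b + 1)
    return float(min(1.0, 2.0 * min(p_lo, p_hi)))


def wilcoxon_effect(a, b) -> tuple[float, float]:
    """Paired Wilcoxon signed-rank test with effect size r = Z/sqrt(N).

    N is the number of complete pairs supplied; r carries the sign of the
    median paired difference. Interpretation thresholds: small r~0.1,
    medium r~0.3, large r>=0.5. All-zero differences give (p=1, r=0).
    Requires at least 6 non-tied pairs for the normal approximation.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = a - b
    nonzero = np.count_nonzero(d)
    if nonzero == 0:
        return 1.0, 0.0
    if nonzero < 6:
        raise ValueError("need at least 6 non-tied pairs")
    res = sps.wilcoxon(a, b, method="approx", correction=False)
    n = d.size
    r = abs(float(res.zstatistic)) / np.sqrt(n)
    sign = np.sign(np.median(d))
    if sign == 0:
        sign = np.sign(np.mean(d))
    return float(res.pvalue), float(sign * r)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with average-rank ties; p from the
    t approximation. Constant input is undefined: returns (nan, nan)
    with a warning."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need aligned samples with N >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant input: Spearman correlation undefined", RuntimeWarning)
        return float("nan"), float("nan")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def bonferroni_gate(
    p_values, alpha: float = BONFERRONI_ALPHA, n_comparisons: int = BONFERRONI_FAMILY
):
    """Strict significance flags at the Bonferroni-corrected threshold.

    With the default four-detector family the gate is p < 0.0125; the
    boundary value itself is not significant.
    """
    threshold = alpha / n_comparisons
    p_values = np.asarray(p_values, float)
    return p_values < threshold


def prevalence_percent(n_positive: int, n_total: int) -> float:
    """Class prevalence in percent, e.g. SOZ sites among training sites."""
    if n_total <= 0 or n_positive < 0 or n_positive > n_total:
        raise ValueError("need 0 <= n_positive <= n_total, n_total > 0")
    return 100.0 * n_positive / n_total


def permutation_p(observed: float, null_values) -> float:
    """Add-one permutation p-value: (1 + #{null >= observed}) / (n + 1).

    With 100 null replicates all below the observed statistic this floors
    at 1/101 = 0.0099.
    """
    null_values = np.asarray(null_values, float)
    return float((1 + np.sum(null_values >= observed)) / (null_values.size + 1))
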