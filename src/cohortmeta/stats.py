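"""Shared statistical primitives: rank tests, correlation, ROC, Youden cutoff.

Pure computation, no file formats. Two-sided p values throughout; midranks
for ties; exact small-sample null distributions where stated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from sklearn.metrics import roc_auc_score, roc_curve

EXACT_MAX_N = 12  # exact rank-test enumeration up to this total sample size


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    n: tuple[int, ...]
    estimate: float | None = None  # e.g. Pearson r, Kendall tau

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0 + 1e-12:
            raise ValueError(f"p value {self.p_value} outside [0, 1]")


@dataclass(frozen=True)
class RocCurve:
    """ROC curve over every distinct threshold, positives = higher scores."""

    thresholds: np.ndarray  # descending; predicted positive iff score >= threshold
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float

    def __post_init__(self) -> None:
        if np.any(self.tpr < -1e-12) or np.any(self.tpr > 1 + 1e-12):
            raise ValueError("tpr outside [0, 1]")
        if np.any(self.fpr < -1e-12) or np.any(self.fpr > 1 + 1e-12):
            raise ValueError("fpr outside [0, 1]")
        if not 0.0 <= self.auc <= 1.0 + 1e-12:
            raise ValueError("auc outside [0, 1]")


def _as_vector(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError(f"{name} is empty")
    if np.isnan(arr).any():
        raise ValueError(f"{name} contains NaN")
    return arr


def wilcoxon_rank_sum(x, y) -> TestResult:
    """Two-sided Mann–Whitney/Wilcoxon rank-sum test.

    Exact enumeration when n_x + n_y <= 12 and the data are tie-free;
    otherwise the normal approximation with tie and continuity correction.
    """
    x = _as_vector(x, "x")
    y = _as_vector(y, "y")
    pooled = np.concatenate([x, y])
    tie_free = len(np.unique(pooled)) == len(pooled)
    exact = tie_free and (len(x) + len(y) <= EXACT_MAX_N)
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        method="wilcoxon-rank-sum-" + ("exact" if exact else "normal"),
        n=(len(x), len(y)),
    )


def wilcoxon_signed_rank(diff) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped first; exact null enumeration for up to 12
    nonzero tie-free differences, else normal approximation with continuity
    correction. All-zero input is an error (no information).
    """
    diff = _as_vector(diff, "diff")
    nz = diff[diff != 0]
    if nz.size == 0:
        raise ValueError("all paired differences are zero")
    tie_free = len(np.unique(np.abs(nz))) == len(nz)
    exact = tie_free and len(nz) <= EXACT_MAX_N
    res = sps.wilcoxon(
        nz, zero_method="wilcox", correction=not exact,
        alternative="two-sided", method="exact" if exact else "approx",
    )
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        method="wilcoxon-signed-rank-" + ("exact" if exact else "normal"),
        n=(len(nz),),
    )


def pearson_corr(x, y) -> TestResult:
    """Pearson correlation with the t-based two-sided p on n-2 df."""
    x = _as_vector(x, "x")
    y = _as_vector(y, "y")
    if len(x) != len(y):
        raise ValueError("x and y lengths differ")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: correlation undefined")
    res = sps.pearsonr(x, y)
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        method="pearson",
        n=(len(x),),
        estimate=float(res.statistic),
    )


def kendall_tau(u, v) -> TestResult:
    """Kendall's tau-b with tie correction; continuity-corrected normal p.

    The variance of the concordance score S uses the standard tie-corrected
    formula; z = (|S| - 1)/sd(S). When either margin is fully tied there are
    no comparable pairs: tau = 0, p = 1.
    """
    u = _as_vector(u, "u")
    v = _as_vector(v, "v")
    if len(u) != len(v):
        raise ValueError("u and v lengths differ")
    n = len(u)
    if n < 2:
        raise ValueError("need at least 2 observations")

    du = np.sign(u[:, None] - u[None, :])
    dv = np.sign(v[:, None] - v[None, :])
    iu = np.triu_indices(n, k=1)
    s = float(np.sum(du[iu] * dv[iu]))

    n0 = n * (n - 1) / 2.0
    _, tcnt = np.unique(u, return_counts=True)
    _, ucnt = np.unique(v, return_counts=True)
    n1 = float(np.sum(tcnt * (tcnt - 1) / 2.0))
    n2 = float(np.sum(ucnt * (ucnt - 1) / 2.0))
    denom = np.sqrt((n0 - n1) * (n0 - n2))
    if denom == 0:
        return TestResult(statistic=0.0, p_value=1.0, method="kendall-tau-b", n=(n,),
                          estimate=0.0)
    tau = s / denom

    v0 = n * (n - 1) * (2 * n + 5)
    vt = float(np.sum(tcnt * (tcnt - 1) * (2 * tcnt + 5)))
    vu = float(np.sum(ucnt * (ucnt - 1) * (2 * ucnt + 5)))
    v1 = float(np.sum(tcnt * (tcnt - 1))) * float(np.sum(ucnt * (ucnt - 1))) / (
        2.0 * n * (n - 1)
    )
    v2 = 0.0
    if n > 2:
        v2 = (
            float(np.sum(tcnt * (tcnt - 1) * (tcnt - 2)))
            * float(np.sum(ucnt * (ucnt - 1) * (ucnt - 2)))
            / (9.0 * n * (n - 1) * (n - 2))
        )
    var_s = (v0 - vt - vu) / 18.0 + v1 + v2
    if var_s <= 0:
        p = 1.0
    else:
        z = max(abs(s) - 1.0, 0.0) / np.sqrt(var_s)
        p = float(2.0 * sps.norm.sf(z))
    return TestResult(statistic=s, p_value=min(p, 1.0), method="kendall-tau-b",
                      n=(n,), estimate=float(tau))


def roc_auc(scores, labels) -> RocCurve:
    """ROC curve and AUC; higher scores indicate the positive class.

    AUC equals the Mann–Whitney concordance probability (ties count 0.5);
    curve points at every distinct threshold, running from (0,0) to (1,1).
    """
    scores = _as_vector(scores, "scores")
    labels = np.asarray(labels).astype(bool).ravel()
    if len(scores) != len(labels):
        raise ValueError("scores and labels lengths differ")
    if labels.all() or (~labels).all():
        raise ValueError("both label classes must be present")
    fpr, tpr, thr = roc_curve(labels, scores, drop_intermediate=False)
    auc = float(roc_auc_score(labels, scores))
    return RocCurve(thresholds=thr, tpr=tpr, fpr=fpr, auc=auc)


def youden_threshold(curve: RocCurve) -> tuple[float, float, float]:
    """Cutoff maximizing Youden's J = sens + spec - 1 (positive iff score >= cutoff).

    Ties in J are broken toward the higher-specificity (lower-FPR) cutoff.
    Returns (threshold, sensitivity, specificity).
    """
    j = curve.tpr - curve.fpr
    # ROC points are ordered by ascending FPR; first argmax hits the
    # lowest-FPR (highest-specificity) maximizer.
    best = int(np.argmax(j >= j.max() - 1e-12))
    thr = float(curve.thresholds[best])
    if np.isinf(thr):  # the (0,0) corner: use the top observed score
        thr = float(curve.thresholds[1]) if len(curve.thresholds) > 1 else 0.0
    return thr, float(curve.tpr[best]), float(1.0 - curve.fpr[best])


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH-adjusted p values (scipy's false discovery rate control)."""
    return sps.false_discovery_control(np.asarray(p_values, dtype=float), method="bh")
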