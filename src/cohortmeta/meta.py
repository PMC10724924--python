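"""Standardized-mean-difference meta-analysis with heterogeneity-adaptive pooling.

Per study the SMD is Hedges' g (Cohen's d with the small-sample correction
J = 1 - 3/(4(n1+n2-2) - 1)). Studies are combined by inverse-variance
weighting; between-study heterogeneity is quantified by Cochran's Q, I² and
the DerSimonian–Laird moment estimate of τ². The model is chosen by the
literal rule used throughout the forest-plot literature this package
emulates: fixed effect iff I² <= 50% or p(Q) > 0.05, otherwise
DerSimonian–Laird random effects. A pooled effect is called significant when
its 95% CI excludes zero. Leave-one-out re-pooling and Begg's rank
correlation test of funnel-plot asymmetry round out the per-gene machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import ExpressionCohort
from .preprocess import HarmonizedSet
from .stats import TestResult, kendall_tau

Z95 = 1.959963984540054  # two-sided 95% normal quantile
I2_FIXED_MAX = 50.0
PQ_FIXED_MIN = 0.05


@dataclass(frozen=True)
class StudyEffect:
    """Hedges' g (tumor minus normal) for one study."""

    study_label: str
    g: float
    variance: float
    n_tumor: int
    n_normal: int

    def __post_init__(self) -> None:
        if self.variance <= 0:
            raise ValueError("effect variance must be positive")
        if self.n_tumor < 1 or self.n_normal < 1:
            raise ValueError("group sizes must be >= 1")


@dataclass(frozen=True)
class HeterogeneityStats:
    Q: float
    df: int
    p_Q: float
    I2: float  # percent, in [0, 100]
    tau2: float

    def __post_init__(self) -> None:
        if self.Q < 0 or self.tau2 < 0:
            raise ValueError("Q and tau2 must be nonnegative")


@dataclass(frozen=True)
class MetaResult:
    pooled: float
    se: float
    ci_low: float
    ci_high: float
    model: str  # "fixed" or "random"
    weights: tuple[float, ...]  # normalized, sum to 1
    het: HeterogeneityStats | None
    significant: bool
    study_labels: tuple[str, ...] = ()

    @property
    def p_value(self) -> float:
        """Two-sided p from z = pooled/se."""
        return float(2.0 * sps.norm.sf(abs(self.pooled / self.se)))


def hedges_g(
    mean_t: float, sd_t: float, n_t: int,
    mean_n: float, sd_n: float, n_n: int,
    study_label: str = "", correction: bool = True,
) -> StudyEffect:
    """Standardized mean difference, tumor minus normal.

    d = (mean_t - mean_n)/s_pooled; g = J*d with
    J = 1 - 3/(4(n_t+n_n-2) - 1); var(g) = J²[(n_t+n_n)/(n_t n_n) + d²/(2(n_t+n_n))].
    ``correction=False`` gives plain Cohen's d (J = 1).
    """
    if n_t < 2 or n_n < 2:
        raise ValueError("need n >= 2 per group for a standardized mean difference")
    if sd_t <= 0 or sd_n <= 0:
        raise ValueError("group SDs must be positive")
    n = n_t + n_n
    s_pooled = np.sqrt(((n_t - 1) * sd_t**2 + (n_n - 1) * sd_n**2) / (n - 2))
    d = (mean_t - mean_n) / s_pooled
    j = 1.0 - 3.0 / (4.0 * (n - 2) - 1.0) if correction else 1.0
    g = j * d
    var = j**2 * (n / (n_t * n_n) + d**2 / (2.0 * n))
    return StudyEffect(study_label=study_label, g=float(g), variance=float(var),
                       n_tumor=n_t, n_normal=n_n)


def heterogeneity(effects: list[StudyEffect]) -> HeterogeneityStats:
    """Cochran's Q, I² and the DerSimonian–Laird τ² moment estimate."""
    if len(effects) < 2:
        raise ValueError("heterogeneity needs at least 2 studies")
    g = np.array([e.g for e in effects])
    v = np.array([e.variance for e in effects])
    w = 1.0 / v
    theta_f = float(np.sum(w * g) / np.sum(w))
    q = float(np.sum(w * (g - theta_f) ** 2))
    df = len(effects) - 1
    p_q = float(sps.chi2.sf(q, df))
    i2 = max(0.0, (q - df) / q) * 100.0 if q > 0 else 0.0
    c = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    tau2 = max(0.0, (q - df) / c) if c > 0 else 0.0
    return HeterogeneityStats(Q=q, df=df, p_Q=p_q, I2=i2, tau2=tau2)


def pool(
    effects: list[StudyEffect], het: HeterogeneityStats | None = None
) -> MetaResult:
    """Inverse-variance pooling with the fixed/random model-selection rule.

    Fixed effect iff I² <= 50% or p(Q) > 0.05; otherwise random effects with
    DL weights 1/(v_i + τ²). A single study is returned as-is (fixed).
    CI multiplier is the normal 1.96.
    """
    if not effects:
        raise ValueError("no studies to pool")
    if len(effects) == 1:
        e = effects[0]
        se = float(np.sqrt(e.variance))
        lo, hi = e.g - Z95 * se, e.g + Z95 * se
        return MetaResult(pooled=e.g, se=se, ci_low=lo, ci_high=hi, model="fixed",
                          weights=(1.0,), het=None, significant=not lo <= 0.0 <= hi,
                          study_labels=(e.study_label,))
    if het is None:
        het = heterogeneity(effects)
    g = np.array([e.g for e in effects])
    v = np.array([e.variance for e in effects])
    fixed = het.I2 <= I2_FIXED_MAX or het.p_Q > PQ_FIXED_MIN
    w = 1.0 / v if fixed else 1.0 / (v + het.tau2)
    pooled = float(np.sum(w * g) / np.sum(w))
    se = float(np.sqrt(1.0 / np.sum(w)))
    lo, hi = pooled - Z95 * se, pooled + Z95 * se
    return MetaResult(
        pooled=pooled, se=se, ci_low=lo, ci_high=hi,
        model="fixed" if fixed else "random",
        weights=tuple(w / np.sum(w)), het=het,
        significant=not lo <= 0.0 <= hi,
        study_labels=tuple(e.study_label for e in effects),
    )


def leave_one_out(effects: list[StudyEffect]) -> tuple[list[MetaResult], bool]:
    """Re-run the full pooling pipeline omitting each study in turn.

    Heterogeneity is re-estimated and the model re-selected per omission.
    Returns the k results plus a stability flag: True when every omission
    leaves the pooled effect significant.
    """
    if len(effects) < 2:
        raise ValueError("leave-one-out needs at least 2 studies")
    results = []
    for i in range(len(effects)):
        rest = effects[:i] + effects[i + 1 :]
        results.append(pool(rest))
    stable = all(r.significant for r in results)
    return results, stable


def begg_test(effects: list[StudyEffect]) -> TestResult:
    """Begg's rank correlation test of funnel-plot asymmetry.

    Standardized deviates u_i = (g_i - θ_F)/sqrt(v_i - 1/Σw) are rank-correlated
    (Kendall tau-b, continuity-corrected p) with the variances v_i.
    """
    if len(effects) < 3:
        raise ValueError("Begg's test needs at least 3 studies")
    g = np.array([e.g for e in effects])
    v = np.array([e.variance for e in effects])
    w = 1.0 / v
    theta_f = np.sum(w * g) / np.sum(w)
    resid_var = v - 1.0 / np.sum(w)
    if np.any(resid_var <= 1e-12):
        raise ValueError("degenerate standardized deviate: v_i <= 1/sum(w)")
    u = (g - theta_f) / np.sqrt(resid_var)
    res = kendall_tau(u, v)
    return TestResult(statistic=res.statistic, p_value=res.p_value,
                      method="begg-rank-correlation", n=res.n, estimate=res.estimate)


def cohort_effect(cohort: ExpressionCohort, gene: str) -> StudyEffect:
    """Hedges' g for one gene in one cohort (two-sample form, paired or not)."""
    t = cohort.tumor_values(gene)
    n = cohort.normal_values(gene)
    return hedges_g(
        float(t.mean()), float(t.std(ddof=1)), len(t),
        float(n.mean()), float(n.std(ddof=1)), len(n),
        study_label=cohort.label,
    )


def gene_effects(hset: HarmonizedSet, gene: str) -> list[StudyEffect]:
    """Per-study effects for one gene across a harmonized set."""
    return [cohort_effect(c, gene) for c in hset.cohorts]


def meta_per_gene(hset: HarmonizedSet) -> pd.DataFrame:
    """Gene-wise Hedges' g → heterogeneity → adaptive pooling over all cohorts.

    Genes with zero within-group SD in any cohort are flagged (``usable``
    False) and carry no estimates. Returns a DataFrame indexed by gene with
    pooled effect, se, CI, model, Q, I², τ², p_Q, the pooled-z two-sided p,
    and the significance flag (CI excludes zero).
    """
    genes = hset.common_genes
    k = len(hset.cohorts)
    means_t = np.empty((len(genes), k))
    means_n = np.empty((len(genes), k))
    sds_t = np.empty((len(genes), k))
    sds_n = np.empty((len(genes), k))
    ns_t = np.empty(k, dtype=int)
    ns_n = np.empty(k, dtype=int)
    for j, c in enumerate(hset.cohorts):
        mat = c.values.to_numpy()
        t_mask = (c.group == "tumor").to_numpy()
        ns_t[j], ns_n[j] = t_mask.sum(), (~t_mask).sum()
        means_t[:, j] = mat[:, t_mask].mean(axis=1)
        means_n[:, j] = mat[:, ~t_mask].mean(axis=1)
        sds_t[:, j] = mat[:, t_mask].std(axis=1, ddof=1)
        sds_n[:, j] = mat[:, ~t_mask].std(axis=1, ddof=1)

    usable = (sds_t > 0).all(axis=1) & (sds_n > 0).all(axis=1)
    labels = [c.label for c in hset.cohorts]
    rows = {}
    for gi, gene in enumerate(genes):
        if not usable[gi]:
            continue
        effects = [
            hedges_g(means_t[gi, j], sds_t[gi, j], int(ns_t[j]),
                     means_n[gi, j], sds_n[gi, j], int(ns_n[j]),
                     study_label=labels[j])
            for j in range(k)
        ]
        res = pool(effects)
        het = res.het
        rows[gene] = {
            "pooled": res.pooled, "se": res.se,
            "ci_low": res.ci_low, "ci_high": res.ci_high,
            "model": res.model, "p": res.p_value, "significant": res.significant,
            "Q": het.Q if het else np.nan, "I2": het.I2 if het else np.nan,
            "tau2": het.tau2 if het else np.nan, "p_Q": het.p_Q if het else np.nan,
            "k": k,
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "gene"
    table.attrs["skipped_genes"] = [g for gi, g in enumerate(genes) if not usable[gi]]
    return table


def forest_table(effects: list[StudyEffect], result: MetaResult) -> pd.DataFrame:
    """Plot-ready forest table: one row per study plus the pooled row."""
    rows = []
    for e, w in zip(effects, result.weights):
        se = np.sqrt(e.variance)
        rows.append({
            "study": e.study_label, "g": e.g, "variance": e.variance,
            "ci_low": e.g - Z95 * se, "ci_high": e.g + Z95 * se,
            "weight_pct": 100.0 * w,
            "n_tumor": e.n_tumor, "n_normal": e.n_normal,
        })
    het = result.het
    rows.append({
        "study": f"pooled ({result.model})", "g": result.pooled,
        "variance": result.se**2, "ci_low": result.ci_low,
        "ci_high": result.ci_high, "weight_pct": 100.0,
        "n_tumor": sum(e.n_tumor for e in effects),
        "n_normal": sum(e.n_normal for e in effects),
    })
    table = pd.DataFrame(rows)
    if het is not None:
        table.attrs["heterogeneity"] = {
            "Q": het.Q, "df": het.df, "p_Q": het.p_Q, "I2": het.I2, "tau2": het.tau2,
        }
    return table
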