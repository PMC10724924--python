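"""Diagnostic test-accuracy meta-analysis: 2×2 tables → bivariate fit → SROC.

Per study the marker is dichotomized at its Youden-optimal cutoff, giving a
2×2 confusion table (tumor = condition positive). Logit-sensitivity and
logit-specificity are then modeled as bivariate normal across studies
(within-study variances from the binomial delta method, continuity
correction 0.5 on all four cells of any table containing a zero). The
between-study mean vector and covariance are fit by restricted maximum
likelihood (Nelder–Mead over a Cholesky parameterization), with a
method-of-moments fallback on non-convergence. The summary ROC curve is the
regression of logit-sens on logit-FPR through the random-effects
distribution; its AUC is evaluated by trapezoid on an FPR grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.special import expit, logit

from .cohort import ExpressionCohort, TUMOR
from .stats import roc_auc, youden_threshold

Z95 = 1.959963984540054


@dataclass(frozen=True)
class TwoByTwo:
    """Confusion counts for one study (tumor = condition positive)."""

    tp: int
    fp: int
    fn: int
    tn: int
    study_label: str = ""
    degenerate: bool = False  # cutoff carried no information (Youden J ~ 0)

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("negative cell count")
        if self.tp + self.fn < 1 or self.fp + self.tn < 1:
            raise ValueError("each condition arm needs at least one subject")

    @property
    def has_zero(self) -> bool:
        return min(self.tp, self.fp, self.fn, self.tn) == 0

    def corrected(self) -> tuple[float, float, float, float]:
        """Cells with the 0.5 continuity correction iff any cell is zero."""
        c = 0.5 if self.has_zero else 0.0
        return self.tp + c, self.fp + c, self.fn + c, self.tn + c


@dataclass(frozen=True)
class BivariateFit:
    mu_sens_logit: float
    mu_spec_logit: float
    between_study_cov: np.ndarray  # 2×2, symmetric PSD
    k: int
    converged: bool
    mu_cov: np.ndarray  # 2×2 GLS covariance of the mean vector
    method: str = "reml"

    def __post_init__(self) -> None:
        cov = np.asarray(self.between_study_cov, dtype=float)
        if cov.shape != (2, 2) or not np.allclose(cov, cov.T, atol=1e-8):
            raise ValueError("between-study covariance must be symmetric 2×2")
        if cov[0, 0] < 0 or cov[1, 1] < 0:
            raise ValueError("negative between-study variance")


@dataclass(frozen=True)
class SrocCurve:
    fpr_grid: np.ndarray
    sens_curve: np.ndarray
    auc: float
    summary_point: tuple[float, float]  # (1 - spec, sens)

    def __post_init__(self) -> None:
        if not 0.0 <= self.auc <= 1.0 + 1e-12:
            raise ValueError("AUC outside [0, 1]")


def dataset_confusion(cohort: ExpressionCohort, gene: str) -> TwoByTwo:
    """Youden-cutoff 2×2 table for one gene in one cohort.

    A constant gene yields a degenerate table (everything called positive at
    the minimum-score cutoff, Youden J = 0) flagged via ``degenerate``.
    """
    scores = cohort.expression(gene).to_numpy(float)
    labels = (cohort.group == TUMOR).to_numpy()
    if np.ptp(scores) == 0:
        return TwoByTwo(
            tp=int(labels.sum()), fp=int((~labels).sum()), fn=0, tn=0,
            study_label=cohort.label, degenerate=True,
        )
    curve = roc_auc(scores, labels)
    thr, sens, spec = youden_threshold(curve)
    pos = scores >= thr
    table = TwoByTwo(
        tp=int(np.sum(pos & labels)), fp=int(np.sum(pos & ~labels)),
        fn=int(np.sum(~pos & labels)), tn=int(np.sum(~pos & ~labels)),
        study_label=cohort.label, degenerate=bool(sens + spec - 1.0 <= 1e-12),
    )
    return table


def _logit_data(tables: list[TwoByTwo]) -> tuple[np.ndarray, np.ndarray]:
    """Per-study (logit sens, logit spec) and their binomial-approx variances."""
    y = np.empty((len(tables), 2))
    s2 = np.empty((len(tables), 2))
    for i, t in enumerate(tables):
        tp, fp, fn, tn = t.corrected()
        y[i] = logit(tp / (tp + fn)), logit(tn / (tn + fp))
        s2[i] = 1.0 / tp + 1.0 / fn, 1.0 / tn + 1.0 / fp
    return y, s2


def _gls_mu(y: np.ndarray, s2: np.ndarray, sigma: np.ndarray):
    """GLS mean, its covariance, and the REML negative log-likelihood."""
    sum_w = np.zeros((2, 2))
    sum_wy = np.zeros(2)
    logdet = 0.0
    invs = []
    for i in range(len(y)):
        v = sigma + np.diag(s2[i])
        vin = np.linalg.inv(v)
        invs.append(vin)
        sum_w += vin
        sum_wy += vin @ y[i]
        sign, ld = np.linalg.slogdet(v)
        if sign <= 0:
            return None
        logdet += ld
    mu_cov = np.linalg.inv(sum_w)
    mu = mu_cov @ sum_wy
    quad = sum(
        float((y[i] - mu) @ invs[i] @ (y[i] - mu)) for i in range(len(y))
    )
    sign, ld_w = np.linalg.slogdet(sum_w)
    nll = 0.5 * (logdet + quad + ld_w)
    return mu, mu_cov, nll


def _moments_fit(tables: list[TwoByTwo]) -> BivariateFit:
    """DerSimonian–Laird per margin; covariance from deviate correlation."""
    y, s2 = _logit_data(tables)
    k = len(tables)
    tau2 = np.zeros(2)
    mu = np.zeros(2)
    for m in range(2):
        w = 1.0 / s2[:, m]
        theta = np.sum(w * y[:, m]) / np.sum(w)
        q = np.sum(w * (y[:, m] - theta) ** 2)
        c = np.sum(w) - np.sum(w**2) / np.sum(w)
        tau2[m] = max(0.0, (q - (k - 1)) / c) if c > 0 else 0.0
        wr = 1.0 / (s2[:, m] + tau2[m])
        mu[m] = np.sum(wr * y[:, m]) / np.sum(wr)
    dev = y - mu
    if tau2[0] > 0 and tau2[1] > 0 and k > 2:
        r = np.corrcoef(dev[:, 0], dev[:, 1])[0, 1]
        r = float(np.clip(np.nan_to_num(r), -0.999, 0.999))
    else:
        r = 0.0
    sigma = np.array(
        [[tau2[0], r * np.sqrt(tau2[0] * tau2[1])],
         [r * np.sqrt(tau2[0] * tau2[1]), tau2[1]]]
    )
    out = _gls_mu(y, s2, sigma)
    mu, mu_cov, _ = out
    return BivariateFit(
        mu_sens_logit=float(mu[0]), mu_spec_logit=float(mu[1]),
        between_study_cov=sigma, k=k, converged=False, mu_cov=mu_cov,
        method="moments",
    )


def fit_bivariate(tables: list[TwoByTwo], maxiter: int = 2000) -> BivariateFit:
    """REML bivariate normal fit of (logit sens, logit spec) across studies.

    The between-study covariance is parameterized through its Cholesky
    factor (log-diagonal) so positive semidefiniteness is automatic; the
    mean vector is profiled out by GLS inside the objective. Falls back to
    the method-of-moments fit when the optimizer fails; ``converged``
    records which path produced the result.
    """
    if len(tables) < 2:
        raise ValueError("bivariate fit needs at least 2 studies")
    y, s2 = _logit_data(tables)
    start = _moments_fit(tables)
    sig0 = start.between_study_cov
    # Cholesky start (guard zero variances)
    l11 = np.sqrt(max(sig0[0, 0], 1e-4))
    l22 = np.sqrt(max(sig0[1, 1] - (sig0[0, 1] / l11) ** 2, 1e-4))
    x0 = np.array([np.log(l11), sig0[0, 1] / l11, np.log(l22)])

    def unpack(x: np.ndarray) -> np.ndarray:
        low = np.array([[np.exp(x[0]), 0.0], [x[1], np.exp(x[2])]])
        return low @ low.T

    def objective(x: np.ndarray) -> float:
        if np.any(np.abs(x) > 20):
            return 1e10
        out = _gls_mu(y, s2, unpack(x))
        if out is None or not np.isfinite(out[2]):
            return 1e10
        return out[2]

    res = optimize.minimize(
        objective, x0, method="Nelder-Mead",
        options={"maxiter": maxiter, "xatol": 1e-8, "fatol": 1e-10},
    )
    if not res.success or not np.isfinite(res.fun) or res.fun >= 1e9:
        return start
    sigma = unpack(res.x)
    mu, mu_cov, _ = _gls_mu(y, s2, sigma)
    return BivariateFit(
        mu_sens_logit=float(mu[0]), mu_spec_logit=float(mu[1]),
        between_study_cov=sigma, k=len(tables), converged=True, mu_cov=mu_cov,
        method="reml",
    )


def pooled_accuracy(fit: BivariateFit) -> dict:
    """Pooled sensitivity/specificity and PLR/NLR with delta-method 95% CIs.

    Sens/spec are inverse-logits of the fitted means (CIs transformed from
    the logit scale); PLR = sens/(1-spec) and NLR = (1-sens)/spec with CIs
    via the delta method on the log scale. Specificity of exactly 1 leaves
    PLR undefined and raises.
    """
    mu_s, mu_p = fit.mu_sens_logit, fit.mu_spec_logit
    se_s = float(np.sqrt(fit.mu_cov[0, 0]))
    se_p = float(np.sqrt(fit.mu_cov[1, 1]))
    sens, spec = float(expit(mu_s)), float(expit(mu_p))
    if 1.0 - spec < 1e-12:
        raise ValueError("specificity = 1: positive likelihood ratio undefined")
    if spec < 1e-12:
        raise ValueError("specificity = 0: negative likelihood ratio undefined")
    plr = sens / (1.0 - spec)
    nlr = (1.0 - sens) / spec
    # d log PLR = (1-sens) d mu_s + spec d mu_p ; d log NLR = -sens d mu_s - (1-spec) d mu_p
    cov_sp = float(fit.mu_cov[0, 1])
    var_lplr = ((1 - sens) * se_s) ** 2 + (spec * se_p) ** 2 \
        + 2 * (1 - sens) * spec * cov_sp
    var_lnlr = (sens * se_s) ** 2 + ((1 - spec) * se_p) ** 2 \
        + 2 * sens * (1 - spec) * cov_sp
    var_lplr, var_lnlr = max(var_lplr, 0.0), max(var_lnlr, 0.0)

    def ci_logit(mu: float, se: float) -> tuple[float, float]:
        return float(expit(mu - Z95 * se)), float(expit(mu + Z95 * se))

    def ci_log(val: float, var: float) -> tuple[float, float]:
        half = Z95 * np.sqrt(var)
        return float(val * np.exp(-half)), float(val * np.exp(half))

    return {
        "sens": sens, "sens_ci": ci_logit(mu_s, se_s),
        "spec": spec, "spec_ci": ci_logit(mu_p, se_p),
        "plr": float(plr), "plr_ci": ci_log(plr, var_lplr),
        "nlr": float(nlr), "nlr_ci": ci_log(nlr, var_lnlr),
    }


def sroc_curve(fit: BivariateFit, grid_size: int = 1001) -> SrocCurve:
    """Summary ROC curve from the bivariate parameters, AUC by trapezoid.

    The curve is the random-effects regression of logit-sens on logit-FPR:
    slope cov/var of the between-study distribution (in FPR coordinates).
    When the logit-spec variance is ~0 or the implied slope is nonpositive
    the curve degenerates; the documented fallback is the symmetric
    (constant diagnostic odds ratio) line with slope 1.
    """
    if grid_size < 10:
        raise ValueError("grid_size must be >= 10")
    mu_y = fit.mu_sens_logit
    mu_x = -fit.mu_spec_logit  # logit FPR at the summary point
    var_x = float(fit.between_study_cov[1, 1])
    cov_yx = -float(fit.between_study_cov[0, 1])
    if var_x > 1e-8 and cov_yx / var_x > 1e-6:
        beta = cov_yx / var_x
        method = "bivariate-regression"
    else:
        beta = 1.0  # symmetric fallback: constant diagnostic odds ratio
        method = "symmetric"
    # half uniform, half logit-spaced points: the curve behaves like
    # fpr**beta near 0 (infinite slope for beta < 1), so uniform spacing
    # alone converges slowly at the corners
    uniform = np.linspace(0.0, 1.0, grid_size - grid_size // 2)
    tail = expit(np.linspace(-14.0, 14.0, grid_size // 2))
    fpr = np.unique(np.concatenate([uniform, tail]))
    with np.errstate(divide="ignore", invalid="ignore"):
        x = logit(fpr)
        sens = expit(mu_y + beta * (x - mu_x))
    sens[0], sens[-1] = 0.0, 1.0
    auc = float(np.trapezoid(sens, fpr))
    curve = SrocCurve(
        fpr_grid=fpr, sens_curve=sens, auc=auc,
        summary_point=(float(expit(mu_x)), float(expit(mu_y))),
    )
    object.__setattr__(curve, "method", method)
    return curve
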