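"""Synthetic multi-cohort expression data with known ground truth.

Emulates the structure of a multi-study tumor/normal expression compendium:
several cohorts of unequal size (some paired), a shared per-gene baseline,
gene-level tumor-vs-normal shifts with between-study heterogeneity
(random-effects location model), platform-specific gene subsets via
dropout, a latent-factor co-expression module around a target gene, and
expression-linked survival for prognostic cohorts.

Model for gene g, sample s in study k::

    x_gs = base_g + delta_gk * 1[s tumor] + pair_g,p(s) + resid_gs
    delta_gk ~ Normal(true_delta_g, tau2_true)
    resid_gs = noise_sd * (lam * f_s + sqrt(1 - lam^2) * eps_gs)   (module genes)
             = noise_sd * eps_gs                                    (other genes)

with f_s a per-sample standard-normal latent factor shared by the
co-expression module and ``lam = coexpr_strength``. The residual variance is
normalized so every gene's marginal SD is ``noise_sd`` regardless of module
membership; the true standardized mean difference is therefore
``true_delta_g / noise_sd`` and the pairwise Pearson correlation between two
module genes is ``lam**2``. Paired cohorts additionally receive a per-gene,
per-pair random intercept with SD ``pair_sd`` shared by the tumor/normal
members of a pair.

All randomness flows from a single integer seed through named
``numpy.random.Generator`` streams; identical inputs give bit-identical
cohorts.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .cohort import ExpressionCohort, NORMAL, TUMOR

DEFAULT_TARGET = "TPI1"


@dataclass(frozen=True)
class CohortSpec:
    """Size and design of one synthetic cohort.

    ``n_genes=None`` keeps the full truth gene universe (before dropout);
    a smaller value subsamples genes (never the target) to emulate a
    platform measuring fewer genes. ``noise_sd`` is the residual SD in
    log2-expression units. ``pair_sd`` (paired designs only) is the SD of
    the shared within-pair intercept.
    """

    n_tumor: int
    n_normal: int
    paired: bool = False
    n_genes: int | None = None
    platform_label: str = ""
    gene_dropout_fraction: float = 0.0
    noise_sd: float = 1.0
    pair_sd: float = 0.5
    label: str = ""

    def __post_init__(self) -> None:
        if self.n_tumor < 1 or self.n_normal < 1:
            raise ValueError("each group needs at least one sample")
        if self.paired and self.n_tumor != self.n_normal:
            raise ValueError("paired cohorts need n_tumor == n_normal")
        if not 0.0 <= self.gene_dropout_fraction < 1.0:
            raise ValueError("gene_dropout_fraction must be in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")

    @property
    def n_samples(self) -> int:
        return self.n_tumor + self.n_normal


@dataclass
class TruthRecord:
    """Ground truth behind one simulated world, used by recovery tests."""

    true_delta: pd.Series  # per-gene log2 shift, tumor minus normal
    tau2_true: float  # between-study variance of the shift
    coexpr_members: set[str]
    coexpr_strength: float
    target_gene: str
    hr_true: float  # hazard ratio per SD of target expression
    censor_rate: float

    def __post_init__(self) -> None:
        self.true_delta = pd.Series(self.true_delta, dtype=float)
        self.coexpr_members = set(self.coexpr_members)
        if self.target_gene not in self.coexpr_members:
            raise ValueError("target gene must belong to its own co-expression module")
        if self.target_gene not in self.true_delta.index:
            raise ValueError("target gene absent from true_delta")
        if self.tau2_true < 0:
            raise ValueError("tau2_true must be nonnegative")
        if self.hr_true <= 0:
            raise ValueError("hr_true must be positive")
        if not 0.0 <= self.censor_rate < 1.0:
            raise ValueError("censor_rate must be in [0, 1)")
        if not 0.0 < self.coexpr_strength <= 1.0:
            raise ValueError("coexpr_strength must be in (0, 1]")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.true_delta.index)


def make_truth(
    n_genes: int = 2000,
    n_members: int = 30,
    delta_target: float = 1.0,
    delta_members: float = 1.0,
    tau2: float = 0.05,
    coexpr_strength: float = 0.7,
    target_gene: str = DEFAULT_TARGET,
    hr_true: float = 2.0,
    censor_rate: float = 0.3,
) -> TruthRecord:
    """Build a default truth: a target-centred upshifted co-expression module.

    Genes are ``G0001``..; the target symbol replaces the first. The first
    ``n_members`` genes (target included) form the module with log2 shift
    ``delta_members`` (target: ``delta_target``); every other gene is null.
    """
    if not 1 <= n_members <= n_genes:
        raise ValueError("need 1 <= n_members <= n_genes")
    genes = [target_gene] + [f"G{i:04d}" for i in range(1, n_genes)]
    delta = pd.Series(0.0, index=genes)
    members = set(genes[:n_members])
    delta[list(members)] = delta_members
    delta[target_gene] = delta_target
    return TruthRecord(
        true_delta=delta,
        tau2_true=tau2,
        coexpr_members=members,
        coexpr_strength=coexpr_strength,
        target_gene=target_gene,
        hr_true=hr_true,
        censor_rate=censor_rate,
    )


def default_cohort_specs() -> list[CohortSpec]:
    """Eight-cohort profile totalling 251 tumor / 136 normal samples.

    Mirrors a realistic public-compendium mix: one large unbalanced
    TCGA-style RNA-seq cohort, a large paired RNA-seq cohort, and several
    small microarray cohorts (two sharing a platform so the merge +
    batch-adjustment path is exercised).
    """
    return [
        CohortSpec(111, 12, platform_label="rnaseq-A", label="study1",
                   gene_dropout_fraction=0.02),
        CohortSpec(57, 57, paired=True, platform_label="rnaseq-B", label="study2",
                   gene_dropout_fraction=0.02),
        CohortSpec(29, 13, platform_label="chip-C", label="study3",
                   gene_dropout_fraction=0.10),
        CohortSpec(25, 25, platform_label="chip-D", label="study4",
                   gene_dropout_fraction=0.10),
        CohortSpec(10, 10, platform_label="chip-E", label="study5",
                   gene_dropout_fraction=0.10),
        CohortSpec(9, 9, paired=True, platform_label="chip-F", label="study6",
                   gene_dropout_fraction=0.10),
        CohortSpec(6, 6, platform_label="chip-G", label="study7",
                   gene_dropout_fraction=0.10),
        CohortSpec(4, 4, platform_label="chip-G", label="study8",
                   gene_dropout_fraction=0.10),
    ]


def strong_signal_specs(k: int = 8, n_tumor: int = 40, n_normal: int = 20) -> list[CohortSpec]:
    """Well-powered recovery profile: k equal mid-size unpaired cohorts.

    Sized a priori by a power argument for the co-expression vote: with
    module correlation lam**2 = 0.49 and tumor-only scope, a dataset with 40
    tumors passes the (r >= 0.30, p < 0.05) vote with probability ~0.9
    (Fisher-z), so >= 3 votes out of 8 are near-certain for true members.
    """
    return [
        CohortSpec(n_tumor, n_normal, platform_label=f"plat-{i}", label=f"sim{i + 1}")
        for i in range(k)
    ]


def _simulate_one(
    spec: CohortSpec, truth: TruthRecord, rng: np.random.Generator, index: int
) -> ExpressionCohort:
    genes = np.asarray(truth.gene_ids)
    if spec.n_genes is not None:
        if spec.n_genes < 1 or spec.n_genes > len(genes):
            raise ValueError("n_genes out of range for the truth gene universe")
        others = genes[genes != truth.target_gene]
        keep = rng.choice(others, size=spec.n_genes - 1, replace=False)
        genes = np.concatenate([[truth.target_gene], keep])

    n_drop = int(np.floor(spec.gene_dropout_fraction * len(genes)))
    if n_drop >= len(genes):
        raise ValueError("dropout would remove every gene including the target")
    if n_drop > 0:
        others = genes[genes != truth.target_gene]
        dropped = set(rng.choice(others, size=n_drop, replace=False))
        genes = np.asarray([g for g in genes if g not in dropped])

    n_g = len(genes)
    n_s = spec.n_samples
    delta = truth.true_delta[genes].to_numpy()
    if truth.tau2_true > 0:
        delta = delta + rng.normal(0.0, np.sqrt(truth.tau2_true), size=n_g)

    is_tumor = np.zeros(n_s, dtype=bool)
    is_tumor[: spec.n_tumor] = True

    lam = truth.coexpr_strength
    member = np.isin(genes, list(truth.coexpr_members))
    factor = rng.normal(size=n_s)
    eps = rng.normal(size=(n_g, n_s))
    resid = eps.copy()
    resid[member] = lam * factor[None, :] + np.sqrt(1.0 - lam**2) * eps[member]
    resid *= spec.noise_sd

    mat = _baseline(truth)[genes].to_numpy()[:, None] + delta[:, None] * is_tumor[None, :] + resid

    pair_id = None
    if spec.paired:
        pair_eff = rng.normal(0.0, spec.pair_sd, size=(n_g, spec.n_tumor))
        mat[:, : spec.n_tumor] += pair_eff
        mat[:, spec.n_tumor :] += pair_eff
        pair_id = pd.Series(
            [f"P{j + 1:03d}" for j in range(spec.n_tumor)] * 2, dtype=str
        )

    label = spec.label or f"study{index + 1}"
    sample_ids = [f"{label}-T{j + 1:03d}" for j in range(spec.n_tumor)] + [
        f"{label}-N{j + 1:03d}" for j in range(spec.n_normal)
    ]
    values = pd.DataFrame(mat, index=genes, columns=sample_ids)
    group = pd.Series(np.where(is_tumor, TUMOR, NORMAL), index=sample_ids)
    return ExpressionCohort(
        values=values,
        group=group,
        pair_id=pair_id,
        platform_label=spec.platform_label or label,
        log_scale=True,
        label=label,
    )


def _baseline(truth: TruthRecord) -> pd.Series:
    """Per-gene baseline, drawn once per truth and cached on the record.

    Log-normal expression levels: normal on the log2 scale, mean 7 SD 2
    (typical log2 microarray/RNA-seq summary range 2–14). Seeded from a
    stable hash of the gene list so the same truth always maps to the same
    baseline irrespective of which cohorts are generated from it.
    """
    cached = getattr(truth, "_baseline", None)
    if cached is not None:
        return cached
    key = zlib.crc32("\x00".join(truth.gene_ids).encode()) % (2**31)
    rng = np.random.default_rng(np.random.SeedSequence([key, 20230701]))
    base = pd.Series(rng.normal(7.0, 2.0, size=len(truth.gene_ids)), index=truth.gene_ids)
    object.__setattr__(truth, "_baseline", base)
    return base


def generate_cohorts(
    specs: list[CohortSpec], truth: TruthRecord, seed: int
) -> tuple[list[ExpressionCohort], TruthRecord]:
    """Generate one cohort per spec under the stated truth; deterministic in seed."""
    if not specs:
        raise ValueError("need at least one cohort spec")
    streams = np.random.SeedSequence(seed).spawn(len(specs))
    cohorts = [
        _simulate_one(spec, truth, np.random.default_rng(stream), i)
        for i, (spec, stream) in enumerate(zip(specs, streams))
    ]
    return cohorts, truth


def inject_batch_effect(
    cohort: ExpressionCohort,
    location_shift: float,
    scale_factor: float,
    batch_assignment: pd.Series | list[str],
    seed: int | None = None,
    jitter_sd: float = 0.0,
) -> ExpressionCohort:
    """Apply ``x -> scale_factor * x + location_shift`` to every non-reference batch.

    The lexicographically first batch label is the untouched reference.
    ``jitter_sd`` adds seeded per-gene offsets to the affected batches on
    top of the systematic shift. Group labels are unchanged.
    """
    if scale_factor <= 0:
        raise ValueError("scale_factor must be positive")
    batch = pd.Series(batch_assignment)
    batch.index = cohort.values.columns
    if batch.isna().any():
        raise ValueError("batch assignment must cover all samples")
    labels = sorted(batch.unique())
    out = cohort.values.copy()
    if len(labels) > 1:
        affected = batch.isin(labels[1:]).to_numpy()
        block = out.loc[:, affected] * scale_factor + location_shift
        if jitter_sd > 0:
            rng = np.random.default_rng(seed)
            block = block.add(rng.normal(0.0, jitter_sd, size=out.shape[0]), axis=0)
        out.loc[:, affected] = block
    return cohort.with_values(out)


def generate_survival(
    expression: pd.Series,
    hr_true: float,
    censor_rate: float,
    seed: int,
) -> pd.DataFrame:
    """Exponential survival driven by standardized expression, uniform censoring.

    The per-sample hazard is ``hr_true ** z`` with ``z`` the standardized
    expression (baseline rate 1, so the reference median time is ln 2).
    Censoring is uniform on [0, c] with c solved so the expected censored
    fraction equals ``censor_rate``. Returns a DataFrame (index: sample id)
    with positive ``time`` and boolean ``event``.
    """
    if hr_true <= 0:
        raise ValueError("hr_true must be positive")
    if not 0.0 <= censor_rate < 1.0:
        raise ValueError("censor_rate must be in [0, 1)")
    expression = pd.Series(expression, dtype=float)
    if expression.empty:
        raise ValueError("expression vector is empty")
    x = expression.to_numpy()
    sd = x.std(ddof=0)
    z = np.zeros_like(x) if sd == 0 else (x - x.mean()) / sd
    rate = np.power(hr_true, z)

    rng = np.random.default_rng(seed)
    t_event = rng.exponential(1.0 / rate)

    if censor_rate == 0.0:
        time, event = t_event, np.ones_like(t_event, dtype=bool)
    else:
        # expected censored fraction under C ~ U(0, c): mean_i (1-exp(-r_i c))/(r_i c)
        def p_cens(log_c: float) -> float:
            c = np.exp(log_c)
            return float(np.mean((1.0 - np.exp(-rate * c)) / (rate * c))) - censor_rate

        log_c = brentq(p_cens, -20.0, 20.0)
        c = np.exp(log_c)
        t_cens = rng.uniform(0.0, c, size=len(x))
        event = t_event <= t_cens
        time = np.minimum(t_event, t_cens)
    time = np.maximum(time, 1e-9)
    return pd.DataFrame({"time": time, "event": event}, index=expression.index)


def generate_feature_matrix(
    expression: pd.Series,
    n_features: int = 22,
    n_linked: int = 5,
    strength: float = 0.6,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[str]]:
    """Samples × features matrix with the first ``n_linked`` features tied to expression.

    A stand-in for an immune-infiltration fraction table: linked features are
    ``strength * z(expr) + sqrt(1-strength^2) * noise``; the rest are pure
    noise. Returns the matrix and the linked feature names.
    """
    if not 0 <= n_linked <= n_features:
        raise ValueError("need 0 <= n_linked <= n_features")
    expression = pd.Series(expression, dtype=float)
    z = (expression - expression.mean()) / expression.std(ddof=0)
    rng = np.random.default_rng(seed)
    names = [f"feature{j + 1:02d}" for j in range(n_features)]
    mat = rng.normal(size=(len(expression), n_features))
    for j in range(n_linked):
        mat[:, j] = strength * z.to_numpy() + np.sqrt(1 - strength**2) * mat[:, j]
    return pd.DataFrame(mat, index=expression.index, columns=names), names[:n_linked]
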