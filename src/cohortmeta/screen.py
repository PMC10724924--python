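"""Co-expression voting screen, overexpression screen, and their intersection.

A gene is co-expressed with the target when its Pearson correlation with the
target reaches r >= r_min with p < alpha in at least ``min_datasets``
usable datasets (threshold inclusive). A gene is overexpressed when its
pooled SMD is positive with a pooled-z two-sided p < alpha. The highly
expressed co-expressed genes (HECEGs) are the intersection of the two sets,
with the target itself excluded. Raw thresholds by default, no
multiple-testing correction (a BH option exists for the vote p values).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import TUMOR
from .preprocess import HarmonizedSet

R_MIN = 0.30
ALPHA = 0.05
MIN_DATASETS = 3


@dataclass(frozen=True)
class DatasetVote:
    study_label: str
    r: float
    p: float
    n: int
    usable: bool


@dataclass(frozen=True)
class CorrelationVote:
    gene: str
    per_dataset: tuple[DatasetVote, ...]
    votes: int
    passed: bool


@dataclass(frozen=True)
class ScreenResult:
    coexpressed: frozenset[str]
    overexpressed: frozenset[str]
    heceg: tuple[str, ...]  # sorted

    def __post_init__(self) -> None:
        if not set(self.heceg) <= set(self.coexpressed) & set(self.overexpressed):
            raise ValueError("heceg must be a subset of both screens")


def _corr_with_target(mat: np.ndarray, target_row: int):
    """Pearson r and two-sided t-test p of every row against the target row.

    Rows with zero variance come back unusable (NaN r). Vectorized over
    genes; p from t = r*sqrt((n-2)/(1-r^2)) on n-2 df.
    """
    n = mat.shape[1]
    centered = mat - mat.mean(axis=1, keepdims=True)
    sd = np.sqrt((centered**2).sum(axis=1))
    t = centered[target_row]
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (centered @ t) / (sd * sd[target_row])
    r = np.clip(r, -1.0, 1.0)
    usable = (sd > 0) & (sd[target_row] > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * sps.t.sf(np.abs(tstat), df=n - 2)
    p = np.where(np.isnan(p), 0.0, p)  # |r| == 1 exactly
    return r, p, usable


def coexpression_votes(
    hset: HarmonizedSet,
    target: str,
    r_min: float = R_MIN,
    alpha: float = ALPHA,
    min_datasets: int = MIN_DATASETS,
    sample_scope: str = "tumor_only",
    bh_correct: bool = False,
) -> dict[str, CorrelationVote]:
    """Per-gene, per-dataset Pearson correlation with the target, plus votes.

    ``sample_scope`` selects tumor samples only (the default disease-tissue
    contrast) or all samples. Datasets with fewer than 3 in-scope samples or
    a constant target are unusable everywhere; individual constant genes are
    unusable in that dataset only. Unusable entries never count as votes.
    ``bh_correct`` applies Benjamini–Hochberg across genes within each
    dataset before thresholding (off by default: raw thresholds).
    """
    target = target.upper()
    if sample_scope not in ("tumor_only", "all"):
        raise ValueError("sample_scope must be 'tumor_only' or 'all'")
    genes = hset.common_genes
    if target not in genes:
        raise ValueError(f"target gene {target!r} absent from the common gene set")
    target_row = genes.index(target)

    per_gene: list[list[DatasetVote]] = [[] for _ in genes]
    for cohort in hset.cohorts:
        if sample_scope == "tumor_only":
            mask = (cohort.group == TUMOR).to_numpy()
        else:
            mask = np.ones(cohort.n_samples, dtype=bool)
        mat = cohort.values.to_numpy()[:, mask]
        n = int(mask.sum())
        if n < 3:
            for gi in range(len(genes)):
                per_gene[gi].append(DatasetVote(cohort.label, np.nan, np.nan, n, False))
            continue
        r, p, usable = _corr_with_target(mat, target_row)
        if bh_correct:
            ok = usable.copy()
            ok[target_row] = False
            if ok.any():
                p = p.copy()
                p[ok] = sps.false_discovery_control(p[ok], method="bh")
        for gi in range(len(genes)):
            per_gene[gi].append(
                DatasetVote(cohort.label, float(r[gi]), float(p[gi]), n, bool(usable[gi]))
            )

    out: dict[str, CorrelationVote] = {}
    for gi, gene in enumerate(genes):
        entries = tuple(per_gene[gi])
        votes = sum(
            1 for e in entries if e.usable and e.r >= r_min and e.p < alpha
        )
        out[gene] = CorrelationVote(
            gene=gene, per_dataset=entries, votes=votes,
            passed=votes >= min_datasets,
        )
    return out


def votes_table(votes: dict[str, CorrelationVote]) -> pd.DataFrame:
    """Long-format TSV-ready view of a vote table."""
    rows = []
    for gene, v in votes.items():
        for e in v.per_dataset:
            rows.append({
                "gene": gene, "study": e.study_label, "r": e.r, "p": e.p,
                "n": e.n, "usable": e.usable, "votes": v.votes, "passed": v.passed,
            })
    return pd.DataFrame(rows)


def overexpressed_genes(meta_table: pd.DataFrame, alpha: float = ALPHA) -> set[str]:
    """Genes with pooled SMD > 0 and pooled-z two-sided p < alpha."""
    sel = (meta_table["pooled"] > 0) & (meta_table["p"] < alpha)
    return set(meta_table.index[sel])


def heceg_intersection(
    votes: dict[str, CorrelationVote],
    overexpressed: set[str],
    target: str,
    meta_universe: set[str] | None = None,
) -> ScreenResult:
    """Intersect the co-expression voters with the overexpressed set.

    Both screens must come from the same harmonized gene universe (checked
    when ``meta_universe`` is supplied — the meta table may legitimately
    omit flagged constant genes, so the check is that it is contained in the
    vote universe). The target gene never appears in its own HECEG list.
    Output is deterministic: sorted gene symbols.
    """
    target = target.upper()
    vote_universe = set(votes)
    if meta_universe is not None and not set(meta_universe) <= vote_universe:
        extra = sorted(set(meta_universe) - vote_universe)
        raise ValueError(f"mismatched gene universes between screens: {extra[:5]}")
    if not overexpressed <= vote_universe:
        extra = sorted(overexpressed - vote_universe)
        raise ValueError(f"overexpressed genes outside the vote universe: {extra[:5]}")
    coexpressed = frozenset(g for g, v in votes.items() if v.passed)
    heceg = sorted((coexpressed & overexpressed) - {target})
    return ScreenResult(
        coexpressed=coexpressed,
        overexpressed=frozenset(overexpressed),
        heceg=tuple(heceg),
    )
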