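"""Cohort filtering, scale detection, gene harmonization, and batch adjustment.

Pipeline order: per-cohort linear-vs-log detection (``maybe_log2``), sample
-size filter, platform-wise merge + empirical-Bayes batch adjustment
(``combat_adjust``, backed by scanpy's parametric ComBat with the
tumor/normal contrast preserved as a model covariate), then gene-set
intersection across cohorts (``harmonize_genes``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import ExpressionCohort, TUMOR
from .io import read_cohort, read_survival, write_cohort  # re-exported dialect

__all__ = [
    "HarmonizedSet", "read_cohort", "write_cohort", "read_survival",
    "filter_datasets", "maybe_log2", "combat_adjust", "harmonize_genes",
    "merge_by_platform",
]

LOG2_THRESHOLD = 50.0  # values above this are taken to be on the linear scale
MIN_TOTAL_SAMPLES = 6


@dataclass
class HarmonizedSet:
    """Cohorts restricted to one ordered common gene set."""

    cohorts: list[ExpressionCohort]
    common_genes: list[str]
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.common_genes:
            raise ValueError("empty common gene set")
        for c in self.cohorts:
            if c.gene_ids != self.common_genes:
                raise ValueError(
                    f"cohort {c.label!r} gene order does not match common_genes"
                )
        if not self.provenance:
            self.provenance = [c.label for c in self.cohorts]


def filter_datasets(
    cohorts: list[ExpressionCohort], min_total: int = MIN_TOTAL_SAMPLES
) -> list[ExpressionCohort]:
    """Drop cohorts with fewer than ``min_total`` samples overall (inclusive bound).

    Mirrors the compendium inclusion criterion "sample size >= six". Raises
    when every cohort is removed (nothing left to meta-analyze) — but an
    empty input list passes through empty.
    """
    kept = [c for c in cohorts if c.n_samples >= min_total]
    if cohorts and not kept:
        raise ValueError(
            f"all {len(cohorts)} cohorts fall below min_total={min_total}"
        )
    return kept


def maybe_log2(
    cohort: ExpressionCohort, threshold: float = LOG2_THRESHOLD
) -> ExpressionCohort:
    """Log2(x+1)-transform cohorts that look linear-scale (max value > threshold)."""
    mx = float(cohort.values.to_numpy().max(initial=0.0))
    if mx <= threshold:
        return cohort
    if (cohort.values.to_numpy() < 0).any():
        raise ValueError(
            f"cohort {cohort.label!r}: negative values with max > {threshold}; "
            "cannot log-transform"
        )
    out = cohort.with_values(np.log2(cohort.values + 1.0))
    out.log_scale = True
    return out


def combat_adjust(
    matrix: pd.DataFrame, batch, group=None
) -> pd.DataFrame:
    """Parametric empirical-Bayes location/scale batch adjustment (ComBat).

    ``matrix`` is genes × samples; ``batch`` and optional ``group`` are
    per-sample labels. The tumor/normal contrast is kept as a covariate in
    the standardization model so group signal survives adjustment. Per-gene
    batch effects are shrunk by parametric EB (normal prior on locations,
    inverse-gamma on scales) and removed. Degenerate designs error out:
    a single batch, a batch with fewer than 2 samples (scale not
    estimable), or batch perfectly confounded with group.
    """
    import scanpy as sc  # deferred: heavy import
    from anndata import AnnData

    batch = pd.Series(np.asarray(batch, dtype=object), index=matrix.columns)
    counts = batch.value_counts()
    if len(counts) < 2:
        raise ValueError("combat_adjust needs at least 2 batches")
    if (counts < 2).any():
        small = counts[counts < 2].index.tolist()
        raise ValueError(f"batch scale not estimable with <2 samples: {small}")

    obs = pd.DataFrame({"batch": batch.astype(str)}, index=matrix.columns.astype(str))
    covariates = None
    if group is not None:
        group = pd.Series(np.asarray(group, dtype=object), index=matrix.columns)
        dummies = pd.get_dummies(group.astype(str), drop_first=True).astype(float)
        design = np.column_stack(
            [pd.get_dummies(batch.astype(str)).to_numpy(float), dummies.to_numpy()]
        )
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise ValueError(
                "batch is confounded with group: batch effects not identifiable"
            )
        for col in dummies.columns:
            obs[f"grp_{col}"] = dummies[col].to_numpy()
        covariates = [f"grp_{col}" for col in dummies.columns]

    adata = AnnData(
        matrix.to_numpy(float).T.copy(), obs=obs,
        var=pd.DataFrame(index=matrix.index.astype(str)),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sc.pp.combat(adata, key="batch", covariates=covariates)
    return pd.DataFrame(adata.X.T, index=matrix.index, columns=matrix.columns)


def harmonize_genes(cohorts: list[ExpressionCohort]) -> HarmonizedSet:
    """Intersect gene sets across cohorts and reorder every matrix identically.

    The common gene order is sorted for reproducibility (invariant under
    cohort input order). Cohorts contributing no exclusive loss are left
    untouched apart from row reordering. An empty global intersection is an
    error.
    """
    if not cohorts:
        raise ValueError("no cohorts to harmonize")
    common: set[str] = set(cohorts[0].gene_ids)
    for c in cohorts[1:]:
        common &= set(c.gene_ids)
    if not common:
        raise ValueError("empty gene intersection across cohorts")
    ordered = sorted(common)
    restricted = [c.subset_genes(ordered) for c in cohorts]
    return HarmonizedSet(cohorts=restricted, common_genes=ordered,
                         provenance=[c.label for c in cohorts])


def merge_by_platform(cohorts: list[ExpressionCohort]) -> list[ExpressionCohort]:
    """Merge cohorts sharing a platform label, batch-adjusting by source study.

    Cohorts with a unique platform pass through unchanged. Merged cohorts
    are restricted to the genes shared within the platform, concatenated,
    and ComBat-adjusted with the source study as batch and tumor/normal as
    the preserved covariate. Pairing information does not survive a merge.
    """
    by_platform: dict[str, list[ExpressionCohort]] = {}
    for c in cohorts:
        by_platform.setdefault(c.platform_label, []).append(c)
    out: list[ExpressionCohort] = []
    for platform, members in by_platform.items():
        if len(members) == 1:
            out.append(members[0])
            continue
        shared = harmonize_genes(members)
        mat = pd.concat([c.values for c in shared.cohorts], axis=1)
        batch = np.concatenate(
            [[c.label] * c.n_samples for c in shared.cohorts]
        )
        group = pd.concat([c.group for c in shared.cohorts])
        adjusted = combat_adjust(mat, batch, group)
        out.append(
            ExpressionCohort(
                values=adjusted,
                group=group,
                pair_id=None,
                platform_label=platform,
                log_scale=all(c.log_scale for c in shared.cohorts),
                label="+".join(c.label for c in shared.cohorts),
            )
        )
    return out
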