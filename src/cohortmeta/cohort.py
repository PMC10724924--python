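"""Core container for one study's expression matrix plus phenotype labels.

An :class:`ExpressionCohort` holds a genes × samples matrix of (log2)
expression values together with the tumor/normal group label of every
sample, optional tumor–normal pairing, and a platform tag used to decide
which cohorts get merged before batch adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

TUMOR = "tumor"
NORMAL = "normal"
VALID_GROUPS = frozenset({TUMOR, NORMAL})


@dataclass
class ExpressionCohort:
    """One study: genes × samples expression values and per-sample phenotype.

    Parameters
    ----------
    values
        DataFrame indexed by gene symbol (uppercase, unique), columns are
        sample ids (unique). Values are expression measurements, usually on
        the log2 scale (see ``log_scale``).
    group
        Per-sample label, ``"tumor"`` or ``"normal"``, aligned with the
        matrix columns.
    pair_id
        Optional per-sample pair identifier for paired tumor/normal designs;
        each id must occur exactly once in each group.
    platform_label
        Free-text platform/source tag; cohorts sharing a label are merged
        (with the source as batch) before empirical-Bayes batch adjustment.
    log_scale
        True when values are on the log2 scale.
    label
        Human-readable study label used in forest plots and manifests.
    """

    values: pd.DataFrame
    group: pd.Series
    pair_id: pd.Series | None = None
    platform_label: str = ""
    log_scale: bool = True
    label: str = ""

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        self.values.index = self.values.index.astype(str)
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate gene ids: {list(dups)[:5]}")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        self.group = pd.Series(self.group)
        self.group.index = self.values.columns
        bad = set(self.group.unique()) - VALID_GROUPS
        if bad:
            raise ValueError(f"invalid group labels {sorted(bad)}; expected tumor/normal")
        if len(self.group) != self.values.shape[1]:
            raise ValueError("group labels do not match sample count")
        for g in (TUMOR, NORMAL):
            if (self.group == g).sum() == 0:
                raise ValueError(f"cohort {self.label!r} has no {g} samples")
        if not np.issubdtype(np.asarray(self.values).dtype, np.number):
            raise ValueError("expression matrix contains non-numeric cells")
        if self.pair_id is not None:
            self.pair_id = pd.Series(self.pair_id)
            self.pair_id.index = self.values.columns
            for g in (TUMOR, NORMAL):
                ids = self.pair_id[self.group == g].dropna()
                if ids.duplicated().any():
                    raise ValueError(f"pair id repeated within {g} group")

    # -- convenience accessors -------------------------------------------

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_tumor(self) -> int:
        return int((self.group == TUMOR).sum())

    @property
    def n_normal(self) -> int:
        return int((self.group == NORMAL).sum())

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def paired(self) -> bool:
        return self.pair_id is not None and self.pair_id.notna().all()

    def expression(self, gene: str) -> pd.Series:
        """Expression of one gene across all samples."""
        gene = gene.upper()
        if gene not in self.values.index:
            raise KeyError(f"gene {gene!r} absent from cohort {self.label!r}")
        return self.values.loc[gene]

    def tumor_values(self, gene: str) -> np.ndarray:
        return self.expression(gene)[self.group == TUMOR].to_numpy(float)

    def normal_values(self, gene: str) -> np.ndarray:
        return self.expression(gene)[self.group == NORMAL].to_numpy(float)

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionCohort":
        """Restrict (and reorder) to the given genes."""
        missing = [g for g in genes if g not in self.values.index]
        if missing:
            raise KeyError(f"genes absent from cohort {self.label!r}: {missing[:5]}")
        return replace(self, values=self.values.loc[list(genes)].copy())

    def with_values(self, values: pd.DataFrame) -> "ExpressionCohort":
        return replace(self, values=values)

    def copy(self) -> "ExpressionCohort":
        return replace(
            self,
            values=self.values.copy(),
            group=self.group.copy(),
            pair_id=None if self.pair_id is None else self.pair_id.copy(),
        )

    def equals(self, other: "ExpressionCohort") -> bool:
        if not self.values.equals(other.values):
            return False
        if not self.group.equals(other.group):
            return False
        if (self.pair_id is None) != (other.pair_id is None):
            return False
        if self.pair_id is not None and not self.pair_id.equals(other.pair_id):
            return False
        return (
            self.platform_label == other.platform_label
            and self.log_scale == other.log_scale
        )
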