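import numpy as np
import pandas as pd
import pytest

from cohortmeta.cohort import ExpressionCohort
from cohortmeta.preprocess import harmonize_genes
from cohortmeta.simulate import CohortSpec, generate_cohorts, make_truth


@pytest.fixture(scope="session")
def small_world():
    """Four modest cohorts with a true upshifted 8-gene module, harmonized."""
    specs = [
        CohortSpec(15, 10, label="w1", platform_label="p1"),
        CohortSpec(12, 12, paired=True, label="w2", platform_label="p2"),
        CohortSpec(8, 8, label="w3", platform_label="p3"),
        CohortSpec(20, 5, label="w4", platform_label="p4"),
    ]
    truth = make_truth(
        n_genes=60, n_members=8, delta_target=1.0, delta_members=1.0,
        tau2=0.02, coexpr_strength=0.7,
    )
    cohorts, truth = generate_cohorts(specs, truth, seed=11)
    return harmonize_genes(cohorts), truth


def toy_cohort(tumor, normal, gene="TPI1", label="toy"):
    """One-gene cohort from explicit tumor/normal value lists."""
    values = pd.DataFrame(
        [list(tumor) + list(normal)],
        index=[gene],
        columns=[f"t{i}" for i in range(len(tumor))]
        + [f"n{i}" for i in range(len(normal))],
    )
    group = pd.Series(["tumor"] * len(tumor) + ["normal"] * len(normal),
                      index=values.columns)
    return ExpressionCohort(values=values, group=group, label=label,
                            platform_label=label)


def multi_gene_cohort(matrix: dict, n_tumor: int, label="mg"):
    """Cohort from {gene: values}; first n_tumor columns are tumor."""
    values = pd.DataFrame(matrix).T
    n = values.shape[1]
    values.columns = [f"{label}-s{i}" for i in range(n)]
    group = pd.Series(["tumor"] * n_tumor + ["normal"] * (n - n_tumor),
                      index=values.columns)
    return ExpressionCohort(values=values, group=group, label=label,
                            platform_label=label)
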