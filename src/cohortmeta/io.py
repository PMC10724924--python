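"""Reading and writing the cohort TSV dialect.

Expression: genes × samples TSV, first column ``gene`` (symbol), header row
of sample ids. Phenotype: TSV with columns ``sample_id``, ``group``
(tumor/normal) and optional ``pair_id``, ``time``, ``event``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import ExpressionCohort, VALID_GROUPS

PHENO_COLUMNS = ["sample_id", "group", "pair_id", "time", "event"]


def write_cohort(
    cohort: ExpressionCohort,
    expression_path: str | Path,
    phenotype_path: str | Path,
    survival: pd.DataFrame | None = None,
) -> None:
    """Write one cohort as expression + phenotype TSVs.

    ``survival``, if given, is a DataFrame indexed by sample id with
    ``time``/``event`` columns merged into the phenotype table.
    """
    expression_path = Path(expression_path)
    phenotype_path = Path(phenotype_path)
    mat = cohort.values.copy()
    mat.index.name = "gene"
    mat.to_csv(expression_path, sep="\t", float_format="%.10g")

    pheno = pd.DataFrame(
        {
            "sample_id": cohort.sample_ids,
            "group": cohort.group.to_numpy(),
            "pair_id": (
                cohort.pair_id.to_numpy() if cohort.pair_id is not None else ""
            ),
        }
    )
    if survival is not None:
        pheno["time"] = pheno["sample_id"].map(survival["time"])
        pheno["event"] = pheno["sample_id"].map(survival["event"]).astype("Int64")
    pheno.to_csv(phenotype_path, sep="\t", index=False, float_format="%.10g")


def read_cohort(
    expression_path: str | Path,
    phenotype_path: str | Path,
    platform_label: str | None = None,
    label: str | None = None,
) -> ExpressionCohort:
    """Read a cohort from the TSV dialect, validating and harmonizing symbols.

    Gene symbols are uppercased; duplicate symbols are collapsed by row-mean.
    Raises ``ValueError`` naming the offending sample when the phenotype and
    matrix disagree, and on non-numeric cells or a missing group.
    """
    expression_path = Path(expression_path)
    phenotype_path = Path(phenotype_path)
    if not expression_path.exists():
        raise FileNotFoundError(str(expression_path))
    if not phenotype_path.exists():
        raise FileNotFoundError(str(phenotype_path))

    mat = pd.read_csv(expression_path, sep="\t", index_col=0)
    try:
        mat = mat.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric expression cells in {expression_path}: {exc}")
    mat.index = mat.index.astype(str).str.upper()
    if mat.index.has_duplicates:
        mat = mat.groupby(level=0, sort=False).mean()

    pheno = pd.read_csv(phenotype_path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in pheno.columns or "group" not in pheno.columns:
        raise ValueError(f"phenotype {phenotype_path} needs sample_id and group columns")
    pheno = pheno.set_index("sample_id")

    missing_in_matrix = [s for s in pheno.index if s not in mat.columns]
    if missing_in_matrix:
        raise ValueError(
            f"samples in phenotype but absent from matrix: {missing_in_matrix[:5]}"
        )
    missing_in_pheno = [s for s in mat.columns if s not in pheno.index]
    if missing_in_pheno:
        raise ValueError(
            f"samples in matrix but absent from phenotype: {missing_in_pheno[:5]}"
        )
    mat = mat[list(pheno.index)]

    group = pheno["group"].astype(str).str.lower()
    bad = set(group.unique()) - VALID_GROUPS
    if bad:
        raise ValueError(f"unknown group labels {sorted(bad)} in {phenotype_path}")

    pair_id = None
    if "pair_id" in pheno.columns:
        raw = pheno["pair_id"].replace("", np.nan)
        if raw.notna().any():
            pair_id = raw

    return ExpressionCohort(
        values=mat,
        group=group,
        pair_id=pair_id,
        platform_label=platform_label if platform_label is not None else expression_path.stem,
        log_scale=True,
        label=label if label is not None else expression_path.stem,
    )


def read_survival(phenotype_path: str | Path) -> pd.DataFrame:
    """Extract the time/event columns of a phenotype TSV (samples with both)."""
    pheno = pd.read_csv(phenotype_path, sep="\t", dtype={"sample_id": str})
    if "time" not in pheno.columns or "event" not in pheno.columns:
        raise ValueError(f"{phenotype_path} has no time/event columns")
    out = pheno.set_index("sample_id")[["time", "event"]].dropna()
    out["time"] = out["time"].astype(float)
    out["event"] = out["event"].astype(int).astype(bool)
    return out


def write_truth(truth, path: str | Path) -> None:
    """Serialize a TruthRecord as JSON (gene-indexed shift vector included)."""
    payload = {
        "true_delta": {g: float(d) for g, d in truth.true_delta.items()},
        "tau2_true": float(truth.tau2_true),
        "coexpr_members": sorted(truth.coexpr_members),
        "coexpr_strength": float(truth.coexpr_strength),
        "target_gene": truth.target_gene,
        "hr_true": float(truth.hr_true),
        "censor_rate": float(truth.censor_rate),
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))
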