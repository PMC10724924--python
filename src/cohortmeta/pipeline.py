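"""End-to-end orchestration: simulate/read → preprocess → meta → SROC →
screen → survival → group comparisons, with a logged run manifest.

Every stage writes plot-ready TSV/JSON into the output directory; the run
is deterministic given the config and seed, and a failure removes partial
outputs and re-raises with the stage name attached.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import ExpressionCohort, TUMOR
from .io import read_cohort, read_survival, write_cohort, write_truth
from .meta import begg_test, forest_table, gene_effects, leave_one_out, meta_per_gene, pool
from .preprocess import (
    filter_datasets, harmonize_genes, maybe_log2, merge_by_platform,
)
from .screen import (
    coexpression_votes, heceg_intersection, overexpressed_genes, votes_table,
)
from .simulate import (
    CohortSpec, TruthRecord, default_cohort_specs, generate_cohorts,
    generate_feature_matrix, generate_survival, make_truth,
)
from .sroc import dataset_confusion, fit_bivariate, pooled_accuracy, sroc_curve
from .stats import benjamini_hochberg, pearson_corr, wilcoxon_rank_sum
from .survival import SurvivalTable, km_table, logrank_test, median_split

FLOAT_FMT = "%.10g"


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name (and cohort when known)."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage {stage}] {message}")


@dataclass
class PipelineConfig:
    """All knobs of one run; every threshold the analysis uses lives here.

    Either ``cohort_paths`` (list of {expression, phenotype, platform,
    label} mappings) or ``simulate=True`` must be set. Thresholds default
    to the analysis conventions: co-expression r >= 0.30 with p < 0.05 in
    >= 3 datasets, dataset inclusion at >= 6 samples, fixed-effect pooling
    iff I² <= 50% or p(Q) > 0.05.
    """

    out_dir: str = "cohortmeta-out"
    target_gene: str = "TPI1"
    seed: int = 0
    simulate: bool = True
    cohort_paths: list[dict] = field(default_factory=list)
    # screen / meta thresholds
    r_min: float = 0.30
    alpha: float = 0.05
    min_datasets: int = 3
    min_total: int = 6
    log2_threshold: float = 50.0
    sample_scope: str = "tumor_only"
    bh_compare: bool = True  # BH for the feature-comparison table
    # simulation profile (used when simulate=True)
    n_genes: int = 2000
    n_members: int = 30
    delta: float = 1.0
    tau2: float = 0.05
    coexpr_strength: float = 0.7
    hr_true: float = 2.0
    censor_rate: float = 0.3
    specs: list[CohortSpec] | None = None
    n_survival_cohorts: int = 3  # prognostic cohorts: largest by tumor count
    n_features: int = 22
    n_linked_features: int = 5

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_min <= 1.0:
            raise ValueError("r_min must be in [0, 1]")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.min_datasets < 1:
            raise ValueError("min_datasets must be >= 1")
        if not self.simulate and not self.cohort_paths:
            raise ValueError("either simulate=True or cohort_paths is required")
        if self.simulate and self.seed is None:
            raise ValueError("simulation requires a seed")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        specs = d.pop("specs", None)
        cfg = cls(**d)
        if specs is not None:
            cfg.specs = [CohortSpec(**s) if isinstance(s, dict) else s for s in specs]
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def echo(self) -> dict:
        d = dataclasses.asdict(self)
        if self.specs is not None:
            d["specs"] = [dataclasses.asdict(s) for s in self.specs]
        return d


def _stage_seed(seed: int, stage: int) -> int:
    return int(np.random.SeedSequence([seed, stage]).generate_state(1)[0] % (2**31))


def compare_feature_matrix(
    features: pd.DataFrame,
    groups: pd.Series,
    target_expression: pd.Series | None = None,
    bh: bool = True,
) -> pd.DataFrame:
    """Per-feature two-group Wilcoxon comparison (plus optional target correlation).

    ``features`` is samples × features; ``groups`` a two-level label per
    sample. Returns one row per feature with the rank-sum statistic, raw p,
    BH-adjusted q (when ``bh``), and Pearson r against the target
    expression when supplied.
    """
    groups = pd.Series(groups)
    levels = sorted(groups.unique())
    if len(levels) != 2:
        raise ValueError(f"need exactly two group levels, got {levels}")
    a_mask = (groups == levels[0]).to_numpy()
    rows = []
    for name in features.columns:
        x = features[name].to_numpy(float)
        if np.ptp(x) == 0:
            rows.append({"feature": name, "statistic": np.nan, "p": 1.0, "r": np.nan})
            continue
        res = wilcoxon_rank_sum(x[a_mask], x[~a_mask])
        r = np.nan
        if target_expression is not None:
            aligned = pd.Series(target_expression).loc[features.index].to_numpy(float)
            if np.ptp(aligned) > 0:
                r = pearson_corr(x, aligned).estimate
        rows.append({"feature": name, "statistic": res.statistic, "p": res.p_value,
                     "r": r})
    out = pd.DataFrame(rows).set_index("feature")
    if bh:
        out["q"] = benjamini_hochberg(out["p"].to_numpy())
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage, write the report bundle, and return it in memory.

    Outputs (under ``config.out_dir``): cohort TSVs + truth JSON (when
    simulating), forest.tsv, loo.tsv, meta_genes.tsv, confusion.tsv,
    sroc.json, sroc_curve.tsv, votes.tsv, gene lists (coexpressed.txt,
    overexpressed.txt, heceg.txt), km_curves.tsv, logrank.json,
    compare.tsv, manifest.json.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage_log: list[dict] = []
    report: dict = {}

    def emit_frame(frame: pd.DataFrame, name: str, index: bool = True) -> None:
        path = out_dir / name
        frame.to_csv(path, sep="\t", float_format=FLOAT_FMT, index=index)
        written.append(path)

    def emit_json(payload: dict, name: str) -> None:
        path = out_dir / name
        path.write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")
        written.append(path)

    current_stage = "setup"
    try:
        # -- acquire ------------------------------------------------------
        current_stage = "acquire"
        truth: TruthRecord | None = None
        if config.simulate:
            specs = config.specs if config.specs is not None else default_cohort_specs()
            truth = make_truth(
                n_genes=config.n_genes, n_members=config.n_members,
                delta_target=config.delta, delta_members=config.delta,
                tau2=config.tau2, coexpr_strength=config.coexpr_strength,
                target_gene=config.target_gene, hr_true=config.hr_true,
                censor_rate=config.censor_rate,
            )
            cohorts, truth = generate_cohorts(specs, truth, _stage_seed(config.seed, 0))
            write_truth(truth, out_dir / "truth.json")
            written.append(out_dir / "truth.json")
        else:
            cohorts = [
                read_cohort(
                    entry["expression"], entry["phenotype"],
                    platform_label=entry.get("platform"), label=entry.get("label"),
                )
                for entry in config.cohort_paths
            ]
        stage_log.append({
            "stage": "acquire",
            "cohorts": [
                {"label": c.label, "n_tumor": c.n_tumor, "n_normal": c.n_normal,
                 "n_genes": len(c.gene_ids), "platform": c.platform_label}
                for c in cohorts
            ],
        })

        # survival inputs must be captured before merging renames cohorts
        current_stage = "survival-setup"
        surv_cohorts = sorted(cohorts, key=lambda c: -c.n_tumor)[
            : config.n_survival_cohorts
        ]
        surv_inputs = []  # (label, expression Series over tumor samples, table)
        for i, c in enumerate(surv_cohorts):
            if config.target_gene.upper() not in c.values.index:
                continue
            expr = c.expression(config.target_gene)[c.group == TUMOR]
            if config.simulate:
                surv = generate_survival(
                    expr, truth.hr_true, truth.censor_rate,
                    _stage_seed(config.seed, 100 + i),
                )
            else:
                entry = next(
                    e for e in config.cohort_paths if e.get("label") == c.label
                )
                try:
                    surv = read_survival(entry["phenotype"]).reindex(expr.index).dropna()
                except ValueError:
                    continue
                expr = expr.loc[surv.index]
            if len(surv) >= 4 and expr.nunique() > 1:
                surv_inputs.append((c.label, expr, surv))

        # -- preprocess ---------------------------------------------------
        current_stage = "preprocess"
        cohorts = [maybe_log2(c, config.log2_threshold) for c in cohorts]
        n_before = len(cohorts)
        cohorts = filter_datasets(cohorts, config.min_total)
        n_excluded = n_before - len(cohorts)
        cohorts = merge_by_platform(cohorts)
        hset = harmonize_genes(cohorts)
        stage_log.append({
            "stage": "preprocess", "excluded_small": n_excluded,
            "cohorts_after_merge": [c.label for c in hset.cohorts],
            "common_genes": len(hset.common_genes),
        })

        # -- effect-size meta-analysis ------------------------------------
        current_stage = "meta"
        target = config.target_gene.upper()
        if target not in hset.common_genes:
            raise ValueError(f"target gene {target!r} lost during harmonization")
        effects = gene_effects(hset, target)
        pooled = pool(effects)
        emit_frame(forest_table(effects, pooled), "forest.tsv", index=False)
        loo_rows = []
        if len(effects) >= 2:
            loo, stable = leave_one_out(effects)
            for e, r in zip(effects, loo):
                loo_rows.append({
                    "omitted": e.study_label, "pooled": r.pooled, "se": r.se,
                    "ci_low": r.ci_low, "ci_high": r.ci_high, "model": r.model,
                    "significant": r.significant,
                })
            emit_frame(pd.DataFrame(loo_rows), "loo.tsv", index=False)
        begg = None
        if len(effects) >= 3:
            begg = begg_test(effects)
        meta_table = meta_per_gene(hset)
        emit_frame(meta_table, "meta_genes.tsv")
        report["target_meta"] = pooled
        report["meta_table"] = meta_table
        het = pooled.het
        stage_log.append({
            "stage": "meta", "target": target,
            "pooled_smd": pooled.pooled, "ci": [pooled.ci_low, pooled.ci_high],
            "model": pooled.model, "I2": het.I2 if het else None,
            "p_Q": het.p_Q if het else None,
            "loo_stable": bool(loo_rows) and all(r["significant"] for r in loo_rows),
            "begg_p": begg.p_value if begg else None,
            "genes_tested": int(len(meta_table)),
        })

        # -- diagnostic meta-analysis -------------------------------------
        current_stage = "sroc"
        tables = [dataset_confusion(c, target) for c in hset.cohorts]
        usable_tables = [t for t in tables if not t.degenerate]
        emit_frame(pd.DataFrame([
            {"study": t.study_label, "tp": t.tp, "fp": t.fp, "fn": t.fn,
             "tn": t.tn, "degenerate": t.degenerate} for t in tables
        ]), "confusion.tsv", index=False)
        sroc_payload: dict = {"k": len(usable_tables)}
        if len(usable_tables) >= 2:
            fit = fit_bivariate(usable_tables)
            acc = pooled_accuracy(fit)
            curve = sroc_curve(fit)
            emit_frame(
                pd.DataFrame({"fpr": curve.fpr_grid, "sens": curve.sens_curve}),
                "sroc_curve.tsv", index=False,
            )
            sroc_payload.update({
                "mu_sens_logit": fit.mu_sens_logit,
                "mu_spec_logit": fit.mu_spec_logit,
                "between_study_cov": fit.between_study_cov.tolist(),
                "converged": bool(fit.converged), "method": fit.method,
                "auc": curve.auc,
                "summary_point": list(curve.summary_point),
                "accuracy": {
                    k: (list(v) if isinstance(v, tuple) else v)
                    for k, v in acc.items()
                },
            })
            report["sroc"] = sroc_payload
        emit_json(sroc_payload, "sroc.json")
        stage_log.append({"stage": "sroc", "k": len(usable_tables),
                          "auc": sroc_payload.get("auc")})

        # -- screens ------------------------------------------------------
        current_stage = "screen"
        votes = coexpression_votes(
            hset, target, r_min=config.r_min, alpha=config.alpha,
            min_datasets=config.min_datasets, sample_scope=config.sample_scope,
        )
        over = overexpressed_genes(meta_table, alpha=config.alpha)
        result = heceg_intersection(votes, over, target,
                                    meta_universe=set(meta_table.index))
        emit_frame(votes_table(votes), "votes.tsv", index=False)
        for name, genes in (
            ("coexpressed.txt", sorted(result.coexpressed)),
            ("overexpressed.txt", sorted(result.overexpressed)),
            ("heceg.txt", list(result.heceg)),
        ):
            path = out_dir / name
            path.write_text("\n".join(genes) + ("\n" if genes else ""))
            written.append(path)
        report["screen"] = result
        stage_log.append({
            "stage": "screen", "coexpressed": len(result.coexpressed),
            "overexpressed": len(result.overexpressed), "heceg": len(result.heceg),
        })

        # -- survival -----------------------------------------------------
        current_stage = "survival"
        km_frames, logrank_payload = [], {}
        surv_table_first: SurvivalTable | None = None
        for label, expr, surv in surv_inputs:
            groups = median_split(expr)
            table = SurvivalTable(surv["time"], surv["event"], groups.loc[surv.index])
            frame = km_table(table)
            frame.insert(0, "cohort", label)
            km_frames.append(frame)
            res = logrank_test(table)
            logrank_payload[label] = {
                "chi2": res.statistic, "p": res.p_value,
                "n_high": res.n[0], "n_low": res.n[1],
            }
            if surv_table_first is None:
                surv_table_first = table
        if km_frames:
            emit_frame(pd.concat(km_frames, ignore_index=True), "km_curves.tsv",
                       index=False)
        emit_json(logrank_payload, "logrank.json")
        report["logrank"] = logrank_payload
        stage_log.append({"stage": "survival",
                          "cohorts": sorted(logrank_payload)})

        # -- feature-matrix comparison ------------------------------------
        current_stage = "compare"
        if config.simulate and surv_inputs:
            label, expr, _ = surv_inputs[0]
            feats, linked = generate_feature_matrix(
                expr, n_features=config.n_features,
                n_linked=config.n_linked_features,
                seed=_stage_seed(config.seed, 200),
            )
            comp = compare_feature_matrix(
                feats, median_split(expr), target_expression=expr,
                bh=config.bh_compare,
            )
            emit_frame(comp, "compare.tsv")
            report["compare"] = comp
            stage_log.append({"stage": "compare", "cohort": label,
                              "n_features": config.n_features,
                              "linked": linked})

        # -- manifest -----------------------------------------------------
        current_stage = "manifest"
        import lifelines, scipy, sklearn  # versions for provenance

        manifest = {
            "config": config.echo(),
            "seed": config.seed,
            "versions": {
                "cohortmeta": __version__, "numpy": np.__version__,
                "pandas": pd.__version__, "scipy": scipy.__version__,
                "lifelines": lifelines.__version__,
                "scikit-learn": sklearn.__version__,
            },
            "stages": stage_log,
        }
        emit_json(manifest, "manifest.json")
        report["manifest"] = manifest
        report["harmonized"] = hset
        report["truth"] = truth
        return report
    except Exception as exc:
        for path in written:
            path.unlink(missing_ok=True)
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(current_stage, str(exc)) from exc
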