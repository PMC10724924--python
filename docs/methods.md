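# Methods

This note documents the statistical models, the synthetic world the tests
run against, numerical choices, and the places where the design was
genuinely open. Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Effect-size meta-analysis

Per study, the tumor-vs-normal standardized mean difference is Hedges' *g*
(Cohen's *d* times the small-sample correction J = 1 − 3/(4m − 1),
m = n_t + n_n − 2), with variance
J²[(n_t + n_n)/(n_t n_n) + d²/(2(n_t + n_n))]. *d* without the correction is
available behind a flag. Heterogeneity uses Cochran's Q with fixed-effect
weights, I² = max(0, (Q − df)/Q)·100, and the closed-form DerSimonian–Laird
moment estimator for τ² — deterministic and the classic forest-plot default;
REML was deliberately not used. Model choice is the literal disjunction
used by standard forest-plot tooling: **fixed-effect iff I² ≤ 50 % or
p(Q) > 0.05**, otherwise DL random effects. The CI multiplier is the normal
1.96 (no Hartung–Knapp). A pooled effect is "significant" iff its 95 % CI
excludes zero; the per-gene screen p is the two-sided pooled-z p — the
overall-effect p of the forest plot — not any per-dataset p.

Paired cohorts: effects are still computed from group means/SDs in the
two-sample form so they are comparable across paired and unpaired studies;
pairing is honored only by the Wilcoxon comparisons. This is a documented
divergence from a strictly paired effect size and attenuates the realized
SMD in paired cohorts when a within-pair intercept is simulated (below).

Begg's funnel-asymmetry test rank-correlates the standardized deviates
u_i = (g_i − θ_F)/√(v_i − 1/Σw) with the variances v_i using Kendall's
tau-b; the p value uses the tie-corrected normal approximation with
continuity correction (z = (|S| − 1)/√var S). It requires k ≥ 3 and errors
on degenerate deviates (v_i ≤ 1/Σw).

## Diagnostic (SROC) meta-analysis

Per-dataset sensitivity/specificity come from the Youden-optimal cutoff
(ties broken toward higher specificity) — the source analyses never state
their dichotomization rule, and Youden is standard and deterministic. Tables
containing a zero cell get 0.5 added to all four cells (the common Stata
convention); others are untouched.

The bivariate model treats y_i = (logit sens_i, logit spec_i) as
N(μ, Σ + S_i) with S_i the delta-method binomial variances
(1/tp + 1/fn, 1/tn + 1/fp). Σ is estimated by REML: Nelder–Mead over the
Cholesky factor of Σ (log-diagonal, so PSD is structural), with μ profiled
out by GLS inside the objective; convergence tolerances 1e-8/1e-10, at most
2000 iterations. On optimizer failure the fit falls back to per-margin
DerSimonian–Laird plus the observed deviate correlation for the
off-diagonal, flagged via `converged=False`.

The summary ROC curve is the random-effects regression of logit-sens on
logit-FPR: slope β = −Σ₁₂/Σ₂₂ in FPR coordinates. When Σ₂₂ ≈ 0 or β ≤ 0
the regression is degenerate and the curve falls back to the symmetric
constant-diagnostic-odds-ratio line (slope 1). AUC is a trapezoid over an
FPR grid that is half uniform, half logit-spaced: near FPR = 0 the curve
behaves like FPR^β with infinite slope for β < 1, and uniform grids converge
too slowly there (the mixed grid keeps 1001-point AUC within 1e-4 of a
100001-point grid). PLR/NLR are computed from the bivariate summary point —
PLR = sens/(1 − spec), NLR = (1 − sens)/spec — with delta-method CIs on the
log scale. Note that published analyses sometimes pool likelihood ratios
separately, which can disagree with the closed form applied to their own
pooled sens/spec; this package always uses the closed form.

## Screens

Co-expression: Pearson r of every gene against the target, per dataset, on
tumor samples by default (`sample_scope="all"` exists; correlating across
tumor+normal inflates r for any differentially expressed gene, so it is not
the default). A dataset votes for a gene when r ≥ 0.30 (inclusive) and
p < 0.05; datasets with under 3 in-scope samples or zero variance are marked
unusable and count neither votes nor denominators. A gene passes with ≥ 3
votes. Overexpression: pooled SMD > 0 and pooled-z p < 0.05. No
multiple-testing correction in either screen by default (the thresholds are
raw by design); Benjamini–Hochberg is available as an option. HECEG = the
intersection, target excluded, sorted.

## Preprocessing

Order: linear-vs-log detection → sample-size filter → platform merge with
batch adjustment → gene intersection. Values with a matrix maximum above 50
are treated as linear-scale and log2(x+1)-transformed (common practice for
array/RNA-seq summaries; overridable). Cohorts with fewer than 6 samples
total are excluded (inclusive bound: 3+3 stays). Duplicate gene symbols
collapse by row-mean (symmetric, variance-reducing; max would bias
upward); matching is by uppercase symbol only, no alias maps.

Batch adjustment is parametric empirical-Bayes ComBat (scanpy's
implementation behind this package's validation layer), with tumor/normal
kept as a covariate so group signal survives. Designs that cannot be
adjusted error out: one batch, a singleton batch, or batch perfectly
confounded with group. Two properties of parametric EB worth knowing:

- With a batch effect that is *constant across genes*, the EB weight
  n·τ̄²/(n·τ̄² + δ*) tends to ~1/2, because the cross-gene spread of the
  per-gene batch estimates is then pure estimation noise. Adjustment removes
  the batch effect *on average* across genes but leaves per-gene residuals
  of order half the estimation noise. With realistically heterogeneous
  per-gene batch effects the weight approaches 1 and per-gene removal is
  nearly complete. The tests assert exactly this pair of statements.
- ComBat is therefore *not* idempotent to machine precision: re-applying it
  changes values at a fraction of the noise scale, shrinking with each
  pass. The test suite asserts the contraction (second pass ≪ first pass),
  not exact idempotence.

## Synthetic world

The generator emulates a public tumor/normal expression compendium:

- **Baseline** per gene, drawn once per truth record: normal on the log2
  scale, mean 7, SD 2 (typical log2 summary range 2–14), shared across
  cohorts so cross-cohort harmonization is meaningful.
- **Shifts**: gene g in study k gets δ_gk ~ N(true_delta_g, τ²_true) added
  to tumor samples — a random-effects location model matching the SMD model
  under test. Heterogeneity enters the shift only, not the noise SD.
- **Co-expression**: one latent standard-normal factor per sample; module
  genes get residual noise_sd·(λf + √(1−λ²)ε) with λ = coexpr_strength,
  other genes noise_sd·ε. This normalization (a deliberate refinement of a
  plain additive loading) keeps every gene's marginal SD at noise_sd, so
  the true SMD is exactly true_delta/noise_sd regardless of module
  membership, and the pairwise module correlation is λ².
- **Pairing**: paired cohorts add a per-gene, per-pair N(0, pair_sd²)
  intercept to both pair members (default 0.5 log2 units), producing real
  within-pair correlation at the cost of attenuating the realized SMD by
  1/√(1 + pair_sd²/noise_sd²) ≈ 0.89 at the defaults.
- **Platform subsets**: a per-cohort dropout fraction removes random genes
  (never the target), so gene universes differ across cohorts.
- **Survival**: exponential event times with hazard hr_true^z (z =
  standardized target expression; baseline rate 1), censoring uniform on
  [0, c] with c solved by Brent's method so the expected censored fraction
  equals censor_rate. Defaults hr_true = 2.0 per SD (a strong but realistic
  prognostic marker) and censor_rate = 0.3.
- **Default cohort profile**: eight cohorts totalling 251 tumor / 136
  normal samples (111/12, 57/57 paired, 29/13, 25/25, 10/10, 9/9 paired,
  6/6, 4/4; the last two share a platform so the merge + ComBat path runs),
  matching the pooled sample counts of the kind of compendium analysis the
  pipeline reimplements. 2000 genes, a 30-gene module at λ = 0.7,
  δ = 1.0, τ² = 0.05.
- **Strong-signal profile** (`strong_signal_specs`): eight unpaired cohorts
  of 40 tumor / 20 normal, sized a priori by a Fisher-z power argument:
  with module correlation λ² = 0.49, a 40-tumor dataset passes the
  (r ≥ 0.30, p < 0.05) vote with probability ≈ 0.9, making ≥ 3 of 8 votes
  near-certain for true members. Recovery tests (screen recall/FDP) use
  this profile; the paper-scale default profile is deliberately
  underpowered in its smallest cohorts and is not expected to reach high
  recall.

What a green test does **not** establish: the generator produces Gaussian
log-intensities with a single-factor module — no count-level RNA-seq noise,
probe artifacts, non-linear batch distortions, correlated censoring, or
multi-module structure. Calibration/recovery results transfer to real data
only to the extent those features do not dominate.

All randomness flows from one integer seed through spawned
`numpy.random.Generator` streams; no global RNG state is touched, and
identical (specs, truth, seed) triples are bit-identical.

## Survival analysis

Median split sends ties to the low group (deterministic, keeps the low
group ≥ n/2); a constant expression vector cannot be split and errors.
Kaplan–Meier and the two-group log-rank χ² = (O − E)²/V (hypergeometric V,
1 df) are delegated to lifelines; conventions are the standard ones (events
precede censoring at tied times; subjects censored at t remain at risk for
deaths at t). No Cox model by design.

## Statistical primitives

Wilcoxon rank-sum/signed-rank use exact enumeration up to 12 (tie-free)
observations, otherwise the normal approximation with tie and continuity
corrections (scipy backend). Pearson p comes from the t transform on n − 2
df. Kendall's tau-b is computed in-house (O(n²), fine at meta-analysis k)
because Begg's test needs the continuity-corrected normal p that scipy does
not expose; scipy cross-checks the statistic in tests. ROC/AUC use
scikit-learn (every distinct threshold kept; AUC equals the tie-aware
Mann–Whitney probability), with the Youden maximizer resolved toward the
higher-specificity cutoff on ties.

## Pipeline conventions

Stage order is fixed and logged: acquire → preprocess (log2 → filter →
platform merge/ComBat → harmonize) → per-gene meta → SROC → screens →
survival → feature comparison → manifest. Prognostic cohorts default to the
three largest by tumor count, mirroring the typical three-cohort survival
validation. The 22-feature comparison table (an immune-infiltration-style
stand-in simulated from the target's expression) gets Benjamini–Hochberg by
default; the gene screens do not — both choices are logged. Outputs are
written with a fixed float format ("%.10g") and sorted JSON keys so
identical config + seed reproduces files byte-for-byte; partial outputs are
deleted when a stage fails. Common gene order after harmonization is
sorted, making results invariant to cohort input order.

## Known limitations

- The bivariate REML fit can sit on the τ = 0 boundary for homogeneous
  inputs; the reported covariance is then effectively zero and the SROC
  falls back to the symmetric line.
- Hedges' g from paired designs ignores the pairing (see above), which is
  conservative for the pooled estimate when pairs correlate positively.
- The vote screen's per-dataset p uses the plain Pearson t test; with
  n < 10 in-scope samples its calibration is approximate.
- No probe-level modeling, alias mapping, or enrichment analysis; gene
  lists are written in enrichment-tool-ready plain text instead.
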