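# Methods

## Model

Let E be the t×n matrix of essentiality scores (targets × cell lines;
DEMETER-like, more negative = more essential, −2 the viability cutoff) and
M the p×n binary mutation matrix, m_ij = 1 iff gene i carries a qualifying
variant in line j. A screen fixes a cohort of n′ lines (one tumor type, or
an explicit list) and, for every (target t, biomarker p) pair, tests

    H0: the distribution of e′_t is identical in mutant and wild-type lines

via the two-group linear model on the cohort columns. The effect is
ΔEss = mean(MUT) − mean(WT); negative values mean mutant lines are
sensitive to inhibition of the target, positive values mean wild-type
lines are. The residual variance is the pooled two-group variance with
df = n′ − 2.

### Variance moderation

Cohorts are small (default study conditions: n′ = 22), so raw per-target
variances are unstable. For each biomarker design we fit the standard
empirical-Bayes scaled-F model across all targets tested against that
design: s² ~ s₀²·F(df, d₀). The prior (d₀, s₀²) is estimated by matching
the mean and spread of log s² (digamma/trigamma method of moments, with a
Newton inversion of the trigamma function); when the spread of log s² does
not exceed what equal true variances would produce, d₀ = ∞. The moderated
statistic uses the posterior variance s̃² = (d₀s₀² + df·s²)/(d₀ + df) and
d₀ + df degrees of freedom (standard normal when d₀ = ∞). d₀ = 0 is the
documented no-shrinkage limit and reproduces the ordinary pooled t-test
exactly (verified to 1e−10 against an independent implementation).

Scope of pooling: one prior per biomarker design (the set of fits sharing
a design matrix), with a global-prior option (`prior_scope="global"`). A
biomarker whose mutant or wild-type group is smaller than `min_group`
(default 2) is skipped with a recorded reason; `min_group=1` is allowed
but warned against, since a one-line group contributes no spread. Zero
variances enter prior estimation with an offset of 1e−6 times the
smallest positive s² (log s² is undefined at 0); a biomarker design with
a single eligible target gets no shrinkage (d₀ = 0), since one variance
is no ensemble.

### Grouped local FDR

All tested pairs are corrected together, partitioned by biomarker gene —
the covariate-grouping idea of independent hypothesis weighting, so that a
biomarker gene with genuine signal is not drowned by the full pair
collection. Per group:

- π₀ by Storey's estimator on the λ grid 0.05…0.90 (step 0.05), smoothed
  by a cubic least-squares polynomial evaluated at λ = 0.90 and clamped to
  [0, 1]. The polynomial is the same smoothness class as the customary
  df≈4 smoothing spline but has no data-driven smoothing parameter, which
  keeps small groups deterministic and reproducible.
- The p-value mixture density f via Gaussian KDE (Silverman bandwidth) on
  the probit scale x = Φ⁻¹(p) (p clamped to [1e−8, 1−1e−8]), evaluated on
  a 1024-point grid and interpolated, back-transformed by the normal
  Jacobian; lfdr(p) = min(1, π₀/f(p)) since the null density is uniform.
- Monotone regularization: lfdr is made non-decreasing in p by a running
  maximum in p order, removing density-estimation wiggles so rankings are
  total and reproducible.

Groups with fewer than `fdr_min_group_size` (default 50) p-values fall
back to the pooled all-pairs density with π₀ forced to 1 — conservative,
but every tested pair receives an lfdr, so rankings are total. Degenerate
groups (all p identical) receive lfdr = min(1, π₀) with a flag.

Known limitation: at the single most extreme p-value of a large null
collection, any kernel estimate of f is dominated by that point's own
kernel divided by φ(x), which grows without bound as p → 0. In a fully
null collection of ~20,000 pairs the global minimum p (~5·10⁻⁵) therefore
receives a spuriously small raw lfdr. The screen's thresholds (the
|ΔEss| gate and the pre-filter) make this immaterial at the ranked-output
level — null screens come out empty — but raw pair-level lfdrs below ~0.2
at isolated extreme p-values should not be over-read.

### Pre-filter, drugs, co-occurrence

A target enters pair testing only if, within the cohort: (1) essential
(score strictly below the cutoff, default −2) in strictly more than 20 %
of lines; (2) specific — essentiality odds ratio cohort-vs-rest > 1
(Haldane–Anscombe +0.5 applied only when a 2×2 cell is zero) and
essential in ≤ 20 % of non-cohort lines; (3) expressed at ≥ 1 TPM
(inclusive) in strictly more than 75 % of cohort lines. Strict/inclusive
boundaries follow the filter definitions ("more than", "at most",
"lower than", "minimal score of"). Targets absent from the expression
matrix fail criterion (3).

Ranked pairs keep targets without any known inhibitor (the drug list is
then empty); the drug–target table can be pre-filtered to assay potencies
(IC50/Ki) strictly below 1 µM, with curated mechanism-of-action rows
always kept. An interaction set (STRING-like unordered pairs) annotates
each pair, or filters when `require_interaction` is set. The
co-occurrence helper cross-tabulates one biomarker against every other
mutated gene in the cohort (two-sided Fisher exact; Haldane-corrected
odds ratio) to flag biomarkers that merely tag along with another
mutation.

Ranking is by lfdr, with deterministic tie-breaks (p-value, |ΔEss|
descending, then lexicographic), so identical inputs give byte-identical
output tables. The grouped null model is always fitted on the full tested
collection before any query restriction, so case-by-case lfdrs and screen
lfdrs agree, and the four query modes (targets / drugs / mutations / all)
return exact slices of the unrestricted screen.

## Input handling

Matrices are TSV/CSV with row identifiers in the first column; "NA" or
empty cells mark missing essentiality scores, are rejected in mutation
matrices, and become 0 (with a warning) in expression matrices. MAF-like
variant tables are dichotomized with a default exclusion list of silent
and non-coding classes (Silent, Intron, 3'UTR, 5'UTR, 5'Flank, IGR, RNA)
and an optional minimum allele fraction, off by default — the upstream
variant-calling filters of a real panel are assumed already applied, so
the binary matrix is the primary input path. Cell lines are aligned by
intersection across all sources (at least 3 required), in the
essentiality matrix's column order.

Missing essentiality scores are imputed by nearest-neighbor averaging
over target rows: distance = mean squared difference over mutually
observed coordinates (so differing missingness patterns stay comparable),
donors restricted to rows observed at the missing column, k = 10 by
default (the convention of the reference nearest-neighbor imputation
implementation), ties broken by row order. Observed entries are never
altered, and imputation runs on the full panel before cohort selection.

## Synthetic data

The generator emulates the shapes of a real dependency screen at reduced
scale. Defaults are the documented study conditions: 400-line panel,
22-line cohort, 500 targets, 40 biomarker genes, per-gene mutation
frequencies uniform on [0.05, 0.5], scores Gaussian with unit noise
around a per-target baseline (sd 1.0 — genes differ systematically in
essentiality, which also gives the k-NN imputer genuine row structure to
exploit; a per-line offset is available but defaults to 0 so that
global-null pair tests stay independent). Planted (target, biomarker,
delta) effects shift mutant lines' scores, optionally cohort-only and
with an exact forced cohort mutant count for reproducible recovery
conditions; planted effect magnitudes in tests follow reported pairs
(ΔEss −3.9). "Commonly essential" background targets shift a chosen
fraction of the whole panel, giving the specificity filter something to
reject. Expression is log-normal TPM with ~10 % of targets forced below
1 TPM in >25 % of cohort lines to exercise the expression filter.
Drug–target rows (0–3 fictitious drugs per target) and an interaction set
(planted pairs plus decoys) complete the bundle. One seed, one bundle.

Planted targets draw a neutral per-target baseline and are excluded from
the low-TPM slice: the planted delta alone defines their ground truth, so
"recoverable" configurations pass the pre-filter by construction. A
configuration is recoverable when the forced mutant count alone clears the
20 % prevalence bar with a one-line margin (≥ 6 of 22) at |delta| ≳ 3.5;
with fewer mutants the prevalence criterion depends on chance wild-type
essentiality and recovery is genuinely unreliable (~75–85 % at 4–5
mutants), which is a property of the filter, not of the implementation.

What the generator does not emulate: shRNA-level structure and off-target
effects (upstream of the score matrix), copy-number and fusion events,
tissue or batch covariates, correlated mutation co-occurrence, and
heavy-tailed score noise. Passing tests therefore demonstrate correctness
and calibration of the statistical machinery under its own assumptions,
not performance on any real panel.

## Numerical and design choices

- Haldane–Anscombe correction only when a 2×2 cell is zero, leaving clean
  tables exact.
- The test is two-sided: both sensitivity directions are biologically
  real and are labeled (mutant-sensitive iff ΔEss < 0).
- The screen's |ΔEss| gate (default ≥ 2 in magnitude, applied to both
  signs) and lfdr ceiling (default 0.5) are configurable; an optional
  best-per-target reduction keeps one top biomarker per target.
- Problem sizes in tests and in the acceptance script (panels of 60–400
  lines, 40–500 targets, 20–50 replicate seeds) were chosen so the whole
  statistical battery — including 50-replicate planted-recovery and
  20-replicate null-calibration runs at the full 400×500×40 study scale —
  completes in seconds while leaving per-check Monte-Carlo error well
  inside the asserted margins.
- All randomness flows through explicit integer seeds; there is no hidden
  global state, and repeated runs are byte-identical.

## Limitations

- Mutation status is strictly binary; a line absent from the variant
  table is wild-type. Missing mutation data is not modeled.
- No covariate adjustment (tissue, batch) and no robust/trend variants of
  the variance moderation.
- π₀ estimation inherits the usual Storey bias when the alternative
  retains mass near p = 1 (the estimand converges to π₀ + (1−π₀)·a for a
  Beta(a,1) alternative); negligible for sharply concentrated
  alternatives.
- The KDE tail artifact described above affects isolated extreme
  p-values in large null collections at the raw pair level.
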