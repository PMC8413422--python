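# Methods

## The evaluation problem

A connectivity-map corpus is a collection of differential-expression (DE)
profiles, one per instance of a *condition* — compound × concentration ×
cell line × treatment duration. Users query it with an up/down gene-list
signature and receive a compound ranking. `cmapbench` measures the
properties that determine whether such rankings can be trusted:

1. *within-dataset agreement* — similarity of replicate DE profiles of the
   same condition inside one corpus;
2. *cross-dataset agreement* — similarity of profiles for the same
   condition measured on two platforms;
3. *retrieval performance* — whether querying a corpus with a signature
   derived from a condition ranks that condition's compound highly;
4. *explanatory structure* — how DE strength, dose, cell-line
   responsiveness and sample-level expression reproducibility predict 1–3.

Because the real compendia are external multi-gigabyte resources, every
stage here runs against a synthetic corpus whose generative parameters are
known, so each statistic can be checked against the planted truth.

## Generative model of the synthetic corpus

For gene g and sample s on platform P:

    x_gs = baseline_g + plate(s) + f(d) · resp(c, l) · θ^P_g(c, l) + ε_gs + η_gs

- `baseline_g` ~ U(4, 12) on the log2 scale, drawn once per corpus.
  Rank-based metrics downstream are invariant to this distribution, so a
  broad uniform is sufficient.
- `plate(s)` ~ N(0, plate_effect_sd²): a gene-independent scalar offset
  shared by a treatment replicate group and its plate-matched control
  group. Because treatment and control always share a plate pool, the
  offset cancels exactly in within-plate DE — which is exactly why
  plate-matching controls is worth modeling.
- `f(d) = d^h / (EC50^h + d^h)`: Hill saturation in the concentration d
  (µM). EC50 is drawn log-uniformly over the corpus's concentration range
  (so dose series span their EC50s) and h ~ U(1, 2). A Hill curve is the
  simplest saturating form with one interpretable midpoint parameter; the
  empirical dose–reproducibility trends it must reproduce are saturating.
- `resp(c, l)` ~ U(0.3, 1): per-(compound, cell line) responsiveness.
  Zero responsiveness switches the treatment signal off identically.
- `θ^A`: sparse effect vector; each gene is affected with probability
  `frac_de_genes` (default 0.15) and affected genes draw N(0, effect_scale²)
  log2-fold-change effects (default scale 2.0, so a substantial fraction
  of planted effects clear the |log2FC| ≥ 1 DE cutoff at saturating dose).
- `θ^B = ρ·z₁ + √(1−ρ²)·z₂` with z₁ = θ^A and z₂ an independent draw from
  the same sparse distribution: corr(θ^A, θ^B) has expectation ρ
  (`concordance_rho`, default 0.8).
- `ε_gs` ~ N(0, sample_noise_sd²) per-sample expression noise (default
  0.5); `η_gs` ~ N(0, platform_noise_sd²) platform-specific distortion on
  treatment samples (default 0.25).

Defaults describe the demo corpus: 1000 genes (100 landmark), 20 compounds
× 2 cell lines × 4 log-spaced concentrations (0.1–100 µM) × 6 h, three
replicate groups per condition, four treatment and four control samples
per group. These sizes keep a full pipeline run under a minute on one CPU
while leaving every downstream filter (group bounds, signature sizes,
replicate/concentration eligibility) non-trivially exercised.

All randomness flows through named substreams of one corpus seed, keyed by
stage and entity (compound, cell line, replicate tag) but never by ρ or
noise levels. Two consequences: identical (spec, seed) reproduce
byte-identical corpora, and a sweep over ρ (or a noise parameter) is a
common-random-numbers experiment in which only the swept parameter moves —
this is what makes the monotonicity checks in the test suite sharp.

### What the generator does not emulate

Bead-array detection physics, the landmark→inferred-gene imputation model,
probe-level artifacts on the synthetic path (probe collapsing is exercised
on constructed fixtures), batch structure beyond additive plate offsets,
and heavy-tailed or correlated gene noise. Passing tests demonstrate that
the *analysis machinery* is correct and recovers planted structure; they
do not certify conclusions about any real corpus.

## DE computation

FC profiles: per treatment replicate group, the largest control group
sharing its plate pool is selected (ties by lexicographic label); both
groups are subsampled (seeded, uniform) to a common size within [2, 20];
the profile is mean(treatment) − mean(control) per gene. Groups that
cannot reach the minimum, or lack a plate-matched control, are skipped and
recorded in a machine-readable exclusion table.

MZS profiles: z = (mean_t − mean_c) / √((s²_t + s²_c)/n + 10⁻³). The small
variance floor guards near-constant genes. This is a plain moderated-z
construction; the weighting scheme used by the upstream provider of real
level-5 data is proprietary to that pipeline and is not reproduced. The
recorded n (group size) drives de-standardization: z·√n, thresholded at
±2.0. FC values threshold at ±1.0. Values exactly at a threshold count as
DE — the inclusive convention is a choice, documented so counts are
reproducible.

Probe collapsing keeps, per gene and per profile independently, the probe
value with the greatest absolute magnitude (sign preserved); probes mapping
to more than one gene are dropped before collapsing, and thresholds are
applied after collapsing.

## Agreement statistics

Spearman r_s is the Pearson correlation of average ranks (tie-corrected by
construction). Constant vectors yield a missing value (NaN), not 0:
rank correlation is undefined there, and missing values are excluded from
summaries rather than silently counted.

The ternary Jaccard index on thresholded profiles A, B ∈ {−1, 0, +1}ⁿ:

    J_T(A, B) = #{i : A_i = B_i ≠ 0} / #{i : A_i ≠ 0 or B_i ≠ 0}

— genes DE in both profiles *in the same direction*, over genes DE in
either. A sign conflict contributes to the denominator only. When neither
profile has a DE gene the index is 0, not the classical 1: two empty hit
lists are not evidence of agreement.

Within-dataset agreement scores all unordered replicate pairs per
condition (pairs iterate in sorted replicate-label order for deterministic
output) and summarizes each condition by its maximum — the best case.
Each pair also records the lesser of the two profiles' DE-gene counts
("limiting profile"). Cross-dataset agreement first harmonizes conditions
(exact four-field match, or a concentration tolerance |c_a − c_b|/c_a <
tol with corpus A as reference — 0.5 reproduces the "10 ± 5 µM" rule) and
restricts both profiles to the shared gene index; pairs with fewer than 10
shared genes are skipped because rank correlation on shorter vectors is
uninformative.

Sample-level agreement uses treatment samples of the two replicate groups
behind a DE pair. In-replicate: the maximum pairwise r_s within each
group, then the minimum of the two maxima (the noisier replicate caps the
achievable DE agreement). Cross-replicate: the maximum r_s over all
between-group sample pairs.

## Retrieval

The scoring engine is the classic unweighted two-sided KS running sum:
walking the profile's genes in descending DE order (ties broken by gene
id), the sum rises 1/|list| at list members and falls 1/(N−|list|)
otherwise; the enrichment score is the signed extreme. The connectivity
score is (ES_up − ES_down)/2, set to 0 when both enrichment scores share a
sign. The production query services behind real compendia are remote and
unpublished in detail; this engine is the package's own documented scorer,
and every benchmark number in this repository refers to it.

A query scores every profile passing the cell-line filter; a compound
aggregates over its profiles by maximum score (median available). Ranks
run 1..K over the K compounds of the shared universe, descending score
with lexicographic tie-break (a deterministic total order). Top-decile
success is rank ≤ ⌈0.1·K⌉ — derived from the universe size, never a fixed
number. Meta-rankings combine several queries' rank lists: rank-product
orders by the product of ranks (equivalent to the geometric mean and exact
for integer ranks), the percentile variant by the linearly interpolated
75th percentile; both operate on ranks, not scores, and break ties
lexicographically.

## The predictive regression

Per condition: Y = maximal pairwise DE agreement; X₁ = that max pair's
lesser DE-gene count; X₂, X₃ = the same pair's in-replicate and
cross-replicate sample agreement. Taking X₂/X₃ from the same pair that
furnished Y (rather than maximizing each separately) keeps the row
internally consistent; rows with any missing component are excluded and
counted. Y and each X are z-scored and fitted by OLS with an intercept —
on standardized variables the intercept is ~0 and is kept purely for
numerical stability. Reported: standardized coefficients Β, adjusted R²,
F with (3, n−4) degrees of freedom, per-coefficient two-sided p-values.

`simulate_regression_dataset` draws data from this model itself with
planted Β = (0.60, 0.13, 0.19) and target R² = 0.372. Predictors are
standard normal with corr(X₁,X₂) = corr(X₁,X₃) = (R² − ΣΒ²)/(2(Β₁Β₂+Β₁Β₃))
≈ −0.11 and residual variance 1 − R², which makes the population response
variance exactly 1 — so the population standardized coefficients equal the
planted Β *and* the population R² equals the target simultaneously
(independent predictors cannot satisfy both). The mild negative
correlation between the DE-count predictor and the sample-agreement
predictors also mirrors what real compendia show.

Dose trends pool all pairwise agreement values of eligible conditions
(≥ 3 replicate profiles) within a (compound, cell line) group spanning
≥ 3 distinct concentrations, and report the Spearman correlation of
agreement against log10 concentration with its p-value. A rank trend
replaces visual curve smoothing because it is scalar, assumption-light and
directly testable; note that with several pairs per dose, tied log-doses
cap the statistic below +1 even for a perfectly monotone relationship.

## Numerical conventions and edge cases

- Boundary thresholds inclusive (±1.0 FC, ±2.0 de-standardized MZS).
- All magnitude orderings break ties by lexicographic gene id; compound
  rankings break score ties by lexicographic compound id.
- A gene valued exactly 0 never enters a top-k list; profiles with fewer
  than k strictly signed genes are disqualified, not padded.
- Disqualifications and skipped conditions are values/records, not
  exceptions; every exclusion appears in exactly one TSV table.
- GCT text (1.2 written, 1.2/1.3 read) round-trips values at six
  significant digits; GRP is one gene id per line with `#` comments.
- Config documents reject unknown keys before any stage runs; every output
  carries the config hash (sha256 of the canonical JSON) and seed.

## Known limitations

Retrieval scores are not normalized against a reference compound
distribution (no analogue of service-side non-specificity correction), so
scores are comparable within a run, not across corpora. The MZS path is a
generic moderated z, not a reimplementation of any provider's weighting.
Real-data adapters are limited to the text formats (GCT/GRP/TSV); binary
container formats are out of scope. The regression is descriptive — the
synthetic experiment shows the fitting machinery recovers planted effects,
not that the three predictors are causal in real data.
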