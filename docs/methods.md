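# Methods

This note documents the statistical models the package implements, the
parameters that matter, what the synthetic-data generator does and does
not emulate, and the numerical choices made where the design was open.

## Expression scale and log-ratios

All expression values are log2 intensities. The per-gene "log-ratio" of a
tumor sample is its log2 value minus the arithmetic mean of the log2
values of the normal-reference samples (`to_log_ratios`). No
normalization is performed: inputs are assumed already normalized. Gene
identifiers are opaque strings; no probe/symbol mapping is attempted.

## Differential expression state calling

For each tumor grade, every gene is tested against the normal reference
with a two-sided unequal-variance (Welch) t-test on the raw log2 values.
Welch is the default because group sizes and variances differ between
tumor cohorts and references; an equal-variance option exists. P-values
are adjusted per grade across the full gene list by Benjamini–Hochberg
(a Storey-style variant with lambda = 0.5 is available). A gene is OVER
(UNDER) when q < `q_threshold` (default 10⁻⁴) and its mean log-ratio is
positive (negative); otherwise UNCHANGED.

Degenerate inputs: a gene constant across all samples is flagged and left
UNCHANGED with missing p; zero variance in both groups with unequal means
yields t = ±inf, p = 0 (flagged). Category enrichment is one-sided
hypergeometric (P(X ≥ k)) with the universe equal to all measured genes.
The grade trend is the Pearson correlation of per-grade DE counts with
numeric grade 1–4, two-sided p.

## Subtype classification

A sample is correlated with each centroid over the genes shared between
sample and centroid table (centroid order fixes the gene order). The
correlation p-value is one-sided for positive correlation via
t = r·√(n−2)/√(1−r²) with n−2 df; the assigned label is the subtype with
the greatest significant (p < `subtype_alpha`, default 0.05) positive r.
Exact ties in r go to the first subtype in centroid column order — a
reproducibility convention, not a claim about the original procedure.
Samples with no significant positive subtype are UNCLASSIFIED rather
than forced to the argmax. Generic profile–profile probes (e.g. a
hypermethylator signature, microglia/macrophage markers) reuse the same
Pearson machinery (`signature_correlation`, two-sided by default).

## Signature derivation

Six criteria compare a gene's PA I state with its states in AS II, AS III
and GBM IV: under/unchanged/overexpressed in PA I "but not in" the higher
grades, and the three reversed forms. The quantifier of "but not in A, B
or C" is linguistically ambiguous; the default (`mode="any"`) admits a
gene whose PA I state differs from at least one higher grade — the
disjunctive reading, whose union reduces to "PA I differs from ≥ 1 higher
grade". A strict mode (`mode="all"`, differs from all three) is provided.
The magnitude filter keeps genes with |mean PA I log-ratio − mean pooled
adult log-ratio| ≥ `lfc_threshold` (default 2 log2 units = 4-fold),
boundary inclusive. The defaults are documented choices, not assertions
about the original authors' intent.

## Regulatory network inference

Model: for each signature gene *i*, e_id = Σ_{j ∈ TF∖{i}} a_ji · e_jd,
with no intercept (log-ratios are approximately centered). Predictors are
standardized to mean 0 / sd 1 and the response centered before the
lasso/LAR path is computed (scikit-learn's `lars_path`, lasso mode, which
handles drops); knots are reported on the λ = max|Xᵀr| scale. The KKT
conditions are checkable at every knot (`check_kkt`, tolerance 1e-8).

Each predictor entering the path at knot λ_k receives the covariance-test
statistic T_k = (⟨y, Xβ(λ_{k+1})⟩ − ⟨y, X_A β̃_A(λ_{k+1})⟩)/σ², where A is
the active set just before entry and β̃_A the lasso solution restricted
to A at λ_{k+1}; p = exp(−T_k), the tail of the statistic's asymptotic
standard-exponential null. A predictor's p is taken at its first entry;
re-entries after drops are recorded but not re-scored.

σ² is the df-corrected residual variance of the full least-squares fit
when n > p + 1, else of a least-squares refit on the support selected by
a cross-validated lasso. Exactly-linear responses hit a 10⁻⁸ variance
floor with a warning so noiseless toys remain usable. These estimator
choices are this package's reconstruction — they are deliberate,
documented defaults rather than a published recipe.

Edges are predictors with p < `network_p_threshold` (default 5×10⁻⁵);
the reported coefficient a_ji comes from a no-intercept least-squares
refit on the selected set (the lasso estimate is shrunken); its sign
labels activator vs repressor. A sensitivity mode reports the
back-transformed path coefficient at entry instead. The possible-link
denominator is reported as |TF| × N including TF self-pairs (matching
the headline convention) with the self-excluded count logged alongside;
the fitted models themselves never include self-edges.

## Network analysis

Hub ranking sorts TFs by total out-degree (ties lexicographic); the TF
hierarchy lists TFs with strictly more than `threshold` (default 5)
outgoing links to other TFs. Predictive validation computes ê_id =
Σ_j a_ji e_jd on an independent cohort and summarizes per-gene Pearson r
(genes with ≥ 1 regulator) by the median and the fraction positive.

The expression-vs-mutation map categorizes TFs by their adult-minus-PA I
expression contrast and mutation log-ratio: CENTER when both magnitudes
are below `deviation_threshold` (default 1 log2 unit — "strongly
deviating" is otherwise unquantified), EXPR_ONLY / MUT_ONLY when exactly
one exceeds it, else CONCORDANT when the signs match the layer's expected
coupling (copy number: same sign; methylation: opposite sign, promoter
hypermethylation accompanying underexpression) and DISCORDANT otherwise.
The methylation anti-coupling is a naming convention for the categories,
not a biological claim about any particular gene.

## Synthetic cohorts

`simulate_cohort` plants, in documented draw order: per-gene baselines
N(7, 2²) log2 units (typical microarray dynamic range; irrelevant to all
log-ratio stages); a sparse TF×target coefficient matrix (default 20
TFs × 200 targets, density 0.02, |a_ji| uniform in [1, 3], random sign);
mirrored TF grade effects (PA I contrast ±U(1.5, 2.5), adult grades the
negation) plus per-tumor TF variability (sd 1.0 log2 units — a chosen
realistic tumor-to-tumor spread; nothing in the analysis pins it);
grade-specific background DE sets with counts (50, 100, 150, 300) rising
across grades and effect size 2.0; and measurement noise sd 0.5. Target
log-ratios are exactly coeffᵀ · TF log-ratios plus noise, so with zero
noise the regulatory layer reproduces the linear model identically.
Randomness is split into a structural stream (`seed`) and a sample-noise
stream (`sampling_seed`), so independent cohorts can share one planted
truth for cross-cohort validation.

The generator emulates the statistical structure the analysis assumes —
it does **not** emulate probe-level effects, batch structure, within-grade
biological subgroups, correlated noise, or copy-number segmentation. A
green recovery test therefore establishes that the pipeline recovers its
own generative model at realistic noise, not that it would recover
biology from a real cohort.

Synthetic centroids (`make_centroids`) are orthogonalized Gaussian
columns scaled to per-gene sd `separation` (default 1.0 log2 units);
orthogonality makes null correlations independent across subtypes, which
the classifier's null-calibration test exploits. Mutation layers couple a
random half of the TFs (methylation sign −1, copy number +1, strength
U(1, 2)); uncoupled TFs are pure noise.

## Known limitations

- The covariance test's Exp(1) null is asymptotic; at very small n or
  heavily correlated predictors the first-entry statistic can drift from
  mean 1 (the null suite checks n = 100, p = 10).
- The least-squares refit reports unbiased coefficients only for the
  selected support; post-selection inference beyond the covariance test
  is out of scope.
- The pipeline assumes one normal reference group; cohort-specific
  references (e.g. pediatric cerebellum vs adult cortex) must be handled
  by running the pipeline per cohort.
- Subtype calls depend on the shared-gene overlap with the centroid
  table; coverage is reported but no imputation is attempted.
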