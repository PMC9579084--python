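# Methods

This note documents the models, numerical choices and limitations of
the package; the README gives the user-facing overview.

## Semantic space

The space is classical LSA: a term–document count matrix over a
pre-lemmatized, whitespace-tokenized corpus; log-entropy weighting; a
truncated SVD keeping `k` dimensions; term vectors are rows of **U·S**
(the right singular vectors are discarded after training).

Weighting. Entry `(t,d)` becomes `log(1 + f_td) · g_t` with global
weight `g_t = 1 + Σ_d p_td log p_td / log n`, `p_td = f_td / Σ_d f_td`.
`g_t ∈ [0,1]`: 1 for a term confined to one document, 0 for a term
spread uniformly. Natural logarithms everywhere; the entropy ratio is
base-invariant and the local-weight scale cancels in cosines. A
single-document corpus is rejected (`log 1 = 0` in the denominator).

Vocabulary. Terms in fewer than `min_doc_freq = 2` documents are
dropped by default: a single-document term has global weight exactly 1
and can dominate a concept vector; the threshold is configurable.

Determinism. The sparse SVD is started from a seeded vector and each
singular vector's sign is fixed (largest-magnitude coordinate
positive), so a given matrix and `k` reproduce the space bit-for-bit.
When `k` reaches the matrix's small dimension a dense SVD is used.

Fold-in. A document is the bag-of-words sum of its terms' vectors;
out-of-vocabulary tokens are skipped and counted. Multiplying each term
by its global weight during fold-in is available behind a flag but off
by default, and document vectors are not length-normalized by default —
raw projections scale with document length, which is itself
informative for summary scoring (total scores correlate positively
with length on the synthetic summaries, matching what raw content
coverage should do). Unit normalization is a flag.

## Concept vectors and the meaningful basis

A concept vector is the unit-normalized sum of the term vectors of the
concept's lemmas. Normalization happens once, after summation, so
frequent/strong terms contribute proportionally to their vector length;
`prenormalize_terms` switches to equal-weight summation. The fragment
variant is the identical construction over the nouns of an
instructional-text fragment; a noun repeated in the fragment counts per
occurrence (multiset), with set semantics behind a flag. Out-of-
vocabulary lemmas warn and are dropped; strict mode errors. About three
descriptors per concept is treated as a lint guideline, not a
constraint.

The basis **β** holds the unit concept columns first, then standard-
basis fill columns drawn uniformly at random without replacement under
a seed. Orthogonalization is *modified* Gram–Schmidt (chosen for
numerical stability; the method itself fixes only the reliability
check, not the variant), strictly in column order so the meaningful
block retains maximal fidelity. A residual norm below 1e-10 raises,
naming the offending column, so the caller can re-seed the fill rather
than silently skip.

Fidelity is the uncentered correlation (cosine) between each meaningful
column before and after orthogonalization, gated at 0.80 (warn; error
in strict mode). The uncentered form is used deliberately: for the
high-dimensional, approximately mean-zero columns of a real basis it
coincides numerically with the Pearson correlation, but it remains
defined for columns with constant coordinates, where centering
degenerates (the two-dimensional worked case in the tests has exactly
this property).

The change of basis maps every term vector `v` to `βᵀv`. With an
orthonormal β this is a rotation; the implementation verifies
orthonormality to 1e-10 on entry and the tests assert cosine
preservation to 1e-8.

## Bifactor general dimension

Each concept's usable lemmas are split into two balanced random subsets
(seeded; a concept with a single usable lemma falls back to duplication
with a warning, or errors in strict mode). Each subset becomes a unit
vector; a one-factor minimum-residual factor analysis of the subset
vectors — variables are the `2k` subsets, observations the `p` space
coordinates — yields loadings, and the general vector is the normalized
loadings-weighted sum of the subset vectors (raw loadings; the
normalization is applied only to the final vector). Heywood-type
solutions (|loading| > 1) and all-zero solutions raise with
diagnostics.

Column order is genuinely open: the after-the-concepts layout keeps the
concept dimensions identical to the classic method and residualizes
only G, while placing G first residualizes every concept against shared
meaning, which is what bifactor semantics ask of specific factors. Both
are exposed; `after_concepts` is the default layout, and the
distillation analyses in the tests and the acceptance script use
`general_first`, since with `after_concepts` the concept scores are
unchanged by construction and no distillation can occur.

Known limitation: the general vector is a weighted sum of subset
vectors built from the same descriptors as the concepts, so it lies
close to the concept span. Orthogonalizing six nearly dependent
meaningful columns leaves little residual for whichever column comes
last, and its fidelity can fall far below 0.80 — the gate flags exactly
this. On the synthetic fixture the last concept under `general_first`
typically fails the gate while the distillation effect (lower
concept-score intercorrelation than classic) still holds.

## Scoring

A scored document's leading `k` (+1 with a general dimension)
coordinates are its concept scores, written as `score__<concept>` /
`score__G`. Raw coordinates may be negative and are not floored or
rescaled; downstream statistics consume them as-is. Rows with more than
50% out-of-vocabulary tokens (configurable) are flagged unreliable, not
dropped. The pipeline (`run_pipeline`) validates its config with
field-path error messages and writes deterministic artifacts: fixed
float formats, sorted JSON keys, no timestamps, and a provenance record
keyed by a hash of the scientific configuration (the output directory
is excluded).

## Psychometric battery

ICC. Two-way mixed-effects intraclass correlations from ANOVA mean
squares; all four forms (single/average × consistency/agreement) are
implemented and the variant is recorded in the result. The default is
single-measure consistency. Rows with missing cells are removed
listwise with a logged count. The tests cross-check every form against
an independent scalar-loop ANOVA oracle and against `pingouin`.

Paired contrasts. `scipy` paired t plus Cohen's d; d defaults to the
mean difference over the SD of differences (d_z), with the pooled-SD
form behind a flag. Identical samples return t = 0, d = 0; a constant
nonzero difference has no finite t and raises.

Parallel analysis. Principal-component eigenvalues of the correlation
matrix and common-factor eigenvalues of the SMC-reduced matrix are
compared position-by-position against the chosen percentile (default
95) of eigenvalues from seeded standard-normal data of identical shape;
retention stops at the first non-exceeding eigenvalue.

EFA. Maximum-likelihood extraction profiles the likelihood over
uniquenesses (bounded in [0.005, 1]; bound-hitting solutions are
flagged as Heywood cases); minres extraction is available and is what
the general-vector estimate uses. Rotation is oblimin in its quartimin
form via oblique gradient projection. Chi-square uses the Bartlett
correction; RMSEA confidence bounds invert the noncentral chi-square;
TLI is computed against the no-correlation null; factor scores use the
regression (Thomson) method. Columns are sign- and order-standardized
for determinism.

Regression. Standardized βs are OLS on z-scored variables
(statsmodels); exact collinearity errors name the offending columns and
an ill-conditioned design (condition number > 1e8) is rejected. No
multiple-testing correction is applied; raw p-values are reported.

CFA/SEM. A RAM-parameterized covariance-structure engine: directed
paths (loadings, regressions) in A, variances/covariances in S,
`Σ = F(I−A)⁻¹S(I−A)⁻ᵀFᵀ`, fitted by unweighted least squares
(`F_ULS = ½·tr[(S−Σ)²]`, analytic gradient, L-BFGS-B with variance
floors). Identification fixes each factor's first loading to 1.
Exogenous variables covary freely by default; covariances can be
freed or pinned explicitly (the bifactor models pin all human-factor
correlations to zero). ULS has no native chi-square: the reported
chi-square is `(N−1)·tr[(S−Σ)²]`, a documented convention, with CFI,
TLI and RMSEA (plus a noncentral 90% CI) formed against the
independence baseline under the same estimator, and SRMR from
standardized residuals. Standard errors are curvature-based
approximations from the discrepancy Hessian, not sandwich estimates —
use them for rough inference only. ULS is not scale-invariant, so the
cross-loading models z-score the observed variables first (projection
scores run three orders of magnitude above 0–2 ratings).

The classic cross-loading model regresses each human concept factor
(one indicator per rater) on every computational concept predictor and
frees the disturbance covariances among the human factors — raters
share variance the computational scores cannot explain, and forcing
those covariances to zero funnels it through the structural paths as a
suppression pattern. The bifactor form gives the human ratings a
general factor over all indicators plus per-concept specific factors,
all factor correlations fixed to zero, specific factors regressed on
the concept scores and the general factor on the observed general
score(s); with several general indicators their covariance is
estimated. The largest-|standardized| structural path per human factor
is flagged as its convergent path.

## Synthetic data generator

The generator emulates the study conditions end to end and is the test
surface for everything else.

Corpus: `n_topics` disjoint topic vocabularies (40 words each by
default) with a mild power-law word profile (exponent 0.8). Each
document belongs to one topic but is a *mixture dominated by that
topic*: tokens come from a random other topic with probability
`topic_mixing = 0.10` and from a shared pool with probability
`shared_vocab_fraction` (0 by default; 0.2 in the bifactor analyses).
The mixing term matters: with pure single-topic documents, cross-topic
term vectors are exactly orthogonal, the concept subset vectors
correlate as isolated pairs, and no common variance exists for a
general factor to summarize.

Summaries: coverage weights are `quality × shares`, with per-summary
quality ~ Beta(2,2) scaling all concepts and shares ~ Dirichlet(α = 2);
the remainder of each summary is off-topic noise drawn from the whole
vocabulary (rate 0.10). The quality factor plants the positive manifold
real summary ratings exhibit (stronger students cover more of
everything); a pure Dirichlet would make concept coverages negatively
correlated and a bifactor description of the ratings misspecified.

Raters: per concept, true coverage is rank-normalized to a latent
standard-normal score; each rater observes a correlated noisy copy and
bins it into `scale_max + 1` equal-probability categories (default
0–2). The pre-discretization correlation needed to hit a target
reliability is solved numerically from bivariate-normal cell
probabilities (Brent's method on the discretized correlation); a linear
attenuation approximation cannot reach reliabilities near 0.8 on a
3-point scale, where discretization caps the linearized correlation at
about 0.79. Reliability 1 means no noise and identical rater columns.

What the fixture does *not* emulate: natural-language syntax and
discourse, Zipfian vocabulary growth at realistic scale, polysemy,
rater drift or systematic leniency, and concept structures that overlap
lexically. Passing tests show the pipeline recovers planted structure
under these idealized conditions; they do not certify performance on
real corpora.

## Problem sizes

The test suite and `scripts/acceptance.py` use a desk-scale standard
study — 5 topics × 200 training documents, 200 summaries, 50 retained
dimensions, 2 raters at reliability 0.8, 20 seeded replications for the
recovery and distillation checks — chosen so the planted structure is
comfortably identified while a full run stays in the tens of seconds.

## Named tolerances

Gram–Schmidt orthonormality 1e-10; degeneracy 1e-10; rotation
invariance 1e-8; general-vector collinearity |cos| > 0.999; fidelity
gate 0.80; variance floor 1e-6 in all covariance-structure fits. All
live in `inbuilt_rubric/config.py`.
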