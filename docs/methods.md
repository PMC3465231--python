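# Methods

## Model

Each target gene *g* is modeled by a first-order lag-linear regression: the
expected expression at time *t* is an affine combination of the expression
of its regulators at *t − 1*, pooled over all samples and transitions
(`N = (T − 1) · S` observations). Steady-state data use the same model with
the time subscript removed; in that mode a gene is excluded from its own
candidate set, while in lag mode time-lagged autoregulation is allowed and
flagged when selected.

Model uncertainty is handled by Bayesian model averaging. A candidate model
is a regulator subset; its integrated likelihood is approximated through
the Gaussian-regression BIC with the error variance profiled out,

    BIC = N ln(RSS/N) + (k + 1) ln N,

where *k* counts regulators and the +1 the intercept (additive constants
cancel in posterior odds). The model prior is a product of independent
inclusion probabilities π_gr over the reference candidate set, the
posterior model probability is proportional to `exp(−BIC/2 + log prior)`,
Occam's window discards models whose posterior odds against the best model
fall below 1/OR (OR = 20, survivors renormalized, cutoff inclusive), and
the posterior inclusion probability of a regulator is the summed posterior
mass of retained models containing it.

## Exact best-subset search

`best_subset_search` returns, for every model size 0..max_size, the `nbest`
subsets with smallest RSS. It is a depth-first branch and bound on the
centered Gram matrix: including a variable performs a rank-one sweep
(O(pool²)), and a subtree is pruned when the RSS of its subset joined with
its entire remaining pool — a valid lower bound, since adding variables
never increases RSS — cannot beat the current nbest thresholds at any
reachable size. A cheap necessary condition (sum of marginal reductions)
gates the exact bound computation. Candidates are visited in order of
decreasing marginal RSS reduction, which maximizes pruning; the hot loop is
JIT-compiled (numba) and subsets are tracked as bitmasks, limiting a single
search to 62 candidates (windows are 30 by default). Near-exact RSS ties at
the nbest boundary are broken deterministically by bitmask in the internal
ordering. Collinear subsets are singular: the offending pivot is detected
at relative tolerance 1e−9, the model is skipped, and (since every superset
inherits the collinearity) the subtree is abandoned. Search output equals
exhaustive enumeration; the test suite verifies this against an
independent per-subset least-squares oracle on 20 seeded instances up to
q = 12 and checks the downstream inclusion probabilities against a
brute-force sum over the full model space.

## The iterative engine

Per target gene: rank all candidates (by π_gr for `prior`/`shortlist`, by
univariate lag-regression R² for `size`/`noprior`); shortlist the top
p = 100; fill a window with the top w = 30; search, weight models with
priors computed relative to the window, apply Occam's window; archive every
retained model (keyed by member set; on re-encounter the lower BIC is kept
and a discrepancy beyond 1e−6 is logged, as BICs should be identical);
drop window candidates with inclusion < 5% and refill from the shortlist;
if nothing falls below the threshold, the single lowest-inclusion candidate
is forced out (a stall guard that bounds the loop at p iterations). When
the shortlist is exhausted, all archived models are re-weighted with priors
computed relative to the full shortlist (candidates absent from a model
contribute explicit 1 − π factors), Occam's window is applied to the
cumulative archive, and edges are called at inclusion ≥ 50%.

Per-variant prior inclusion vectors: `prior` → π_gr; `size` → the constant
network density τ (default 2.76/6000 ≈ 0.00046), turning the prior into a
pure size penalty; `shortlist`/`noprior` → 0.5, i.e. a flat prior over
models. Genes are processed independently, so results do not depend on
scheduling; identical configuration and seed reproduce the edge list
exactly.

Numerical guards: RSS is floored at 1e−12 before logarithms (perfect fits
on noise-free data stay finite); π is clipped to [1e−10, 1 − 1e−10] so that
a prior of 0/1 still effectively forces a candidate out/in with finite
log-space arithmetic. The per-model size cap defaults to min(10, N − 2)
and is configurable.

## Supervised prior construction

Training examples are labeled TF–gene pairs with per-pair features; the
ChIP feature may be missing (p-value-style evidence is undefined for many
pairs). Missing ChIP values are multiply imputed (20 copies by default) by
drawing with replacement from the observed values of the same label class.
Feature values outside the training range are truncated to the training
extremes — documented behaviour for the upper tail, symmetric by default
for the lower tail and switchable off. Per imputed copy, all 2^F feature
subsets (F ≤ 15; exhaustive enumeration, since leaps-style bounds do not
apply to logistic likelihoods) are fit by maximum likelihood (L-BFGS on the
exact log-likelihood with analytic gradient), weighted by exp(−BIC/2) and
passed through Occam's window (OR = 20). Subsets showing separation
(non-convergence or |β| > 30) are refit with a small ridge penalty (1e−6)
and flagged. Predictions average the BMA probability across imputations —
the standard multiple-imputation predictive rule, which avoids the
non-collapsibility of averaging logistic coefficients.

Because positives are enormously over-sampled relative to a sparse network,
predicted odds are divided by the sampling-rate ratio

    π₁/π₀, π₁ = n_pos/(G · m̄), π₀ = n_neg/(G · (G − m̄)),

with G genes and m̄ mean regulators per gene; m̄ = 1/(1 − e^(−λ)) ≈ 2.76
under the empirical exponential in-degree law with decay λ = 0.45. For
583/444 training pairs over 6000 genes this gives π₁ = 3.52%,
π₀ = 0.0012%, ratio ≈ 2853: a raw prediction of 0.9 (odds 9) becomes odds
9/2853 ≈ 0.00315, i.e. a probability of ≈ 0.0031 — the correction, not the
evidence, dominates the prior scale. Pairs missing ChIP evidence at
prediction time are imputed unconditionally from the training empirical
distribution (their label is unknown).

## Simulation benchmark

The generator emulates the study design the method targets: 97 samples
(95 segregants plus two parents) over six time points, with defaults at the
full 3556-gene scale. Per regulated gene the in-degree is truncated
geometric (`p(m) ∝ e^(−λm)`, m ≥ 1, λ = 0.45; a configurable fraction of
genes may be unregulated, default 0); regulators are uniform without
replacement excluding self. Coefficients have uniform magnitude in
[0.2, 1] with random sign — large enough to matter, small enough that a
sparse random matrix is near-stable — and if a power-iteration estimate of
the spectral radius exceeds 0.95 all coefficients are rescaled, keeping the
five-step recursion bounded. Intercepts are N(0, 0.25²); noise standard
deviations are uniform in [0.5, 1.5] × noise_scale (default 0.5), giving
signal-to-noise in the range where the N ≈ 485-observation regressions are
informative but not trivial. Initial conditions default to independent
standard normals, standing in for observed baseline measurements.

External evidence is generated per ordered non-self pair: continuous
co-expression / polymorphism / GO scores whose means shift upward on true
edges in proportion to an informativeness parameter (default 0.8), a rare
curated-indicator enriched on true edges, and an exponential ChIP score
inflated on true edges and set missing at rate 0.09. The training sample
draws 583 positives from true edges and 444 negatives from non-edges
(either among all pairs or restricted to pairs whose regulator has targets,
both schemes exposed).

What the generator does *not* emulate: the correlation structure of real
expression (population genetic structure, batch effects), network motifs
beyond random wiring, heavy-tailed measurement noise, or realistically
weak and redundant external evidence. Recovery rates on this benchmark are
therefore upper bounds on real-data behaviour; what the benchmark does
establish is the *ordering* of the engine variants under identical data.

## Benchmark problem sizes

The recovery study in the test suite runs 300 genes × 97 samples × 6 time
points for five seeds and three variants (`prior`, `shortlist`,
`noprior`), with the per-model size cap set to 5 regulators — comfortably
above the 2.76 mean in-degree (≈ 90% of regulated genes have ≤ 5
regulators) while keeping the exact subset search fast. Mean TPR against
the generating network is strictly ordered prior > shortlist > noprior in
every seed.

## Design choices where the design was open

* The model prior enters after the likelihood-driven subset search (the
  search ranks by RSS only); the prior is always included in the posterior
  odds used by Occam's window.
* Cycle removal for static networks deletes the minimum-probability edge
  per nontrivial strongly connected component and iterates to a fixed
  point; enumerating individual cycles is exponential, and each deletion
  strictly shrinks some component, guaranteeing termination and acyclicity.
  Ties break on (regulator, target) ids.
* Edge thresholding is inclusive (≥).
* The contingency universe is configurable (all ordered pairs, or
  restricted to reference regulators) and reports name the universe used;
  the Fisher test for TF target-set enrichment is one-sided (enrichment),
  and the chi-square is plain Pearson without continuity correction.

## Known limitations

* Non-uniform time intervals are not interpolated; time points are assumed
  equally spaced.
* A single subset search handles at most 62 candidates (bitmask subsets);
  the iterative window makes this irrelevant in practice.
* The supervised stage assumes ≤ 15 features (exhaustive subset
  enumeration) and only the ChIP feature may be missing.
* Dense networks (spectral radius near 1 with strong coefficients) are
  rescaled rather than rejected, which shrinks all true effects.
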