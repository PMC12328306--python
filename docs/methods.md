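# Methods

## Overview

`onidsc` infers a directed gene regulatory network from single-cell
expression of a population traversing a biological process.  The chain is:
log-normalization → gene filtering → marker-sum pseudotime → per-gene
cross-validated penalty selection → kernel-smoothed lagged lasso Granger
regression over an ensemble of hyperparameter instances → Borda rank
aggregation → precision/recall evaluation → cross-subject comparison.
This note records the model assumptions, the parameters that matter, the
numerical choices, and what the synthetic test substrate does and does not
establish.

## Normalization and filtering

Expression values are mapped to ln(x+1) (natural log by default,
configurable base).  The transform is required before pseudotime and
regression stages; applying it twice is an error rather than a silent
no-op.  Genes are removed when they have fewer than 4 nonzero values,
constant expression (standardization would divide by a zero standard
deviation), or fewer than 5 distinct values (the response-side requirement
of 10-fold cross-validation).  Filtering is idempotent and reports each
dropped gene with the rule that triggered it.

## Pseudotime

The ordering is supervised: the per-cell score is the sum of normalized
expression over a marker panel chosen to represent the process (for immune
activation, interferon-stimulated genes), and cells are sorted ascending by
that score.  Assumption: the summed marker signal increases monotonically
along the process.  Direction is a convention — a `descending` flag inverts
it (pseudotime values are then negated sums so they still increase along
the order).  Ties are broken by cell identifier, making the order total and
deterministic.  The pseudotime values passed downstream are the raw sums by
default; `rank_time()` replaces them by ranks 1..n (uniform spacing), which
is the sensible companion to integer Δt settings.  Marker genes missing
from the matrix are skipped with a warning; an empty panel is an error.

Cell typing before ordering is rule-based: per-type cell-id sets plus an
ordered list of pairwise exclusion rules (`both`/`a`/`b` sides of each
intersection removed), with every removal logged.

## Penalty optimization

For each gene g, the response is g's expression over cells and the
predictors are all other genes; the elastic-net objective with α = 1 (pure
lasso) is solved by cyclical coordinate descent.  The implementation works
on centered, optionally variance-scaled predictors with precomputed Gram
products, so one coordinate update costs O(p) independent of N, and zero
coordinates are free — with warm starts along the path this makes a
100-point path scan cheap.  Convergence is declared when the largest
coefficient change in a full cycle falls below `tol` (default 1e-7);
non-convergence raises an error carrying the last iterate.  Zero-variance
predictors get coefficient 0.  The recorded objective (and the
monotonicity guarantee) refers to the internal centered/standardized
problem; for `standardize=False` that is exactly the original objective.

The path runs geometrically from λ_max = max_j |(1/N) Σ w_i x_ij (y_i −
ȳ)| (on the standardized predictors) down to λ_max·ratio, ratio 1e-4 when
N > p else 1e-2, 100 points by default.  10-fold cross-validation assigns
folds by a seeded shuffle; `lambda_min` minimizes mean held-out MSE
(largest λ on ties, since the grid is scanned in descending order) and
`lambda_1se` is the largest λ within one standard error (sd/√k) of that
minimum.  "Optimal minimum and maximum lambda" per gene are read as
`lambda_min` and `lambda_1se`, the standard convention of the CV procedure
this stage follows; the reading is isolated in one function so an
alternative (e.g. literal grid extremes of an acceptable-MSE band) can be
swapped in.

Every gene's CV runs on **one shared grid** — the path of the gene with the
largest λ_max — because the mode of a continuous quantity is ill-defined;
restriction to a shared grid makes "most frequent minimum/maximum" an
exact count.  Mode ties break toward the smaller value for the minimum and
the larger for the maximum.  Per-gene fold seeds derive from (global seed,
gene index), so the scan is reproducible and independent of iteration
order.  A single common penalty across data subsets is the modal
`lambda_min` candidate with the highest pooled gene count, ties broken by
lower pooled median MSE, then by the smaller λ.

## Network inference

Lagged features are built by Gaussian kernel smoothing on the irregular
pseudotime grid: for target observation time tᵢ and lag ℓ, the feature is
the kernel-weighted average of the regulator's samples centered at
tᵢ − ℓ·Δt, restricted to samples **strictly before tᵢ**.  Strict past was
chosen over inclusive or two-sided windows to preserve the causal
direction of the test.  Rows whose features are undefined (no past sample)
are dropped; targets with fewer than L+2 usable rows are skipped with a
warning.  When all kernel weights underflow (σ far below the sampling
gap), the nearest past sample is used — the delta-kernel limit.  Features
are scale-covariant: multiplying all pseudotimes, Δt and σ by one constant
changes nothing.

The target's own lags are included as covariates and discarded from the
output, so reported regulators carry predictive power beyond the target's
autoregression.  The design is standardized and solved at the single
optimized λ; the edge weight is Σ_ℓ |β| over the regulator's lags —
summing aggregates evidence across lags (the max over lags is a one-line
swap).  Constant-response targets yield no incoming edges.

Dropout handling: each zero-valued sample (and its pseudotime) is removed
with probability p_z (default 0.2) per gene before smoothing; only
zero-handling code 0 (nothing beyond this removal) is implemented, other
codes are rejected explicitly.  Technical replicas (default 8) repeat
inference with independent removal draws.  RNG streams are keyed by the
instance's *content* — (seed, Δt, L, σ, replica, gene index) — not by its
position in the ensemble list, so results are invariant to the order in
which hyperparameter combinations are specified and to execution
scheduling (parallel target fits via joblib give identical results for any
worker count).

Each instance's nonzero weights are ranked descending (ties take the mean
of tied positions) and aggregated by a modified Borda count: an edge
scores Σ 1/rank over the instances where it appears, 0 where absent —
1/rank was chosen because it handles unequal-length instance lists
gracefully; the scheme is isolated in `borda_aggregate` for substitution.
Per-edge contributions are summed with `math.fsum`, so aggregate scores
are exactly independent of instance order.  The final list is sorted by
score with lexicographic tie-breaks and dense ranks 1..m.

## Evaluation

The evaluable universe is all ordered non-self pairs over the evaluable
genes (closed world: pairs absent from the gold standard are negatives).
Predictions and gold edges outside the universe are excluded
symmetrically.  The cumulative curve gives precision tp/k and recall tp/P
at every cutoff; average precision sums precision at each
positive-gaining rank divided by P; early metrics are the curve values at
the smallest cutoff reaching a partial recall threshold (0.1–0.5
typical), with accuracy (tp+tn)/M counted over the full universe.  An
unreachable threshold reports the final rank with a warning rather than
erroring.  The default accuracy cutoff is k = P (the gold-standard size),
configurable.  The random control samples edges uniformly without
replacement with a random ranking; replicate comparisons use Welch's
unequal-variance t-test on average precision.

Note that the average precision of a uniformly random ranking is *not* the
prevalence P/M at small M — it has a positive bias (≈0.36 vs 0.25 at
M=20, P=5).  The test suite checks random-ranking AP against the exact
combinatorial expectation (average over all C(M,P) positive-position
sets), and checks random-control *precision* against prevalence.

## Cross-subset comparison

Per-subject networks (top edges of each ranked list; default all nonzero)
are compared by support counting: edges in ≥ τ subjects form the shared
network.  The variable threshold scans τ from the number of subjects down
to 1 and returns the largest τ whose shared gene count (distinct
regulators ∪ targets) lands in a target band (default 60–105); when two τ
qualify the larger (more stringent) wins, and when none does the closest
count above the lower bound is used with a logged warning.

## Synthetic data

The generator emulates exactly the structure the method exploits: cells at
integer pseudotimes 1..n; background genes as half-normal |N(0,1)| noise;
markers strictly increasing in pseudotime (distinct slopes per marker)
plus N(0, noise_sd) jitter; planted edges making each target the lagged
linear combination of its regulators plus noise (exact when noise_sd = 0);
values clipped at 0; independent dropout zeroing.  Defaults — 300 cells,
10 genes, coefficient ~0.8–0.9 at lag 1, noise sd 0.05, dropout off unless
exercised — represent a small, clean benchmark where ground truth is
unambiguous.

What passing tests on this substrate shows: the solver, CV, smoothing,
aggregation and metrics are correct, and the pipeline recovers planted
lagged structure well above the random baseline while staying calibrated
on null data.  What it does not show: performance on real scRNA-seq with
library-size variation, batch effects, branching trajectories,
non-monotone markers, or indirect/confounded regulation — none of which
the generator models.  One realistic sensitivity does appear even here:
local errors in a marker-derived ordering (rank correlation ≈0.996)
noticeably degrade recovery of weaker one-step-lag edges, since lag-based
Granger features depend on fine-grained order.

## Problem sizes and runtime choices

The validation suite and `scripts/acceptance.py` use deliberately small
problem sizes — 10–20 genes, 120–300 cells, 8 replicas, 50–100 point
lambda paths, 10 seeds per stochastic claim — chosen so the full
validation runs in about a minute on one CPU while keeping each check
statistically meaningful (recovery claims use ≥8/10-seed criteria and
3-standard-error separations).  Real datasets in the hundreds of genes and
thousands of cells are handled by the same code; cost grows roughly as
(genes² × lags) per instance for the design construction and per-gene CV
cost times genes for the lambda scan.

## Known limitations

* Single linear trajectory only; branching topologies need a different
  ordering strategy.
* The Borda variant (Σ 1/rank) and the strict-past kernel support are
  normative definitions of this package, chosen and documented where the
  underlying methods literature leaves the detail open.
* Per-network truncation before cross-subject counting defaults to "all
  nonzero edges"; with very dense networks a `top_edges` cutoff matters
  and must be chosen by the user.
* The common-lambda procedure assumes subsets share a comparable
  expression scale; it does not harmonize scales across subjects.
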