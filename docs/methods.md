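# Methods

## Model

Observed ordinal item `j` with `K_j` categories is assumed to arise from a
latent variable `z_j` with a standard normal margin, cut at ordered
thresholds `τ_j1 < … < τ_j,K_j−1`.  The latent vector `z` is multivariate
normal with correlation matrix `Σ = Ω⁻¹` (rescaled to unit variances);
the object of inference is the partial-correlation network

    w_ij = −ω_ij / sqrt(ω_ii ω_jj),

i.e. the conditional association of items i and j given all others.  An
absent edge means conditional independence under the joint normal.

## Estimation

**Thresholds and latent correlations (two-step).**  Thresholds are the
standard-normal quantiles of the cumulative category proportions.  With
thresholds fixed, each pairwise correlation maximises the bivariate
likelihood: contingency-cell probabilities are rectangle probabilities of
the bivariate normal (polychoric/tetrachoric), or conditional normal CDF
differences when one margin is continuous (polyserial).  Two-step rather
than full joint ML is deliberate: it is the convention of the R estimation
stack used throughout the applied psychometric-network literature, so
results are comparable with published analyses.  Rectangle probabilities
use Owen's T function (absolute error far below 1e−8); the correlation is
found by bounded scalar minimisation with tolerance 1e−6 on ρ ∈
[−0.999, 0.999].  Pairs are estimated on pairwise-complete observations by
default; a matrix assembled pairwise can be indefinite and is then
repaired by clipping eigenvalues at 1e−6 and rescaling to unit diagonal
(flagged in the result).  Pairs with fewer than 10 complete cases are
refused — below that the polychoric likelihood is too flat to be useful.

**Graphical lasso.**  The precision matrix solves

    min_Θ  tr(RΘ) − log det Θ + λ Σ_{i≠j} |θ_ij|,   Θ ≻ 0,

with the penalty on off-diagonals only.  The solver is proximal gradient
descent over the positive-definite cone: a gradient step on the smooth
part (gradient `R − Θ⁻¹`), soft-thresholding of the off-diagonals,
Barzilai–Borwein step lengths safeguarded by backtracking (halving until
the iterate is PD and a quadratic upper bound holds).  Convergence is
declared when the largest parameter change falls below `convergence_tol`
(default 1e−7).  This solver was chosen over an off-the-shelf coordinate-
descent implementation because it converges reliably at tight tolerances
and is roughly 60× faster over a warm-started penalty path, which the
bootstrap and permutation loops re-run thousands of times; tests verify it
against both direct numerical optimisation of the objective and an
independent coordinate-descent implementation.  λ = 0 is computed by
direct inversion.

**Penalty selection.**  The path runs from `λ_max = max_{i<j} |r_ij|`
(empty model) down to `λ_max/100`, log-spaced, 100 points by default, each
fit warm-started from the previous.  Models are scored by

    EBIC = −2L + E log n + 4 E γ log p,   L = (n/2)(log det Θ − tr(RΘ)),

with `E` the number of nonzero off-diagonal pairs.  Defaults γ = 0.5,
100 λ's, ratio 0.01 are the standard conservative settings of the
psychometric toolchain; ties break toward the sparser (larger-λ) model.
Under pairwise-complete estimation the scalar `n` is the number of rows
with any observation at that wave (a mean-pairwise-n alternative is
exposed).  Note that EBIC-glasso is not support-selection-consistent:
on synthetic data small spurious edges (|w| < 0.06) appear at rates that
vary with the graph draw even at n = 5000, while edge-*weight* recovery
correlates ≥ 0.99 with truth.  Analyses should interpret small edges
through the bootstrap CIs, not as certain discoveries.

## Centrality

Strength `s_i = Σ_j |w_ij|`; betweenness and closeness use edge lengths
`1/|w_ij|` (strong association = short distance; negative edges enter by
magnitude — the standard convention, stated here because different choices
change rankings).  Betweenness counts ordered source–target pairs with
fractional credit across tied shortest paths (Brandes).  Closeness is
`1/Σ_j d(i,j)`; on a disconnected network the sum runs over the reachable
set and is scaled by `reachable/(p−1)` so isolated regions get finite,
comparable values.  z-standardisation is across the nodes of one network
(denominator n−1), covariate nodes included by default so all nodes share
one axis; exact-constant metrics map to z = 0.

## Robustness

Nonparametric bootstrap (subjects resampled with replacement, default
1000 replicates, replicate b seeded `seed + b` so runs are resumable and
worker-count-independent) re-runs the entire correlation + EBIC-glasso
pipeline and summarises each edge as its 2.5%/97.5% replicate quantiles;
under regularisation the point estimate can fall outside the resampled
interval, which is flagged rather than forbidden.  Replicate failures are
skipped and counted; more than 10% aborts.

Case-dropping stability re-estimates on subsets retaining 90% … 25% of
subjects (default grid, step 0.05) and correlates subset centralities with
the full-sample values across nodes (product-moment by default).  The CS
coefficient is the largest drop proportion at which ≥ 95% of replicates
correlate ≥ 0.7; 0.25/0.5 are the conventional moderate/strong readings.
The (0.7, 0.95) pair is the tutorial convention; both are configurable.

Difference tests reuse the same replicate store (edges and node strengths
are saved per replicate): a pair "differs" when the 95% bootstrap interval
of the replicate-wise difference excludes zero, with no multiplicity
correction — deliberately matching the applied convention, so the outputs
are read as descriptive.

## Paired network comparison

For two waves measured on the same subjects (complete cases only), the
test statistics are `M = max_{i<j} |w^A_ij − w^B_ij|` (structure
invariance) and `S = |GS_A − GS_B|` (global-strength invariance).  The
null is simulated by the standard paired scheme: each permutation swaps,
per subject with probability 1/2, the subject's two observation vectors
between occasions, and both networks are re-estimated with the identical
pipeline configuration.  p-values use `(1 + #{perm ≥ obs})/(1 + n_perm)`,
so they are never exactly zero.  Failed permutations are redrawn (> 10%
aborts).  The per-subject coin-flip is symmetric in the two occasions, so
exchanging the roles of A and B leaves statistics and p-values unchanged
with the same seed.

Descriptive similarity complements the test: Spearman (default) or
Pearson correlation of the lower-triangle edge vectors — zeros included,
because a regularised network's zeros are estimates, and excluding them
would condition on the selected support — and correlation of per-node
centrality vectors (Pearson default, Spearman available).

## Synthetic-data generator

`make_true_network` draws Bernoulli(edge_prob) edges with uniform weights
on `weight_range`, sets `Ω = I − W`, loads the diagonal until the minimum
eigenvalue reaches 0.05, and rescales to unit partial variances — PD is
guaranteed while the support (and signs) of the partial correlations are
preserved.  Items default to 4 categories with shared cut points (−1, 0, 1);
one threshold vector per item is shared across waves.  The longitudinal
sampler gives each subject a latent trait `u ~ N(0, I)`; wave t draws
`L_t(√c·u + √(1−c)·e_t)` so each wave keeps its own marginal network while
items correlate across waves at ≈ c (default 0.5).  Missingness is MCAR at
the (subject, wave) level — the mechanism is an assumption, as applied
datasets rarely document theirs — with default rate 0.135 per wave, which
leaves ≈ 56% of a 306-subject, 4-wave design as complete cases, the
shape of the motivating study design.

What the generator does *not* emulate: item-specific marginal
distributions (real symptom items are skewed, with item-varying
thresholds), intervention effects on the latent process, non-MCAR
dropout, and measurement error beyond discretisation.  Passing recovery
tests therefore demonstrate estimator correctness under the latent-normal
model, not robustness to violations of it.

## Problem sizes used in tests and the acceptance script

Oracle equivalences run on p = 2–3 instances (direct optimisation), 2×2
tables (likelihood grid search), and 6-node graphs (exhaustive path
enumeration).  Parameter recovery uses p = 10, n = 2000 (criterion) and
n = 5000 (spurious-edge behaviour).  The permutation test's type-I error
is calibrated with 40 independent studies of n = 300 subjects, p = 8
items, 50 permutations each, a 10-point penalty path and solver tolerance
1e−5 inside the loop — re-estimating ~4000 networks; the rejection rate
at nominal α = 0.05 is compared by exact binomial test against the
discrete effective level `⌊0.05·51⌋/51 ≈ 0.039` implied by 50
permutations.  These sizes are the package's chosen trade-off between
statistical resolution and runtime; the binomial comparison adapts
automatically if the replicate count is changed.

## Known limitations

* Two-step (not full-information ML) polychoric estimation; no weighted or
  robust correlation variants.
* EBIC-glasso edge selection admits small false-positive edges (see
  above); support recovery is approximate even at large n.
* Betweenness and closeness on resampled regularised networks are
  unstable by nature (shortest paths flip under small weight changes);
  strength is the metric the stability machinery is designed around.
* The dependent comparison test assumes complete cases and exchangeability
  of occasions within subject under the null; it does not adjust for
  covariate shifts between occasions.
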