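# Methods

## Model and estimation pipeline

The pipeline estimates a Gaussian graphical model for ordinal survey data
in three stages.

**Polychoric correlation.** Each pair of items is modelled as a
discretized bivariate normal. Estimation is two-step ML: thresholds are
fixed at inverse-normal cumulative marginal proportions (step 1), then the
latent correlation ρ maximizes the multinomial log-likelihood
Σ n_ij log P_ij(ρ, τ_x, τ_y) of the contingency table (step 2), where P_ij
are bivariate-normal rectangle probabilities. Two-step rather than full
joint ML: it is the standard practice for this estimator, far cheaper, and
the difference is negligible at the sample sizes involved (thousands of
rows). The 1-D search uses bounded Brent minimization on (−0.999, 0.999)
with xatol 1e−7; the likelihood is unimodal in practice. Rectangle
probabilities come from the identity
Φ₂(x, y; ρ) = Φ(x)Φ(y) + ∫₀^ρ φ₂(x, y; r) dr evaluated by 48-node
Gauss–Legendre quadrature, vectorized over the threshold grid; against
scipy's bivariate normal CDF the error is below 1e−8 for |ρ| ≤ 0.99.
Estimates with |ρ| ≥ 0.99 carry a `boundary` flag. A table whose margins
collapse to one category cannot identify ρ and is returned as ρ = 0 with
`converged=False` and the boundary flag set; at the matrix level an item
with fewer than two observed categories raises an error naming the item.
Empty categories are dropped before threshold placement (they contribute
no likelihood). Missing responses are handled by pairwise deletion, and
the missing-cell count is logged — the expected use case is complete
baseline questionnaires, so this path is a permissive default rather than
a studied design.

The assembled pairwise matrix need not be positive semidefinite. Repair is
by eigenvalue clipping at 1e−6 followed by re-standardization to unit
diagonal, with a flag and the pre-repair minimum eigenvalue kept for
audit. Clipping rather than a full nearest-correlation iteration (Higham)
is sufficient here because the downstream estimator enforces positive
definiteness anyway.

**Graphical lasso with EBIC selection.** The precision matrix maximizes
log det K − tr(S K) − λΣ_{i≠j}|K_ij| (diagonal unpenalized) by block
coordinate descent: each column is a lasso subproblem on the working
covariance, solved by coordinate descent. Convergence is declared when the
*true* duality gap — primal objective minus the dual objective at the
feasible point obtained by clipping W − S into the λ-box — falls below
`tol` (default 1e−6). The per-column KKT residual is a poor stopping
signal (it can vanish after a single sweep), which is why the global
certificate is used. At λ = 0 the exact MLE `inv(S)` is returned directly
rather than iterating to tolerance. The inner loops are numba-compiled;
a full 100-λ path at p = 26 takes well under a second.

EBIC = −2L + E log n + 4γE log p with L = (n/2)(log det K − tr(S K)); the
polychoric S is plugged in as the sample covariance with the ordinal n,
following the standard ordinal-data EBIC-glasso convention. E counts
nonzero off-diagonal *pairs* (one per undirected edge, not both triangle
entries); an entry counts as nonzero when |K_ij| > 1e−10, since coordinate
descent produces exact zeros and the threshold only guards float noise.
Defaults: γ = 0.5 (the conservative literature default; the analysis this
package reproduces does not state γ), 100 log-spaced λ values from
λ_max = max off-diagonal |S| down to λ_max/100. All three are exposed in
the API and CLI. EBIC ties resolve to the sparser (larger-λ) model.

**Centrality.** Strength s_i = Σ_j |W_ij| and one-step expected influence
ei_i = Σ_j W_ij, computed on raw weights; z-standardized versions are
emitted alongside for plotting. Rankings break ties lexicographically by
node name. Two-step expected influence is deliberately out of scope: the
definition implemented is the one-step signed sum.

## Bootstrap procedures

Both procedures re-run the full estimator (polychoric matrix, λ path, EBIC
re-selection) per replicate, so selection uncertainty is propagated
honestly. Replicate b draws its RNG from `(seed, b[, attempt])`, making
results bit-identical under a fixed seed and independent of execution
order.

*Edge accuracy*: B row-resamples with replacement; 95% percentile
intervals per edge (percentile, not BCa — the simpler convention, adequate
for display alongside point estimates). Resamples in which an item
collapses to one observed category are redrawn and counted; more than 10%
redraws aborts with advice to use a larger sample. Note a known property
of percentile intervals around an L1-regularized estimator: weights are
shrunk toward zero, so intervals for weak true edges sit low and their
coverage of the *true* weight can fall somewhat below nominal. The
intervals describe sampling variability of the regularized estimate, not
debiased confidence intervals.

*Case-dropping stability*: for each drop fraction f, B subsets of
round((1−f)·n) rows without replacement; Pearson correlation between
subset and full-sample centrality. CS-coefficient = largest f in the grid
with ≥ 95% of replicates correlating ≥ 0.7 (0 when none; both thresholds
config-exposed). A replicate with zero centrality variance has no defined
correlation: it is recorded NaN and excluded from the tally, except that a
subset identical to the full sample (f = 0) counts as correlation 1.
Fractions leaving fewer than 50 rows are skipped with a warning. Defaults
B = 1000 (edges) and B = 500 (stability) follow the bootstrap-methodology
literature; the test suite and acceptance script run B = 100–200 with a
40-point λ grid, which keeps a full stability run at n = 4000 under a
minute without changing any scientific conclusion checked.

## Synthetic cohorts

The generator exists because cohort data of this kind are not publicly
shareable; it gives every downstream stage a ground truth. A sparse
precision matrix K is drawn by selecting round(density·p(p−1)/2) edges
uniformly (or per-block for the domain-structured cohort), assigning
weights uniform in `weight_range` with a fixed fraction negative, and
setting the diagonal to 1 + row-sum of |off-diagonal| + jitter. Diagonal
dominance guarantees positive definiteness deterministically — no
rejection sampling — at the cost that realized partial correlations
−K_ij/√(K_ii K_jj) are smaller than the raw weights (a weight range of
0.15–0.35 yields realized |W| of roughly 0.07–0.23). Respondents are
i.i.d. draws of z ~ N(0, Σ) with Σ the standardized K⁻¹, discretized by
per-item cutpoints, so the data satisfy the polychoric model *exactly*.

The default cohort mirrors the motivating study: n = 4901 respondents and
26 items in seven domains of sizes 3/3/6/4/4/4/2, with denser ground-truth
connectivity within domains (edge probability 0.6) than between (0.08),
and one edge in fifteen negative — matching the one negative edge among
the fifteen nonzero domain-level associations in the motivating analysis.
The source instrument's response scales are not published, so items
default to five categories (configurable per item) with equal-probability
cutpoints. The seven-node `recovery_cohort` fixture (density 0.5, weights
0.15–0.35, alternating 5/4 categories, n = 4000) is the workhorse for
recovery and stability checks.

What the generator does *not* emulate: missing responses, skewed or
heaped category usage, non-Gaussian latent structure, subgroup
heterogeneity, and longitudinal dependence. Passing recovery tests
therefore show that the estimator chain is correct under its own model
assumptions — not that those assumptions hold for any particular real
questionnaire.

## Domain ratings

Healthy/fair/poor ratings per domain use a configurable rubric (JSON):
per-domain aggregation (sum of 0-based item codes by default) and two
ordered cutoffs. An aggregate exactly at a cutoff is assigned to the
less-severe category. The shipped default places cutoffs at 40% and 70% of
each domain's aggregate range; it is a synthetic stand-in for the
instrument's unavailable clinical thresholds and carries no clinical
validity. Summaries report per-domain poor counts and the 0 / exactly 1 /
≥ 2 poor-domain partition (which always sums to n), with integer
percentages under half-up rounding — 3085/4901 = 62.95% reports as 63%.

## Numerical and design notes

- Polychoric ρ is clamped to (−0.999, 0.999); the λ-box clipping in the
  glasso dual certificate uses the λ of the current fit.
- λ_max ≤ 0 (an exactly diagonal S) degenerates the path to the single
  unpenalized fit, which is then the empty network.
- Warm starts carry the working covariance and lasso coefficients down the
  descending λ path.
- Layout is Fruchterman–Reingold with |W| as attraction weight
  (networkx `spring_layout`), deterministic under seed; exports are
  GraphML (full float precision) and tidy edge-list CSV; every JSON
  artifact embeds the package version, a SHA-256 of its configuration, and
  the seed.
- Known limitations: no polyserial/mixed correlations, no missing-data
  model beyond pairwise deletion, no bootstrapped difference tests, no
  directed or temporal networks.
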