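# Methods

`symptomnet` implements the comparative symptom-network workflow used in
psychometric studies of depression: two groups of participants scored on
the nine binary DSM-5 criteria of a major depressive episode are each
summarized as a conditional-dependence network, and the two networks are
compared globally and locally. This note records the models, the defaults
and why, the numerical choices, and what the synthetic validation does and
does not establish.

## The Ising model and its estimator

Binary symptom vectors x ∈ {0,1}^p are modeled as a pairwise Markov random
field

P(x) ∝ exp( Σ_i τ_i x_i + Σ_{i<j} w_ij x_i x_j ),

with thresholds τ_i (log-odds scale) and symmetric edge weights w_ij.
State coding is {0,1}, not {−1,+1}, so the parameters line up exactly with
the logistic-regression parameterization of the estimator: the conditional
of one symptom given the rest is logistic with intercept τ_i and slopes
w_ij.

Estimation is nodewise ("eLASSO"): for each node, an L1-penalized logistic
regression on the other p−1 columns over a path of 100 log-spaced penalties
from the node's λ_max (the smallest penalty with an all-zero solution) down
to 0.01·λ_max. The per-node model is chosen by the extended BIC,
EBIC = −2ℓ + k·log n + 2γ·k·log(p−1), with γ = 0.25 by default — the
established eLASSO default, exposed in `EstimatorConfig` because published
analyses rarely state it. Ties resolve to the sparser model. Directed
coefficient pairs are symmetrized with the AND rule by default (an edge
requires selection in both directions; its weight is the mean of the two
estimates); the OR rule (mean of the nonzero estimates) is available.
Penalties are applied to raw binary columns (no variance standardization);
predictors are mean-centered internally, which leaves the L1 solution for
the slopes unchanged while decoupling high-frequency symptoms from the
intercept — without this, coordinate descent converges at a uselessly slow
linear rate when symptom frequencies approach 1.

The solver is a penalized IRLS/coordinate-descent written over *aggregated
states*: rows are collapsed to distinct binary patterns with counts
(≤ 2^p of them, typically a few hundred at p = 9), which makes the cost of
a refit nearly independent of n. IRLS weights are floored at 1e-5 and the
penalty path stops early once the deviance is essentially saturated
(explained deviance > 0.999) — beyond that point the fit only chases
separation and is never EBIC-optimal. Convergence tolerance is 1e-6 on the
maximum parameter change. The solver agrees with an independent penalized
implementation to four decimals on fixtures, and selected supports agree
in sign with unpenalized refits.

Zero-variance symptoms (possible at 99% endorsement) are kept as nodes
with no edges and a clipped-frequency threshold, with a warning — symptoms
are never dropped post hoc.

## Centrality, distances, small world

Strength Σ_j |w_ij| and expected influence Σ_j w_ij are one-step sums.
Closeness and betweenness use the convention of the psychometric
literature: edge length 1/|w_ij|, Dijkstra geodesics, Brandes accounting
with fractional credit for ties. Closeness on a disconnected network is
computed within the node's component and scaled by (reachable−1)/(p−1)
(the Wasserman–Faust correction), because regularized networks can
disconnect; an isolated node scores 0. z-standardization subtracts the
mean and divides by the sample SD (n−1) across nodes; a constant metric
yields all-zero z with a warning.

The small-world index binarizes edges and compares global transitivity C
and the mean unweighted shortest path L over connected pairs against
Erdős–Rényi graphs with matched node and edge counts (1000 replicates by
default; the reference model is a package choice since published analyses
rarely name one): σ = (C/⟨C_rand⟩)/(L/⟨L_rand⟩), with σ > 1 read as
small-world organisation. A saturated (complete) network scores exactly 1;
⟨C_rand⟩ = 0 yields an undefined index with a warning.

## Stability (CS-coefficient)

The case-dropping bootstrap subsamples ⌈n(1−q)⌉ participants without
replacement for q in {0.05, …, 0.75} (the conventional grid and cap),
refits the entire pipeline, and correlates subsample centralities with the
full-sample ones — Pearson on raw values, since z-scoring discards scale
within a replicate. CS(metric) is the largest grid q at which ≥ 95% of
replicates reach r ≥ 0.70, taken literally over the grid (a
scan-from-below variant that stops at the first failing q would differ
only when sampling noise makes the curve non-monotone). Default 1000
replicates per proportion; 250 is the fast mode. Metrics that are constant
across nodes in the full sample have no defined stability correlation and
are rejected (the pipeline skips them with a warning).

## Network comparison (NCT)

Networks are fit per group with identical settings; the statistics are
M = max_{i<j} |w_a − w_b| (structure invariance) and
S = |Σ|w_a| − Σ|w_b|| over unordered pairs (global strength invariance).
The null distribution reassigns pooled participants to groups of the
original sizes, refitting both networks per permutation; p-values use the
add-one rule (1 + #{null ≥ obs})/(1 + n_perm), so they are never exactly
zero. Default n_perm = 1000. Pooled rows are sorted canonically and the
permuted subset size is min(n_a, n_b), which makes results exactly
invariant to swapping the input order. Per-edge difference tests exist
but are off by default; a centrality-invariance test beyond S is
deliberately not implemented.

## Adjusted frequency comparison

For each symptom, a logistic regression of presence on a group indicator
plus the participant's total symptom count fits by Newton/IRLS
(tolerance 1e-8) via statsmodels; the group coefficient is reported as an
odds ratio with 95% Wald CI and two-sided Wald p, one row per symptom with
no multiplicity correction. The modeled symptom is excluded from the
adjustment count by default (otherwise outcome and covariate are
deterministically linked); inclusion is available as an option. Perfect
separation is detected (non-finite or extreme Wald quantities) and the
symptom refit with Firth's Jeffreys-penalized likelihood, flagged in the
output.

## Synthetic cohorts

For p ≤ 20 the state space is enumerated exactly (log-sum-exp
normalization), which provides exact probabilities, exact sampling, and
exact conditioning on the diagnostic event "≥ 5 of 9 symptoms and at
least one of sadness/anhedonia" by restriction and renormalization — not
rejection. Above the guard, a single-site Gibbs sampler (burn-in 1000,
thinning 10 by default) takes over; its conditional updates are the
logistic conditionals above, and it is validated against enumeration by
chi-square goodness of fit at p = 9.

The bundled two-group "paper-like" truths place group-specific signed
edges among the nine criteria, with relative magnitudes and signs taken
from the qualitative structure reported for PPD vs MDE networks and
mapped onto the log-odds scale by a single factor (4.0) chosen so the
structure is recoverable at cohort-sized n; a few filler edges provide
connectivity and local clustering among the mid-frequency symptoms.
Thresholds are then solved by damped fixed-point iteration on the
log-odds scale so that the model marginals — under the diagnostic
constraint, by default — hit target frequencies (cardinal symptoms and
fatigue at 0.83–0.99 in the group-specific order reported; the six
remaining criteria at plausible mid-range values of 0.45–0.85, fixed
once). Both conditioned and unconditioned calibration are exposed, since
published marginal frequencies rarely state which applies.

Two emergent properties of the generator are worth knowing. First,
conditioning on the diagnostic rule induces additional negative
dependence among symptoms (a collider effect), so networks estimated from
constrained cohorts legitimately contain negative edges absent from the
generating weights — the same mechanism that can produce a negative
sadness–anhedonia edge in real diagnosed cohorts. Second, a symptom
endorsed by ~99% of a group carries almost no information, so its edges
are rarely recovered at realistic n; that is faithful to the estimator,
not a defect of the sampler.

What the generator does not emulate: latent-trait (factor) structure,
continuous severities, item wording or rater effects, missing data, and
any covariate structure (age, comorbidity). Passing the validation suite
therefore shows the pipeline is correct and calibrated *for data of this
kind*, not that real MDE/PPD networks have any particular structure.

## Validation scales and numerical choices

The validation suite checks, among others: exact-sampler χ² agreement
(n = 100,000 per seed, 20 seeds, α = 0.01, ≥ 18 expected to pass);
full-sign recovery of a fixed 9-node/6-edge truth at n = 2000 over 50
seeds with ≤ 2 false positives per fit on average and RMSE monotone over
n ∈ {500, 2000, 8000}; exact agreement of all four centralities with an
all-simple-paths oracle on 200 random connected graphs; type-I calibration
of the permutation test (80 null simulations × 100 permutations, exact
binomial band around α = 0.05) and ≥ 80% power against a single Δw = 1.5
edge (30 simulations × 150 permutations at n = 1000/group);
CS monotonicity over n ∈ {300, 1000, 5000} at 250 replicates; adjusted-OR
recovery and CI coverage over 100 simulations; and byte-identical
pipeline outputs across repeated runs. Simulation counts are sized for a
single CPU; each check's statistical form does not depend on the count,
and the binomial acceptance bands are computed exactly at the n used.

## Known limitations

- The Ising weights and the marginal Pearson/phi matrix answer different
  questions; published "r" values for network edges are ambiguous between
  the two, so both are always produced and neither is claimed to
  reproduce any published number.
- EBIC selection with the AND rule is conservative: weak true edges
  (|w| ≲ 0.5 at n ≲ 1000) are routinely missed. This is the documented
  behavior of the estimator class, not a bug.
- The CS-coefficient is reported on the grid only; it is capped at 0.75
  and not interpolated.
- Community detection (a sixth step in some published workflows) is out
  of scope.
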