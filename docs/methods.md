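# Methods

This note documents the models, procedures, and numerical choices behind the
package, in the spirit of a statistical software methods appendix. It states
no empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## The three-form design and its allocation procedures

A three-form planned missing data design partitions the item pool into blocks
X, A, B, C and fields the forms XAB, XAC, XBC. Items in X are observed for
everyone; each rotating-block item is missing for the third of participants
whose form omits its block. Because form assignment ignores every variable in
the study, the induced missingness is MCAR by construction (the package's
permutation-style test checks this on simulated data).

**Basic RIA** (`allocate_ria`) draws a uniformly random partition of the
pooled items subject only to per-block target counts, ignoring scale
membership. Uniformity over count-respecting labeled partitions is verified
against full enumeration (90 partitions of six items into three pairs,
chi-square on 10,000 seeded draws).

**Hybrid RIA** (`allocate_hybrid`, scales of 5–11 items) conditions the
randomization so that *every* block — X included — receives at least one item
from the scale. The count vector is the most even split of P items over the
four blocks (all counts differ by at most one; surplus blocks chosen at
random), and items are assigned uniformly given the counts. Including X in
the balance constraint is a design choice: it is what makes the count vector
for P = 8 uniquely (2,2,2,2), and it guarantees X-coverage, the hybrid's
purpose. The flowchart-level ordering of the randomization (first the
guaranteed item per block, then the remainder) is not observable in the
output distribution given the count constraint, so the implementation draws
the whole assignment in one conditional step.

**Very small scales** (`allocate_tiny`, P ≤ 4): one item to X, the rest
deterministically one-per-block into A, then B, then C — so a four-item scale
puts one item in every block and a three-item scale leaves C empty. An option
randomizes which rotating blocks are filled.

**Deterministic assignments** (`allocate_deterministic`): *between-block*
spreads a scale's items across A/B/C with counts differing by at most one
(round-robin over a randomly permuted block order); *within-block* places all
items into one randomly chosen block. Within-block assignment floors every
cross-scale covariance coverage at 1/3 and is provided as the known-bad
comparator.

**The full workflow** (`build_design`): forced-X items (demographics,
covariates, auxiliaries) go to X; scales at or above the small-scale
threshold (default 12) are pooled through basic RIA with `p_x` items in X;
smaller scales go through the hybrid or tiny rule; the final blocks are the
blockwise union; singletons not forced into X scatter randomly over A/B/C.
When `(P − p_x) mod 3 ≠ 0` the 1–2 surplus items go to rotating blocks drawn
without replacement and a warning notes the unequal form lengths — the
recommended practice is to pick `p_x` so the remainder is divisible by three.
With `require_x_coverage`, the pooled RIA draw is repeated (default cap 100)
until every pooled scale has at least one X item; exhausting the retries is
an error, never a silent fallback. Seeding is hierarchical: one master seed,
with child streams derived per scale/step from a stable hash of the scale
name, so adding a scale does not perturb the allocations of existing ones.

Forms list X items first (participants complete the common block before the
rotating ones), then blocks in label order, preserving input item order; a
flag shuffles within-form order instead.

## Synthetic population

`default_population()` emulates a motivational-climate survey population:
three correlated constructs — ego-involving climate (13 items),
task-involving climate (14 items), caring climate (13 items) — measured by
quasi-continuous items under a linear factor model with standardized latents,

    y_ij = nu_ij + lambda_ij * eta_j + e_ij,   e_ij ~ N(0, theta_ij).

Within each scale the loadings are evenly spaced over [0.45, 0.85] (a
realistic mix of weak-to-strong indicators), residual variances are set to
1 − λ² so items have unit variance, and intercepts sit around the midpoint of
a five-point response format. The latent correlations are
(ego, task) = −0.30, (ego, caring) = −0.25, (task, caring) = 0.60 — signs and
magnitudes matching the substantive relations among these climate constructs.
Demographics reproduce the emulated sample's printed marginals (98.5% female;
age ~ N(49.27, 11.09²); 90.2% white) as independent columns; any joint
structure among demographics, or between demographics and the constructs, is
deliberately not modeled. Extant (naturally occurring) missingness is applied
per cell, completely at random, at a default rate of 0.5% — inside the
0.04%–1.47% variable-wise range of the emulated data. Ordinal discretization
onto a 1–5 scale (thresholds at μ ± 0.5σ and μ ± 1.5σ, giving roughly
symmetric category margins) is available but off by default; with it off, the
items are exactly normal, which is what the normal-model imputation assumes.

What passing tests therefore show — and do not show: parameter recovery and
efficiency results hold for continuous, linear, well-behaved indicators with
MCAR missingness. They do not speak to coarse ordinal items, skewed
distributions, MAR/MNAR nonresponse, or structurally dependent demographics.

## The resampling study

`run_study` crosses three factors (default 3 × 3 × 5 = 45 conditions):

* **X-block**: `trivial` (demographics only), `informed` (demographics plus a
  fixed item list; the default proxy takes the highest-loading item per scale
  from the generating model, standing in for theory-driven selection — it is
  a proxy, not a reconstruction of any published informed block), `random`
  (demographics plus `p_x` = 4 scale items drawn uniformly ignoring scale
  membership).
* **Parcel / A-B-C assignment**: `within`, `between`, `random`. The
  deterministic levels operate on the canonical round-robin parcel groups —
  all items of a parcel into one block (`within`) or spread across blocks
  (`between`) — because parcels are the analysis units whose coverage the
  factor is meant to manipulate. `random` pools all non-X scale items and
  allots them at random; random X + random allotment is the RIA condition.
* **Sample size**: 500, 400, 300, 200, 100. Each replication draws a
  bootstrap sample (with replacement) of 500 from the N = 5244 synthetic
  population, then recursively removes uniformly random rows to produce
  nested subsamples at the smaller sizes.

Random-level conditions redraw their allocation every replication. Before any
imposition, the analysis model is fit to the untouched sample once per
(replication, size); these complete-data control estimates are shared across
all design conditions at that size, define the "true" values for PRB, and
supply the complete-data SE series for RE.

Default scale is a desk profile — R = 50 replications, M = 20 imputations —
chosen so the bundled end-to-end checks run in minutes on one core; the
emulated study's scale (R = 495, M = 100) is reachable through
`StudyConfig`. The acceptance-style pipeline check runs the RIA and
between-block conditions plus the control at N = 500 under the desk profile.

## Estimation stack

* **EM for the multivariate normal** (`em_mvn`): rows grouped by missingness
  pattern; E-step sweeps via Cholesky solves per pattern; observed-data
  log-likelihood is monotone nondecreasing (tested). Convergence when the
  relative log-likelihood change or the largest parameter change drops below
  `tol` (default 1e-6, max 500 iterations). Near-singular observed blocks
  receive a small logged ridge (1e-8 × mean diagonal). Complete data
  reproduces the closed-form moments (divisor n) after one sweep.
* **Multiple imputation** (`draw_imputations`): missing cells drawn from the
  conditional normal of the missing block given the row's observed block at
  the EM estimate. This is normal-model improper MI — no draws of the
  parameters themselves — so between-imputation variance reflects only
  conditional-draw noise; a known, documented simplification relative to
  posterior-draw MI, adequate for the MCAR designs studied here. The
  imputation model includes the demographic columns as auxiliaries.
* **Parcels** (`build_parcels`): each scale's items are dealt round-robin
  into three parcels (13 items → 5/4/4); the parcel score is the mean of its
  items, computed after imputation so inputs are complete. The parceling
  scheme is a configurable stand-in — any three-group partition can be
  supplied.
* **One-factor fit** (`fit_one_factor`): unweighted least squares on the
  covariance with the latent variance fixed to 1 (fixed-factor
  identification) and the first loading sign-constrained nonnegative. For
  exactly three indicators the model is just-identified and the closed-form
  triad solution (λ₁ = √(s₁₂s₁₃/s₂₃), …) is the exact ULS minimizer whenever
  its products are positive; otherwise L-BFGS from a first-principal-
  component start (gradient tolerance 1e-10). Residual variances are left
  unconstrained so Heywood cases surface as `admissible=False` rather than
  being clipped away.
* **Latent correlations**: method of moments from cross-scale parcel
  covariances, φ = mean over parcel pairs of s_ab/(λ_a λ_b). Together with
  the per-scale fits this replaces a simultaneous saturated-latent CFA; the
  two coincide in population for a correctly specified model.
* **Standard errors**: normal-theory delta method. The asymptotic covariance
  of vech(S), Γ = (2/n) D⁺(S ⊗ S)D⁺′, is propagated through the parameter
  map by central finite differences (step 1e-6·(1+|s|), vectorized through
  the closed-form triad path). Intercept SEs are √(s_aa/n). A Monte-Carlo
  test confirms the delta SEs track the empirical estimator spread.
* **Rubin pooling** (`rubin_pool`): pooled point = mean; total variance
  T = W + (1 + 1/M)·B; large-sample degrees of freedom
  (M−1)(1 + W/((1+1/M)B))², infinite when B = 0. Small-sample df adjustments
  are out of scope.
* **Latent reliability** is computed from the fitted parcel-level loadings
  and residual variances with ψ = 1; it is pooled as a point estimate only
  (no SE), so it enters PRB summaries but not RE.

## Failure taxonomy

Four mutually exclusive categories per replication, with precedence
complete-run failure > imputation failure > non-convergent model >
inadmissible (Heywood) solution: (1) unexpected crash anywhere in the
replication; (2) EM/imputation failure, including EM non-convergence; (3) a
factor fit that fails or does not converge; (4) a converged fit with a
negative residual variance in any imputation. Failures are recorded, never
raised; summaries exclude flagged replications from RE/PRB.

## Numerical and reporting choices

* RE is the mean of per-replication SE ratios, as defined — not the ratio of
  mean SEs; the two differ.
* The |PRB| > 10 flag is a reporting convention, configurable.
* Parcel covariances use the ddof = 1 sample covariance of the completed
  data.
* `summarize` reports per-parameter RE/PRB plus unweighted class means
  (rows labeled `class:<name>`), since cross-parameter aggregation is a
  presentation choice, not part of the definitions.
* Balanced form assignment (random permutation of a maximally even label
  vector) is the default; iid assignment mirrors survey-software randomizers
  and converges to the same coverage as n grows.
* CSV convention: empty cell = missing ("NA" also accepted on read);
  reproducibility metadata (seed, config hash) goes to a `.meta.json`
  sidecar so the CSVs themselves round-trip losslessly.

## Known limitations

* Normal-model improper MI understates between-imputation variance relative
  to proper (posterior-draw) MI; with MCAR missingness and the moderate
  missing fractions of three-form designs the effect on RE comparisons is
  second-order, but absolute coverage of pooled intervals is not evaluated.
* The per-scale fit plus method-of-moments latent correlations is not a
  full-information simultaneous CFA; with three parcels per factor each
  sub-model is just-identified, so no fit assessment is available.
* The informed X-block is a proxy by construction.
* "On-the-fly" per-participant item randomization is intentionally not
  implemented: the procedures here produce one fixed set of three forms, and
  the package's evidence does not transfer to per-participant randomization.
* Demographic columns are treated as continuous in the imputation model;
  with extreme marginals (e.g. 98.5% female) and very small samples a
  demographic column can be observed as constant, in which case the ridge
  guard keeps EM running but the column carries no information.
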