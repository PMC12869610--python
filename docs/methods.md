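# Methods

## Model

A subject's assessment is the vector (digit-span serial score, unique
animals, delayed recall, recognition triple). The population model is a
finite mixture over K clusters partitioned into three diagnosis groups
(CU / MCI / Dem); the default structure has one CU, three MCI, and two
Dem clusters. Metrics are conditionally independent given the cluster —
no within-cluster correlation is modeled — and each cluster-metric pair
uses a Conway–Maxwell count family:

- CM-Poisson: `P(k) ∝ λᵏ / (k!)^ν`, normalizer `Z(λ, ν) = Σ_j λʲ/(j!)^ν`.
- CM-binomial on {0..n}: `P(k) ∝ C(n,k)^ν pᵏ (1−p)^{n−k}`.
- CM-multinomial over m-part compositions of n:
  `P(x) ∝ (n!/Πxᵢ!)^ν Π qᵢ^{xᵢ}`.

ν = 1 recovers the classical family; ν < 1 over-disperses, ν > 1
under-disperses. Boundary inflation mixes a point mass at the support
minimum (zero-inflation: animal fluency, recall) or maximum (N-inflation:
digit span, n = 15) with weight π. An additional lognormal family serves
the age-only baseline mixtures.

### Numerical choices

- The CM-Poisson normalizer is summed in log space until the last term
  falls below 1e-12 of the partial sum, with a hard cap of 10,000 terms;
  the sum starts past the term mode (≈ λ^{1/ν}) and doubles its
  truncation until the tail is negligible. ν = 0 with λ ≥ 1 (divergent)
  is rejected with a distinct `NormalizationError`, as is a series that
  still carries material tail mass at the cap.
- The CM-multinomial support for n = 6, m = 3 is enumerated exactly
  (28 compositions); no approximation anywhere on that metric.
- Weighted maximum-likelihood fits optimize unconstrained transforms
  (log λ, logit p, log ν, logit π; additive log-ratio for q) with
  L-BFGS-B and three seeded starts (warm starts inside EM), and the best
  of starting points and optimizer outputs is kept, so an M-step can
  never worsen its objective. Probabilities are clipped to
  [1e-6, 1−1e-6] and ν to [1e-4, 50] to keep EM iterations finite;
  all-boundary data (e.g. every observation zero under a zero-inflated
  family) short-circuits to the inflation cap.
- Sampling is exact inverse-CDF / full-support table sampling; the
  CM-Poisson table is truncated at tail mass 1e-12 and renormalized.

## Semi-supervised EM

Supervision enters through a binary N×K constraint matrix C built from
labels: unlabeled rows are all-ones; a diagnosis-group label marks the
group's clusters (partial when the group holds several clusters); an
exact cluster name pins one cluster. The E-step computes
`γ_ic ∝ C_ic · w_c · f_c(x_i)` and renormalizes rows; entries are exactly
zero wherever C is zero. The M-step sets `w_c = Σ_i γ_ic / N` and refits
every cluster-metric parameter set by γ-weighted maximum likelihood
(observations are first aggregated onto unique support points, making the
M-step cost independent of N). A record whose permitted clusters all give
zero likelihood raises an error naming the record.

- **Initialization**: responsibilities start from the constraint rows,
  perturbed by seeded Dirichlet noise (concentration 20) so symmetric
  clusters separate; labeled rows stay inside their permitted clusters.
  If a cluster comes up empty the fit restarts with a fresh seeded
  perturbation, up to five times.
- **Convergence**: relative change of the constrained observed-data
  log-likelihood below 1e-8, at most 500 iterations. The trace is
  checked non-decreasing (slack 1e-8 relative); because the M-step never
  worsens its objective the algorithm is a generalized EM with the usual
  ascent guarantee.
- **Empty clusters**: during iterations a weight floor of 1e-6 and a
  warning (small clusters — the smallest default cluster holds 2.75% of
  the population — must stay representable); a hard error is raised only
  if a cluster is still empty at convergence.
- **Label switching**: clusters within a diagnosis group are
  exchangeable; `canonicalized()` orders them by ascending delayed-recall
  mean. The default structure lists each group's clusters in
  ascending-recall order too, so canonical slots carry the names their
  phenotypes suggest (severe-amnestic slots get the lowest recall means).
- **Decision rules**: the 3-class call is the argmax of the collapsed
  (CU, MCI, Dem) posterior, breaking exact ties toward the less impaired
  class. The four binary tasks (impairment = CU vs MCI+Dem, dementia =
  CU+MCI vs Dem, and the conditional CU-vs-MCI and MCI-vs-Dem contrasts)
  threshold the summed — for conditional tasks renormalized — positive
  probability at 0.5. The two rules genuinely differ: a row like
  (0.45, 0.35, 0.20) is argmax-CU yet impairment-positive. The threshold
  rule is adopted because a binary screening decision should depend on
  the total probability of the positive condition, not on which single
  cluster group is largest.

## Diagnostics

Cross-validation shuffles records once (seeded) into near-equal
unstratified folds, refits on each complement, and evaluates the
constrained log-likelihood on the held-out fold; labeled records keep
their constraints on both sides. Folds containing a record that is
impossible under the refit contribute −inf and are flagged, never
silently dropped.

Randomized quantile residuals use the *marginal* mixture CDF per metric
(mixture-weight average across clusters): for discrete y the residual is
Φ⁻¹(u) with u uniform on (F(y−1), F(y)). The marginal construction is
the standard one for mixtures and requires no cluster assignment; the
recognition triple is summarized by its correct-count marginal. Under a
correctly specified model the residuals are standard normal; missing
zero-inflation or dispersion misspecification shows up as gross
non-normality (both directions are exercised in the test suite).

## Soft-membership rank tests

With effective sizes `n_c = Σ_i γ_ic` and weighted mean mid-ranks
`R̄_c = Σ_i γ_ic r_i / n_c`:

- omnibus: `H = [12/(N(N+1))] Σ_c n_c (R̄_c − (N+1)/2)²` divided by the
  tie correction `1 − Σ_j (t_j³−t_j)/(N³−N)`;
- pairwise: `Z_ab = (R̄_a − R̄_b) / sqrt([N(N+1)/12 − Σ_j(t_j³−t_j)/(12(N−1))](1/n_a + 1/n_b))`.

With one-hot γ both reduce exactly to the classical tie-corrected
Kruskal–Wallis and Dunn statistics, which is the validation anchor for
this reconstruction (the generalized statistic is otherwise specified
only by its behavior). p-values are Monte-Carlo:
`p = (1 + #{H* ≥ H_obs})/(B+1)` over B = 10,000 permutations of the
values against the fixed membership rows — permuting values rather than
memberships preserves the membership-uncertainty structure under the
null. Pairwise tests share the permutation stream and are corrected by
step-down max-T: pairs ordered by descending |Z|, each adjusted p counts
permutations whose maximum |Z*| over the not-yet-rejected pairs reaches
the observed value, with monotonicity enforced down the ordering.
Missing covariate values are removed complete-case per variable.

## Classifier validation

Overall accuracy and all task proportions carry exact Clopper–Pearson
(beta-quantile) 95% intervals; zero-denominator metrics are reported as
undefined (flagged NaN), never coerced to 0 or 1. AUROC is the
Mann–Whitney probability with half credit for ties (identical to the
trapezoidal area under the empirical ROC curve). AUROC intervals use the
bias-corrected and accelerated (BCa) nonparametric bootstrap with 10,000
replications, resampling positives and negatives separately so every
replicate contains both classes; task scores are the collapsed
posteriors (P(MCI)+P(Dem) for impairment, P(Dem) for dementia, and the
renormalized conditional probabilities for the two conditional tasks).
A packaged 75-pair confusion fixture exercises all of this arithmetic
end to end.

## Synthetic data generator

The generator defines the study conditions the tests run under:

- cluster weights 26.32 / 20.98 / 21.10 / 2.75 / 15.67 / 13.18 percent;
- per-cluster metric parameters frozen by one-time numerical moment
  matching (least squares on the exact mean and SD implied by the PMF)
  against the published per-cluster means and SDs. Two moments cannot
  identify three parameters, so the boundary-inflation weights were fixed
  a priori — small throughout, slightly larger where impairment makes
  floor effects more common (digit-span ceiling inflation 0.10 for CU
  falling to 0.01 for dementia clusters; recall zero-inflation rising
  from 0.01 for CU to 0.45 for the severe-amnestic MCI cluster). All but
  one cluster-metric pair match their target moments essentially exactly;
  severe-amnestic recall (target mean 0.7, SD 1.4) is matched to
  (0.74, 1.33), the closest point attainable at its fixed inflation
  weight. Distinct parameterizations with near-identical first two
  moments exist for some pairs; the frozen config resolves that
  arbitrarily and discloses itself for recovery tests.
- label regime: 80% unlabeled, 10% exact-cluster labels, 10%
  diagnosis-group labels (partial for multi-cluster groups);
- covariates: age (lognormal) and education / MMSE-like / clock-score
  surrogates (normal), location-shifted by diagnosis group in the
  clinically expected directions with magnitudes taken from the published
  group summaries. These are convenience surrogates: the generator makes
  no claim to reproduce real covariate joint distributions, item-level
  responses, or transcription noise.

**What passing tests do and do not show.** The generator reproduces the
published first and second moments, boundary excess, and label mixture,
so recovery and calibration results demonstrate the estimator works under
realistic dispersion and overlap. They do not certify behavior on real
populations — PMF shapes beyond two moments are a modeling choice, and
metric independence within cluster is assumed on both sides.

A consequence of honoring the published moments: neighboring clusters
(CU vs the dysexecutive-MCI cluster; mixed-MCI vs moderate-amnestic
dementia) differ by less than one SD on every metric, so the Bayes-optimal
3-class accuracy against generating labels is about 0.76 (the acceptance
script measures this by classifying 100,000 draws with the generating
model itself). Fitted
models approach that ceiling; no tuning can exceed it under these
conditions. Likewise the smallest cluster (2.75%, ≈80 records at
N=3000) carries enough sampling noise that its fitted animal-fluency
mean can sit 2-3 points from the generating value even when the fitted
likelihood exceeds the truth's.

## Problem sizes used by the checks

Simulation sizes were chosen to keep the full suite comfortably
desk-scale: parameter recovery at N=3000 across five seeds; residual
calibration at N=2000; rank-test size with 500 null replicates at
B=2000; bootstrap coverage with 500 replicates of n=50 at B=2000; EM
contract checks on 20 fixtures of N=100. The acceptance script uses the
same designs with 200-replicate calibration studies.

## Known limitations

- Within-cluster metric independence is assumed, as is the fixed family
  assignment per metric; alternative overdispersion families
  (negative-binomial, beta-binomial, Dirichlet-multinomial) are not
  implemented.
- Model-ladder search (choosing K or families automatically) is manual:
  the diagnostics expose cross-validated likelihood and residuals, but no
  automated selection loop is provided.
- Mixture weights are global; covariate-dependent weights and Bayesian
  estimation are out of scope.
- The generalized rank statistics are validated by their hard-membership
  reduction and permutation calibration; their soft-membership variance
  behavior beyond that is a design reconstruction.
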