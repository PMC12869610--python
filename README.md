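# cogmix

Semi-supervised model-based clustering of brief digital cognitive
assessment scores, for staging cognitive impairment: the model assigns
each subject a posterior probability of being cognitively unimpaired
(CU), having mild cognitive impairment (MCI), or having probable dementia
(Dem), using only four count-valued test scores.

The package is aimed at biostatisticians and cognitive-assessment
researchers who have a large pool of unlabeled assessment results plus a
much smaller set with gold-standard clinical diagnoses, and who want a
calibrated probabilistic classifier together with the validation
machinery around it (model diagnostics, covariate association tests,
and held-out classification metrics with exact intervals).

## The model

Each subject contributes four independent-given-cluster metrics:

- backward digit span serial-order score `y₁ ∈ {0..15}`,
- unique animals named in a fluency minute `y₂ ∈ {0, 1, …}`,
- delayed word recall `y₃ ∈ {0..6}`,
- delayed recognition triple `y₄ = (correct, prototypical foil, generic foil)`, summing to 6.

The population is a K-cluster finite mixture (default K = 6: one CU,
three MCI, two Dem clusters) with density

```
f(y) = Σ_c w_c · f₁c(y₁) · f₂c(y₂) · f₃c(y₃) · f₄c(y₄)
```

Per-cluster metric families are Conway–Maxwell (CM) generalizations of
the classical count families, which carry a dispersion exponent ν on the
combinatorial kernel (ν = 1 classical, ν < 1 over-dispersed, ν > 1
under-dispersed), plus boundary inflation for excess floor/ceiling
scores:

| metric | family | modification |
|---|---|---|
| digit span | CM-binomial(15, p, ν) | inflated at 15 |
| animal fluency | CM-Poisson(λ, ν) | zero-inflated |
| delayed recall | CM-binomial(6, p, ν) | zero-inflated |
| recognition triple | CM-multinomial(6, q, ν) | none |

Fitting is maximum likelihood by a constrained EM algorithm. Partial
supervision enters through a binary N×K constraint matrix applied in the
E-step: unlabeled rows are unconstrained; a diagnosis label restricts a
record to its group's clusters (an MCI label with three MCI clusters is a
*partial* label); an exact cluster label pins a single cluster. Posterior
responsibilities are collapsed to the 3-class scale by summing within
diagnosis groups.

Downstream machinery:

- **diagnostics** — k-fold cross-validated held-out log-likelihood and
  randomized quantile residuals under the fitted marginal mixtures;
- **group_tests** — generalized (soft-membership) Kruskal–Wallis and Dunn
  tests weighted by posterior membership, Monte-Carlo permutation
  p-values, and step-down max-T multiplicity correction;
- **classification_eval** — 3-class confusion matrices, sensitivity /
  specificity / PPV / NPV with exact Clopper–Pearson intervals, AUROC
  (Mann–Whitney form) with BCa bootstrap intervals;
- **synthetic_data** — a generator calibrated to the published six-cluster
  weights and cluster moments, so the entire pipeline is testable without
  any private data.

## Worked example

Fit on synthetic default-condition data and evaluate on a labeled
holdout:

```python
import numpy as np
from cogmix import synthetic_data as sd, mixture as mx
from cogmix import classification_eval as ce

train = sd.generate(N=1200, seed=7)
fit = mx.fit_em(train.records, seed=7)
model = fit.model.canonicalized()
print(f"converged: {fit.converged} after {fit.n_iter} iterations, "
      f"log-likelihood {fit.log_likelihood:.1f}")
print("weights:", {c: round(float(w), 3)
                   for c, w in zip(model.structure.names, model.weights)})

test = sd.generate(N=300, seed=8)
gamma = mx.predict_posteriors(model, test.records)
p3 = mx.collapse_posteriors(gamma, model.structure)
report = ce.evaluate_posteriors(test.true_labels, p3, B=2000, seed=8)
print(report.to_table())
```

prints

```
converged: True after 76 iterations, log-likelihood -10985.4
weights: {'CU': 0.246, 'dMCI': 0.217, 'mxMCI': 0.176, 'aMCI': 0.046, 'maDem': 0.175, 'saDem': 0.14}
confusion (rows=diagnosis, cols=predicted; CU/MCI/Dem):
    CU [56, 18, 2]
   MCI [13, 103, 21]
   Dem [0, 23, 64]
accuracy 0.743 [0.690, 0.792]
impairment: sensitivity 0.942 [0.903, 0.969]  specificity 0.724 [0.609, 0.820]  ppv 0.909 [0.865, 0.943]  npv 0.809 [0.695, 0.894]  auroc 0.940 [0.906, 0.962]
dementia: sensitivity 0.724 [0.618, 0.815]  specificity 0.892 [0.842, 0.930]  ppv 0.733 [0.626, 0.822]  npv 0.888 [0.838, 0.927]  auroc 0.909 [0.869, 0.939]
cu_vs_mci: sensitivity 0.905 [0.843, 0.949]  specificity 0.737 [0.623, 0.831]  ppv 0.861 [0.794, 0.913]  npv 0.812 [0.699, 0.896]  auroc 0.911 [0.863, 0.944]
mci_vs_dem: sensitivity 0.736 [0.630, 0.824]  specificity 0.847 [0.775, 0.903]  ppv 0.753 [0.647, 0.840]  npv 0.835 [0.762, 0.892]  auroc 0.869 [0.812, 0.911]
```

The recovered mixture weights sit close to the generating shares (26.3 /
21.0 / 21.1 / 2.75 / 15.7 / 13.2 percent). Accuracy against the
*generating* labels is bounded by the real overlap between neighboring
clusters — the published cluster moments put adjacent clusters within one
standard deviation of each other on every metric, so even the generating
model classifies only about 76% of its own draws correctly; the AUROCs
show the ranking information is much stronger than the hard 3-class
calls. Real clinician-diagnosis validation data for this class of
assessment behaves the same way (the packaged holdout fixture: 78.7%
accuracy alongside excellent AUROCs).

There is also a CLI mirroring the stages (`cogmix generate | fit |
diagnose | validate | evaluate | report`), driven by a YAML config with
explicit seeds; see `cogmix --help`.

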