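# repsig

Analysis toolkit for bulk TCRβ repertoires: diversity and clonality
statistics, public-clonotype sharing with rank–size power-law fitting,
tissue↔blood overlap of expanded clonotypes, annotation against reference
TCR pools, and discovery of disease-associated clonotype *signatures* with a
Gaussian naive Bayes classifier selected by leave-one-out cross-validation.

It is aimed at immunogenomics analysts working with ImmunoSEQ-style or AIRR
Rearrangement clonotype tables who want a tested, scriptable implementation
of these analyses — for example to ask whether cancer-predisposed
individuals (such as Lynch-syndrome carriers) share circulating TCRβ clones
that separate them from average-risk controls.

## The statistics at the core

For a repertoire with clonotype frequencies $p_i$ (fractions of productive
templates):

- **Hill diversity** $D_q = \left(\sum_i p_i^q\right)^{1/(1-q)}$, the
  effective number of equally abundant clonotypes at order $q$
  ($D_0$ richness, $D_1 = e^{-\sum p_i \ln p_i}$, $D_2$ inverse Simpson).
- **Simpson clonality** $\mathrm{SCI} = \sqrt{\sum_i p_i^2}$, from ~0
  (maximally diverse) to 1 (monoclonal), and homeostasis-bin occupancies
  over frequency intervals Small $(0,10^{-4}]$ … Hyperexpanded
  $(10^{-2},1]$.
- **Public clonotypes**: keys (CDR3β amino-acid sequence, optionally with
  V/J gene segments) carried by ≥ 2 individuals.  Ranking public keys by
  the fraction of samples sharing them gives a rank–size spectrum fitted as
  $f(x) = k\,x^{-\alpha}$ by OLS in log10–log10 space; a larger $\alpha$
  means more sharing.  Spectra are compared with an extra-sum-of-squares
  F test on the log–log slopes.
- **Signature selection**: a clonotype enters the signature when it is
  present in at least a fraction $r$ of positive samples, enriched in
  incidence by a two-sided Fisher exact test ($p < p_F$), and increased in
  per-sample frequency by a two-sided Wilcoxon rank-sum test
  ($p < p_W$), both in the positive direction.  A sample's score is
  $\arcsin\sqrt{\bar{m}}$, where $\bar{m}$ is its mean signature-clone
  frequency; class-conditional Gaussians over the score give posterior
  probabilities, and performance is the rank-based AUROC.  The
  hyperparameters $(\text{key mode}, r, p_F, p_W)$ are chosen by a LOOCV
  grid search; AUROC ties at two decimals prefer shorter key modes, then
  smaller signatures.

A first-class synthetic-cohort generator (`repsig.synth`) produces
repertoires with Zipf clone-size distributions, a power-law sharing
spectrum, planted signature clones and finite sequencing depth — with
ground-truth manifests, so every analysis above can be validated by
parameter recovery.

## Worked example

```python
from repsig import (CohortSpec, generate_cohort, Hyperparameters,
                    select_signature, split_cohort, evaluate_holdout)

cohort, truth = generate_cohort(CohortSpec(seed=0))   # 40 carriers vs 40 controls
hp = Hyperparameters("CDR3aa", presence_ratio=0.10, fisher_p=1e-4, wilcoxon_p=1e-4)

signature = select_signature(cohort, "previvor", hp)
planted = set(truth["signature_keys_cdr3"])
print(len(signature), len(signature & planted) / len(signature))
# 167 1.0        <- 167 selected keys, all of them planted (precision 1.0)

training, validation = split_cohort(cohort, 0.2, seed=0)
result, model = evaluate_holdout(training, validation, hp, "previvor")
print(round(result.auroc, 3))
# 1.0            <- held-out validation AUROC on 16 samples
```

The selected signature contains 167 of the 200 planted carrier-enriched
clones and nothing else; scoring the held-out 20% of samples separates
carriers from controls perfectly in this synthetic regime.

The same analyses are available as numbered drivers under `analysis/`
(simulation → diversity → sharing → overlap → classifier), each writing
its tables to `results/`, and as a CLI (`repsig simulate|diversity|public|
overlap|annotate|classify|run`).

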