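# Methods

## Repertoire model and conventions

A repertoire is one sample's table of productive TCRβ rearrangements.  A
clonotype is identified by its CDR3β amino-acid sequence and, optionally,
its V and J gene segments at gene-level resolution — allele suffixes
(`*01`) are stripped on read, because bulk clonotype exports resolve genes,
not alleles, and cross-sample matching is defined at the amino-acid/gene
level.  Four key modes are supported (CDR3aa, CDR3aa+J, CDR3aa+V,
CDR3aa+V+J); the finer modes refine the partitions of the coarser ones, so
any overlap or sharing count computed at CDR3aa is an upper bound for the
same count at CDR3aa+V+J.

Rows with identical keys are merged by summing template counts before
normalization, which makes frequencies well-defined under any key mode.
Frequencies are always recomputed from template counts after productive
filtering; vendor-provided frequency columns are ignored for
reproducibility across dialects.  Non-productive rows (out-of-frame, stop
codons, `X` residues) are excluded before any statistic is computed.

## Diversity and clonality

Hill numbers `D_q = (Σ p_i^q)^(1/(1-q))` are reported at orders 0, 1 and 2;
`D_1` (exponential Shannon) is used where a single effective-clonotype
number is needed, as the standard single-number summary.  Simpson clonality
is `sqrt(Σ p_i²)`.  Homeostasis bins are lower-exclusive/upper-inclusive —
a clone at exactly 1e-3 is Medium, not Large — so the four bins partition
(0, 1] exactly and occupancies sum to 1.

Group comparisons use the two-tailed Wilcoxon rank-sum (Mann–Whitney) test
with midranks.  The null distribution is enumerated exactly when
`n + m ≤ 12` and the pooled sample is tie-free (threshold configurable);
otherwise a tie-corrected normal approximation with continuity correction
is used, which agrees with `scipy.stats.mannwhitneyu(method="asymptotic")`
to machine precision.  A fully degenerate comparison (all values equal)
returns p = 1 with no direction.  The same approximation, vectorized over
matrix rows, powers the per-clonotype abundance screen in the classifier,
so the scalar test and the screen cannot drift apart.

## Public sharing and the rank–size power law

A clonotype is public when carried by at least `min_individuals = 2`
samples.  Sharing spectra sort public keys by the fraction of samples
carrying them (ties broken lexicographically for determinism), with
x = rank/|keys| and y = 100·sharing fraction.  The power law
`f(x) = k·x^(-α)` is fitted by OLS of log10(y) on log10(x); α = −slope.
Group spectra are compared by the nested extra-sum-of-squares F test:
reduced model with separate intercepts and a common slope, full model with
separate slopes, F ~ (1, n_a + n_b − 4) under the null.  Keeping separate
intercepts in the reduced model ensures only the exponent, not the overall
sharing level, is tested.

Jaccard similarity of key sets is |A∩B|/|A∪B| (0 when both are empty).
Repertoire similarity uses the frequency-based Morisita–Horn index
`2·Σ p_i q_i / (Σ p_i² + Σ q_i²)` over the union of keys, appropriate when
sequencing depth differs between samples.

## Signature selection and classification

Candidate clonotypes must pass all three filters, each with a directional
gate requiring enrichment in the positive class:

1. present in ≥ `ceil(presence_ratio · n_pos)` positive samples;
2. two-sided Fisher exact incidence p < `fisher_p`, with a higher carrier
   proportion among positives;
3. two-sided Wilcoxon rank-sum p < `wilcoxon_p` on per-sample frequencies,
   with the larger rank sum in positives.  Samples lacking the clone enter
   at frequency 0 — excluding them would simply repeat the incidence
   criterion.

Relaxing any single cutoff can only grow the selected set (tested as an
invariant).  P-value cutoffs are applied raw, without multiple-testing
adjustment: the cutoffs are tuned hyperparameters, not inference
thresholds.

The sample score is `arcsin(sqrt(mean signature-clone frequency))`, a
variance-stabilizing transform for proportions.  Class-conditional
Gaussians (sample mean and sd, sd floored at 1e-6 to handle constant
scores) give the posterior for the positive class; the floor only matters
for degenerate training sets.  AUROC is computed rank-based with half
credit for ties, i.e. the probability that a random positive sample
outscores a random negative one, and is therefore invariant to the prior
and to any monotone transform of the score.

The LOOCV grid search holds out each training sample once; by default the
signature is reselected within each fold (`reselect_per_fold=True`), which
is the leakage-free protocol; a faster select-once variant is available.
A fold whose signature comes out empty contributes a held-out posterior of
0.  Because the Fisher and Wilcoxon p-values do not depend on the cutoffs,
they are computed once per (key mode, fold) and thresholded per
combination — an exact optimization.  Ties in LOOCV AUROC at two decimal
places are broken toward shorter key modes, then smaller full-training
signatures, preferring the most parsimonious model.  The 80/20 validation
split is stratified by group and driven by its own seed (default 1234);
validation samples never touch selection or fitting, verified by a
perturbation test.

## Synthetic cohorts

The generator emulates the structure these analyses assume:

- **Abundance**: a pool of `pool_size` clones with Zipf weights
  `w_k ∝ k^(-zipf_exponent)` (default exponent 1, the classic clone-size
  law for bulk repertoires).
- **Sharing**: clone k enters a sample with probability
  `π_k = min(1, s₀·(k/K)^(-sharing_alpha))`, coupling publicity to
  abundance as observed in real repertoires; `s₀` (`sharing_floor`,
  default 0.05) is the inclusion probability of the rarest pool clone.
  The cohort's expected sharing spectrum is then itself a power law with
  the configured exponent (default 0.35, the middle of the range reported
  for human cohorts).
- **Planted signal**: `n_signature` clones (default 200) drawn from
  mid-abundance ranks [K/10, K/2] — rare enough to be realistic signature
  candidates, common enough to survive sampling at the default depth — are
  carried with probability `incidence_pos` (0.6) by positives and
  `incidence_neg` (0.1) by negatives, with frequencies multiplied by
  `abundance_fold` (5) in positives.  Carriage is Bernoulli per clone and
  sample, so realized incidences fluctuate binomially around the nominal
  rates.
- **Depth**: template counts are multinomial at `depth` (default 5e4)
  templates, reproducing the dropout of rare clones seen in real data.
  `depth=None` switches to deterministic rounding with a one-template
  floor, retaining every included clone; this regime is used when the
  sharing law itself is under test, isolating it from sequencing noise.
- **Default cohort size** is 40 positives vs 40 negatives, a desk-scale
  stand-in for cohorts of a few hundred samples.

The matched tissue/blood generator plants an exact number of the tissue's
top-expanded clones into blood at `frequency / tissue_enrichment`, using
deterministic count rounding so ground-truth overlap counts are exact.

What the generator does **not** emulate: V(D)J recombination biology
(clone identities are random CDR3-like strings), sequencing error, HLA
structure, or covariate effects (age, sex, site).  Passing recovery tests
therefore demonstrates the statistical machinery is correct under the
assumed model, not that the biological findings transfer to any real
cohort.

## Calibration and validated regimes

- Sharing-exponent recovery is validated on a 100k-key pool with 200
  samples and `sharing_floor = 0.2` (the dense regime), where the fitted α
  lands within ±0.05 of the configured 0.35.  In sparse regimes (low
  floor, few samples) the rank–size OLS estimator is biased upward:
  binomial noise in observed sharing fractions spreads the spectrum, and
  the ≥2-carrier filter truncates its tail.  This is a property of the
  estimator on finite cohorts — real-data fits carry the same bias — so
  recovery is asserted only where estimation is well-posed.
- The planted-signature recovery conditions (40+40 samples, incidence 0.6
  vs 0.1, cutoffs 1e-4) sit near the resolution limit of the Fisher
  filter: integrating the exact Fisher p over the binomial incidence
  distribution gives a per-clone pass probability of ≈ 0.79, so expected
  recall is just below 0.8 and individual seeds land on either side of it.
  Precision is ≈ 1 throughout (false positives require two simultaneous
  rare events at these cutoffs).
- Null-cohort behaviour (no planted effect) is asserted on the *mean*
  validation AUROC across 20 replicate seeds: with validation sets of ~8
  samples the per-seed null AUROC has a standard deviation near 0.1, so a
  per-seed band of [0.35, 0.65] would be violated by chance; the mean over
  20 seeds (sd ≈ 0.02) tests the no-signal property directly.  The same
  reasoning applies to the label-permutation check of the LOOCV search.
- Type-I error of the slope F test is checked against log-normally
  perturbed power-law spectra, where the OLS assumptions hold and the test
  is exact up to simulation error.

## Problem sizes

Test and driver simulations use desk-scale cohorts (10–100 samples per
arm, pools of 1.5k–100k clones, depths of 1.5e4–5e4 templates), chosen so
each statistical regime — separable, marginal, null — is represented while
every analysis remains a routine laptop computation.

## Known limitations

- The exact rank-sum branch enumerates all label assignments and is
  restricted to `n + m ≤ 12`; beyond that the tie-corrected normal
  approximation is used even when an exact tie-aware enumeration would be
  feasible.
- `read_immunoseq_tsv`/`read_airr_tsv` cover the common column dialects
  via the configurable mapping; exotic vendor exports may need a custom
  `ColumnMap`.
- No rarefaction or depth harmonization: diversity statistics are computed
  at observed depth, so samples sequenced at very different depths are not
  directly comparable.
- The classifier is strictly two-class; three-arm designs are analyzed as
  one-vs-rest contrasts.
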