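# Methods

This note documents the models and procedures the package implements, the
defaults it fixes, and what the synthetic-data experiments do and do not
demonstrate.

## Preprocessing

**Quantile normalisation.** Every sample column is mapped onto the common
distribution of row-rank means: sort each column, average across columns at
each rank, and assign each value the reference value at its rank.  Ties
within a column receive the mean of the reference values their tied span
covers, which makes the operation deterministic and idempotent.  A
single-sample table cannot be quantile normalised against itself; callers
are directed to the single-sample mode, which normalises the sample jointly
with a background cohort.

**Probe collapsing.** Two rules are provided.  *MedianMerge* takes the
per-sample median over a gene's probes.  *MaxAvgMerge* averages the probes
when they agree and takes the per-sample element-wise maximum when they do
not: the decision statistic is the mean pairwise Pearson correlation over
all probe pairs of the gene (one threshold decision per gene, at r > 0.2).
The pairwise rule in the literature is stated only for probe pairs; the
mean-over-pairs generalisation keeps a single coherent rule for genes with
three or more probes.  "Maximum" is interpreted as the element-wise
per-sample maximum rather than "the probe with the maximal mean"; both
readings exist in practice and the choice is fixed here for
reproducibility.  Correlations undefined because a probe is constant count
as zero, which routes such genes to the max branch.  Unmapped probes are
dropped with a logged count.

**Z-scores.** Per gene across samples, $(x - \bar x)/s$ with the sample
standard deviation (ddof = 1).  Constant genes become all-zero rows and are
flagged rather than producing NaNs.

## The voting classifier

Four probabilistic base learners are trained on the classifier-gene
Z-scores and combined with the average-of-probabilities rule; the class
with the highest averaged probability is assigned, with the fixed canonical
tie-break ABC < GCB < Type-III on exact ties (ties are measure-zero but the
rule must be deterministic).  The learner roster mirrors the LMT/J48/RF100/
SMO combination:

- **RF100** — a 100-tree random forest with a fixed seed;
- **J48-like** — a pre-pruned decision tree (minimum leaf size 5) whose
  leaf class frequencies are Laplace smoothed so no leaf emits a hard 0/1
  probability;
- **SMO-like** — a linear-kernel maximum-margin classifier with
  Platt-style sigmoid calibration fitted on the training data (margin
  classifiers do not natively emit the probabilities the vote rule needs);
- **LMT-like** — a stagewise additive logistic model built from shallow
  regression trees (gradient boosting), a functional substitute for a
  logistic model tree; it satisfies the same probability contract and the
  same recovery properties in the test suite.

Exact third-party parameterisations of the historical tools are not
reproducible bit-for-bit; the substitutes are documented by their defaults
above and validated at the contract level (probabilities sum to one,
determinism given the seed, separable-data recovery, held-out accuracy).

The default classifier-gene panel ships with the 17 genes identifiable from
the main published gene lists (9 ABC-associated, 7 GCB-associated, plus
BMF); the original panel had 20 genes, the remainder being available only
in supplementary material.  The panel is a plain configurable list: every
entry point accepts any gene list, and the ensemble records the list it was
trained with.

**Confidence thresholds.** `apply_confidence_threshold` reassigns ABC/GCB
calls with confidence ≤ τ to Type-III, leaving probability vectors
untouched.  The operation is monotone in τ by construction.

**LPS comparator.** Gene weights are pooled-variance two-sample
t-statistics between ABC and GCB training cases (Type-III cases never
influence the weights).  Per-class normal distributions are fitted to the
training scores by sample mean/sd, and a case is assigned ABC (GCB) only
when the equal-prior posterior density ratio exceeds the threshold τ ∈
{0.8, 0.9}; everything else is Type-III.  Because LPS defines no Type-III
posterior, calls carry probabilities (P_ABC, P_GCB, 0) and Type-III appears
only in the predicted label.

**Single-sample mode.** Each query sample is appended alone to a background
cohort (> 30 samples recommended; ≤ 30 triggers a warning, not an error),
the combined table is quantile normalised, probe-merged and Z-scored, and
only the query's Z-row is classified.  Batch mode applies quantile
normalisation before probe merging as well, so the two modes share one
order of operations.

## Feature selection

Information gain uses equal-frequency discretisation (default 10 bins),
which makes the score invariant under monotone transforms of a gene;
entropies are in bits.  CFS merit for a subset S of size k is
$k\,\bar r_{cf} / \sqrt{k + k(k-1)\,\bar r_{ff}}$ with $\bar r_{cf}$ the
mean absolute gene-class correlation and $\bar r_{ff}$ the mean absolute
gene-gene correlation within S.  For the 3-class label, the gene-class
correlation is the mean absolute point-biserial correlation against
one-vs-rest indicators.  Greedy forward selection stops when no candidate
improves the merit; the reported score of each gene is the subset merit at
its moment of inclusion, which is non-decreasing along the selection path
(unlike the descending scores of the ranking methods — consumers should
read the order, not compare scores across methods).  Consensus ranking
averages per-dataset ranks, imputing rank len+1 for genes a ranking does
not contain, with alphabetical tie-break.  The whole-platform path ranks by
information gain, truncates to the top 1000 and re-ranks the survivors with
CFS.

## Survival evaluation

Separation of assigned ABC/GCB classes is the univariate Cox
proportional-hazards coefficient of a GCB indicator (ABC baseline), with
Efron handling of tied event times and the Wald p-value as the ranking
statistic — the convention matching a reported HR with 95% CI and one p per
contrast.  Type-III cases are excluded from the model.  Classifier variants
are ranked per data set by p-value (ties broken by |log HR| descending) and
ordered overall by average rank.  The threshold sweep re-applies
`apply_confidence_threshold` at τ = 0.5 … 0.9 and re-fits; a τ that leaves
too few events flags its row rather than aborting the sweep.

## Differential expression

Per gene, a two-group comparison of ABC vs GCB samples with
empirical-Bayes variance moderation: sample variances are modelled as
$s^2 \sim s_0^2 F(d, d_0)$ and the prior degrees of freedom $d_0$ and prior
variance $s_0^2$ are fitted by method of moments on $\log s^2$ (digamma/
trigamma matching; the trigamma equation is inverted by Newton iteration).
The moderated t uses the posterior variance
$(d_0 s_0^2 + d s^2)/(d_0 + d)$ on $d_0 + d$ degrees of freedom; as
$d_0 \to 0$ this recovers the ordinary pooled-variance t exactly (verified
in the tests), and $d_0 = \infty$ (variances less dispersed than chi-square
sampling noise) collapses all variances to $s_0^2$ with normal tails.
Constant genes get p = 1 and a flag.  Multiple testing uses
Benjamini–Hochberg at α = 0.05 (configurable).  Class-associated lists are
the sign-partition of the significant genes, so they are disjoint by
construction.

**Normalised fold change.** The published definition of NFC is only "0–1
for differentially expressed genes"; whether it is max-scaled, min-max
scaled or rank scaled is not recoverable from the main text.  This package
divides |log2 FC| by the maximum |log2 FC| among the same data set's
significant genes of the same class — the simplest map onto (0, 1] whose
top gene scores exactly 1 — and records that convention here and in the
output metadata.

## Meta-analysis

The meta-profile keeps genes class-associated in at least `min_datasets`
data sets (default 6, i.e. more than half of 11) and sorts by (number of
data sets descending, median NFC descending).  `pct_present` is computed
over the data sets whose platform carries the gene, so a gene missing from
some platforms can still be 100% consistent.

Enrichment uses the exact hypergeometric tail (draw = profile, successes =
signature, population = platform genes), and, alongside it, an empirical
null: the overlap count under random draws without replacement, summarised
by the mean and sd of the sampled distribution and reported as a Z-score.
Defaults are 10^6 samplings for the signature screen and 10^7 for pairwise
dataset concordance, both configurable (tests use 10^3–10^5 with
correspondingly widened tolerances).  Classifier genes are removed from the
signatures, from the draw and from the population before testing, since
they are class-biased by construction; the removed members of each
signature are reported under the `EXCLUDED_GENES:` tag.  FDR is computed by
BH on the hypergeometric tail p in the favoured direction (enrichment or
depletion, whichever tail is smaller), with the Monte-Carlo Z reported
alongside; computing FDR on an empirical p from the sampled distribution
would be the main alternative and is intentionally not done, so that the
FDR does not depend on the sampling count.

For pairwise concordance the four Z-scores of a dataset pair (two
directions × ABC/GCB) are averaged into one symmetric cell.  When the two
platforms differ, the population is the draw-side data set's platform —
the direction-averaging makes the final cell symmetric in this choice,
which is recorded in the output.

Cytoband consistency reports chromosome-region signatures significantly
enriched in ≥ 6 data sets with their average Z, flagged in two tiers by the
meta-profile FDR (< 0.05 and < 0.1).

## Synthetic data

The generators define the study conditions the tests run under:

- **Training cohort**: 240 samples split exactly 73/115/52 across
  ABC/GCB/Type-III (largest-remainder rounding of the published
  proportions).  Classifier genes are shifted ±1.5 sd by class; Type-III
  cases lean weakly (±0.3 sd) toward one class, producing the intermediate
  expression of the molecular gray zone.  Noise sd is 1 on a log2-like
  baseline of 8.
- **Probes**: 1–3 probes per gene (probabilities 0.5/0.3/0.2); replicate
  probes correlate at 0.8 with the gene signal (technical noise
  sd = $\sqrt{1/\rho - 1}$), exercising the MaxAvgMerge average branch,
  while 10% of probes in multi-probe genes are uncorrelated decoys
  exercising the max branch.
- **Survival**: exponential event times with class-specific rates (GCB =
  baseline × HR, Type-III at the geometric mean), censored by independent
  Uniform(0, M) times with M solved numerically so the expected censored
  fraction matches the requested rate.
- **Multi-dataset families**: default 11 data sets of 80 samples sharing 30
  planted always-ABC and 30 always-GCB core genes at effect 1.2 sd with
  ±20% per-dataset jitter, their own noise genes, and optional platform
  dropout that never removes classifier genes (the shared trained ensemble
  must be applicable to every member).  BMF, whose class is not stated in
  the main text, is treated as GCB-associated purely as a generator
  convention.
- **Signature databases**: planted signatures draw 80% of their genes from
  a supplied profile; random signatures draw uniformly from the population.

What passing on these conditions shows — and does not.  The generators
produce well-separated Gaussian class structure with exchangeable noise
genes; they do not emulate platform-specific intensity distributions,
batch effects, correlated noise modules, or FFPE degradation beyond dropout
and noise scale.  Recovery rates here (≈ 95% held-out accuracy, 100%
meta-profile core recovery) therefore bound the pipeline's correctness, not
its clinical performance; hazard ratios and p-values published for the real
GEO cohorts are not reproducible without those data and the original
third-party learners and are deliberately out of scope.

## Problem sizes and numerics

Test and acceptance runs use desk-scale sizes chosen to keep the suite
fast while leaving comfortable statistical margins: cohorts of 100–240
samples, 11-dataset families of 80 samples, Monte-Carlo nulls of 10^3–10^5
samplings, and a 200-replicate null for survival-p calibration.  Numeric
conventions fixed throughout: sample sd (ddof = 1) everywhere a sd is
estimated; seeds recorded in every artifact (ensembles carry a training
fingerprint); scientific-notation decimals accepted on input, locale
separators rejected; composite `#`-joined gene identifiers treated as
atomic and never re-annotated.
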