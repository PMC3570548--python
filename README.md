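# dac — cell-of-origin classification of DLBCL and comparative meta-analysis

Diffuse large B-cell lymphoma (DLBCL) splits into two principal
cell-of-origin classes with different outcome and biology — activated
B-cell-like (ABC) and germinal-center B-cell-like (GCB) — plus a
Type-III/unclassified "molecular gray zone".  Published classifiers differ
in gene sets, platforms and implementation details, which makes cohorts
classified by different groups hard to compare.

`dac` implements a platform-independent **DLBCL Automatic Classifier**: a
balanced-voting ensemble of four probabilistic learners (a logistic
model-tree substitute, a pruned decision tree with smoothed leaves, a
100-tree random forest, and a calibrated maximum-margin classifier), all
trained on Z-scores of a small classifier-gene panel.  For a sample with
feature vector $x$, each learner $m$ emits class probabilities
$p_m(c \mid x)$ over $c \in \{\text{ABC}, \text{GCB}, \text{Type-III}\}$ and
the ensemble averages them:

$$\hat p(c \mid x) = \tfrac{1}{M}\sum_{m=1}^{M} p_m(c \mid x), \qquad
\hat c = \arg\max_c \hat p(c \mid x),$$

with no hard confidence threshold by default (optional thresholds reassign
low-confidence ABC/GCB calls to Type-III).  A linear-predictor-score (LPS)
comparator is included: $S = \sum_j a_j x_j$ with $a_j$ the ABC-vs-GCB
t-statistic of gene $j$, classified by the Bayesian posterior under normal
score distributions fitted per class and a 0.8/0.9 threshold.

Around the classifier the package provides the full comparative-analysis
stack:

- **io_formats** — TSV expression tables, GMT signature collections, ARFF,
  survival tables, and HGNC-style symbol re-annotation;
- **preprocess** — quantile normalisation, probe→gene collapsing
  (MedianMerge, or MaxAvgMerge: average probes with mean pairwise Pearson
  r > 0.2, else per-sample maximum), per-gene Z-scores;
- **classifier** — the voting ensemble, LPS, and a single-sample mode that
  classifies one case at a time against a >30-sample background cohort;
- **feature_selection** — information-gain ranking, greedy CFS subset
  selection, and consensus ranks across data sets;
- **survival_eval** — Cox proportional-hazards separation of assigned
  ABC/GCB classes (GCB vs ABC baseline, Efron ties, Wald p), classifier
  ranking and confidence-threshold sweeps;
- **diffexp** — moderated-t differential expression with empirical-Bayes
  variance shrinkage and Benjamini–Hochberg correction, plus normalised
  fold changes in (0, 1];
- **meta_analysis** — meta-profiles (genes class-associated in ≥ 6 of 11
  data sets, ranked by consistency then median NFC), pairwise dataset
  concordance, and signature/cytoband enrichment with exact hypergeometric
  p-values and Monte-Carlo empirical-null Z-scores;
- **synthetic** — generators for Wright-like training cohorts (240 cases,
  73/115/52 across ABC/GCB/Type-III), multi-dataset families with a planted
  class core, survival with planted hazard ratios, and signature databases,
  so the entire pipeline is testable offline.

## Worked example

```bash
python examples/01_classify_cohort.py
```

trains the ensemble on the simulated 240-case training cohort and
classifies a fresh 100-sample cohort:

```
trained 4-learner ensemble (LMT+J48+RF100+SMO) on 240 samples, 17 classifier genes

first five calls (P_* are the averaged learner probabilities;
'predicted' is the class with the highest mean probability):
sample_id  P_ABC  P_GCB  P_TypeIII predicted  confidence
    S0000  0.549  0.019      0.432       ABC       0.549
    S0001  0.728  0.023      0.249       ABC       0.728
    S0002  0.940  0.004      0.056       ABC       0.940
    S0003  0.751  0.026      0.224       ABC       0.751
    S0004  0.963  0.004      0.033       ABC       0.963

agreement with planted labels: 96.0% (gray-zone Type-III cases account for most disagreements)
```

Each row is one sample: the three probabilities are the ensemble's averaged
class confidences (summing to 1), and the first sample illustrates the gray
zone — a low-confidence ABC call that a hard threshold of 0.6 would push to
Type-III.  The other examples cover single-sample classification against a
background cohort (`02`), survival-based ranking of DAC against LPS (`03`),
and meta-profiles with signature enrichment (`04`).

A thin CLI wraps the same functions: `dac train`, `dac classify`
(batch or single-sample with `--background`), and `dac enrich`.

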