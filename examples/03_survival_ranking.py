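"""Rank classifier variants by ABC/GCB survival separation.

Classifier quality is judged by how well the assigned ABC and GCB classes
separate overall survival (Cox hazard ratio for GCB vs ABC; HR < 1 means
better GCB outcome).  This example compares the DAC ensemble with the LPS
comparator at both of its thresholds on a synthetic cohort with a planted
hazard ratio of 0.4, then sweeps hard confidence thresholds.
"""

import dac
from dac.synthetic import CohortSpec, simulate_cohort, simulate_survival

ensemble, features, labels = dac.train_wright_like_ensemble(seed=0)
lps = dac.train_lps(features, labels)

cohort, probe_map, truth = simulate_cohort(CohortSpec(n_samples=200, seed=1))
feats, _ = dac.cohort_to_features(cohort, probe_map,
                                  classifier_genes=ensemble.gene_list)
survival = simulate_survival(truth, hr_gcb_vs_abc=0.4, censor_rate=0.2,
                             seed=1, sample_ids=feats.index)

variants = {
    "DAC": dac.predict(ensemble, feats),
    "LPS 0.8": dac.predict_lps(lps, feats, tau=0.8),
    "LPS 0.9": dac.predict_lps(lps, feats, tau=0.9),
}
separations = {}
print(f"{'classifier':<10} {'HR':>6} {'95% CI':>14} {'p':>10} {'Type-III':>9}")
for name, calls in variants.items():
    sep = dac.survival_separation(calls, survival)
    separations[name] = sep
    print(f"{name:<10} {sep.hazard_ratio:>6.2f} "
          f"[{sep.ci_low:.2f}, {sep.ci_high:.2f}]   {sep.p_value:>9.2e} "
          f"{sep.n_type_iii:>9}")

ranked = dac.rank_classifiers({"synthetic": separations})
print("\nrank by p-value (1 = strongest separation):")
print(ranked[["average_rank"]].to_string())

print("\nhard confidence thresholds for the DAC calls "
      "(%Type-III grows, separation should persist):")
sweep = dac.confidence_sweep(variants["DAC"], survival)
print(sweep[["tau", "pct_type_iii", "hazard_ratio", "p_value"]]
      .to_string(index=False, float_format="%.3f"))
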