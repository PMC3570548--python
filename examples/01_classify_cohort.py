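"""Train the DAC ensemble on a Wright-like cohort and classify new samples.

Simulates the 240-case training cohort (73 ABC / 115 GCB / 52 Type-III),
fits the four-learner balanced-voting ensemble on classifier-gene Z-scores,
then classifies a fresh 100-sample cohort and compares the calls with the
planted truth.
"""

import numpy as np

import dac
from dac.synthetic import CohortSpec, simulate_cohort

ensemble, features, labels = dac.train_wright_like_ensemble(seed=0)
print(f"trained {len(ensemble.learners)}-learner ensemble "
      f"({'+'.join(ensemble.kinds)}) on {len(features)} samples, "
      f"{len(ensemble.gene_list)} classifier genes")

cohort, probe_map, truth = simulate_cohort(CohortSpec(n_samples=100, seed=1))
feats, missing = dac.cohort_to_features(cohort, probe_map,
                                        classifier_genes=ensemble.gene_list)
calls = dac.predict(ensemble, feats)

frame = dac.calls_to_frame(calls)
print("\nfirst five calls (P_* are the averaged learner probabilities;")
print("'predicted' is the class with the highest mean probability):")
print(frame.head().to_string(index=False, float_format="%.3f"))

accuracy = np.mean([c.predicted == t for c, t in zip(calls, truth)])
print(f"\nagreement with planted labels: {100 * accuracy:.1f}% "
      f"(gray-zone Type-III cases account for most disagreements)")
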