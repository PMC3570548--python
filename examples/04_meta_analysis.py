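"""Cross-dataset meta-profiles, concordance and signature enrichment.

Simulates a family of data sets sharing a planted core of class-associated
genes, classifies each with the same trained ensemble, finds differentially
expressed genes per data set, builds the ABC meta-profile (genes
class-associated in at least half the data sets, ranked by consistency then
median normalised fold change), and screens a synthetic signature database
against it with hypergeometric p-values and Monte-Carlo Z-scores.
"""

import dac
from dac.synthetic import MultiDatasetSpec, simulate_multidataset, simulate_signature_db

ensemble, _, _ = dac.train_wright_like_ensemble(seed=0)
spec = MultiDatasetSpec(n_datasets=6, n_samples=80, seed=0)
bundles = simulate_multidataset(spec)

abc_lists, nfcs, populations = {}, {}, {}
for b in bundles:
    gene_matrix = dac.cohort_to_gene_matrix(b.matrix, b.probe_map)
    feats, _ = dac.cohort_to_features(b.matrix, b.probe_map,
                                      classifier_genes=ensemble.gene_list)
    calls = dac.predict(ensemble, feats)
    det = dac.moderated_t_test(gene_matrix.values, calls)
    abc, gcb = dac.class_associated_lists(det)
    abc_lists[b.name] = abc
    nfcs[b.name] = dac.normalized_fold_change(det).to_dict()
    populations[b.name] = b.platform_genes
    print(f"{b.name}: {len(abc)} ABC-associated, {len(gcb)} GCB-associated genes")

profile = dac.build_meta_profile(abc_lists, nfcs, min_datasets=spec.n_datasets // 2,
                                 platform_genes_by_dataset=populations)
print(f"\nABC meta-profile: {len(profile)} genes; top five by "
      "(datasets, median NFC):")
for r in profile[:5]:
    print(f"  {r.gene:<14} num_files={r.num_files}  median_nfc={r.median_nfc:.2f}")

conc = dac.pairwise_dataset_concordance(
    {d: (abc_lists[d], abc_lists[d]) for d in abc_lists},
    populations, n_samplings=10_000, seed=0)
print("\npairwise concordance Z (same planted core -> strongly positive):")
print(conc.round(1).to_string())

profile_genes = [r.gene for r in profile]
population = sorted(set().union(*populations.values()))
signatures = simulate_signature_db(population, planted_from_profile=profile_genes,
                                   n_random_sigs=50, size_range=(40, 60),
                                   n_planted=2, seed=0)
results = dac.signature_enrichment(profile_genes, signatures, population,
                                   classifier_genes=ensemble.gene_list,
                                   n_samplings=100_000, seed=0)
table = dac.enrichment_to_frame(results).sort_values("FDR").head(5)
print("\ntop signatures by FDR (planted ones should lead, Z >> 0):")
print(table[["Gene Signature", "Overlapping", "GeneSigSize", "%Overlap",
             "Zscore", "FDR"]].to_string(index=False))
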