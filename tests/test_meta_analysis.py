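import itertools
import math

import numpy as np
import pytest

from dac.io_formats import GeneSignature
from dac.meta_analysis import (
    EnrichmentResult,
    build_meta_profile,
    cytoband_consistency,
    hypergeometric_test,
    mc_null_moments,
    pairwise_dataset_concordance,
    pct_overlap,
    per_dataset_consistency,
    signature_enrichment,
)


class TestHypergeometric:
    def test_worked_example(self):
        # N=10, K=4, n=5, k=3: [C(4,3)C(6,2)+C(4,4)C(6,1)]/C(10,5) = 66/252
        p_enr, _ = hypergeometric_test(3, 4, 5, 10)
        assert p_enr == pytest.approx(66 / 252, abs=1e-12)

    def test_empty_success_set(self):
        p_enr, p_dep = hypergeometric_test(0, 0, 5, 10)
        assert p_enr == 1.0 and p_dep == 1.0

    def test_drawing_whole_population(self):
        p_enr, _ = hypergeometric_test(4, 4, 10, 10)
        assert p_enr == pytest.approx(1.0)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            hypergeometric_test(5, 4, 5, 10)
        with pytest.raises(ValueError):
            hypergeometric_test(1, 4, 11, 10)

    def test_matches_exhaustive_enumeration_small_populations(self):
        # brute force over all subsets for a few (N, K, n)
        for N, K, n in [(6, 2, 3), (8, 4, 3), (10, 5, 4)]:
            pop = range(N)
            successes = set(range(K))
            counts = {}
            for draw in itertools.combinations(pop, n):
                k = len(successes & set(draw))
                counts[k] = counts.get(k, 0) + 1
            total = math.comb(N, n)
            for k in counts:
                p_enr, p_dep = hypergeometric_test(k, K, n, N)
                brute_enr = sum(c for kk, c in counts.items() if kk >= k) / total
                brute_dep = sum(c for kk, c in counts.items() if kk <= k) / total
                assert p_enr == pytest.approx(brute_enr, abs=1e-12)
                assert p_dep == pytest.approx(brute_dep, abs=1e-12)


class TestMCNullMoments:
    def test_matches_analytic_mean_and_sd(self):
        N, K, n, reps = 100, 10, 20, 100_000
        mu, sd = mc_null_moments(K, n, N, n_samplings=reps, seed=0)
        mean = n * K / N
        var = n * (K / N) * (1 - K / N) * (N - n) / (N - 1)
        assert abs(mu - mean) <= 3 * np.sqrt(var / reps)
        assert abs(sd - np.sqrt(var)) <= 0.1 * np.sqrt(var)

    def test_zero_successes(self):
        assert mc_null_moments(0, 20, 100, n_samplings=1000, seed=0) == (0.0, 0.0)

    def test_overdraw_rejected(self):
        with pytest.raises(ValueError):
            mc_null_moments(10, 101, 100)


class TestSignatureEnrichment:
    def _setup(self, seed=0):
        rng = np.random.default_rng(seed)
        population = [f"G{i:04d}" for i in range(2000)]
        profile = list(rng.choice(population, size=200, replace=False))
        return rng, population, profile

    def test_planted_signature_detected(self):
        rng, population, profile = self._setup()
        inside = rng.choice(profile, size=40, replace=False)
        outside = rng.choice([g for g in population if g not in set(profile)],
                             size=10, replace=False)
        sigs = [
            GeneSignature("planted", "syn", frozenset(inside) | frozenset(outside)),
            GeneSignature("random", "syn",
                          frozenset(rng.choice(population, size=50, replace=False))),
        ]
        res = signature_enrichment(profile, sigs, population,
                                   n_samplings=10_000, seed=0)
        by_name = {r.name: r for r in res}
        assert by_name["planted"].fdr < 0.05
        assert by_name["planted"].z > 5
        assert by_name["planted"].pct_overlap == pytest.approx(100 * 40 / 50)

    def test_classifier_genes_removed_everywhere(self):
        _, population, profile = self._setup(1)
        excl = profile[:5]
        sig = GeneSignature("s", "syn", frozenset(profile[:20]))
        (res,) = signature_enrichment(profile, [sig], population,
                                      classifier_genes=excl,
                                      n_samplings=1_000, seed=0)
        assert res.sig_size == 15          # 20 - 5 excluded
        assert res.overlap == 15
        assert res.draw_size == len(profile) - 5
        assert res.excluded_genes == sorted(excl)

    def test_disjoint_signature_not_enriched(self):
        _, population, profile = self._setup(2)
        outside = [g for g in population if g not in set(profile)][:30]
        (res,) = signature_enrichment(profile, [GeneSignature("d", "syn",
                                                              frozenset(outside))],
                                      population, n_samplings=1_000, seed=0)
        assert res.overlap == 0 and not res.enriched

    def test_empty_signature_after_exclusion_skipped(self):
        _, population, profile = self._setup(3)
        sig = GeneSignature("gone", "syn", frozenset(profile[:3]))
        res = signature_enrichment(profile, [sig], population,
                                   classifier_genes=profile[:3],
                                   n_samplings=1_000, seed=0)
        assert res == []


class TestPairwiseConcordance:
    def test_identical_lists_give_huge_z(self):
        rng = np.random.default_rng(0)
        pop = [f"G{i}" for i in range(5000)]
        abc = list(rng.choice(pop, 100, replace=False))
        gcb = list(rng.choice([g for g in pop if g not in set(abc)], 100,
                              replace=False))
        lists = {"d1": (abc, gcb), "d2": (abc, gcb)}
        pops = {"d1": pop, "d2": pop}
        z = pairwise_dataset_concordance(lists, pops, n_samplings=10_000, seed=0)
        assert z.loc["d1", "d2"] >= 10

    def test_independent_lists_give_null_z(self):
        rng = np.random.default_rng(1)
        pop = [f"G{i}" for i in range(3000)]
        zs = []
        for rep in range(20):
            lists = {
                d: (list(rng.choice(pop, 80, replace=False)),
                    list(rng.choice(pop, 80, replace=False)))
                for d in ("d1", "d2")
            }
            z = pairwise_dataset_concordance(lists, {"d1": pop, "d2": pop},
                                             n_samplings=5_000, seed=rep)
            zs.append(z.loc["d1", "d2"])
        assert np.mean(np.abs(zs) <= 3) >= 0.95

    def test_matrix_symmetric_with_nan_diagonal(self):
        rng = np.random.default_rng(2)
        pop = [f"G{i}" for i in range(1000)]
        lists = {
            d: (list(rng.choice(pop, 40, replace=False)),
                list(rng.choice(pop, 40, replace=False)))
            for d in ("d1", "d2", "d3")
        }
        z = pairwise_dataset_concordance(lists, {d: pop for d in lists},
                                         n_samplings=2_000, seed=0)
        assert np.allclose(z.to_numpy(), z.to_numpy().T, equal_nan=True)
        assert np.isnan(np.diag(z.to_numpy())).all()

    def test_empty_class_list_flags_cell_missing(self):
        pop = [f"G{i}" for i in range(100)]
        lists = {"d1": (pop[:10], []), "d2": (pop[5:15], pop[20:30])}
        z = pairwise_dataset_concordance(lists, {"d1": pop, "d2": pop},
                                         n_samplings=2_000, seed=0)
        assert np.isnan(z.loc["d1", "d2"])


class TestMetaProfile:
    def test_sort_and_threshold_rule(self):
        datasets = [f"d{i}" for i in range(11)]
        genes = {"a": (11, 0.5), "b": (11, 0.7), "c": (9, 0.9), "d": (5, 1.0)}
        class_lists = {
            ds: [g for g, (nf, _) in genes.items() if i < nf]
            for i, ds in enumerate(datasets)
        }
        nfc = {ds: {g: v for g, (nf, v) in genes.items() if i < nf}
               for i, ds in enumerate(datasets)}
        rows = build_meta_profile(class_lists, nfc, min_datasets=6)
        assert [(r.gene, r.num_files) for r in rows] == [("b", 11), ("a", 11), ("c", 9)]

    def test_min_datasets_one_keeps_everything(self):
        class_lists = {"d1": ["a"], "d2": ["b"]}
        nfc = {"d1": {"a": 0.5}, "d2": {"b": 0.7}}
        rows = build_meta_profile(class_lists, nfc, min_datasets=1)
        assert {r.gene for r in rows} == {"a", "b"}

    def test_pct_present_counts_only_carrying_platforms(self):
        datasets = [f"d{i}" for i in range(11)]
        carrying = datasets[:8]
        class_lists = {ds: (["g"] if ds in carrying else []) for ds in datasets}
        nfc = {ds: ({"g": 0.4} if ds in carrying else {}) for ds in datasets}
        platforms = {ds: (["g"] if ds in carrying else []) for ds in datasets}
        (row,) = build_meta_profile(class_lists, nfc, min_datasets=6,
                                    platform_genes_by_dataset=platforms)
        assert row.num_files == 8 and row.pct_present == pytest.approx(100.0)


def _er(name, z, fdr):
    return EnrichmentResult(
        name=name, source="syn", overlap=1, sig_size=10, draw_size=100,
        population_size=1000, random_avg=1.0, random_sd=1.0,
        pct_overlap=10.0, z=z, p=0.5, fdr=fdr, enriched=z > 0,
    )


class TestConsistencySummaries:
    def test_always_enriched_signature(self):
        by_ds = {f"d{i}": [_er("sig", 5.0, 0.001)] for i in range(11)}
        out = per_dataset_consistency(by_ds)
        row = out.loc["sig"]
        assert row["Number_of_Samples"] == 11
        assert row["ZscoresAllSameSign"]
        assert row["Annotation"] == "+" * 11

    def test_never_significant_signature(self):
        by_ds = {f"d{i}": [_er("sig", 0.5, 0.9)] for i in range(4)}
        out = per_dataset_consistency(by_ds)
        assert out.loc["sig", "Number_of_Samples"] == 0
        assert out.loc["sig", "Annotation"] == "****"

    def test_mixed_signs_flagged(self):
        by_ds = {"d0": [_er("sig", 3.0, 0.01)], "d1": [_er("sig", -3.0, 0.01)]}
        out = per_dataset_consistency(by_ds)
        assert not out.loc["sig", "ZscoresAllSameSign"]
        assert out.loc["sig", "Annotation"] == "+-"

    @pytest.mark.parametrize("n_sig,included", [(6, True), (5, False)])
    def test_cytoband_inclusion_threshold(self, n_sig, included):
        by_ds = {
            f"d{i}": [_er("chr3q29", 4.0, 0.01 if i < n_sig else 0.5)]
            for i in range(11)
        }
        meta = [_er("chr3q29", 4.0, 0.03)]
        out = cytoband_consistency(by_ds, meta, min_datasets=6)
        assert ("chr3q29" in out.index) == included

    @pytest.mark.parametrize("fdr,tier", [(0.03, 1), (0.07, 2), (0.5, 0)])
    def test_cytoband_two_tier_flag(self, fdr, tier):
        by_ds = {f"d{i}": [_er("band", 4.0, 0.01)] for i in range(11)}
        out = cytoband_consistency(by_ds, [_er("band", 4.0, fdr)], min_datasets=6)
        assert out.loc["band", "meta_profile_tier"] == tier
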