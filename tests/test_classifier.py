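import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dac.classifier import (
    ClassCall,
    ClassLabel,
    LPSModel,
    TrainedEnsemble,
    apply_confidence_threshold,
    classify_single_samples,
    predict,
    predict_lps,
    train_base_learner,
    train_ensemble,
    train_lps,
)
from dac.io_formats import ExpressionMatrix, Level
from dac.synthetic import CohortSpec, simulate_cohort

KINDS = ("LMT", "J48", "RF100", "SMO")


class _StubLearner:
    """Fixed-output learner for exercising the vote-combination rule."""

    def __init__(self, probs):
        self.probs = np.asarray(probs, dtype=float)

    def predict_proba(self, X):
        return np.tile(self.probs, (X.shape[0], 1))


def _stub_ensemble(prob_rows):
    return TrainedEnsemble(
        learners=[_StubLearner(p) for p in prob_rows],
        kinds=["stub"] * len(prob_rows),
        gene_list=["gene1", "gene2"],
        training_fingerprint="stub",
        seed=0,
    )


class TestBaseLearners:
    @pytest.mark.parametrize("kind", KINDS)
    def test_separable_toy_perfect_training_accuracy(self, kind, separable_features):
        features, labels = separable_features
        learner = train_base_learner(kind, features, labels, seed=0)
        probs = learner.predict_proba(features.to_numpy())
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-9)
        preds = probs.argmax(axis=1)
        assert np.array_equal(preds, [int(l) for l in labels])

    def test_rf100_deterministic_given_seed(self, separable_features):
        features, labels = separable_features
        p1 = train_base_learner("RF100", features, labels, seed=7).predict_proba(
            features.to_numpy()
        )
        p2 = train_base_learner("RF100", features, labels, seed=7).predict_proba(
            features.to_numpy()
        )
        assert np.array_equal(p1, p2)

    def test_single_class_labels_rejected(self, separable_features):
        features, _ = separable_features
        with pytest.raises(ValueError, match="single class"):
            train_base_learner("RF100", features, [ClassLabel.ABC] * len(features))


class TestEnsemble:
    def test_default_call_has_four_learners(self, wright_ensemble):
        ensemble, _, _ = wright_ensemble
        assert len(ensemble.learners) == 4
        assert ensemble.kinds == list(KINDS)

    def test_single_kind_degenerate_ensemble(self, separable_features):
        features, labels = separable_features
        ens = train_ensemble(features, labels, kinds=["RF100"], seed=0)
        assert len(ens.learners) == 1
        calls = predict(ens, features)
        solo = ens.learners[0].predict_proba(features.to_numpy())
        assert np.allclose([c.probs for c in calls], solo)

    def test_training_set_agreement_on_wright_like_cohort(self, wright_ensemble):
        ensemble, features, labels = wright_ensemble
        calls = predict(ensemble, features)
        agreement = np.mean([c.predicted == l for c, l in zip(calls, labels)])
        assert agreement >= 0.90

    def test_vote_is_arithmetic_mean(self):
        ens = _stub_ensemble([[0.6, 0.3, 0.1], [0.4, 0.5, 0.1]])
        X = pd.DataFrame([[0.0, 0.0]], index=["s"], columns=["gene1", "gene2"])
        (call,) = predict(ens, X)
        assert np.allclose(call.probs, [0.5, 0.4, 0.1])
        assert call.predicted == ClassLabel.ABC
        assert call.confidence == pytest.approx(0.5)

    def test_unanimous_vote(self):
        ens = _stub_ensemble([[0, 1, 0], [0, 1, 0]])
        X = pd.DataFrame([[0.0, 0.0]], index=["s"], columns=["gene1", "gene2"])
        (call,) = predict(ens, X)
        assert call.predicted == ClassLabel.GCB and call.confidence == 1.0

    def test_prediction_invariant_to_learner_order(self, wright_ensemble):
        ensemble, features, _ = wright_ensemble
        flipped = TrainedEnsemble(
            learners=list(reversed(ensemble.learners)),
            kinds=list(reversed(ensemble.kinds)),
            gene_list=ensemble.gene_list,
            training_fingerprint=ensemble.training_fingerprint,
            seed=ensemble.seed,
        )
        c1 = predict(ensemble, features.head(20))
        c2 = predict(flipped, features.head(20))
        assert all(np.allclose(a.probs, b.probs) for a, b in zip(c1, c2))

    def test_canonical_tie_break(self):
        call = ClassCall.from_probs("s", np.array([0.4, 0.4, 0.2]))
        assert call.predicted == ClassLabel.ABC

    def test_empty_features_rejected(self, wright_ensemble):
        ensemble, features, _ = wright_ensemble
        with pytest.raises(ValueError, match="empty"):
            predict(ensemble, features.iloc[0:0])


class TestConfidenceThreshold:
    def _call(self, conf):
        rest = (1 - conf) / 2
        return ClassCall.from_probs("s", np.array([conf, rest, rest]))

    def test_below_threshold_reassigned(self):
        (out,) = apply_confidence_threshold([self._call(0.55)], 0.6)
        assert out.predicted == ClassLabel.TYPE_III
        assert np.allclose(out.probs, self._call(0.55).probs)  # probs untouched

    def test_strictly_above_threshold_unchanged(self):
        (out,) = apply_confidence_threshold([self._call(0.55)], 0.5)
        assert out.predicted == ClassLabel.ABC

    def test_tau_zero_is_identity(self):
        calls = [self._call(c) for c in (0.4, 0.6, 0.9)]
        out = apply_confidence_threshold(calls, 0.0)
        assert [c.predicted for c in out] == [c.predicted for c in calls]

    def test_monotone_in_tau(self):
        rng = np.random.default_rng(0)
        calls = [
            ClassCall.from_probs(f"s{i}", np.sort(rng.dirichlet([1, 1, 1]))[::-1])
            for i in range(50)
        ]
        taus = [0.3, 0.5, 0.7, 0.9]
        t3_sets = []
        for tau in taus:
            out = apply_confidence_threshold(calls, tau)
            t3_sets.append({c.sample_id for c in out if c.predicted == ClassLabel.TYPE_III})
        for small, big in zip(t3_sets, t3_sets[1:]):
            assert small <= big


class TestLPS:
    def _toy(self):
        rng = np.random.default_rng(1)
        n = 12
        f = pd.DataFrame({
            "g1": np.concatenate([rng.normal(2, 1, n), rng.normal(-2, 1, n)]),
            "g2": np.concatenate([rng.normal(-1, 1, n), rng.normal(1, 1, n)]),
        }, index=[f"s{i}" for i in range(2 * n)])
        labels = [ClassLabel.ABC] * n + [ClassLabel.GCB] * n
        return f, labels

    def test_weights_match_direct_t_statistic(self):
        f, labels = self._toy()
        model = train_lps(f, labels)
        a, b = f.iloc[:12], f.iloc[12:]
        for j, gene in enumerate(f.columns):
            t, _ = stats.ttest_ind(a[gene], b[gene], equal_var=True)
            assert model.weights[j] == pytest.approx(t, abs=1e-9)

    def test_identical_gene_gets_zero_weight(self):
        f, labels = self._toy()
        f = f.assign(flat=1.0)
        model = train_lps(f, labels)
        assert model.weights[-1] == 0.0

    def test_swapping_labels_negates_weights(self):
        f, labels = self._toy()
        swapped = [ClassLabel.GCB if l == ClassLabel.ABC else ClassLabel.ABC for l in labels]
        w1 = train_lps(f, labels).weights
        w2 = train_lps(f, swapped).weights
        assert np.allclose(w1, -w2)

    def test_type_iii_cases_do_not_change_weights(self):
        f, labels = self._toy()
        extra = pd.DataFrame(
            {"g1": [0.1, -0.2], "g2": [0.0, 0.3]}, index=["t1", "t2"]
        )
        w1 = train_lps(f, labels).weights
        w2 = train_lps(
            pd.concat([f, extra]), labels + [ClassLabel.TYPE_III] * 2
        ).weights
        assert np.allclose(w1, w2)

    def test_too_few_cases_rejected(self):
        f, _ = self._toy()
        labels = [ClassLabel.ABC] + [ClassLabel.GCB] * (len(f) - 1)
        with pytest.raises(ValueError, match=">=2"):
            train_lps(f, labels)

    def _sym_model(self):
        return LPSModel(
            gene_list=["g"], weights=np.array([1.0]),
            mu_abc=3.0, sigma_abc=1.0, mu_gcb=-3.0, sigma_gcb=1.0,
        )

    def test_midpoint_score_is_type_iii(self):
        model = self._sym_model()
        X = pd.DataFrame({"g": [0.0]}, index=["s"])
        (call,) = predict_lps(model, X, tau=0.5)
        assert call.probs[0] == pytest.approx(0.5)
        assert call.predicted == ClassLabel.TYPE_III

    def test_score_at_class_mean_with_6_sigma_separation(self):
        model = self._sym_model()
        X = pd.DataFrame({"g": [3.0]}, index=["s"])
        (call,) = predict_lps(model, X, tau=0.9)
        assert call.probs[0] > 0.99
        assert call.predicted == ClassLabel.ABC

    def test_posteriors_sum_to_one(self):
        model = self._sym_model()
        X = pd.DataFrame({"g": np.linspace(-10, 10, 21)})
        calls = predict_lps(model, X, tau=0.8)
        for c in calls:
            assert c.probs[0] + c.probs[1] == pytest.approx(1.0, abs=1e-12)

    def test_higher_threshold_assigns_more_type_iii(self):
        f, labels = self._toy()
        model = train_lps(f, labels)
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.normal(0, 1.5, size=(200, 2)), columns=["g1", "g2"])
        n_t3 = {
            tau: sum(c.predicted == ClassLabel.TYPE_III for c in predict_lps(model, X, tau))
            for tau in (0.8, 0.9)
        }
        assert n_t3[0.9] >= n_t3[0.8]


class TestSingleSampleMode:
    def test_background_size_warning_boundary(self, wright_ensemble, caplog):
        ensemble, _, _ = wright_ensemble
        sample_mat, smap, _ = simulate_cohort(CohortSpec(n_samples=2, seed=5))
        for n_bg, expect_warning in ((30, True), (31, False)):
            bg, bmap, _ = simulate_cohort(CohortSpec(n_samples=n_bg, seed=6))
            with caplog.at_level("WARNING", logger="dac.classifier"):
                caplog.clear()
                classify_single_samples(sample_mat, bg, ensemble, probe_map=bmap)
            warned = any("background" in r.message for r in caplog.records)
            assert warned == expect_warning

    def test_no_shared_rows_rejected(self, wright_ensemble):
        ensemble, _, _ = wright_ensemble
        a = ExpressionMatrix(
            pd.DataFrame([[1.0, 2.0]], index=["p1"], columns=["s1", "s2"]),
            level=Level.PROBE,
        )
        b = ExpressionMatrix(
            pd.DataFrame([[1.0, 2.0]], index=["q1"], columns=["b1", "b2"]),
            level=Level.PROBE,
        )
        with pytest.raises(ValueError, match="share no rows"):
            classify_single_samples(a, b, ensemble)
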