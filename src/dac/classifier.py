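"""The DLBCL Automatic Classifier (DAC) and the LPS comparator.

DAC assigns cell-of-origin class (ABC / GCB / Type-III) by balanced voting:
four probabilistic learners are trained on the same classifier-gene Z-scores
and their class-probability vectors are combined with the average-of-
probabilities rule; the class with the highest averaged probability wins,
with no hard threshold by default.

The linear predictor score (LPS) comparator computes a weighted sum of gene
Z-scores with two-sample t-statistic weights, fits normal score
distributions to the ABC and GCB training cases, and assigns a class only
when the Bayesian posterior under those two normals exceeds a threshold
(0.8 or 0.9); everything else is Type-III/unclassified.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from enum import IntEnum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .io_formats import ExpressionMatrix, Level
from .preprocess import assemble_features, gene_zscores, merge_probes, quantile_normalize

log = logging.getLogger(__name__)


class ClassLabel(IntEnum):
    """Cell-of-origin classes in canonical (tie-breaking) order."""

    ABC = 0
    GCB = 1
    TYPE_III = 2

    @property
    def display(self) -> str:
        return {"ABC": "ABC", "GCB": "GCB", "TYPE_III": "Type-III"}[self.name]

    @classmethod
    def from_string(cls, s: str) -> "ClassLabel":
        key = s.strip().upper().replace("-", "_").replace("TYPE_III", "TYPE_III")
        aliases = {"ABC": cls.ABC, "GCB": cls.GCB, "TYPE_III": cls.TYPE_III,
                   "UNCLASSIFIED": cls.TYPE_III, "TYPEIII": cls.TYPE_III}
        if key not in aliases:
            raise ValueError(f"unknown class label {s!r}")
        return aliases[key]


# Classifier genes identifiable from the main text (9 ABC-associated,
# 7 GCB-associated, plus BMF).  The original classifier used 20 genes; the
# remainder are published only in supplementary material, so the default
# list here is the 17 recoverable ones.  The list is configurable everywhere
# it is consumed.
ABC_CLASSIFIER_GENES = (
    "CCND2", "IRF4", "FUT8", "SH3BP5", "ENTPD1", "PIM1", "BLNK", "FOXP1", "TBC1D27",
)
GCB_CLASSIFIER_GENES = (
    "MME", "LMO2", "LRMP", "BCL6", "DENND3", "ITPKB", "SERPINA9",
)
DEFAULT_CLASSIFIER_GENES = list(ABC_CLASSIFIER_GENES + GCB_CLASSIFIER_GENES + ("BMF",))

DEFAULT_LEARNER_KINDS = ("LMT", "J48", "RF100", "SMO")


@dataclass
class ClassCall:
    """Predicted class for one sample plus the full 3-way confidence vector."""

    sample_id: str
    probs: np.ndarray  # (P_ABC, P_GCB, P_TypeIII)
    predicted: ClassLabel
    confidence: float

    @classmethod
    def from_probs(cls, sample_id: str, probs: np.ndarray) -> "ClassCall":
        probs = np.asarray(probs, dtype=float)
        pred = ClassLabel(int(np.argmax(probs)))  # argmax breaks ties canonically
        return cls(sample_id, probs, pred, float(probs[pred]))


class _CanonicalLearner:
    """Adapter giving any sklearn classifier the 3-class probability contract.

    Classes absent from the training labels get probability zero, so every
    learner emits a vector over (ABC, GCB, Type-III) that sums to one.
    """

    def __init__(self, estimator) -> None:
        self.estimator = estimator

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_CanonicalLearner":
        self.estimator.fit(X, y)
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        raw = self.estimator.predict_proba(X)
        out = np.zeros((raw.shape[0], 3))
        for j, cls in enumerate(self.estimator.classes_):
            out[:, int(cls)] = raw[:, j]
        return out


class _LaplaceSmoothedTree(DecisionTreeClassifier):
    """Pre-pruned decision tree whose leaf class frequencies are Laplace
    smoothed, so leaves never emit hard 0/1 probabilities (the C4.5-style
    behaviour the voting rule expects from its tree member)."""

    def predict_proba(self, X, check_input=True):
        leaves = self.apply(X, check_input=check_input)
        counts = self.tree_.value[leaves, 0, :] * self.tree_.weighted_n_node_samples[
            leaves, None
        ]
        smoothed = counts + 1.0
        return smoothed / smoothed.sum(axis=1, keepdims=True)


def _make_estimator(kind: str, seed: int):
    if kind == "RF100":
        return RandomForestClassifier(n_estimators=100, random_state=seed)
    if kind == "J48":
        return _LaplaceSmoothedTree(min_samples_leaf=5, random_state=seed)
    if kind == "SMO":
        # maximum-margin classifier; probabilities via Platt-style sigmoid
        # calibration fitted on the training data
        return CalibratedClassifierCV(
            SVC(kernel="linear", random_state=seed), method="sigmoid", cv=3,
            ensemble=False,
        )
    if kind == "LMT":
        # additive logistic model built from shallow trees: a functional
        # substitute for a logistic-model tree
        return GradientBoostingClassifier(random_state=seed)
    raise ValueError(f"unknown learner kind {kind!r}; choose from LMT/J48/RF100/SMO")


def train_base_learner(
    kind: str, features: pd.DataFrame, labels: Sequence[ClassLabel], seed: int = 0
) -> _CanonicalLearner:
    """Fit one probabilistic base learner on classifier-gene Z-scores.

    ``features`` is samples x genes; ``labels`` must cover at least two
    classes.  All learners are deterministic given the seed.
    """
    y = np.asarray([int(l) for l in labels])
    if len(np.unique(y)) < 2:
        raise ValueError("training labels cover a single class; need >=2")
    learner = _CanonicalLearner(_make_estimator(kind, seed))
    return learner.fit(features.to_numpy(dtype=float), y)


@dataclass
class TrainedEnsemble:
    """A fitted balanced-voting classifier: one learner per kind, a shared
    ordered gene list, and a fingerprint of the training data."""

    learners: list[_CanonicalLearner]
    kinds: list[str]
    gene_list: list[str]
    training_fingerprint: str
    seed: int


def _fingerprint(features: pd.DataFrame, labels: Sequence[ClassLabel]) -> str:
    h = hashlib.sha256()
    h.update(features.to_numpy(dtype=float).tobytes())
    h.update(",".join(features.columns).encode())
    h.update(bytes(int(l) for l in labels))
    return h.hexdigest()[:16]


def train_ensemble(
    features: pd.DataFrame,
    labels: Sequence[ClassLabel],
    kinds: Sequence[str] = DEFAULT_LEARNER_KINDS,
    seed: int = 0,
) -> TrainedEnsemble:
    """Train the balanced-voting ensemble (default: LMT, J48, RF100, SMO)."""
    if len(features) != len(labels):
        raise ValueError("features and labels disagree in length")
    learners = [train_base_learner(k, features, labels, seed=seed) for k in kinds]
    return TrainedEnsemble(
        learners=learners,
        kinds=list(kinds),
        gene_list=list(features.columns),
        training_fingerprint=_fingerprint(features, labels),
        seed=seed,
    )


def predict(ensemble: TrainedEnsemble, features: pd.DataFrame) -> list[ClassCall]:
    """Classify samples: probabilities are the arithmetic mean of the
    learners' vectors; the class with the highest mean wins (canonical
    tie-break ABC < GCB < Type-III on exact ties)."""
    if features.empty:
        raise ValueError("empty feature table")
    extra = [g for g in features.columns if g not in ensemble.gene_list]
    if extra:
        raise ValueError(f"features contain genes unknown to the ensemble: {extra}")
    X = features.reindex(columns=ensemble.gene_list).to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError(
            "feature table is missing ensemble genes; retrain the ensemble on "
            "the shared gene subset"
        )
    mean_probs = np.mean([lr.predict_proba(X) for lr in ensemble.learners], axis=0)
    return [
        ClassCall.from_probs(sid, mean_probs[i])
        for i, sid in enumerate(features.index)
    ]


def apply_confidence_threshold(calls: Sequence[ClassCall], tau: float) -> list[ClassCall]:
    """Reassign ABC/GCB calls with confidence <= tau to Type-III.

    Probability vectors are untouched; only the predicted label moves.  The
    operation is monotone in tau: raising the threshold can only grow the
    Type-III set.
    """
    if not 0.0 <= tau <= 1.0:
        raise ValueError("tau must lie in [0, 1]")
    out = []
    for c in calls:
        if c.predicted != ClassLabel.TYPE_III and c.confidence <= tau:
            out.append(ClassCall(c.sample_id, c.probs, ClassLabel.TYPE_III, c.confidence))
        else:
            out.append(c)
    return out


# --- LPS comparator --------------------------------------------------------

@dataclass
class LPSModel:
    """Linear predictor score model: t-statistic gene weights plus normal
    score distributions fitted to the ABC and GCB training cases."""

    gene_list: list[str]
    weights: np.ndarray
    mu_abc: float
    sigma_abc: float
    mu_gcb: float
    sigma_gcb: float

    def score(self, features: pd.DataFrame) -> np.ndarray:
        X = features.reindex(columns=self.gene_list).to_numpy(dtype=float)
        return X @ self.weights


def train_lps(features: pd.DataFrame, labels: Sequence[ClassLabel]) -> LPSModel:
    """Fit the LPS model.  Weight a_j is the pooled two-sample t-statistic of
    gene j between ABC and GCB training cases (Type-III cases are ignored);
    the per-class score distributions are fitted by sample mean/sd."""
    y = np.asarray([int(l) for l in labels])
    abc_mask, gcb_mask = y == ClassLabel.ABC, y == ClassLabel.GCB
    n1, n2 = int(abc_mask.sum()), int(gcb_mask.sum())
    if n1 < 2 or n2 < 2:
        raise ValueError("need >=2 ABC and >=2 GCB training cases")
    X = features.to_numpy(dtype=float)
    a, b = X[abc_mask], X[gcb_mask]
    m1, m2 = a.mean(axis=0), b.mean(axis=0)
    v1, v2 = a.var(axis=0, ddof=1), b.var(axis=0, ddof=1)
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    denom = np.sqrt(sp2 * (1 / n1 + 1 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        weights = np.where(denom > 0, (m1 - m2) / denom, 0.0)
    scores = X @ weights
    s_abc, s_gcb = scores[abc_mask], scores[gcb_mask]
    model = LPSModel(
        gene_list=list(features.columns),
        weights=weights,
        mu_abc=float(s_abc.mean()),
        sigma_abc=float(s_abc.std(ddof=1)),
        mu_gcb=float(s_gcb.mean()),
        sigma_gcb=float(s_gcb.std(ddof=1)),
    )
    if model.sigma_abc <= 0 or model.sigma_gcb <= 0:
        raise ValueError("degenerate LPS score distribution (sigma = 0)")
    return model


def _normal_pdf(x: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    z = (x - mu) / sigma
    return np.exp(-0.5 * z * z) / (sigma * np.sqrt(2 * np.pi))


def predict_lps(model: LPSModel, features: pd.DataFrame, tau: float = 0.9) -> list[ClassCall]:
    """Classify by LPS posterior.  P(ABC|S) is the normal-density Bayes ratio
    of the two fitted score distributions (equal priors); a class is assigned
    only when its posterior exceeds tau, otherwise Type-III.

    ClassCall.probs follows the (P_ABC, P_GCB, 0) convention: LPS defines no
    Type-III posterior, so Type-III shows up only in the predicted label.
    """
    if model.sigma_abc <= 0 or model.sigma_gcb <= 0:
        raise ValueError("LPS model has sigma = 0")
    s = model.score(features)
    f_abc = _normal_pdf(s, model.mu_abc, model.sigma_abc)
    f_gcb = _normal_pdf(s, model.mu_gcb, model.sigma_gcb)
    with np.errstate(invalid="ignore"):
        p_abc = f_abc / (f_abc + f_gcb)
    p_abc = np.where(np.isfinite(p_abc), p_abc, 0.5)  # both densities underflow
    calls = []
    for sid, pa in zip(features.index, p_abc):
        probs = np.array([pa, 1.0 - pa, 0.0])
        if pa > tau:
            pred = ClassLabel.ABC
        elif (1.0 - pa) > tau:
            pred = ClassLabel.GCB
        else:
            pred = ClassLabel.TYPE_III
        conf = float(probs[pred]) if pred != ClassLabel.TYPE_III else float(max(pa, 1 - pa))
        calls.append(ClassCall(str(sid), probs, pred, conf))
    return calls


# --- single-sample mode ----------------------------------------------------

def classify_single_samples(
    samples: ExpressionMatrix,
    background: ExpressionMatrix,
    ensemble: TrainedEnsemble,
    probe_map: Mapping[str, str] | None = None,
    merge_method: str = "median",
) -> list[ClassCall]:
    """Classify samples one at a time against a background cohort.

    Each sample is separately appended to the background (>30 samples of
    random class from an equivalent platform), the combined table is quantile
    normalised, probe-merged if probe-level, Z-scored, and only that sample's
    Z-row is classified.  Calls are returned in input order.
    """
    shared = [r for r in samples.values.index if r in set(background.values.index)]
    if not shared:
        raise ValueError("samples and background share no rows")
    if background.shape[1] <= 30:
        log.warning(
            "background has %d samples; >30 recommended for stable "
            "single-sample normalization", background.shape[1],
        )
    # namespace background columns so query ids can never collide with them
    bg = background.values.loc[shared]
    bg.columns = [f"BG::{c}" for c in bg.columns]
    calls: list[ClassCall] = []
    for sid in samples.sample_ids:
        combined = pd.concat([bg, samples.values.loc[shared, [sid]]], axis=1)
        mat = ExpressionMatrix(combined, level=background.level,
                               platform_name=background.platform_name)
        mat = quantile_normalize(mat)
        if mat.level == Level.PROBE:
            if probe_map is None:
                raise ValueError("probe-level input needs a probe_map")
            mat = merge_probes(mat, dict(probe_map), method=merge_method)
        zs = gene_zscores(mat)
        genes = [g for g in ensemble.gene_list if g in zs.z.index]
        if not genes:
            raise ValueError("no classifier genes shared with the background")
        feats, _ = assemble_features(zs, genes)
        if genes != ensemble.gene_list:
            raise ValueError(
                "background is missing ensemble genes "
                f"({sorted(set(ensemble.gene_list) - set(genes))}); retrain the "
                "ensemble on the shared subset first"
            )
        calls.append(predict(ensemble, feats.loc[[sid]])[0])
    return calls


def calls_to_frame(calls: Sequence[ClassCall]) -> pd.DataFrame:
    """Tabulate calls with the standard column set."""
    return pd.DataFrame(
        {
            "sample_id": [c.sample_id for c in calls],
            "P_ABC": [c.probs[0] for c in calls],
            "P_GCB": [c.probs[1] for c in calls],
            "P_TypeIII": [c.probs[2] for c in calls],
            "predicted": [c.predicted.display for c in calls],
            "confidence": [c.confidence for c in calls],
        }
    )
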