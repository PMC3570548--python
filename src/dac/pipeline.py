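"""Convenience composition of the standard preprocessing chain."""

from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd

from .classifier import DEFAULT_CLASSIFIER_GENES, ClassLabel, TrainedEnsemble, train_ensemble
from .io_formats import ExpressionMatrix, Level
from .preprocess import assemble_features, gene_zscores, merge_probes, quantile_normalize
from .synthetic import CohortSpec, simulate_cohort


def cohort_to_features(
    matrix: ExpressionMatrix,
    probe_map: Mapping[str, str] | None = None,
    classifier_genes: Sequence[str] | None = None,
    merge_method: str = "median",
) -> tuple[pd.DataFrame, list[str]]:
    """Quantile-normalise, merge probes (if probe level), Z-score and pull
    the classifier-gene feature table.  Returns (features, missing genes)."""
    genes = list(classifier_genes or DEFAULT_CLASSIFIER_GENES)
    mat = quantile_normalize(matrix)
    if mat.level == Level.PROBE:
        if probe_map is None:
            raise ValueError("probe-level matrix needs a probe_map")
        mat = merge_probes(mat, dict(probe_map), method=merge_method)
    zs = gene_zscores(mat)
    return assemble_features(zs, genes)


def cohort_to_gene_matrix(
    matrix: ExpressionMatrix,
    probe_map: Mapping[str, str] | None = None,
    merge_method: str = "median",
) -> ExpressionMatrix:
    """Quantile-normalise and collapse to one row per gene (full platform)."""
    mat = quantile_normalize(matrix)
    if mat.level == Level.PROBE:
        if probe_map is None:
            raise ValueError("probe-level matrix needs a probe_map")
        mat = merge_probes(mat, dict(probe_map), method=merge_method)
    return mat


def train_wright_like_ensemble(
    seed: int = 0, spec: CohortSpec | None = None
) -> tuple[TrainedEnsemble, pd.DataFrame, list[ClassLabel]]:
    """Simulate the Wright-like training cohort and fit the default DAC
    ensemble on it.  Returns (ensemble, training features, true labels)."""
    spec = spec or CohortSpec(seed=seed)
    matrix, probe_map, labels = simulate_cohort(spec)
    features, _ = cohort_to_features(
        matrix, probe_map, classifier_genes=list(spec.abc_genes + spec.gcb_genes)
    )
    ensemble = train_ensemble(features, labels, seed=seed)
    return ensemble, features, labels
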