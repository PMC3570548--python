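"""Quantile normalisation, probe->gene collapsing and per-gene Z-scoring.

These three steps turn a raw probe-level intensity table into the
standardised classifier features: every sample is forced onto a common
empirical distribution, multiple probes for a gene are merged (median rule,
or the average/max rule keyed on inter-probe correlation), and each gene is
standardised across samples.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import ExpressionMatrix, Level

log = logging.getLogger(__name__)

# Probes whose mean pairwise Pearson correlation exceeds this are averaged;
# at or below it the per-sample maximum is taken (MaxAvgMerge rule).
MAXAVG_CORRELATION_THRESHOLD = 0.2


@dataclass
class ZScoreMatrix:
    """Per-gene standard scores (genes x samples), with constant-gene flags."""

    z: pd.DataFrame
    constant_genes: list[str] = field(default_factory=list)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.z.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.z.columns)


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample onto the common distribution of row-rank means.

    After normalisation each column's sorted value vector equals the mean of
    the input columns' sorted vectors; within-column rank order is preserved.
    Ties within a column receive the mean of the rank-means they span, so the
    operation is deterministic and idempotent.
    """
    X = matrix.values.to_numpy(dtype=float)
    n_rows, n_cols = X.shape
    if n_cols < 2:
        raise ValueError(
            "quantile normalization needs >=2 samples; use single-sample mode "
            "(classify_single_samples with a background cohort) for one sample"
        )
    ref = np.sort(X, axis=0).mean(axis=1)  # rank-mean reference distribution
    out = np.empty_like(X)
    for j in range(n_cols):
        col = X[:, j]
        order = np.argsort(col, kind="mergesort")
        normalized = ref.copy()
        # ties: average the reference values over the tied span
        sorted_col = col[order]
        i = 0
        while i < n_rows:
            k = i
            while k + 1 < n_rows and sorted_col[k + 1] == sorted_col[i]:
                k += 1
            if k > i:
                normalized[i : k + 1] = ref[i : k + 1].mean()
            i = k + 1
        out[order, j] = normalized
    df = pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    return ExpressionMatrix(df, level=matrix.level, platform_name=matrix.platform_name)


def merge_probes(
    matrix: ExpressionMatrix,
    probe_map: dict[str, str],
    method: str = "median",
) -> ExpressionMatrix:
    """Collapse probe rows to one row per gene.

    ``method="median"`` takes the per-sample median over a gene's probes.
    ``method="maxavg"`` averages the probes per sample when their mean
    pairwise Pearson correlation across samples exceeds 0.2, and otherwise
    takes the per-sample element-wise maximum.  Probes without a map entry
    are dropped (count logged).
    """
    if method not in ("median", "maxavg"):
        raise ValueError(f"method must be 'median' or 'maxavg', got {method!r}")
    mapped = {p: g for p, g in probe_map.items() if p in matrix.values.index}
    unmapped = [p for p in matrix.values.index if p not in mapped]
    if unmapped:
        log.info("merge_probes: dropping %d unmapped probes", len(unmapped))
    by_gene: dict[str, list[str]] = {}
    for probe, gene in mapped.items():
        by_gene.setdefault(gene, []).append(probe)
    genes = sorted(by_gene)
    out = np.empty((len(genes), matrix.shape[1]))
    for i, gene in enumerate(genes):
        block = matrix.values.loc[by_gene[gene]].to_numpy(dtype=float)
        if block.shape[0] == 1:
            out[i] = block[0]
        elif method == "median":
            out[i] = np.median(block, axis=0)
        else:
            out[i] = _maxavg_collapse(block)
    df = pd.DataFrame(out, index=genes, columns=matrix.values.columns)
    return ExpressionMatrix(df, level=Level.GENE, platform_name=matrix.platform_name)


def _maxavg_collapse(block: np.ndarray) -> np.ndarray:
    """Average probes if mean pairwise r > 0.2, else per-sample maximum.

    A single threshold decision is made per gene using the mean over all
    probe pairs; correlations undefined because a probe is constant count
    as 0.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant probes yield nan correlations
        corr = np.corrcoef(block)
    iu = np.triu_indices(block.shape[0], k=1)
    pair_r = np.nan_to_num(corr[iu], nan=0.0)
    if pair_r.mean() > MAXAVG_CORRELATION_THRESHOLD:
        return block.mean(axis=0)
    return block.max(axis=0)


def gene_zscores(matrix: ExpressionMatrix) -> ZScoreMatrix:
    """Standardise each gene across samples: (x - mean) / sd, sample sd
    (ddof=1).  Constant genes become all-zero rows and are flagged.
    """
    if matrix.level != Level.GENE:
        raise ValueError("gene_zscores requires a GENE-level matrix; merge probes first")
    if matrix.shape[1] < 2:
        raise ValueError("gene_zscores needs >=2 samples")
    X = matrix.values.to_numpy(dtype=float)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    constant = sd[:, 0] == 0
    sd[constant] = 1.0
    z = (X - mu) / sd
    z[constant] = 0.0
    flagged = [g for g, c in zip(matrix.row_ids, constant) if c]
    if flagged:
        log.warning("gene_zscores: %d constant genes set to zero", len(flagged))
    return ZScoreMatrix(
        pd.DataFrame(z, index=matrix.values.index, columns=matrix.values.columns),
        constant_genes=flagged,
    )


def assemble_features(
    zmatrix: ZScoreMatrix, classifier_genes: list[str]
) -> tuple[pd.DataFrame, list[str]]:
    """Build the samples x classifier-genes feature table.

    Requested genes absent from the matrix are omitted from the table and
    returned in the missing-gene report (platforms differ in gene content;
    the classifier uses as many of its genes as the platform carries).
    """
    if not classifier_genes:
        raise ValueError("classifier gene list is empty")
    present = [g for g in classifier_genes if g in zmatrix.z.index]
    missing = [g for g in classifier_genes if g not in zmatrix.z.index]
    if not present:
        raise ValueError("none of the classifier genes are present in the matrix")
    features = zmatrix.z.loc[present].T.copy()
    features.columns = present
    return features, missing
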