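"""Classifier-gene ranking: information gain, correlation-based subset
selection (CFS), and consensus ranks across data sets."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .classifier import ClassLabel


@dataclass
class GeneRanking:
    """Ordered (gene, score) pairs with method and dataset tags."""

    entries: list[tuple[str, float]]
    method: str = ""
    dataset: str = ""

    @property
    def genes(self) -> list[str]:
        return [g for g, _ in self.entries]

    def __len__(self) -> int:
        return len(self.entries)


def _entropy(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log2(p)).sum())


def _equal_frequency_bins(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Discretise by equal-frequency binning (scale-free: depends only on
    ranks).  Duplicate quantile edges collapse, so constant vectors land in
    a single bin."""
    qs = np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1])
    return np.searchsorted(qs, x, side="left")


def info_gain_rank(
    features: pd.DataFrame,
    labels: Sequence[ClassLabel],
    n_bins: int = 10,
    dataset: str = "",
) -> GeneRanking:
    """Rank genes by information gain about the class label.

    IG(gene) = H(class) - H(class | discretised gene), with equal-frequency
    binning; constant genes score 0.  Scores are in bits, bounded by the
    class entropy.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >=2")
    y = np.asarray([int(l) for l in labels])
    class_counts = np.bincount(y, minlength=3)
    h_class = _entropy(class_counts.astype(float))
    n = len(y)
    scores = {}
    for gene in features.columns:
        bins = _equal_frequency_bins(features[gene].to_numpy(dtype=float), n_bins)
        h_cond = 0.0
        for b in np.unique(bins):
            mask = bins == b
            h_cond += mask.sum() / n * _entropy(np.bincount(y[mask], minlength=3).astype(float))
        scores[gene] = h_class - h_cond
    ordered = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    return GeneRanking(ordered, method=f"infogain(bins={n_bins})", dataset=dataset)


def _class_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Mean absolute point-biserial correlation of a gene against one-vs-rest
    class indicators (the scalar gene-class correlation CFS needs for a
    3-class label)."""
    rs = []
    for cls in np.unique(y):
        ind = (y == cls).astype(float)
        sx, si = x.std(), ind.std()
        if sx == 0 or si == 0:
            rs.append(0.0)
        else:
            rs.append(abs(float(np.corrcoef(x, ind)[0, 1])))
    return float(np.mean(rs))


def cfs_merit(r_cf: np.ndarray, r_ff_sum: float, k: int) -> float:
    """CFS subset merit: k*mean|r_cf| / sqrt(k + k(k-1)*mean|r_ff|)."""
    rbar_cf = float(np.mean(r_cf))
    rbar_ff = r_ff_sum / (k * (k - 1) / 2) if k > 1 else 0.0
    return k * rbar_cf / np.sqrt(k + k * (k - 1) * rbar_ff)


def cfs_select(
    features: pd.DataFrame,
    labels: Sequence[ClassLabel],
    max_genes: int | None = None,
    dataset: str = "",
) -> GeneRanking:
    """Greedy stepwise forward selection maximising the CFS merit.

    The merit of a subset rewards genes correlated with the class and
    penalises redundancy between genes.  Output order is the order of
    inclusion; each score is the subset merit at the moment of inclusion.
    Selection stops when no remaining gene improves the merit (or at
    ``max_genes``).
    """
    genes = list(features.columns)
    if len(genes) < 2:
        raise ValueError("cfs_select needs >=2 genes")
    y = np.asarray([int(l) for l in labels])
    X = features.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        r_cf = np.array([_class_correlation(X[:, j], y) for j in range(X.shape[1])])
    # gene-gene |correlation| matrix; constant genes contribute 0
    sd = X.std(axis=0)
    Xs = np.where(sd > 0, (X - X.mean(axis=0)) / np.where(sd == 0, 1, sd), 0.0)
    r_ff = np.abs(Xs.T @ Xs / X.shape[0])
    np.fill_diagonal(r_ff, 0.0)
    r_ff = np.nan_to_num(r_ff, nan=0.0)

    max_genes = max_genes or len(genes)
    selected: list[int] = []
    entries: list[tuple[str, float]] = []
    best_merit = -np.inf
    while len(selected) < max_genes:
        best_j, best_new = -1, best_merit
        for j in range(len(genes)):
            if j in selected:
                continue
            k = len(selected) + 1
            cf = r_cf[selected + [j]]
            ff_sum = sum(r_ff[a, b] for ia, a in enumerate(selected + [j])
                         for b in (selected + [j])[ia + 1:])
            m = cfs_merit(cf, ff_sum, k)
            if m > best_new + 1e-12:
                best_new, best_j = m, j
        if best_j < 0:
            break
        selected.append(best_j)
        best_merit = best_new
        entries.append((genes[best_j], float(best_new)))
    return GeneRanking(entries, method="cfs(greedy-forward)", dataset=dataset)


def consensus_rank(rankings: Sequence[GeneRanking]) -> GeneRanking:
    """Average ranks across data sets: a gene absent from a ranking is
    imputed rank len(ranking)+1; output is ordered by mean rank ascending
    with alphabetical tie-break.  Scores are the mean ranks."""
    if len(rankings) < 2:
        raise ValueError("consensus_rank needs >=2 rankings")
    all_genes = sorted({g for r in rankings for g in r.genes})
    mean_ranks = {}
    for gene in all_genes:
        ranks = []
        for r in rankings:
            try:
                ranks.append(r.genes.index(gene) + 1)
            except ValueError:
                ranks.append(len(r) + 1)
        mean_ranks[gene] = float(np.mean(ranks))
    ordered = sorted(mean_ranks.items(), key=lambda kv: (kv[1], kv[0]))
    return GeneRanking(ordered, method="consensus(mean-rank)")


def two_stage_rank(
    features: pd.DataFrame,
    labels: Sequence[ClassLabel],
    n_top: int = 1000,
    n_bins: int = 10,
    dataset: str = "",
) -> GeneRanking:
    """Whole-platform ranking: information gain first, then CFS on the top
    ``n_top`` survivors (all genes if the platform has fewer)."""
    ig = info_gain_rank(features, labels, n_bins=n_bins, dataset=dataset)
    survivors = ig.genes[:n_top]
    return cfs_select(features[survivors], labels, dataset=dataset)
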