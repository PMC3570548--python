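"""Cross-dataset meta-analysis of class-associated genes.

Builds meta-profiles (genes consistently class-associated across data
sets), measures pairwise dataset concordance, and screens gene-signature
collections for enrichment with a hypergeometric test backed by
Monte-Carlo empirical-null Z-scores: random draws of the profile size are
taken from the platform population and the observed overlap is standardised
against the mean and sd of the sampled overlap distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .diffexp import benjamini_hochberg
from .io_formats import GeneSignature

log = logging.getLogger(__name__)

DEFAULT_SIGNATURE_SAMPLINGS = 1_000_000   # signature screen null
DEFAULT_PAIRWISE_SAMPLINGS = 10_000_000   # pairwise dataset concordance null


@dataclass
class EnrichmentResult:
    """One signature's overlap with a profile, with exact and empirical nulls."""

    name: str
    source: str
    overlap: int            # k
    sig_size: int           # K' (after classifier-gene removal)
    draw_size: int          # n
    population_size: int    # N
    random_avg: float
    random_sd: float
    pct_overlap: float      # 100*k/K'
    z: float
    p: float                # hypergeometric tail in the favoured direction
    fdr: float = np.nan
    enriched: bool = True
    contributing_genes: list[str] = field(default_factory=list)
    excluded_genes: list[str] = field(default_factory=list)


def hypergeometric_test(k: int, K: int, n: int, N: int) -> tuple[float, float]:
    """Exact overlap test: draw n from a population of N containing K
    successes and observe k hits.

    Returns (P(X >= k), P(X <= k)); the enrichment direction is whichever
    tail is smaller.
    """
    if not (0 <= k <= min(n, K) <= N) or n > N:
        raise ValueError(f"inconsistent counts k={k}, K={K}, n={n}, N={N}")
    rv = stats.hypergeom(N, K, n)
    p_enriched = float(rv.sf(k - 1))
    p_depleted = float(rv.cdf(k))
    return p_enriched, p_depleted


def mc_null_moments(
    K: int, n: int, N: int, n_samplings: int = DEFAULT_SIGNATURE_SAMPLINGS,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Monte-Carlo null for the overlap count: repeatedly draw n genes
    without replacement from N and count hits among the K signature genes.
    Returns the sample mean and sd of the hit count."""
    if n > N:
        raise ValueError("cannot draw more genes than the population holds")
    if n_samplings < 1_000:
        raise ValueError("n_samplings must be >=1000 for a stable null")
    if K == 0:
        return 0.0, 0.0
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    draws = rng.hypergeometric(K, N - K, n, size=n_samplings)
    return float(draws.mean()), float(draws.std(ddof=1))


def pct_overlap(overlap: int, sig_size: int) -> float:
    """Percentage of the signature covered by the profile: 100*k/K'."""
    if sig_size <= 0:
        raise ValueError("signature size must be positive")
    return 100.0 * overlap / sig_size


def signature_enrichment(
    profile_genes: Iterable[str],
    signatures: Sequence[GeneSignature],
    population: Iterable[str],
    classifier_genes: Iterable[str] = (),
    alpha: float = 0.05,
    n_samplings: int = DEFAULT_SIGNATURE_SAMPLINGS,
    seed: int = 0,
) -> list[EnrichmentResult]:
    """Screen a signature collection against a gene profile.

    Classifier genes are removed from every signature, from the draw
    (profile) and from the population before testing, since they are biased
    by construction; the removed members of each signature are reported
    separately.  Signatures left empty after removal/population restriction
    are skipped.  FDR is BH across all signatures actually tested, computed
    on the hypergeometric tail p in the favoured direction; the Monte-Carlo
    Z is reported alongside.
    """
    excl = set(classifier_genes)
    pop = set(population) - excl
    profile = (set(profile_genes) & pop) - excl
    n, N = len(profile), len(pop)
    if n == 0:
        raise ValueError("profile is empty after population restriction")
    rng = np.random.default_rng(seed)
    results: list[EnrichmentResult] = []
    moment_cache: dict[int, tuple[float, float]] = {}
    for sig in signatures:
        sig_pop = (sig.genes & pop) - excl
        Kp = len(sig_pop)
        if Kp == 0:
            log.info("signature %s empty after classifier-gene removal; skipped", sig.name)
            continue
        overlap_genes = sorted(profile & sig_pop)
        k = len(overlap_genes)
        p_enr, p_dep = hypergeometric_test(k, Kp, n, N)
        if Kp not in moment_cache:
            moment_cache[Kp] = mc_null_moments(Kp, n, N, n_samplings, seed=rng)
        mu, sd = moment_cache[Kp]
        z = (k - mu) / sd if sd > 0 else 0.0
        enriched = p_enr < p_dep
        results.append(EnrichmentResult(
            name=sig.name, source=sig.source, overlap=k, sig_size=Kp,
            draw_size=n, population_size=N, random_avg=mu, random_sd=sd,
            pct_overlap=pct_overlap(k, Kp), z=float(z),
            p=p_enr if enriched else p_dep, enriched=enriched,
            contributing_genes=overlap_genes,
            excluded_genes=sorted(sig.genes & excl),
        ))
    fdrs = benjamini_hochberg(np.array([r.p for r in results]))
    for r, f in zip(results, fdrs):
        r.fdr = float(f)
    return results


def enrichment_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    """Tabulate enrichment results with the standard reporting columns
    (%Overlap and Z-score rounded to 2 decimals for comparability)."""
    return pd.DataFrame({
        "Gene Signature": [r.name for r in results],
        "Overlapping": [r.overlap for r in results],
        "GeneSigSize": [r.sig_size for r in results],
        "randomAvg": [round(r.random_avg, 2) for r in results],
        "randomSD": [round(r.random_sd, 2) for r in results],
        "%Overlap": [round(r.pct_overlap, 2) for r in results],
        "Zscore": [round(r.z, 2) for r in results],
        "FDR": [r.fdr for r in results],
        "Source": [r.source for r in results],
        "EnrichedGenes": [
            "|".join(r.contributing_genes)
            + ("|EXCLUDED_GENES:" + "|".join(r.excluded_genes) if r.excluded_genes else "")
            for r in results
        ],
    })


def pairwise_dataset_concordance(
    class_lists_by_dataset: Mapping[str, tuple[Iterable[str], Iterable[str]]],
    populations: Mapping[str, Iterable[str]],
    n_samplings: int = DEFAULT_PAIRWISE_SAMPLINGS,
    seed: int = 0,
) -> pd.DataFrame:
    """Averaged concordance Z between every pair of classified data sets.

    For an ordered pair (d1, d2) and one class, dataset-2's class list is
    the signature, dataset-1's list the draw, and dataset-1's platform the
    population.  The four Z-scores (two directions x ABC/GCB) are averaged
    into one symmetric cell; the diagonal is NaN, as is any cell involving a
    data set with an empty class list.
    """
    names = list(class_lists_by_dataset)
    pops = {d: set(populations[d]) for d in names}
    rng = np.random.default_rng(seed)

    def one_direction(d1: str, d2: str, cls_idx: int) -> float:
        draw = set(class_lists_by_dataset[d1][cls_idx]) & pops[d1]
        sig = set(class_lists_by_dataset[d2][cls_idx]) & pops[d1]
        if not draw or not sig:
            return np.nan
        N, n, K = len(pops[d1]), len(draw), len(sig)
        k = len(draw & sig)
        mu, sd = mc_null_moments(K, n, N, n_samplings, seed=rng)
        return (k - mu) / sd if sd > 0 else 0.0

    out = pd.DataFrame(np.nan, index=names, columns=names, dtype=float)
    for i, d1 in enumerate(names):
        for d2 in names[i + 1:]:
            zs = [one_direction(a, b, c)
                  for a, b in ((d1, d2), (d2, d1)) for c in (0, 1)]
            cell = np.nan if np.isnan(zs).any() else float(np.mean(zs))
            out.loc[d1, d2] = out.loc[d2, d1] = cell
    return out


@dataclass
class MetaProfileRow:
    """One meta-profile gene: consistency count and median normalised FC."""

    gene: str
    median_nfc: float
    num_files: int
    pct_present: float
    per_dataset_fc: dict[str, float]


def build_meta_profile(
    class_lists_by_dataset: Mapping[str, Iterable[str]],
    nfc_by_dataset: Mapping[str, Mapping[str, float]],
    min_datasets: int = 6,
    platform_genes_by_dataset: Mapping[str, Iterable[str]] | None = None,
) -> list[MetaProfileRow]:
    """Rank genes by consistency of class association across data sets.

    ``class_lists_by_dataset`` gives one class's associated genes per data
    set and ``nfc_by_dataset`` the matching normalised fold changes.  A gene
    is kept when class-associated in >= ``min_datasets`` data sets; rows are
    sorted by (num_files desc, median_nfc desc).  pct_present counts only
    the data sets whose platform carries the gene (all data sets when
    platform content is not supplied).
    """
    datasets = list(class_lists_by_dataset)
    carriers = {
        d: set(platform_genes_by_dataset[d]) if platform_genes_by_dataset else None
        for d in datasets
    }
    genes = sorted({g for d in datasets for g in class_lists_by_dataset[d]})
    rows = []
    for gene in genes:
        assoc = [d for d in datasets if gene in set(class_lists_by_dataset[d])]
        if len(assoc) < min_datasets:
            continue
        nfcs = [nfc_by_dataset[d][gene] for d in assoc if gene in nfc_by_dataset[d]]
        present = [
            d for d in datasets
            if carriers[d] is None or gene in carriers[d]
        ]
        rows.append(MetaProfileRow(
            gene=gene,
            median_nfc=float(np.median(nfcs)) if nfcs else np.nan,
            num_files=len(assoc),
            pct_present=100.0 * len(assoc) / len(present) if present else np.nan,
            per_dataset_fc={d: nfc_by_dataset[d].get(gene, np.nan) for d in datasets},
        ))
    rows.sort(key=lambda r: (-r.num_files, -r.median_nfc, r.gene))
    return rows


def per_dataset_consistency(
    enrichments_by_dataset: Mapping[str, Sequence[EnrichmentResult]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Summarise a signature screen run per data set.

    Per signature: the number of data sets where it is significant
    (FDR < alpha), mean/sd of its Z-scores, whether all Z-scores share a
    sign, and a per-dataset annotation string using '+' (enriched),
    '-' (depleted) and '*' (not significant).
    """
    datasets = list(enrichments_by_dataset)
    by_sig: dict[str, dict[str, EnrichmentResult]] = {}
    for ds in datasets:
        for r in enrichments_by_dataset[ds]:
            by_sig.setdefault(r.name, {})[ds] = r
    rows = []
    for name, per_ds in by_sig.items():
        zs = [per_ds[d].z for d in datasets if d in per_ds]
        sig_flags = {
            d: (per_ds[d].fdr < alpha) if d in per_ds else False for d in datasets
        }
        annot = []
        for d in datasets:
            if d not in per_ds or not sig_flags[d]:
                annot.append("*")
            else:
                annot.append("+" if per_ds[d].z > 0 else "-")
        rows.append({
            "Gene Signature": name,
            "Number_of_Samples": int(sum(sig_flags.values())),
            "avgZscore": float(np.mean(zs)),
            "sdZscore": float(np.std(zs, ddof=1)) if len(zs) > 1 else 0.0,
            "ZscoresAllSameSign": bool(np.all(np.array(zs) > 0) or np.all(np.array(zs) < 0)),
            "Annotation": "".join(annot),
        })
    return pd.DataFrame(rows).set_index("Gene Signature")


def cytoband_consistency(
    cytoband_enrichments_by_dataset: Mapping[str, Sequence[EnrichmentResult]],
    meta_profile_enrichment: Sequence[EnrichmentResult],
    min_datasets: int = 6,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Report cytobands consistently enriched across data sets.

    A cytoband signature is included when significantly enriched in
    >= ``min_datasets`` data sets (i.e. more than half of 11); its average Z
    is reported together with a two-tier flag from the meta-profile screen
    (FDR < 0.05 -> tier 1, FDR < 0.1 -> tier 2, else 0).
    """
    summary = per_dataset_consistency(cytoband_enrichments_by_dataset, alpha=alpha)
    meta_fdr = {r.name: r.fdr for r in meta_profile_enrichment}
    kept = summary[summary["Number_of_Samples"] >= min_datasets].copy()
    tiers = []
    for name in kept.index:
        f = meta_fdr.get(name, np.nan)
        tiers.append(1 if f < 0.05 else (2 if f < 0.1 else 0))
    kept["meta_profile_tier"] = tiers
    return kept[["Number_of_Samples", "avgZscore", "meta_profile_tier"]]
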