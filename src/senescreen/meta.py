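"""Random-effects meta-analysis of heritability enrichment across traits.

Per trait and gene set, S-LDSC yields the inside-vs-outside per-SNP
heritability difference d = h2_a/|a| - (h2 - h2_a)/(p - |a|) with a
block-jackknife SE. Within a trait group (e.g. aging vs non-aging, or an
organ system) these are pooled by DerSimonian–Laird random-effects
meta-analysis and tested one-sided for d > 0. Gene sets are compared by a
normal z on the difference of pooled estimates, traits are clustered on
their enrichment profiles, and cluster labels are tested for association
with the aging annotation by Fisher's exact test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from sklearn.base import BaseEstimator

from .heritability import SldscRegression

__all__ = ["MetaResult", "RandomEffectsMeta", "per_snp_difference",
           "random_effects_meta", "one_sided_test", "compare_gene_sets",
           "compare_gene_sets_paired", "select_and_cluster_traits",
           "cluster_group_association"]


def per_snp_difference(fit: SldscRegression, annotation: str) -> tuple[float, float]:
    """(d, SE_d): per-SNP heritability inside minus outside an annotation.

    d = h2_a/|a| - (h2 - h2_a)/(p - |a|); the SE comes from the fit's
    delete-one-block jackknife. Undefined (raises) when the annotation
    covers no SNP or every SNP.
    """
    size = fit.annot_sizes_[annotation]
    if size in (0, fit.snp_count_):
        raise ValueError(
            f"per-SNP difference undefined for |a|={int(size)} of "
            f"{fit.snp_count_} SNPs")
    return float(fit.d_[annotation]), float(fit.d_se_[annotation])


@dataclass
class MetaResult:
    pooled: float
    se: float
    tau2: float          # between-study variance (DerSimonian-Laird)
    n_studies: int

    @property
    def z(self) -> float:
        return self.pooled / self.se

    @property
    def p_one_sided(self) -> float:
        return float(stats.norm.sf(self.z))


class RandomEffectsMeta(BaseEstimator):
    """DerSimonian–Laird random-effects pooling of estimates and SEs.

    tau2 = max(0, (Q - (n-1)) / (sum w - sum w^2 / sum w)) with w = 1/se^2;
    pooled = sum(w* est)/sum w*, w* = 1/(se^2 + tau2); SE = 1/sqrt(sum w*).
    A single study is returned unchanged (tau2 = 0).
    """

    def fit(self, estimates, ses):
        est = np.asarray(estimates, dtype=float)
        se = np.asarray(ses, dtype=float)
        if est.size == 0:
            raise ValueError("meta-analysis needs at least one study")
        if np.any(se <= 0):
            raise ValueError("all standard errors must be > 0")
        if est.size == 1:  # a single study passes through unchanged
            self.pooled_, self.se_, self.tau2_ = float(est[0]), float(se[0]), 0.0
            self.n_studies_ = 1
            self.result_ = MetaResult(self.pooled_, self.se_, 0.0, 1)
            return self
        w = 1.0 / se**2
        pooled_fe = (w * est).sum() / w.sum()
        q = (w * (est - pooled_fe) ** 2).sum()
        denom = w.sum() - (w**2).sum() / w.sum()
        tau2 = max(0.0, (q - (est.size - 1)) / denom)
        ws = 1.0 / (se**2 + tau2)
        self.pooled_ = float((ws * est).sum() / ws.sum())
        self.se_ = float(1.0 / np.sqrt(ws.sum()))
        self.tau2_ = float(tau2)
        self.n_studies_ = int(est.size)
        self.result_ = MetaResult(self.pooled_, self.se_, self.tau2_,
                                  self.n_studies_)
        return self


def random_effects_meta(estimates, ses) -> MetaResult:
    """Functional wrapper over :class:`RandomEffectsMeta`."""
    return RandomEffectsMeta().fit(estimates, ses).result_


def one_sided_test(meta: MetaResult) -> float:
    """Upper-tail normal p that the pooled quantity exceeds zero."""
    if meta.se <= 0:
        raise ValueError("pooled SE must be > 0")
    return meta.p_one_sided


def compare_gene_sets(meta_a: MetaResult, meta_b: MetaResult) -> float:
    """One-sided p for pooled(A) > pooled(B), assuming independence.

    Approximate: trait groups shared between the two gene sets induce
    positive correlation that this z-test ignores; see
    :func:`compare_gene_sets_paired` for the trait-paired alternative.
    """
    z = (meta_a.pooled - meta_b.pooled) / np.sqrt(meta_a.se**2 + meta_b.se**2)
    return float(stats.norm.sf(z))


def compare_gene_sets_paired(est_a, se_a, est_b, se_b) -> float:
    """Trait-paired comparison: meta-analyze per-trait d_A - d_B, then test > 0."""
    diff = np.asarray(est_a, dtype=float) - np.asarray(est_b, dtype=float)
    se = np.sqrt(np.asarray(se_a, dtype=float) ** 2
                 + np.asarray(se_b, dtype=float) ** 2)
    return one_sided_test(random_effects_meta(diff, se))


def select_and_cluster_traits(
    enrichment: pd.DataFrame,
    pvalues: pd.DataFrame,
    p_threshold: float = 0.05,
    n_clusters: int | None = None,
    method: str = "ward",
) -> pd.DataFrame:
    """Retain traits enriched by at least one gene set; cluster and label.

    ``enrichment`` and ``pvalues`` are trait x gene-set matrices (one-sided
    enrichment p). Retained traits are hierarchically clustered (default
    Ward linkage on the enrichment rows, ``n_clusters`` defaulting to the
    number of gene sets) and each trait is labelled by its argmax gene set
    (the set contributing the most per-SNP heritability).
    Returns columns ``trait, cluster, specific_set`` plus the enrichment
    values; empty (with a warning) when nothing passes.
    """
    keep = (pvalues < p_threshold).any(axis=1)
    if not keep.any():
        warnings.warn("no trait passes the enrichment threshold")
        return pd.DataFrame(columns=["trait", "cluster", "specific_set"])
    sub = enrichment.loc[keep]
    if n_clusters is None:
        n_clusters = min(len(sub), enrichment.shape[1])
    if len(sub) == 1:
        clusters = np.array([1])
    else:
        link = hierarchy.linkage(sub.to_numpy(), method=method)
        clusters = hierarchy.fcluster(link, t=n_clusters, criterion="maxclust")
    out = sub.copy()
    out.insert(0, "trait", sub.index)
    out.insert(1, "cluster", clusters)
    out.insert(2, "specific_set", sub.idxmax(axis=1).to_numpy())
    return out.reset_index(drop=True)


def cluster_group_association(
    labels: pd.Series, aging: pd.Series, focus: str = "inflammaging",
) -> tuple[np.ndarray, float, float]:
    """Fisher's exact test of (label == focus) x (aging vs non-aging).

    Returns (2x2 table, odds ratio, two-sided p). A degenerate margin gives
    p = 1 with a warning.
    """
    labels, aging = labels.align(aging, join="inner")
    a = (labels == focus).to_numpy()
    b = aging.astype(bool).to_numpy()
    table = np.array([
        [np.sum(a & b), np.sum(a & ~b)],
        [np.sum(~a & b), np.sum(~a & ~b)],
    ])
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        warnings.warn("degenerate margin in the 2x2 table; p set to 1")
        return table, np.nan, 1.0
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return table, float(odds), float(p)
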