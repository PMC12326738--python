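"""Classify screen hits into inflammaging vs common-aging gene sets.

Signature genes — significant (Wald p below threshold) in either the
replicative (RSS) or the inflammatory (ISS) arm — are clustered by k-means
on their two beta scores. Clusters whose centroid is large in the ISS axis
but small in the RSS axis are labelled *inflammaging* (IL-6-specific
senescence regulators); clusters large in both axes with concordant sign are
*common-aging*; everything else is left unassigned. A size-matched random
control set and a hypergeometric enrichment test against reference
(hallmark-style) sets complete the gene-set toolkit.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

__all__ = ["select_signature_genes", "SignatureKMeans", "kmeans_classify",
           "sample_control_genes", "hypergeometric_enrichment",
           "label_clusters"]


def select_signature_genes(
    rss: pd.DataFrame, iss: pd.DataFrame, p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Genes with Wald p < threshold in RSS *or* ISS, with both betas attached.

    Input tables are per-gene screen results (``gene, beta, wald_p, ...``).
    Raises if the selection is empty.
    """
    r = rss.set_index("gene")
    i = iss.set_index("gene")
    shared = r.index.intersection(i.index)
    r, i = r.loc[shared], i.loc[shared]
    keep = (r["wald_p"] < p_threshold) | (i["wald_p"] < p_threshold)
    if not keep.any():
        raise ValueError(
            f"no gene has wald_p < {p_threshold} in either condition")
    out = pd.DataFrame({
        "gene": shared[keep],
        "beta_rss": r.loc[keep, "beta"].to_numpy(),
        "beta_iss": i.loc[keep, "beta"].to_numpy(),
    }).reset_index(drop=True)
    return out


def label_clusters(centers: np.ndarray, large_frac: float = 0.5) -> list[str]:
    """Map (rss, iss) centroids to set labels.

    A centroid coordinate counts as "large" when its magnitude reaches
    ``large_frac`` of the largest magnitude in that column over clusters.
    ISS-large & RSS-small → inflammaging; both large with the same sign →
    common_aging; otherwise unassigned. Depends only on the centroids, so it
    is invariant to cluster index order.
    """
    centers = np.asarray(centers, dtype=float)
    thr = large_frac * np.abs(centers).max(axis=0)
    labels = []
    for c_rss, c_iss in centers:
        # a zero threshold means the RSS axis carries no signal at all
        rss_small = abs(c_rss) < thr[0] or thr[0] == 0
        if abs(c_iss) >= thr[1] and thr[1] > 0 and rss_small:
            labels.append("inflammaging")
        elif (abs(c_iss) >= thr[1] and thr[1] > 0 and not rss_small
              and np.sign(c_rss) == np.sign(c_iss)):
            labels.append("common_aging")
        else:
            labels.append("unassigned")
    return labels


class SignatureKMeans(ClusterMixin, BaseEstimator):
    """K-means on (beta_rss, beta_iss) with centroid-based set labels.

    Lloyd's algorithm, best of ``n_restarts`` by within-cluster sum of
    squares; columns are not scaled (both are beta scores on a shared
    scale). Fitted attributes: ``cluster_centers_`` (k x 2), ``labels_``,
    ``set_labels_`` (per cluster) and ``assignment_`` (per-gene table when
    fit on a signature-gene DataFrame).
    """

    def __init__(self, k: int = 4, n_restarts: int = 50,
                 large_frac: float = 0.5, seed: int = 0):
        self.k = k
        self.n_restarts = n_restarts
        self.large_frac = large_frac
        self.seed = seed

    def fit(self, X, y=None):
        table = None
        if isinstance(X, pd.DataFrame) and {"beta_rss", "beta_iss"} <= set(X.columns):
            table = X
            X = X[["beta_rss", "beta_iss"]].to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.shape[0] < self.k:
            raise ValueError(f"k={self.k} exceeds the {X.shape[0]} genes given")
        km = KMeans(n_clusters=self.k, n_init=self.n_restarts,
                    algorithm="lloyd", random_state=self.seed)
        km.fit(X)
        self._kmeans_ = km
        self.cluster_centers_ = km.cluster_centers_
        self.labels_ = km.labels_
        self.inertia_ = km.inertia_
        self.set_labels_ = label_clusters(self.cluster_centers_,
                                          self.large_frac)
        if table is not None:
            self.assignment_ = pd.DataFrame({
                "gene": table["gene"].to_numpy(),
                "beta_rss": X[:, 0],
                "beta_iss": X[:, 1],
                "cluster": self.labels_ + 1,  # clusters reported 1-based
                "set_label": [self.set_labels_[c] for c in self.labels_],
            })
        return self

    def predict(self, X):
        return self._kmeans_.predict(np.asarray(X, dtype=float))


def kmeans_classify(signature: pd.DataFrame, k: int = 4, n_restarts: int = 50,
                    seed: int = 0, large_frac: float = 0.5) -> pd.DataFrame:
    """Functional wrapper over :class:`SignatureKMeans`; returns assignment_."""
    est = SignatureKMeans(k=k, n_restarts=n_restarts, large_frac=large_frac,
                          seed=seed)
    return est.fit(signature).assignment_


def sample_control_genes(universe, excluded, size: int, seed: int = 0) -> set:
    """Uniform sample of ``size`` genes from universe minus excluded sets.

    ``excluded`` may be one gene set or an iterable of sets.
    """
    universe = set(universe)
    if excluded and isinstance(next(iter(excluded)), str):
        excluded = [excluded]
    drop = set().union(*excluded) if excluded else set()
    pool = sorted(universe - drop)
    if size > len(pool):
        raise ValueError(f"cannot sample {size} genes from a pool of {len(pool)}")
    rng = np.random.default_rng(seed)
    return set(rng.choice(pool, size=size, replace=False)) if size else set()


def hypergeometric_enrichment(
    query, reference_sets: dict, universe,
) -> pd.DataFrame:
    """Upper-tail hypergeometric overlap test of ``query`` vs each reference.

    p = P(X >= overlap) with X ~ Hypergeom(|universe|, |ref|, |query|);
    Benjamini–Hochberg q across the reference sets. Reference genes outside
    the universe are intersected away with a warning.
    """
    universe = set(universe)
    query = set(query)
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    rows = []
    for name, ref in reference_sets.items():
        ref = set(ref)
        if not ref <= universe:
            warnings.warn(f"reference set {name!r} trimmed to the universe")
            ref &= universe
        overlap = len(query & ref)
        p = float(stats.hypergeom.sf(overlap - 1, len(universe), len(ref),
                                     len(query)))
        rows.append((name, len(ref), overlap, min(p, 1.0)))
    out = pd.DataFrame(rows, columns=["set", "set_size", "overlap", "p"])
    out["q"] = multipletests(out["p"], method="fdr_bh")[1] if len(out) else []
    return out
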