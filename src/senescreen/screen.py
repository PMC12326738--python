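"""Per-gene beta scores from pooled-screen counts by negative-binomial MLE.

The beta score is the log selection coefficient of a gene between an initial
and a final cell population: for sgRNA i of gene g in sample s the count is
modelled as

    k_is ~ NB(mean = S_s * exp(b_i + t_s * beta_g), alpha_i)

with S_s the sample size factor, t_s = 1 for final samples, b_i a free
per-sgRNA abundance intercept and alpha_i the sgRNA dispersion
(variance mu + alpha*mu^2). The MLE is taken jointly over {b_i} and beta_g
by Fisher scoring; the Wald standard error comes from the expected
information, and a positive beta means the gene's sgRNAs are enriched in the
final population (positive selection).

Gene-level false discovery rates use the empirical permutation scheme:
sgRNA→gene assignments are shuffled preserving gene sizes, the full
estimator is re-run per permutation, and the pooled null p-values calibrate
the observed ones.

Non-targeting control sgRNAs are grouped into pseudo-genes and fitted
identically, providing an empirical null inside every result table.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import special, stats
from sklearn.base import BaseEstimator

from .simulate import NON_TARGETING

logger = logging.getLogger(__name__)

RESULT_COLUMNS = ["gene", "condition", "beta", "se", "wald_p", "fdr", "n_sgrnas"]
NT_PSEUDO_PREFIX = "NT_PSEUDO_"

__all__ = [
    "RESULT_COLUMNS",
    "NT_PSEUDO_PREFIX",
    "ScreenEffectEstimator",
    "estimate_size_factors",
    "estimate_dispersions",
    "fit_gene_effects",
    "permutation_fdr",
]


def estimate_size_factors(counts) -> np.ndarray:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    ``counts`` is an sgRNA x sample integer matrix (ndarray or DataFrame of
    the sample columns only). The pseudo-reference is the geometric mean
    across samples over sgRNAs that are nonzero in every sample.
    """
    K = np.asarray(counts, dtype=float)
    if K.ndim != 2 or K.shape[1] < 1:
        raise ValueError("counts must be a 2-D sgRNA x sample matrix")
    if np.any(K.sum(axis=0) == 0):
        raise ValueError("a sample has all-zero counts; cannot normalize")
    allpos = np.all(K > 0, axis=1)
    if not allpos.any():
        raise ValueError("no sgRNA is nonzero in every sample")
    ref = np.exp(np.log(K[allpos]).mean(axis=1))
    factors = np.median(K[allpos] / ref[:, None], axis=0)
    return factors / np.exp(np.log(factors).mean())


def estimate_dispersions(
    counts,
    size_factors: np.ndarray,
    design: pd.DataFrame | None = None,
    sample_ids=None,
    floor: float = 0.01,
    prior_df: float = 20.0,
) -> np.ndarray:
    """Per-sgRNA NB dispersions by method of moments with shrinkage.

    For each group of replicate samples sharing a (condition, timepoint) the
    raw moment estimate is ``(s^2 - m) / m^2`` on size-factor-normalized
    counts. Per-sgRNA estimates are precision-weighted over groups, then
    shrunk toward the across-sgRNA mean with weight ``df / (df + prior_df)``
    — with few replicates the raw estimate is dominated by sampling noise,
    and the shrunk estimate keeps downstream Wald tests calibrated. The
    result is floored at ``floor``.

    Without ``design`` (or with no replicated group) every sgRNA falls back
    to the floor, with a warning.
    """
    K = np.asarray(counts, dtype=float)
    norm = K / np.asarray(size_factors, dtype=float)[None, :]

    groups: list[np.ndarray] = []
    if design is not None:
        ids = list(sample_ids) if sample_ids is not None else list(
            design["sample_id"])
        col_of = {s: j for j, s in enumerate(ids)}
        for _, grp in design.groupby(["condition", "timepoint"]):
            cols = [col_of[s] for s in grp["sample_id"] if s in col_of]
            if len(cols) >= 2:
                groups.append(np.array(cols))
    if not groups:
        warnings.warn("no replicated (condition, timepoint) groups; "
                      "dispersions fall back to the floor")
        return np.full(K.shape[0], floor)

    num = np.zeros(K.shape[0])
    df = np.zeros(K.shape[0])
    for cols in groups:
        sub = norm[:, cols]
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            mom = (v - m) / m**2
        ok = np.isfinite(mom)
        w = len(cols) - 1
        num[ok] += w * mom[ok]
        df[ok] += w
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = num / df
    seen = df > 0
    global_alpha = raw[seen].mean() if seen.any() else floor
    shrunk = np.full(K.shape[0], global_alpha)
    shrunk[seen] = (df[seen] * raw[seen] + prior_df * global_alpha) / (
        df[seen] + prior_df)
    return np.maximum(shrunk, floor)


# ---------------------------------------------------------------------------
# vectorized NB Fisher scoring over genes with equal sgRNA count
# ---------------------------------------------------------------------------

def _nb_loglik(K, mu, alpha):
    """Elementwise NB log-likelihood; Poisson limit below alpha = 1e-6."""
    mu = np.clip(mu, 1e-300, None)
    out = np.where(
        alpha < 1e-6,
        K * np.log(mu) - mu - special.gammaln(K + 1),
        0.0,
    )
    nb = alpha >= 1e-6
    if np.any(nb):
        a = np.where(nb, alpha, 1.0)
        r = 1.0 / a
        val = (special.gammaln(K + r) - special.gammaln(r)
               - special.gammaln(K + 1)
               + r * np.log(r / (r + mu)) + K * np.log(mu / (r + mu)))
        out = np.where(nb, val, out)
    return out


def _fit_block(K, sf, t, alpha, mask, tol=1e-8, max_iter=100, beta_bound=15.0):
    """Joint MLE of per-sgRNA intercepts and one beta per gene.

    K: (G, I, S) counts; sf: (S,) size factors; t: (S,) final indicator;
    alpha: (G, I) dispersions; mask: (G, I) sgRNAs included in the fit.
    Returns (beta, se, converged, loglik) arrays of shape (G,).
    """
    G, I, S = K.shape
    m3 = mask[:, :, None]
    with np.errstate(divide="ignore"):
        b = np.log(np.clip((K / sf).mean(axis=2), 1e-8, None))
    b = np.where(mask, b, 0.0)
    beta = np.zeros(G)
    a3 = alpha[:, :, None]

    def loglik(b, beta):
        mu = sf * np.exp(b[:, :, None] + t * beta[:, None, None])
        ll = _nb_loglik(K, mu, a3) * m3
        return ll.sum(axis=(1, 2))

    ll = loglik(b, beta)
    converged = np.zeros(G, dtype=bool)
    schur = np.full(G, np.nan)
    for _ in range(max_iter):
        mu = sf * np.exp(b[:, :, None] + t * beta[:, None, None])
        denom = 1.0 + a3 * mu
        r = (K - mu) / denom * m3
        w = mu / denom * m3
        g_b = r.sum(axis=2)
        g_beta = (r * t).sum(axis=(1, 2))
        H_bb = np.clip(w.sum(axis=2), 1e-12, None)
        H_bB = (w * t).sum(axis=2)
        H_BB = (w * t).sum(axis=(1, 2))
        schur = np.clip(H_BB - (H_bB**2 / H_bb * mask).sum(axis=1), 1e-12, None)
        d_beta = (g_beta - (H_bB * g_b / H_bb * mask).sum(axis=1)) / schur
        d_b = (g_b - H_bB * d_beta[:, None]) / H_bb

        scale = np.where(converged, 0.0, 1.0)
        for _ in range(25):  # per-gene step halving
            beta_new = np.clip(beta + scale * d_beta, -beta_bound, beta_bound)
            b_new = b + scale[:, None] * d_b * mask
            ll_new = loglik(b_new, beta_new)
            bad = ~converged & (ll_new < ll - 1e-10)
            if not bad.any():
                break
            scale[bad] *= 0.5
        newly = ~converged & (np.abs(ll_new - ll) < tol)
        beta, b, ll = beta_new, b_new, ll_new
        converged |= newly
        if converged.all():
            break

    se = np.sqrt(1.0 / schur)
    return beta, se, converged, ll


class ScreenEffectEstimator(BaseEstimator):
    """Per-gene NB-MLE beta scores for one screen condition.

    Parameters
    ----------
    condition : str
        Condition to fit ("rss" or "iss"); final samples of this condition
        are contrasted with its initial samples.
    dispersion_floor, prior_df : float
        Passed to :func:`estimate_dispersions` when dispersions are estimated.
    nt_pseudo_size : int
        Non-targeting sgRNAs are chunked into pseudo-genes of this size and
        fitted identically (empirical null).
    tol, max_iter, beta_bound : float, int, float
        Fisher-scoring convergence tolerance on the log-likelihood change,
        iteration cap, and clip bound on |beta|.

    Attributes
    ----------
    results_ : DataFrame with columns ``gene, condition, beta, se, wald_p,
        fdr, n_sgrnas`` (fdr is NaN until :func:`permutation_fdr` fills it).
    size_factors_, dispersions_ : the normalization actually used.
    """

    def __init__(self, condition: str = "rss", dispersion_floor: float = 0.01,
                 prior_df: float = 20.0, nt_pseudo_size: int = 5,
                 tol: float = 1e-8, max_iter: int = 100,
                 beta_bound: float = 15.0):
        self.condition = condition
        self.dispersion_floor = dispersion_floor
        self.prior_df = prior_df
        self.nt_pseudo_size = nt_pseudo_size
        self.tol = tol
        self.max_iter = max_iter
        self.beta_bound = beta_bound

    # counts carries its own sgrna/gene columns, so y is never used; the
    # sklearn-style signature keeps the estimator pipeline-compatible.
    def fit(self, counts: pd.DataFrame, y=None, *, design: pd.DataFrame,
            size_factors=None, dispersions=None):
        cond = design[design["condition"] == self.condition]
        if not {"initial", "final"} <= set(cond["timepoint"]):
            raise ValueError(
                f"condition {self.condition!r} needs initial and final samples")
        samples = list(cond["sample_id"])
        K = counts[samples].to_numpy(dtype=float)
        t = (cond["timepoint"] == "final").to_numpy(dtype=float)

        if size_factors is None:
            size_factors = estimate_size_factors(K)
        size_factors = np.asarray(size_factors, dtype=float)
        if dispersions is None:
            dispersions = estimate_dispersions(
                counts[list(design["sample_id"])].to_numpy(dtype=float),
                estimate_size_factors(counts[list(design["sample_id"])]),
                design, list(design["sample_id"]),
                floor=self.dispersion_floor, prior_df=self.prior_df)
        dispersions = np.asarray(dispersions, dtype=float)

        genes = self._gene_labels(counts)
        keep = K.sum(axis=1) > 0  # all-zero sgRNAs carry no information
        rows = []
        frame = pd.DataFrame({"gene": genes, "idx": np.arange(len(genes))})
        for size, grp in frame.groupby(frame.groupby("gene")["idx"].transform("size")):
            order = grp.sort_values("gene")
            gnames = order["gene"].to_numpy().reshape(-1, size)[:, 0]
            idx = order["idx"].to_numpy().reshape(-1, size)
            beta, se, conv, _ = _fit_block(
                K[idx], size_factors, t, dispersions[idx], keep[idx],
                tol=self.tol, max_iter=self.max_iter,
                beta_bound=self.beta_bound)
            n_valid = keep[idx].sum(axis=1)
            for g, bt, s, cv, nv in zip(gnames, beta, se, conv, n_valid):
                if nv == 0 or not cv:
                    if not cv:
                        logger.warning("gene %s did not converge; flagged NA", g)
                    bt, s, p = np.nan, np.nan, np.nan
                else:
                    p = max(2.0 * stats.norm.sf(abs(bt) / s), 1e-300)
                rows.append((g, self.condition, bt, s, p, np.nan, int(size)))
        res = pd.DataFrame(rows, columns=RESULT_COLUMNS)
        # keep targeting genes first, pseudo-genes last, each in name order
        res["_nt"] = res["gene"].str.startswith(NT_PSEUDO_PREFIX)
        res = (res.sort_values(["_nt", "gene"]).drop(columns="_nt")
               .reset_index(drop=True))
        self.samples_ = samples
        self.size_factors_ = size_factors
        self.dispersions_ = dispersions
        self.results_ = res
        return self

    def _gene_labels(self, counts: pd.DataFrame) -> np.ndarray:
        """Gene per sgRNA row, with non-targeting rows chunked to pseudo-genes."""
        genes = counts["gene"].to_numpy(dtype=object).copy()
        nt = np.flatnonzero(genes == NON_TARGETING)
        for j, i in enumerate(nt):
            genes[i] = f"{NT_PSEUDO_PREFIX}{j // self.nt_pseudo_size + 1:04d}"
        return genes


def fit_gene_effects(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    condition: str,
    size_factors=None,
    dispersions=None,
    **params,
) -> pd.DataFrame:
    """Functional wrapper over :class:`ScreenEffectEstimator`. Returns results_."""
    est = ScreenEffectEstimator(condition=condition, **params)
    est.fit(counts, design=design, size_factors=size_factors,
            dispersions=dispersions)
    return est.results_


def permutation_fdr(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    condition: str,
    n_perm: int = 100,
    seed: int = 0,
    estimator: ScreenEffectEstimator | None = None,
    observed: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Permutation-based gene-level FDR.

    Each round shuffles the sgRNA→gene assignment (preserving gene sizes),
    re-runs the full NB-MLE, and pools the null Wald p-values; then

        FDR(g) = [(1 + #null p <= p_g) / (1 + #null)] / [frac observed p <= p_g],

    capped at 1 and made monotone non-decreasing in p. Null p-values are
    accumulated as rank counts per permutation, so memory does not grow
    with ``n_perm``. Returns the observed result table with ``fdr`` filled.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    est = estimator or ScreenEffectEstimator(condition=condition)
    est.condition = condition
    if observed is None:
        observed = est.fit(counts, design=design).results_
    obs = observed.copy()
    p_obs = obs["wald_p"].to_numpy()
    ok = np.isfinite(p_obs)
    order = np.argsort(p_obs[ok])

    rng = np.random.default_rng(seed)
    null_le = np.zeros(ok.sum(), dtype=np.int64)
    n_null = 0
    genes_col = counts["gene"].to_numpy()
    for _ in range(n_perm):
        perm = counts.copy()
        perm["gene"] = rng.permutation(genes_col)
        null_p = est.fit(perm, design=design).results_["wald_p"].to_numpy()
        null_p = np.sort(null_p[np.isfinite(null_p)])
        null_le += np.searchsorted(null_p, p_obs[ok][order], side="right")
        n_null += null_p.size

    n_obs = ok.sum()
    sorted_p = p_obs[ok][order]
    # #observed p <= p_g along the sorted order, tie-aware
    rank = np.searchsorted(sorted_p, sorted_p, side="right")
    frac_null = (1.0 + null_le) / (1.0 + n_null)
    fdr_sorted = np.minimum(frac_null / (rank / n_obs), 1.0)
    fdr_sorted = np.maximum.accumulate(fdr_sorted)

    fdr = np.full(len(obs), np.nan)
    idx_ok = np.flatnonzero(ok)
    fdr[idx_ok[order]] = fdr_sorted
    obs["fdr"] = fdr
    return obs
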