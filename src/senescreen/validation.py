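"""Screen quality control by ROC analysis against gold-standard gene sets.

A screen is deemed informative if a simple additive logistic model of the
gold labels on (beta, -log10 p) ranks known positives (e.g. essential or
pro-senescence genes) above known negatives with AUC well above 0.5; the
AUC's significance comes from re-running the whole estimator on
label-permuted count data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression

from .screen import ScreenEffectEstimator

__all__ = ["GoldStandard", "AucResult", "combine_scores", "roc_auc",
           "auc_permutation_p"]


@dataclass(frozen=True)
class GoldStandard:
    """Disjoint positive/negative gene-id sets used as ROC truth."""

    positives: frozenset
    negatives: frozenset

    def __post_init__(self):
        pos, neg = frozenset(self.positives), frozenset(self.negatives)
        object.__setattr__(self, "positives", pos)
        object.__setattr__(self, "negatives", neg)
        if not pos or not neg:
            raise ValueError("both gold classes must be non-empty")
        if pos & neg:
            raise ValueError("gold positive and negative sets overlap")


@dataclass
class AucResult:
    auc: float
    n_pos: int
    n_neg: int
    p_perm: float | None = None


def combine_scores(results: pd.DataFrame, gold: GoldStandard,
                   max_iter: int = 200) -> pd.Series:
    """Fitted linear predictor of a logistic model label ~ beta + (-log10 p).

    The model is fit on the genes present in ``gold`` (in-sample, as a QC
    readout, which is optimistic by construction) and the linear predictor is
    returned for every gene in ``results``. Separable data is handled by the
    iteration cap. Raises if both predictors are constant.
    """
    res = results.dropna(subset=["beta", "wald_p"]).set_index("gene")
    X_all = np.column_stack([
        res["beta"].to_numpy(),
        -np.log10(np.clip(res["wald_p"].to_numpy(), 1e-300, None)),
    ])
    labeled = [g for g in res.index if g in gold.positives or g in gold.negatives]
    if not labeled:
        raise ValueError("no scored genes carry gold labels")
    li = res.index.get_indexer(labeled)
    X, y = X_all[li], np.array([g in gold.positives for g in labeled], int)
    if np.all(X.std(axis=0) < 1e-12):
        raise ValueError("all-constant predictors; cannot fit combiner")
    model = LogisticRegression(C=np.inf, max_iter=max_iter, tol=1e-10)
    model.fit(X, y)
    lin = X_all @ model.coef_.ravel() + model.intercept_[0]
    return pd.Series(lin, index=res.index, name="score")


def roc_auc(scores: pd.Series, gold: GoldStandard) -> AucResult:
    """AUC as the Mann–Whitney pair statistic with midrank tie handling."""
    pos = [g for g in scores.index if g in gold.positives]
    neg = [g for g in scores.index if g in gold.negatives]
    if not pos or not neg:
        raise ValueError("need at least one scored positive and negative")
    s = scores.loc[pos + neg].to_numpy(dtype=float)
    ranks = stats.rankdata(s)  # midranks give ties half credit
    n_pos, n_neg = len(pos), len(neg)
    auc = (ranks[:n_pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    return AucResult(float(auc), n_pos, n_neg)


def auc_permutation_p(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    condition: str,
    gold: GoldStandard,
    n_perm: int = 100,
    seed: int = 0,
    estimator: ScreenEffectEstimator | None = None,
) -> AucResult:
    """Permutation significance of the observed AUC.

    Each round shuffles the sgRNA→gene assignment, refits the screen model,
    refits the logistic combiner and recomputes the AUC;
    p = (1 + #{null AUC >= observed}) / (1 + n_perm).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    est = estimator or ScreenEffectEstimator(condition=condition)
    est.condition = condition

    def screen_auc(c):
        res = est.fit(c, design=design).results_
        return roc_auc(combine_scores(res, gold), gold)

    observed = screen_auc(counts)
    rng = np.random.default_rng(seed)
    genes = counts["gene"].to_numpy()
    n_ge = 0
    for _ in range(n_perm):
        perm = counts.copy()
        perm["gene"] = rng.permutation(genes)
        if screen_auc(perm).auc >= observed.auc:
            n_ge += 1
    observed.p_perm = (1 + n_ge) / (1 + n_perm)
    return observed
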