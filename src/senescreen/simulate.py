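"""Synthetic data generators with known ground truth.

Every downstream stage of the package (beta-score estimation, gene-set
classification, stratified LD score regression, meta-analysis) is exercised
on data produced here, so each generator returns the truth it used alongside
the observables.

Two worlds are simulated:

* a pooled CRISPRi senescence screen — an sgRNA library (~5 guides per gene
  plus non-targeting controls) whose guide abundances drift between an
  initial and a final cell population under two selection conditions,
  replicative senescence ("rss") and IL-6-driven inflammatory senescence
  ("iss");
* a toy genome with block-structured linkage disequilibrium and GWAS
  summary statistics whose per-SNP heritability is stratified by binary
  annotations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Sentinel gene label carried by non-targeting control sgRNAs. Never a real gene.
NON_TARGETING = "NON_TARGETING"

CONDITIONS = ("rss", "iss")

__all__ = [
    "NON_TARGETING",
    "CONDITIONS",
    "GwasTruth",
    "SimulatedScreen",
    "make_library",
    "make_effects",
    "simulate_screen",
    "simulate_genome",
    "simulate_gwas",
    "ar1_block_correlation",
]


# ---------------------------------------------------------------------------
# screen side
# ---------------------------------------------------------------------------

def make_library(
    n_genes: int,
    sgrnas_per_gene: int = 5,
    n_nontargeting: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """Build an sgRNA library table.

    Returns a DataFrame with columns ``sgrna``, ``gene``, ``sequence``
    containing exactly ``n_genes * sgrnas_per_gene`` targeting rows followed
    by ``n_nontargeting`` rows labelled :data:`NON_TARGETING`.

    The emulated design has ~5 sgRNAs for each of 18,905 genes plus 1895
    non-targeting controls; note the real genome-wide library holds 104,535
    targeting sgRNAs because the per-gene guide count varies, whereas this
    generator is exactly rectangular (18,905 x 5 = 94,525 targeting rows).
    """
    for name, v in (("n_genes", n_genes), ("sgrnas_per_gene", sgrnas_per_gene),
                    ("n_nontargeting", n_nontargeting)):
        if v < 0:
            raise ValueError(f"{name} must be >= 0, got {v}")
    rng = np.random.default_rng(seed)
    genes = [f"GENE{i + 1:05d}" for i in range(n_genes)]
    rows = [
        (f"{g}_sg{j + 1}", g)
        for g in genes
        for j in range(sgrnas_per_gene)
    ]
    rows += [(f"NT_sg{j + 1:05d}", NON_TARGETING) for j in range(n_nontargeting)]
    lib = pd.DataFrame(rows, columns=["sgrna", "gene"])
    lib["sequence"] = [
        "".join(s) for s in rng.choice(list("ACGT"), size=(len(lib), 20))
    ]
    return lib


def make_effects(
    gene_ids,
    n_essential: int = 0,
    n_common: int = 0,
    n_inflammaging: int = 0,
    beta: float = 1.0,
    essential_beta: float = -1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Assign ground-truth selection effects to genes.

    Classes (drawn without replacement, in this order, from a shuffled gene
    list):

    - ``essential``: depleted in both arms (``essential_beta`` in RSS and ISS);
    - ``pro_senescence_common``: enriched in both arms (``beta`` in both);
    - ``pro_senescence_inflammaging``: enriched only under IL-6
      (``beta_iss = beta``, ``beta_rss = 0``);
    - ``null``: exactly zero effect in both arms.

    Returns columns ``gene``, ``beta_rss``, ``beta_iss``, ``class_label``.
    """
    gene_ids = list(gene_ids)
    n_special = n_essential + n_common + n_inflammaging
    if n_special > len(gene_ids):
        raise ValueError("more effect genes requested than genes available")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(gene_ids))
    eff = pd.DataFrame({
        "gene": gene_ids,
        "beta_rss": 0.0,
        "beta_iss": 0.0,
        "class_label": "null",
    })
    picks = order[:n_special]
    ess = picks[:n_essential]
    com = picks[n_essential:n_essential + n_common]
    inf = picks[n_essential + n_common:]
    eff.loc[ess, ["beta_rss", "beta_iss"]] = essential_beta
    eff.loc[ess, "class_label"] = "essential"
    eff.loc[com, ["beta_rss", "beta_iss"]] = beta
    eff.loc[com, "class_label"] = "pro_senescence_common"
    eff.loc[inf, "beta_iss"] = beta
    eff.loc[inf, "class_label"] = "pro_senescence_inflammaging"
    return eff


@dataclass
class SimulatedScreen:
    """Counts, sample design and ground truth from :func:`simulate_screen`."""

    counts: pd.DataFrame      # sgrna, gene, one integer column per sample
    design: pd.DataFrame      # sample_id, condition, timepoint, replicate
    effects: pd.DataFrame     # the TrueScreenEffects table passed in
    sgrna_effects: pd.DataFrame  # per-sgRNA realized log effects per condition


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB(mean mu, variance mu + dispersion*mu^2); Poisson at dispersion ~ 0."""
    mean = np.clip(mean, 1e-12, None)
    if dispersion < 1e-9:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def simulate_screen(
    library: pd.DataFrame,
    effects: pd.DataFrame,
    depth: float = 500.0,
    dispersion: float = 0.05,
    n_replicates: int = 2,
    conditions=CONDITIONS,
    efficacy_sd: float = 0.2,
    seed: int = 0,
) -> SimulatedScreen:
    """Simulate initial/final sgRNA counts for a pooled screen.

    Generative model: baseline sgRNA abundances are log-normal(0, 1) and
    renormalized to proportions; each targeting sgRNA carries a realized
    effect ``beta_gene(condition) * e_i`` with per-sgRNA efficacy
    ``e_i ~ Normal(1, efficacy_sd)`` (so null genes stay exactly null and
    unit effects have sd ``efficacy_sd``); final relative abundance is
    proportional to ``initial * exp(effect)``; counts are negative-binomial
    at the requested mean ``depth`` reads per sgRNA (a sample's column sum
    is therefore ~ ``depth * n_sgrnas``) with the given dispersion.

    Samples are named ``{condition}_{timepoint}_r{replicate}``. Non-targeting
    sgRNAs have effect exactly 0.
    """
    if depth <= 0:
        raise ValueError("depth must be > 0")
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    unknown = set(effects["gene"]) - set(library["gene"])
    if unknown:
        raise ValueError(f"effects reference unknown genes: {sorted(unknown)[:5]}")
    rng = np.random.default_rng(seed)
    n_sg = len(library)
    baseline = rng.lognormal(0.0, 1.0, n_sg)
    p0 = baseline / baseline.sum()
    total = depth * n_sg

    beta = {c: library["gene"].map(
        effects.set_index("gene")[f"beta_{c}"]).fillna(0.0).to_numpy()
        for c in conditions}
    targeting = (library["gene"] != NON_TARGETING).to_numpy()
    efficacy = np.ones(n_sg)
    efficacy[targeting] = rng.normal(1.0, efficacy_sd, targeting.sum())

    counts = library[["sgrna", "gene"]].copy()
    design_rows = []
    sg_eff = {"sgrna": library["sgrna"].to_numpy()}
    for cond in conditions:
        eff = beta[cond] * efficacy
        sg_eff[f"effect_{cond}"] = eff
        p1 = p0 * np.exp(eff)
        p1 = p1 / p1.sum()
        for rep in range(1, n_replicates + 1):
            for tp, p in (("initial", p0), ("final", p1)):
                sid = f"{cond}_{tp}_r{rep}"
                counts[sid] = _nb_draw(rng, total * p, dispersion)
                design_rows.append((sid, cond, tp, rep))
    design = pd.DataFrame(
        design_rows, columns=["sample_id", "condition", "timepoint", "replicate"]
    )
    return SimulatedScreen(counts, design, effects.copy(), pd.DataFrame(sg_eff))


# ---------------------------------------------------------------------------
# genome / GWAS side
# ---------------------------------------------------------------------------

def simulate_genome(
    n_genes: int,
    n_snps: int,
    n_blocks: int,
    chrom_length: int,
    gene_length: int = 50_000,
    chromosome: int = 1,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Lay out non-overlapping genes and sorted common SNPs on one chromosome.

    Returns ``(gene_map, snp_map)``; gene coordinates are 1-based inclusive,
    SNP positions strictly increasing, MAFs uniform on [0.05, 0.5] (every
    SNP is "common"), and ``block`` ids contiguous along position.
    """
    if n_blocks > n_snps:
        raise ValueError("n_blocks must be <= n_snps")
    if n_genes * gene_length > chrom_length:
        raise ValueError("genes do not fit on the chromosome without overlap")
    if n_snps > chrom_length:
        raise ValueError("more SNPs than base pairs")
    rng = np.random.default_rng(seed)

    free = chrom_length - n_genes * gene_length
    cuts = np.sort(rng.integers(0, free + 1, size=n_genes))
    starts = cuts + np.arange(n_genes) * gene_length + 1
    gene_map = pd.DataFrame({
        "gene": [f"GENE{i + 1:05d}" for i in range(n_genes)],
        "chrom": chromosome,
        "tx_start": starts,
        "tx_end": starts + gene_length - 1,
    })

    pos = np.sort(rng.choice(chrom_length, size=n_snps, replace=False)) + 1
    block = np.repeat(np.arange(n_blocks), _split_sizes(n_snps, n_blocks))
    snp_map = pd.DataFrame({
        "snp": [f"rs{i + 1}" for i in range(n_snps)],
        "chrom": chromosome,
        "bp": pos,
        "maf": rng.uniform(0.05, 0.5, n_snps),
        "block": block,
    })
    return gene_map, snp_map


def _split_sizes(n: int, k: int) -> np.ndarray:
    """Sizes of k contiguous chunks covering n items (first chunks larger)."""
    base, extra = divmod(n, k)
    return np.array([base + (i < extra) for i in range(k)])


@dataclass
class GwasTruth:
    """Exact generative quantities behind one simulated GWAS."""

    tau: np.ndarray                      # per-annotation per-SNP coefficients
    h2_total: float                      # sum over SNPs of per-SNP variance
    h2_annot: dict = field(default_factory=dict)  # annotation name -> h2 inside
    n: int = 0                           # GWAS sample size

    def enrichment(self, name: str, n_in: int, n_total: int) -> float:
        """True (h2_a/h2)/(|a|/p) for annotation ``name``."""
        return (self.h2_annot[name] / self.h2_total) / (n_in / n_total)


def ar1_block_correlation(size: int, rho: float) -> np.ndarray:
    """AR(1) correlation matrix R_ij = rho^|i-j| for one LD block."""
    idx = np.arange(size)
    return rho ** np.abs(idx[:, None] - idx[None, :])


def simulate_gwas(
    snp_map: pd.DataFrame,
    annotations: pd.DataFrame,
    tau: np.ndarray,
    n_samples: int,
    rho: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, GwasTruth]:
    """Draw GWAS summary statistics under block-AR(1) LD and stratified h².

    Per-SNP effect variance is ``sigma2_k = sum_c tau_c * A_kc`` (standardized
    genotype scale). Within each LD block with correlation matrix R the
    z-scores are ``z = sqrt(N) R beta + eps`` with ``beta_k ~ N(0, sigma2_k)``
    independent and ``eps ~ MVN(0, R)``, so ``E[chi2_j] = N*sum_c tau_c*l(j,c) + 1``.

    ``annotations`` must be SNP-aligned with the base (all-ones) column first.
    Returns a sumstats table (SNP, A1, A2, Z, N) and the exact
    :class:`GwasTruth` (expected-scale h², per annotation).
    """
    if not (-1.0 < rho < 1.0):
        raise ValueError("|rho| must be < 1")
    A = annotations.to_numpy(dtype=float)
    tau = np.asarray(tau, dtype=float)
    if A.shape[1] != tau.size:
        raise ValueError("tau length must match annotation count")
    sigma2 = A @ tau
    if np.any(sigma2 < 0):
        raise ValueError("negative per-SNP variance; check tau")
    rng = np.random.default_rng(seed)

    z = np.empty(len(snp_map))
    beta = rng.normal(0.0, 1.0, len(snp_map)) * np.sqrt(sigma2)
    chol_cache: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for _, idx in snp_map.groupby("block", sort=False).indices.items():
        m = len(idx)
        if m not in chol_cache:
            R = ar1_block_correlation(m, rho)
            chol_cache[m] = (R, np.linalg.cholesky(R))
        R, L = chol_cache[m]
        eps = L @ rng.normal(0.0, 1.0, m)
        z[idx] = np.sqrt(n_samples) * (R @ beta[idx]) + eps

    sumstats = pd.DataFrame({
        "SNP": snp_map["snp"].to_numpy(),
        "A1": "A",
        "A2": "G",
        "Z": z,
        "N": int(n_samples),
    })
    h2_annot = {
        name: float(sigma2[annotations[name].to_numpy(dtype=bool)].sum())
        for name in annotations.columns
    }
    truth = GwasTruth(tau=tau.copy(), h2_total=float(sigma2.sum()),
                      h2_annot=h2_annot, n=int(n_samples))
    return sumstats, truth
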