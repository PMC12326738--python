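"""End-to-end workflows tying the stages together, with a reproducible manifest.

Two chains are wired here, mirroring the study design the synthetic data
emulates:

1. screen → beta scores → permutation FDR → ROC QC → k-means gene sets;
2. gene sets → 100 kb SNP annotations → LD scores → per-trait S-LDSC →
   random-effects meta-analysis of the per-SNP heritability difference.

``run_pipeline`` executes the stages in dependency order from a
:class:`PipelineConfig`, writes every artifact as TSV/GMT/JSON under
``outdir`` and returns a manifest of output paths with content hashes;
re-running with the same config reproduces the hashes bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify, heritability, io, meta, simulate, validation
from .screen import ScreenEffectEstimator, permutation_fdr
from .simulate import NON_TARGETING

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate_screen", "screen_fit", "screen_qc", "classify",
              "simulate_genome", "annotate", "gwas_ldsc", "meta")

__all__ = ["PipelineConfig", "run_pipeline", "tau_for_enrichment",
           "ALL_STAGES"]


def tau_for_enrichment(annotation: np.ndarray, h2_total: float,
                       enrichment: float) -> np.ndarray:
    """Per-annotation tau = (base, annotation) realizing a target enrichment.

    Splits ``h2_total`` so that the fold enrichment (h2_a/h2)/(|a|/p) of the
    binary ``annotation`` equals ``enrichment`` with uniform per-SNP
    heritability inside and outside.
    """
    a = np.asarray(annotation, dtype=bool)
    p, n_in = a.size, int(a.sum())
    if not 0 < n_in < p:
        raise ValueError("annotation must cover some but not all SNPs")
    h2_a = enrichment * (n_in / p) * h2_total
    if h2_a > h2_total:
        raise ValueError("requested enrichment exceeds total heritability")
    sigma_in = h2_a / n_in
    sigma_out = (h2_total - h2_a) / (p - n_in)
    return np.array([sigma_out, sigma_in - sigma_out])


@dataclass
class PipelineConfig:
    """Every knob of the two workflows, with explicit per-stage seeds.

    Round-trips losslessly through YAML (`to_yaml`/`from_yaml`).
    """

    outdir: str = "senescreen_run"
    stages: tuple = ALL_STAGES
    seed: int = 0

    # screen simulation
    n_genes: int = 400
    sgrnas_per_gene: int = 5
    n_nontargeting: int = 100
    n_essential: int = 30
    n_common: int = 30
    n_inflammaging: int = 30
    effect_size: float = 1.0
    depth: float = 500.0
    dispersion: float = 0.05
    n_replicates: int = 2
    efficacy_sd: float = 0.2

    # screen fitting / QC / classification
    n_perm: int = 20
    p_threshold: float = 0.05
    k: int = 4
    kmeans_restarts: int = 50
    control_size: int = 30

    # genome / GWAS / S-LDSC
    n_snps: int = 12_000
    n_blocks_ld: int = 240
    chrom_length: int = 60_000_000
    rho: float = 0.9
    window_bp: int = 100_000
    ld_window_bp: int = 1_000_000
    maf_min: float = 0.05
    h2_z_min: float = 6.0
    n_jackknife_blocks: int = 20
    gwas_n: int = 50_000
    h2_total: float = 0.5
    trait_enrichment: float = 2.0
    n_traits_enriched: int = 10
    n_traits_null: int = 10

    extra: dict = field(default_factory=dict)

    def to_yaml(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["stages"] = tuple(d.get("stages", ALL_STAGES))
        return cls(**d)

    def stage_seed(self, stage: str) -> int:
        """Stable per-stage seed derived from the global seed."""
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31 - 1)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages; return {artifact name: {path, sha256}}.

    Skipped stages must have their upstream artifacts already on disk
    (an actionable error is raised otherwise). Inputs on disk are never
    mutated; each stage writes new files under ``config.outdir``.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    artifacts: dict[str, Path] = {"config": out / "config.yaml"}
    stages = set(config.stages)

    def need(name: str, path: Path) -> Path:
        if not path.exists():
            raise FileNotFoundError(
                f"stage needs artifact {name!r} at {path}; run its upstream "
                f"stage or provide the file")
        return path

    # ---- screen chain ----------------------------------------------------
    if "simulate_screen" in stages:
        lib = simulate.make_library(config.n_genes, config.sgrnas_per_gene,
                                    config.n_nontargeting,
                                    seed=config.stage_seed("library"))
        eff = simulate.make_effects(
            [g for g in lib["gene"].unique() if g != NON_TARGETING],
            n_essential=config.n_essential, n_common=config.n_common,
            n_inflammaging=config.n_inflammaging, beta=config.effect_size,
            seed=config.stage_seed("effects"))
        sim = simulate.simulate_screen(
            lib, eff, depth=config.depth, dispersion=config.dispersion,
            n_replicates=config.n_replicates, efficacy_sd=config.efficacy_sd,
            seed=config.stage_seed("screen"))
        io.write_library(lib, out / "library.tsv")
        io.write_counts(sim.counts, out / "counts.tsv")
        io.write_design(sim.design, out / "design.tsv")
        io.write_tsv(sim.effects, out / "true_effects.tsv")
        artifacts |= {"library": out / "library.tsv",
                      "counts": out / "counts.tsv",
                      "design": out / "design.tsv",
                      "true_effects": out / "true_effects.tsv"}

    if "screen_fit" in stages:
        counts = io.read_counts(need("counts", out / "counts.tsv"))
        design = io.read_design(need("design", out / "design.tsv"))
        for cond in ("rss", "iss"):
            res = permutation_fdr(counts, design, cond, n_perm=config.n_perm,
                                  seed=config.stage_seed(f"perm_{cond}"))
            io.write_gene_results(res, out / f"gene_results_{cond}.tsv")
            artifacts[f"gene_results_{cond}"] = out / f"gene_results_{cond}.tsv"

    if "screen_qc" in stages:
        eff = io.read_tsv(need("true_effects", out / "true_effects.tsv"))
        gold = validation.GoldStandard(
            positives=frozenset(eff.loc[eff["class_label"] == "essential",
                                        "gene"]),
            negatives=frozenset(eff.loc[eff["class_label"] == "null", "gene"]))
        rows = []
        for cond in ("rss", "iss"):
            res = io.read_gene_results(
                need(f"gene_results_{cond}", out / f"gene_results_{cond}.tsv"))
            # depletion of essentials scores them positive: flip the sign
            scores = validation.combine_scores(res, gold)
            auc = validation.roc_auc(scores, gold)
            rows.append((cond, auc.auc, auc.n_pos, auc.n_neg))
        io.write_tsv(pd.DataFrame(rows, columns=["condition", "auc", "n_pos",
                                                 "n_neg"]),
                     out / "auc_report.tsv")
        artifacts["auc_report"] = out / "auc_report.tsv"

    if "classify" in stages:
        rss = io.read_gene_results(need("gene_results_rss",
                                        out / "gene_results_rss.tsv"))
        iss = io.read_gene_results(need("gene_results_iss",
                                        out / "gene_results_iss.tsv"))
        targeting = ~rss["gene"].str.startswith("NT_PSEUDO_")
        sig = classify.select_signature_genes(rss[targeting], iss,
                                              config.p_threshold)
        assign = classify.kmeans_classify(sig, k=config.k,
                                          n_restarts=config.kmeans_restarts,
                                          seed=config.stage_seed("kmeans"))
        universe = set(rss.loc[targeting, "gene"])
        sets = {
            "inflammaging": set(assign.loc[assign["set_label"] ==
                                           "inflammaging", "gene"]),
            "common_aging": set(assign.loc[assign["set_label"] ==
                                           "common_aging", "gene"]),
        }
        sets["control"] = classify.sample_control_genes(
            universe, [sets["inflammaging"], sets["common_aging"]],
            min(config.control_size,
                len(universe - sets["inflammaging"] - sets["common_aging"])),
            seed=config.stage_seed("control"))
        io.write_tsv(assign, out / "clusters.tsv")
        io.write_gmt(sets, out / "gene_sets.gmt")
        artifacts |= {"clusters": out / "clusters.tsv",
                      "gene_sets": out / "gene_sets.gmt"}

    # ---- heritability chain ----------------------------------------------
    if "simulate_genome" in stages:
        gene_map, snp_map = simulate.simulate_genome(
            config.n_genes, config.n_snps, config.n_blocks_ld,
            config.chrom_length, seed=config.stage_seed("genome"))
        io.write_gene_map(gene_map, out / "gene_map.tsv")
        io.write_gene_map_bed(gene_map, out / "gene_map.bed")
        io.write_snp_map(snp_map, out / "snp_map.tsv")
        artifacts |= {"gene_map": out / "gene_map.tsv",
                      "gene_map_bed": out / "gene_map.bed",
                      "snp_map": out / "snp_map.tsv"}

    if "annotate" in stages:
        gene_map = io.read_gene_map(need("gene_map", out / "gene_map.tsv"))
        snp_map = io.read_snp_map(need("snp_map", out / "snp_map.tsv"))
        sets = io.read_gmt(need("gene_sets", out / "gene_sets.gmt"))
        annot = heritability.build_annotation_matrix(
            sets, gene_map, snp_map, window_bp=config.window_bp)
        io.write_annotations(snp_map, annot, out / "annotations.tsv")
        artifacts["annotations"] = out / "annotations.tsv"

    if "gwas_ldsc" in stages:
        snp_map = io.read_snp_map(need("snp_map", out / "snp_map.tsv"))
        _, annot = io.read_annotations(need("annotations",
                                            out / "annotations.tsv"))
        ld = heritability.compute_ld_scores(snp_map, annot, rho=config.rho,
                                            window_bp=config.ld_window_bp)
        io.write_tsv(ld.add_suffix("L2"), out / "ldscores.tsv")
        artifacts["ldscores"] = out / "ldscores.tsv"
        truth_col = (annot["inflammaging"] if "inflammaging" in annot
                     else annot.columns[1])
        tau = tau_for_enrichment(truth_col.to_numpy(), config.h2_total,
                                 config.trait_enrichment)
        base_and_truth = annot[[heritability.BASE, truth_col.name]]

        rows, meta_rows = [], []
        n_traits = config.n_traits_enriched + config.n_traits_null
        for t in range(n_traits):
            enriched = t < config.n_traits_enriched
            tau_t = tau if enriched else np.array(
                [config.h2_total / config.n_snps, 0.0])
            sumstats, truth = simulate.simulate_gwas(
                snp_map, base_and_truth, tau_t, config.gwas_n, rho=config.rho,
                seed=config.stage_seed(f"gwas_{t}"))
            meta_rows.append((f"trait{t + 1:03d}", bool(enriched)))
            for name in annot.columns[1:]:
                cols = [heritability.BASE, name]
                fit = heritability.fit_sldsc(
                    sumstats, ld[cols], annot[cols],
                    n_blocks=config.n_jackknife_blocks)
                d, d_se = meta.per_snp_difference(fit, name)
                rows.append((f"trait{t + 1:03d}", name,
                             fit.enrichment_[name], fit.enrichment_se_[name],
                             d, d_se, fit.p_one_sided_[name]))
        fits = pd.DataFrame(rows, columns=["trait", "gene_set", "enrichment",
                                           "enrichment_se", "d", "d_se",
                                           "p_one_sided"])
        traits = pd.DataFrame(meta_rows, columns=["trait", "aging"])
        io.write_tsv(fits, out / "sldsc_fits.tsv")
        io.write_tsv(traits, out / "trait_metadata.tsv")
        artifacts |= {"sldsc_fits": out / "sldsc_fits.tsv",
                      "trait_metadata": out / "trait_metadata.tsv"}

    if "meta" in stages:
        fits = io.read_tsv(need("sldsc_fits", out / "sldsc_fits.tsv"))
        traits = io.read_tsv(need("trait_metadata",
                                  out / "trait_metadata.tsv"))
        merged = fits.merge(traits, on="trait")
        rows = []
        for (gs, aging), grp in merged.groupby(["gene_set", "aging"]):
            pooled_d = meta.random_effects_meta(grp["d"], grp["d_se"])
            pooled_enr = meta.random_effects_meta(grp["enrichment"],
                                                  grp["enrichment_se"])
            rows.append((gs, bool(aging), pooled_enr.pooled, pooled_enr.se,
                         pooled_d.pooled, pooled_d.se, pooled_d.tau2,
                         pooled_d.p_one_sided, pooled_d.n_studies))
        io.write_tsv(pd.DataFrame(rows, columns=[
            "gene_set", "aging", "enrichment", "enrichment_se", "d", "d_se",
            "tau2", "p_one_sided", "n_traits"]), out / "meta_results.tsv")
        enr_mat = merged.pivot(index="trait", columns="gene_set",
                               values="enrichment")
        io.write_tsv(enr_mat.reset_index(), out / "enrichment_matrix.tsv")
        artifacts |= {"meta_results": out / "meta_results.tsv",
                      "enrichment_matrix": out / "enrichment_matrix.tsv"}

    manifest = {name: {"path": str(p), "sha256": _sha256(p)}
                for name, p in sorted(artifacts.items())}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    logger.info("pipeline wrote %d artifacts to %s", len(manifest), out)
    return manifest
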