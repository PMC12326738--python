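"""Readers and writers for the package's tab-separated exchange formats.

All tables are TSV with headers (pandas handles gzip transparently via the
file extension). Gene coordinates are 1-based inclusive internally; the BED
export converts to 0-based half-open in the writer. Gene sets use the
standard GMT layout (set name, description, tab-separated member genes).
Every ``read_*``/``write_*`` pair round-trips losslessly on all fields.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

SCHEMAS = {
    "library": ["sgrna", "gene"],
    "counts": ["sgrna", "gene"],
    "design": ["sample_id", "condition", "timepoint", "replicate"],
    "gene_map": ["gene", "chrom", "tx_start", "tx_end"],
    "snp_map": ["snp", "chrom", "bp", "maf", "block"],
    "sumstats": ["SNP", "A1", "A2", "Z", "N"],
    "gene_results": ["gene", "condition", "beta", "se", "wald_p", "fdr",
                     "n_sgrnas"],
}

__all__ = ["read_tsv", "write_tsv", "read_library", "write_library",
           "read_counts", "write_counts", "read_design", "write_design",
           "read_gene_map", "write_gene_map", "write_gene_map_bed",
           "read_snp_map", "write_snp_map", "read_sumstats", "write_sumstats",
           "read_annotations", "write_annotations", "read_gene_results",
           "write_gene_results", "read_gmt", "write_gmt"]


def _check_schema(df: pd.DataFrame, kind: str, path) -> pd.DataFrame:
    required = SCHEMAS[kind]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing} "
                         f"for a {kind} table")
    return df


def _check_unique(df: pd.DataFrame, key: str, path) -> pd.DataFrame:
    dup = df[key][df[key].duplicated()]
    if not dup.empty:
        raise ValueError(f"{path}: duplicated {key} value(s): "
                         f"{sorted(set(dup))[:5]}")
    return df


def read_tsv(path) -> pd.DataFrame:
    # only empty fields are missing; keeps labels like "null" intact
    return pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[""])


def write_tsv(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def read_library(path) -> pd.DataFrame:
    return _check_unique(_check_schema(read_tsv(path), "library", path),
                         "sgrna", path)


def write_library(lib: pd.DataFrame, path) -> None:
    write_tsv(lib, path)


def read_counts(path) -> pd.DataFrame:
    df = _check_unique(_check_schema(read_tsv(path), "counts", path),
                       "sgrna", path)
    samples = [c for c in df.columns if c not in ("sgrna", "gene")]
    if not samples:
        raise ValueError(f"{path}: counts table has no sample columns")
    df[samples] = df[samples].astype(np.int64)
    return df


def write_counts(counts: pd.DataFrame, path) -> None:
    write_tsv(counts, path)


def read_design(path) -> pd.DataFrame:
    return _check_unique(_check_schema(read_tsv(path), "design", path),
                         "sample_id", path)


def write_design(design: pd.DataFrame, path) -> None:
    write_tsv(design, path)


def read_gene_map(path) -> pd.DataFrame:
    return _check_unique(_check_schema(read_tsv(path), "gene_map", path),
                         "gene", path)


def write_gene_map(gene_map: pd.DataFrame, path) -> None:
    write_tsv(gene_map, path)


def write_gene_map_bed(gene_map: pd.DataFrame, path) -> None:
    """BED export: 0-based half-open, columns chrom/start/end/name."""
    bed = pd.DataFrame({
        "chrom": gene_map["chrom"],
        "start": gene_map["tx_start"] - 1,
        "end": gene_map["tx_end"],
        "name": gene_map["gene"],
    })
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    bed.to_csv(path, sep="\t", index=False, header=False)


def read_snp_map(path) -> pd.DataFrame:
    return _check_unique(_check_schema(read_tsv(path), "snp_map", path),
                         "snp", path)


def write_snp_map(snp_map: pd.DataFrame, path) -> None:
    write_tsv(snp_map, path)


def read_sumstats(path) -> pd.DataFrame:
    return _check_unique(_check_schema(read_tsv(path), "sumstats", path),
                         "SNP", path)


def write_sumstats(sumstats: pd.DataFrame, path) -> None:
    write_tsv(sumstats, path)


def read_annotations(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """LDSC-style annotation table: CHR, SNP, BP then one 0/1 column per
    annotation. Returns (snp key frame, annotation matrix)."""
    df = read_tsv(path)
    for col in ("CHR", "SNP", "BP"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column(s) ['{col}'] "
                             f"for an annotations table")
    key = df[["CHR", "SNP", "BP"]]
    annot = df.drop(columns=["CHR", "SNP", "BP"])
    return key, annot


def write_annotations(snp_map: pd.DataFrame, annotations: pd.DataFrame,
                      path) -> None:
    out = pd.DataFrame({"CHR": snp_map["chrom"], "SNP": snp_map["snp"],
                        "BP": snp_map["bp"]})
    out = pd.concat([out.reset_index(drop=True),
                     annotations.reset_index(drop=True)], axis=1)
    write_tsv(out, path)


def read_gene_results(path) -> pd.DataFrame:
    return _check_schema(read_tsv(path), "gene_results", path)


def write_gene_results(results: pd.DataFrame, path) -> None:
    write_tsv(results[SCHEMAS["gene_results"]], path)


def read_gmt(path) -> dict[str, set]:
    """GMT gene sets: one line per set — name, description, member genes."""
    sets: dict[str, set] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}: GMT line needs name and "
                                 f"description: {line[:50]!r}")
            sets[parts[0]] = set(parts[2:])
    return sets


def write_gmt(gene_sets: dict, path, descriptions: dict | None = None) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for name, genes in gene_sets.items():
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *sorted(genes)]) + "\n")
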