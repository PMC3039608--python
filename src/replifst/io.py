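"""Readers and writers for the package's on-disk formats.

Tabular data (study records, association summaries, gene profiles, sample
maps, SNP sidecars, dosage matrices) travel as TSV with declared headers.
Genotypes can additionally be written as a plain-text VCF (GT fields, one
sample column per individual) with the population assignment in a sidecar
sample-map TSV and per-SNP annotation/outgroup alleles in an INFO-style
sidecar TSV; VCFs are read back through cyvcf2.  Positions are 0-based
half-open internally and converted to 1-based on VCF write/read.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import GenotypeTable

logger = logging.getLogger(__name__)

__all__ = [
    "write_study_records",
    "read_study_records",
    "write_table",
    "read_table",
    "write_genotypes_tsv",
    "read_genotypes_tsv",
    "write_vcf",
    "read_vcf",
]

_RECORD_COLS = [
    "record_id",
    "gene",
    "disease",
    "outcome",
    "ancestry_label",
    "sample_size",
    "year",
    "marker_id",
]


def write_study_records(records: pd.DataFrame, path) -> None:
    records.reindex(columns=_RECORD_COLS).to_csv(path, sep="\t", index=False)


def read_study_records(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"marker_id": str}, keep_default_na=False)
    missing = set(_RECORD_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"study record table lacks columns {sorted(missing)}")
    return df


def write_table(df: pd.DataFrame, path) -> None:
    """Generic TSV writer used for summaries, profiles and report tables."""
    df.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# genotype tables: dense dosage TSV + sidecars


def write_genotypes_tsv(gt: GenotypeTable, prefix) -> dict[str, Path]:
    """Write dosages, SNP sidecar and sample map as three TSVs.

    ``<prefix>.dosage.tsv`` holds snp_id plus one 0/1/2 column per sample
    (missing as NA); ``<prefix>.snps.tsv`` the per-SNP metadata;
    ``<prefix>.samples.tsv`` the sample -> population map.
    """
    prefix = Path(prefix)
    paths = {
        "dosage": prefix.with_suffix(".dosage.tsv"),
        "snps": prefix.with_suffix(".snps.tsv"),
        "samples": prefix.with_suffix(".samples.tsv"),
    }
    dosage = pd.DataFrame(
        gt.dosages.astype(float),
        columns=gt.samples["sample_id"].to_numpy(),
    )
    dosage[dosage < 0] = np.nan
    dosage.insert(0, "snp_id", gt.snps["snp_id"].to_numpy())
    dosage.to_csv(paths["dosage"], sep="\t", index=False, na_rep="NA")
    gt.snps.to_csv(paths["snps"], sep="\t", index=False)
    gt.samples.to_csv(paths["samples"], sep="\t", index=False)
    return paths


def read_genotypes_tsv(prefix) -> GenotypeTable:
    prefix = Path(prefix)
    snps = pd.read_csv(prefix.with_suffix(".snps.tsv"), sep="\t")
    samples = pd.read_csv(prefix.with_suffix(".samples.tsv"), sep="\t")
    dosage = pd.read_csv(prefix.with_suffix(".dosage.tsv"), sep="\t")
    mat = dosage[samples["sample_id"]].to_numpy(float)
    mat = np.where(np.isnan(mat), -1, mat).astype(np.int8)
    if not (dosage["snp_id"].to_numpy() == snps["snp_id"].to_numpy()).all():
        raise ValueError("dosage and SNP sidecar disagree on SNP order")
    return GenotypeTable(snps, mat, samples)


# ---------------------------------------------------------------------------
# VCF


def write_vcf(gt: GenotypeTable, path) -> None:
    """Write genotypes as a plain-text VCF 4.2 with GT fields.

    REF is the ancestral allele, ALT the derived allele, so the written
    allele dosage of ALT equals the internal derived-allele dosage.
    """
    path = Path(path)
    sample_ids = gt.samples["sample_id"].tolist()
    gt_strings = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=replifst\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("##contig=<ID=chr1>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_ids)
            + "\n"
        )
        snps = gt.snps
        for j in range(len(snps)):
            row = snps.iloc[j]
            calls = "\t".join(gt_strings[int(v)] for v in gt.dosages[j])
            fh.write(
                f"{row['chrom']}\t{int(row['pos']) + 1}\t{row['snp_id']}\t"
                f"{row['ancestral']}\t{row['derived']}\t.\tPASS\t"
                f"GENE={row['gene']}\tGT\t{calls}\n"
            )


def read_vcf(vcf_path, sample_map_path, snp_sidecar_path) -> GenotypeTable:
    """Read a VCF of biallelic SNPs back into a genotype table.

    Multiallelic records are skipped with a warning.  Population labels
    come from the sample-map TSV; gene, annotation class and outgroup
    alleles from the SNP sidecar TSV (joined on snp_id).
    """
    from cyvcf2 import VCF

    samples_df = pd.read_csv(sample_map_path, sep="\t")
    sidecar = pd.read_csv(snp_sidecar_path, sep="\t").set_index("snp_id")

    vcf = VCF(str(vcf_path))
    order = {s: i for i, s in enumerate(vcf.samples)}
    rows, dosages = [], []
    for var in vcf:
        if len(var.ALT) != 1:
            logger.warning("skipping multiallelic record %s", var.ID)
            continue
        g = np.asarray(var.genotypes, dtype=int)[:, :2]
        d = np.where((g >= 0).all(axis=1), g.sum(axis=1), -1).astype(np.int8)
        dosages.append(d)
        meta = sidecar.loc[var.ID]
        rows.append(
            {
                "snp_id": var.ID,
                "gene": meta["gene"],
                "pos": var.POS - 1,  # back to 0-based
                "annotation": meta["annotation"],
                "ancestral": var.REF,
                "derived": var.ALT[0],
                "outgroup_chimp": meta["outgroup_chimp"],
                "outgroup_macaque": meta["outgroup_macaque"],
                "chrom": var.CHROM,
            }
        )
    snps = pd.DataFrame(rows)
    mat = np.vstack(dosages) if dosages else np.zeros((0, len(samples_df)), np.int8)
    # reorder columns to match the sample map
    cols = [order[s] for s in samples_df["sample_id"]]
    return GenotypeTable(snps, mat[:, cols], samples_df)
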