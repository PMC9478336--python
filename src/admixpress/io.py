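"""Readers and writers for the pipeline's external formats.

VCF 4.2 (GT and DP) for genotypes, TSV with documented headers for all
tabular data, and a BED-like segment file. All genomic coordinates in
these files are 1-based and end-inclusive (VCF convention); the BED-like
files say so in a comment header to avoid the 0-based BED ambiguity.
"""

from __future__ import annotations

import os

import pandas as pd
import pysam

__all__ = [
    "write_vcf",
    "read_vcf",
    "write_tsv",
    "read_tsv",
    "write_segments_bed",
    "read_segments_bed",
    "read_gene_bed",
    "write_gene_bed",
    "read_counts",
    "read_sample_sheet",
]

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=admixpress
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
"""


def write_vcf(genotypes: pd.DataFrame, path: str, sample: str) -> None:
    """Write a one-sample genotype table (chrom, pos, ref, alt, gt, dp)
    as minimal VCF 4.2 with GT and DP."""
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for chrom in pd.unique(genotypes["chrom"]):
            sub = genotypes[genotypes["chrom"] == chrom]
            fh.write(f"##contig=<ID={chrom},length={int(sub['pos'].max()) + 1}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            f"{sample}\n"
        )
        for rec in genotypes.itertuples(index=False):
            fh.write(
                f"{rec.chrom}\t{rec.pos}\t.\t{rec.ref}\t{rec.alt}\t.\tPASS\t.\t"
                f"GT:DP\t{rec.gt}:{rec.dp}\n"
            )


def read_vcf(path: str) -> pd.DataFrame:
    """Read a one-sample VCF into a (chrom, pos, ref, alt, gt, dp) table."""
    rows = []
    with pysam.VariantFile(path) as vcf:
        samples = list(vcf.header.samples)
        if len(samples) != 1:
            raise ValueError(f"{path}: expected exactly one sample, found {samples}")
        sample = samples[0]
        for rec in vcf:
            call = rec.samples[sample]
            gt = call.get("GT")
            if gt is None or any(a is None for a in gt):
                gt_str = "./."
            else:
                sep = "|" if call.phased else "/"
                gt_str = sep.join(str(a) for a in gt)
            dp = call.get("DP")
            rows.append(
                (
                    rec.chrom,
                    rec.pos,
                    rec.ref,
                    ",".join(rec.alts) if rec.alts else ".",
                    gt_str,
                    int(dp) if dp is not None else 0,
                )
            )
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "gt", "dp"])


def write_tsv(df: pd.DataFrame, path: str, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_tsv(path: str, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


_SEG_COMMENT = "# coordinates are 1-based, end-inclusive\n"


def write_segments_bed(segments: pd.DataFrame, path: str) -> None:
    """Write ancestry segments (chrom, start, end, label[, n_windows,
    stable]) as a BED-like TSV with a coordinate-convention header."""
    with open(path, "w") as fh:
        fh.write(_SEG_COMMENT)
        segments.to_csv(fh, sep="\t", index=False)


def read_segments_bed(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_gene_bed(genes: pd.DataFrame, path: str) -> None:
    """Write gene models (gene, chrom, start, end, strand), 1-based
    inclusive, as a BED-like TSV."""
    with open(path, "w") as fh:
        fh.write(_SEG_COMMENT)
        genes.to_csv(fh, sep="\t", index=False)


def read_gene_bed(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"gene", "chrom", "start", "end"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: gene table lacks columns {sorted(missing)}")
    return df


def read_counts(path: str) -> pd.DataFrame:
    """Read a genes x samples count matrix; first column is the gene id."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "gene"
    return df


def read_sample_sheet(path: str) -> pd.Series:
    """Read a sample sheet (sample, group[, replicate]) into a
    sample -> group Series."""
    df = pd.read_csv(path, sep="\t")
    for col in ("sample", "group"):
        if col not in df.columns:
            raise ValueError(f"{path}: sample sheet lacks column {col!r}")
    return df.set_index("sample")["group"]


def ensure_dir(path: str) -> None:
    os.makedirs(path, exist_ok=True)
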