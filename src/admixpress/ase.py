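"""Allele-specific expression at species-informative markers and
haplotype-stratified expression summaries.

Within heterozygous (PU/MA) tracts every SIM inside a gene reports RNA
reads for the pummelo and the mandarin allele per biological replicate. A
SIM is usable when its mean depth across replicates reaches 10x and all
replicates agree on the RNA genotype; a gene enters the analysis when at
least 80% of its SIMs are usable. Homozygosity of the RNA genotype at all
usable SIMs is read as exclusive expression of that allele.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

__all__ = [
    "rna_genotype",
    "filter_ase_genes",
    "call_allele_expression",
    "call_ase_table",
    "haplotype_expression_summary",
]

logger = logging.getLogger(__name__)

HAPLOTYPES = ["MA/MA", "PU/MA", "PU/PU"]


def rna_genotype(reads_a: int, reads_b: int) -> str | None:
    """Call the RNA genotype at one SIM in one replicate.

    Homozygous for the major allele when the minor allele has fewer than 2
    reads AND under 5% of the site's reads; heterozygous otherwise; None
    (no call) with zero coverage.
    """
    total = reads_a + reads_b
    if total == 0:
        return None
    minor = min(reads_a, reads_b)
    if minor < 2 and minor / total < 0.05:
        return "A" if reads_a >= reads_b else "B"
    return "AB"


def _per_sim_calls(allele_counts: pd.DataFrame) -> pd.DataFrame:
    """Aggregate the replicate-level table to one row per (gene, chrom,
    pos) with mean depth, replicate-consistent genotype (or None), pooled
    reads and a pass flag placeholder."""
    rows = []
    for (gene, chrom, pos), sub in allele_counts.groupby(
        ["gene", "chrom", "pos"], sort=True
    ):
        calls = [
            rna_genotype(int(r.reads_a), int(r.reads_b))
            for r in sub.itertuples(index=False)
        ]
        depth = (sub["reads_a"] + sub["reads_b"]).mean()
        consistent = len(set(calls)) == 1 and calls[0] is not None
        rows.append(
            (
                gene, chrom, pos, float(depth),
                calls[0] if consistent else None,
                int(sub["reads_a"].sum()), int(sub["reads_b"].sum()),
            )
        )
    return pd.DataFrame(
        rows,
        columns=["gene", "chrom", "pos", "mean_depth", "genotype",
                 "reads_a", "reads_b"],
    )


def filter_ase_genes(
    allele_counts: pd.DataFrame,
    gene_haplotypes: pd.DataFrame,
    min_mean_depth: float = 10.0,
    min_frac_pass: float = 0.8,
) -> tuple[pd.Index, pd.DataFrame]:
    """Select genes eligible for allele-expression analysis.

    Only genes labelled PU/MA enter. A SIM passes when its mean depth
    across replicates is at least ``min_mean_depth`` and its RNA genotype
    call is identical in all replicates; a gene is eligible when the
    fraction of its SIMs passing reaches ``min_frac_pass``. Genes without
    any SIM are excluded and logged.

    Parameters
    ----------
    allele_counts
        Long table (gene, chrom, pos, rep, reads_a, reads_b) for one
        segregant; reads_a are pummelo-allele reads.
    gene_haplotypes
        Per-gene ancestry labels (columns gene, label).

    Returns
    -------
    (eligible gene index, per-SIM table with a ``passes`` column)
    """
    puma = set(gene_haplotypes.loc[gene_haplotypes["label"] == "PU/MA", "gene"])
    sub = allele_counts[allele_counts["gene"].isin(puma)]
    dropped = puma - set(sub["gene"])
    if dropped:
        logger.info("filter_ase_genes: %d PU/MA gene(s) without SIM coverage",
                    len(dropped))
    sims = _per_sim_calls(sub)
    sims["passes"] = (sims["mean_depth"] >= min_mean_depth) & sims[
        "genotype"
    ].notna()
    frac = sims.groupby("gene")["passes"].mean()
    eligible = frac.index[frac >= min_frac_pass]
    return pd.Index(eligible, name="gene"), sims


def call_allele_expression(
    gene: str, sims: pd.DataFrame
) -> dict:
    """Classify the allelic expression of one eligible gene.

    Over its passing SIMs: RNA genotype homozygous pummelo at every SIM ->
    PU_only; homozygous mandarin at every SIM -> MA_only; otherwise
    biallelic. The pummelo-allele fraction pools reads over passing SIMs
    and replicates (depth weighting).
    """
    sub = sims[(sims["gene"] == gene) & sims["passes"]]
    if sub.empty:
        raise ValueError(f"gene {gene!r} has no passing SIM (did it pass the filter?)")
    total_a = int(sub["reads_a"].sum())
    total_b = int(sub["reads_b"].sum())
    if total_a + total_b == 0:
        raise ValueError(f"gene {gene!r} has zero RNA reads at passing SIMs")
    calls = set(sub["genotype"])
    if calls == {"A"}:
        cls = "PU_only"
    elif calls == {"B"}:
        cls = "MA_only"
    else:
        cls = "biallelic"
    n_total = int((sims["gene"] == gene).sum())
    return {
        "gene": gene,
        "n_sims_considered": n_total,
        "n_sims_passing": int(len(sub)),
        "class": cls,
        "pu_fraction": total_a / (total_a + total_b),
    }


def call_ase_table(
    allele_counts: pd.DataFrame,
    gene_haplotypes: pd.DataFrame,
    min_mean_depth: float = 10.0,
    min_frac_pass: float = 0.8,
) -> pd.DataFrame:
    """Filter + classify in one step; one row per eligible gene."""
    eligible, sims = filter_ase_genes(
        allele_counts, gene_haplotypes, min_mean_depth, min_frac_pass
    )
    rows = [call_allele_expression(g, sims) for g in eligible]
    out = pd.DataFrame(
        rows,
        columns=["gene", "n_sims_considered", "n_sims_passing", "class",
                 "pu_fraction"],
    )
    return out


def haplotype_expression_summary(
    gene_haplotypes: pd.DataFrame,
    counts: pd.DataFrame,
    deg_genes: set[str] | pd.Index,
    min_reads: int = 10,
    samples: list[str] | None = None,
) -> pd.DataFrame:
    """Distribution of expressed genes and DEG frequency per haplotype.

    A gene is expressed when some replicate's raw count reaches
    ``min_reads``. Proportions are over assigned (non-UNASSIGNED) expressed
    genes and sum to 1; the DEG frequency of a haplotype is the fraction
    of its expressed genes that are DEGs.
    """
    cols = samples if samples is not None else list(counts.columns)
    deg_genes = set(deg_genes)
    lab = gene_haplotypes.set_index("gene")["label"]
    common = [g for g in lab.index if g in counts.index]
    expressed = counts.loc[common, cols].max(axis=1) >= min_reads
    rows = []
    n_assigned_expressed = sum(
        1 for g in common if expressed[g] and lab[g] in HAPLOTYPES
    )
    for hap in HAPLOTYPES:
        genes_h = [g for g in common if lab[g] == hap and expressed[g]]
        n_deg = sum(1 for g in genes_h if g in deg_genes)
        prop = len(genes_h) / n_assigned_expressed if n_assigned_expressed else 0.0
        freq = n_deg / len(genes_h) if genes_h else 0.0
        rows.append((hap, len(genes_h), prop, n_deg, freq))
    return pd.DataFrame(
        rows,
        columns=["haplotype", "n_expressed", "proportion", "n_deg",
                 "deg_frequency"],
    )
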