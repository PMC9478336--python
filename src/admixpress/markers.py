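"""Species-informative marker (SIM) derivation.

A SIM is a biallelic SNP site at which the two ancestral species panels are
homozygous for different alleles — a fixed interspecific difference — with
adequate read support in both panels. SIMs are the atomic unit of local
ancestry painting and of allele-specific expression.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

__all__ = ["call_sims", "genotype_alleles"]

logger = logging.getLogger(__name__)


class InputFormatError(ValueError):
    """Raised for unsorted or duplicated input sites."""


def _check_sorted_unique(panel: pd.DataFrame, name: str) -> None:
    for chrom, sub in panel.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        if len(pos) > 1:
            diffs = np.diff(pos)
            if (diffs < 0).any():
                where = pos[1:][diffs < 0][0]
                raise InputFormatError(
                    f"{name}: positions not sorted on {chrom} (at {chrom}:{where})"
                )
            if (diffs == 0).any():
                where = pos[1:][diffs == 0][0]
                raise InputFormatError(
                    f"{name}: duplicate site {chrom}:{where}"
                )


def genotype_alleles(gt: str, ref: str, alt: str) -> tuple[str, str] | None:
    """Resolve a GT string against REF/ALT bases.

    Returns the two allele bases, or None for missing calls. ALT may list
    several comma-separated alleles; indices beyond the list raise.
    """
    if gt in ("./.", ".", ".|."):
        return None
    sep = "|" if "|" in gt else "/"
    alleles = [ref] + alt.split(",")
    try:
        i, j = (int(x) for x in gt.split(sep))
    except ValueError:
        return None
    return alleles[i], alleles[j]


def call_sims(
    panel_a: pd.DataFrame,
    panel_b: pd.DataFrame,
    min_depth: int = 20,
) -> pd.DataFrame:
    """Call species-informative markers from two ancestral panels.

    A site qualifies when panel A is homozygous for one allele, panel B is
    homozygous for a different allele, and read depth is at least
    ``min_depth`` in *both* panels (a marker unreliable in either species
    is unreliable overall). Heterozygous, missing and multi-allelic
    genotypes disqualify a site; multi-allelic skips are counted and
    logged.

    Parameters
    ----------
    panel_a, panel_b
        Genotype tables with columns (chrom, pos, ref, alt, gt, dp),
        sorted by position within chromosome, one row per site.
    min_depth
        Minimum supporting reads required in each panel (default 20).

    Returns
    -------
    DataFrame with columns (chrom, pos, allele_a, allele_b), sorted by
    (chrom, pos); allele_a is the base fixed in species A (pummelo),
    allele_b the base fixed in species B (mandarin).
    """
    _check_sorted_unique(panel_a, "panel_a")
    _check_sorted_unique(panel_b, "panel_b")

    merged = panel_a.merge(
        panel_b, on=["chrom", "pos"], suffixes=("_a", "_b"), how="inner"
    )

    n_multi = 0
    rows = []
    for rec in merged.itertuples(index=False):
        if "," in rec.alt_a or "," in rec.alt_b:
            n_multi += 1
            continue
        pa = genotype_alleles(rec.gt_a, rec.ref_a, rec.alt_a)
        pb = genotype_alleles(rec.gt_b, rec.ref_b, rec.alt_b)
        if pa is None or pb is None:
            continue
        if pa[0] != pa[1] or pb[0] != pb[1]:
            continue  # not in homozygosis
        if pa[0] == pb[0]:
            continue  # shared allele, not a fixed difference
        if rec.dp_a < min_depth or rec.dp_b < min_depth:
            continue
        rows.append((rec.chrom, rec.pos, pa[0], pb[0]))

    if n_multi:
        logger.info("call_sims: skipped %d multi-allelic site(s)", n_multi)

    out = pd.DataFrame(rows, columns=["chrom", "pos", "allele_a", "allele_b"])
    return out.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
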