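"""Local ancestry painting of segregant genomes.

For every species-informative marker the copy number of each ancestral
allele (2, 1 or 0) is recorded; non-overlapping windows of 1000 markers are
labelled by the most frequent pattern; runs of at least five identically
labelled windows form stable segments, and every remaining window inherits
the label of the nearest stable block. Genes receive the label of the
segment with which their body overlaps the most.

Labels: PU/PU (two pummelo copies), PU/MA (heterozygous), MA/MA (two
mandarin copies); AMBIGUOUS marks a tied window vote before smoothing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .markers import genotype_alleles

__all__ = [
    "site_patterns",
    "infer_windows",
    "smooth_segments",
    "assign_gene_haplotypes",
    "AMBIGUOUS",
    "UNASSIGNED",
]

logger = logging.getLogger(__name__)

AMBIGUOUS = "AMBIGUOUS"
UNASSIGNED = "UNASSIGNED"

_PATTERN_LABEL = {(2, 0): "PU/PU", (1, 1): "PU/MA", (0, 2): "MA/MA"}
_LABELS = ["PU/PU", "PU/MA", "MA/MA"]


@dataclass
class PatternResult:
    """Per-SIM allele copy numbers plus the count of excluded sites."""

    patterns: pd.DataFrame  # chrom, pos, copies_a, copies_b
    n_excluded: int


def site_patterns(genotypes: pd.DataFrame, sims: pd.DataFrame) -> PatternResult:
    """Copy number of each diagnostic allele at every genotyped SIM.

    ``copies_a`` counts pummelo-allele copies, ``copies_b`` mandarin. Sites
    whose genotype carries an allele matching neither diagnostic allele
    (or a missing call) are excluded and tallied.
    """
    merged = sims.merge(genotypes, on=["chrom", "pos"], how="inner")
    n_excluded = 0
    rows = []
    for rec in merged.itertuples(index=False):
        pair = genotype_alleles(rec.gt, rec.ref, rec.alt)
        if pair is None:
            n_excluded += 1
            continue
        ca = sum(1 for x in pair if x == rec.allele_a)
        cb = sum(1 for x in pair if x == rec.allele_b)
        if ca + cb != 2:
            n_excluded += 1
            continue
        rows.append((rec.chrom, rec.pos, ca, cb))
    if n_excluded:
        logger.info("site_patterns: excluded %d site(s) with off-type alleles",
                    n_excluded)
    df = pd.DataFrame(rows, columns=["chrom", "pos", "copies_a", "copies_b"])
    return PatternResult(df, n_excluded)


def infer_windows(patterns: pd.DataFrame, window_size: int = 1000) -> pd.DataFrame:
    """Tile each chromosome into consecutive blocks of ``window_size``
    markers and label each by majority vote of its patterns.

    The trailing partial window is kept as its own window when it holds at
    least half a window of markers, otherwise it is merged into the
    previous window. An exact tie in the vote yields AMBIGUOUS.

    Returns a DataFrame (chrom, window_index, start_pos, end_pos,
    n_pupu, n_puma, n_mama, label).
    """
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    rows = []
    for chrom in pd.unique(patterns["chrom"]):
        sub = patterns[patterns["chrom"] == chrom]
        pos = sub["pos"].to_numpy()
        if not np.all(np.diff(pos) > 0):
            order = np.argsort(pos, kind="mergesort")
            sub = sub.iloc[order]
            pos = sub["pos"].to_numpy()
        n = len(sub)
        if n == 0:
            logger.warning("infer_windows: no markers on %s", chrom)
            continue
        bounds = list(range(0, n, window_size)) + [n]
        # merge a short trailing partial window into the previous one
        if len(bounds) >= 3 and (bounds[-1] - bounds[-2]) < window_size / 2:
            del bounds[-2]
        ca = sub["copies_a"].to_numpy()
        for w, (lo, hi) in enumerate(zip(bounds[:-1], bounds[1:])):
            block = ca[lo:hi]
            tallies = [
                int((block == 2).sum()),  # PU/PU
                int((block == 1).sum()),  # PU/MA
                int((block == 0).sum()),  # MA/MA
            ]
            best = max(tallies)
            winners = [lab for lab, t in zip(_LABELS, tallies) if t == best]
            label = winners[0] if len(winners) == 1 else AMBIGUOUS
            rows.append(
                (chrom, w, int(pos[lo]), int(pos[hi - 1]), *tallies, label)
            )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "window_index", "start_pos", "end_pos",
            "n_pupu", "n_puma", "n_mama", "label",
        ],
    )


def _stable_runs(labels: np.ndarray, min_stable: int) -> list[tuple[int, int, str]]:
    """Maximal runs [i, j) of identical non-AMBIGUOUS labels of length
    >= min_stable."""
    runs = []
    i = 0
    n = len(labels)
    while i < n:
        j = i
        while j < n and labels[j] == labels[i]:
            j += 1
        if labels[i] != AMBIGUOUS and (j - i) >= min_stable:
            runs.append((i, j, str(labels[i])))
        i = j
    return runs


def smooth_segments(windows: pd.DataFrame, min_stable: int = 5) -> pd.DataFrame:
    """Smooth window labels into ancestry segments.

    Runs of at least ``min_stable`` identically labelled windows are stable
    blocks; every other window (including AMBIGUOUS ones) is reassigned the
    label of the nearest stable block, measured in window-index distance
    with ties going to the left (5') neighbour. Adjacent same-label windows
    are then merged into segments spanning first-to-last member marker. A
    chromosome with no stable run collapses to one unstable segment
    carrying its most frequent window label.

    Returns a DataFrame (chrom, start, end, label, n_windows, stable).
    """
    if min_stable < 1:
        raise ValueError("min_stable must be >= 1")
    out = []
    for chrom in pd.unique(windows["chrom"]):
        sub = windows[windows["chrom"] == chrom].sort_values("window_index")
        labels = sub["label"].to_numpy()
        n = len(labels)
        runs = _stable_runs(labels, min_stable)
        smoothed = np.empty(n, dtype=object)
        in_stable = np.zeros(n, dtype=bool)
        if not runs:
            # fallback: the single most frequent window label (first seen
            # breaks ties), unstable, spanning the chromosome
            counts: dict[str, int] = {}
            for lab in labels:
                if lab != AMBIGUOUS:
                    counts[lab] = counts.get(lab, 0) + 1
            if counts:
                best = max(counts.values())
                label = next(lab for lab in labels if counts.get(lab) == best)
            else:
                label = AMBIGUOUS
            out.append(
                (
                    chrom,
                    int(sub["start_pos"].iloc[0]),
                    int(sub["end_pos"].iloc[-1]),
                    label,
                    n,
                    False,
                )
            )
            continue
        for i0, j0, lab in runs:
            smoothed[i0:j0] = lab
            in_stable[i0:j0] = True
        for w in np.flatnonzero(~in_stable):
            best_lab, best_d = None, None
            for i0, j0, lab in runs:
                d = i0 - w if w < i0 else (w - (j0 - 1) if w >= j0 else 0)
                # tie in distance -> left (5') neighbour: runs are scanned
                # left to right, so strict improvement keeps the left one
                if best_d is None or d < best_d:
                    best_lab, best_d = lab, d
            smoothed[w] = best_lab

        start_pos = sub["start_pos"].to_numpy()
        end_pos = sub["end_pos"].to_numpy()
        i = 0
        while i < n:
            j = i
            while j < n and smoothed[j] == smoothed[i]:
                j += 1
            out.append(
                (
                    chrom,
                    int(start_pos[i]),
                    int(end_pos[j - 1]),
                    str(smoothed[i]),
                    j - i,
                    bool(in_stable[i:j].any()),
                )
            )
            i = j
    return pd.DataFrame(
        out, columns=["chrom", "start", "end", "label", "n_windows", "stable"]
    )


def assign_gene_haplotypes(
    segments: pd.DataFrame, gene_models: pd.DataFrame
) -> pd.DataFrame:
    """Label every gene with the haplotype combination of the ancestry
    segment its body overlaps the most (base pairs, 1-based inclusive).

    An overlap tie goes to the segment containing the gene start; a gene
    with no overlapping segment is UNASSIGNED.
    """
    bad = gene_models[gene_models["end"] < gene_models["start"]]
    if not bad.empty:
        raise ValueError(
            f"malformed gene model(s): {bad['gene'].tolist()} (end < start)"
        )
    seg_by_chrom = {c: s for c, s in segments.groupby("chrom")}
    labels = []
    for rec in gene_models.itertuples(index=False):
        sub = seg_by_chrom.get(rec.chrom)
        if sub is None:
            labels.append(UNASSIGNED)
            continue
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        ov = np.clip(
            np.minimum(ends, rec.end) - np.maximum(starts, rec.start) + 1, 0, None
        )
        if ov.max() == 0:
            labels.append(UNASSIGNED)
            continue
        best = np.flatnonzero(ov == ov.max())
        if len(best) > 1:
            contains = best[(starts[best] <= rec.start) & (ends[best] >= rec.start)]
            pick = contains[0] if len(contains) else best[0]
        else:
            pick = best[0]
        labels.append(str(sub["label"].to_numpy()[pick]))
    out = gene_models[["gene", "chrom", "start", "end"]].copy()
    out["label"] = labels
    return out
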