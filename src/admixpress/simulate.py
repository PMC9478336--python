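"""Synthetic two-species admixture study generator.

Emulates the statistical structure the downstream analysis assumes: two pure
ancestral genomes (species A = pummelo, species B = mandarin) separated by
fixed homozygous differences, F1-cross segregants whose genomes are mosaics
of MA/MA, PU/MA and PU/PU tracts produced by crossovers, Poisson sequencing
depth per site, and negative-binomial expression counts for five genotype
groups (ICH, SCM, S1, S2, S3) with three biological replicates each, with
configurable fold changes and allelic imbalance.

Randomness is split into independent streams per stage and per segregant
(seeded from the master seed) so that, e.g., adding a segregant never
perturbs the panels or an earlier segregant.

Coordinates are 1-based and end-inclusive throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ConfigError, SimConfig

__all__ = [
    "TrueMosaic",
    "ExpressionSim",
    "GROUPS",
    "SEGREGANT_GROUPS",
    "chromosome_length",
    "simulate_panels",
    "simulate_segregant",
    "simulate_gene_models",
    "simulate_expression",
]

#: haplotype-combination labels (pummelo allele copies / mandarin copies)
LABEL_PUPU = "PU/PU"
LABEL_PUMA = "PU/MA"
LABEL_MAMA = "MA/MA"

GROUPS = ["ICH", "SCM", "S1", "S2", "S3"]
SEGREGANT_GROUPS = ["S1", "S2", "S3"]

_BASES = np.array(list("ACGT"))

# stage ids for the per-stage RNG streams
_STAGE_PANELS = 0
_STAGE_SEGREGANT = 1
_STAGE_EXPRESSION = 2
_STAGE_GENES = 3
_STAGE_ASE = 4


def _rng(config: SimConfig, stage: int, index: int = 0) -> np.random.Generator:
    return np.random.default_rng([config.seed, stage, index])


def chromosome_length(config: SimConfig) -> int:
    """Length in bp of each simulated chromosome (sites are ~1 per 10 bp)."""
    return 10 * config.sites_per_chromosome


@dataclass(frozen=True)
class TrueMosaic:
    """Ground-truth ancestry tract structure of one segregant.

    ``tracts`` has columns (chrom, start, end, label); tracts tile each
    chromosome 1..L without gap or overlap, 1-based end-inclusive, and
    adjacent tracts carry different labels.
    """

    segregant: str
    tracts: pd.DataFrame

    def label_at(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Tract label for each position on ``chrom`` (vectorised)."""
        sub = self.tracts[self.tracts["chrom"] == chrom]
        if sub.empty:
            raise KeyError(f"no tracts on chromosome {chrom!r}")
        starts = sub["start"].to_numpy()
        labels = sub["label"].to_numpy()
        idx = np.searchsorted(starts, np.asarray(positions), side="right") - 1
        if (idx < 0).any():
            raise ValueError("position before first tract")
        return labels[idx]

    def breakpoints(self, chrom: str) -> np.ndarray:
        """Start positions of every tract after the first (true crossovers)."""
        sub = self.tracts[self.tracts["chrom"] == chrom]
        return sub["start"].to_numpy()[1:]


def simulate_panels(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate the two pure ancestral genotype panels.

    Returns ``(panel_a, panel_b, site_map)``. Panels have columns
    (chrom, pos, ref, alt, gt, dp); exactly
    ``round(fixed_diff_fraction * sites)`` sites per chromosome carry
    opposite homozygous genotypes in the two panels, the remaining sites
    share one homozygous genotype. Depth is Poisson(mean_dna_depth) per
    site per panel. ``site_map`` additionally records, per site, which
    base is fixed in which species (allele_a = pummelo, allele_b =
    mandarin) and the shared genotype of non-diagnostic sites.
    """
    rng = _rng(config, _STAGE_PANELS)
    L = chromosome_length(config)
    n = config.sites_per_chromosome
    n_fixed = round(config.fixed_diff_fraction * n)

    frames = []
    for c in range(config.n_chromosomes):
        chrom = f"chr{c + 1}"
        pos = np.sort(rng.choice(np.arange(1, L + 1), size=n, replace=False))
        ref_idx = rng.integers(0, 4, size=n)
        alt_idx = (ref_idx + rng.integers(1, 4, size=n)) % 4
        fixed = np.zeros(n, dtype=bool)
        fixed[rng.choice(n, size=n_fixed, replace=False)] = True
        # orientation: is the pummelo-fixed allele the REF base?
        a_is_ref = rng.random(n) < 0.5
        # shared sites: both panels homozygous for the same allele
        shared_is_ref = rng.random(n) < 0.5
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": pos,
                    "ref": _BASES[ref_idx],
                    "alt": _BASES[alt_idx],
                    "is_fixed_diff": fixed,
                    "a_is_ref": a_is_ref,
                    "shared_is_ref": shared_is_ref,
                }
            )
        )
    site_map = pd.concat(frames, ignore_index=True)

    ref = site_map["ref"].to_numpy()
    alt = site_map["alt"].to_numpy()
    fixed = site_map["is_fixed_diff"].to_numpy()
    a_is_ref = site_map["a_is_ref"].to_numpy()
    shared_is_ref = site_map["shared_is_ref"].to_numpy()

    site_map["allele_a"] = np.where(fixed, np.where(a_is_ref, ref, alt), "")
    site_map["allele_b"] = np.where(fixed, np.where(a_is_ref, alt, ref), "")
    site_map["shared_gt"] = np.where(shared_is_ref, "0/0", "1/1")

    gt_a = np.where(fixed, np.where(a_is_ref, "0/0", "1/1"), site_map["shared_gt"])
    gt_b = np.where(fixed, np.where(a_is_ref, "1/1", "0/0"), site_map["shared_gt"])

    m = len(site_map)
    base = site_map[["chrom", "pos", "ref", "alt"]]
    panel_a = base.copy()
    panel_a["gt"] = gt_a
    panel_a["dp"] = rng.poisson(config.mean_dna_depth, size=m)
    panel_b = base.copy()
    panel_b["gt"] = gt_b
    panel_b["dp"] = rng.poisson(config.mean_dna_depth, size=m)
    return panel_a, panel_b, site_map


def _draw_gamete_breakpoints(
    rng: np.random.Generator, rate: float, length: int
) -> tuple[np.ndarray, int]:
    """Crossover positions (sorted, 2..length) and the starting species
    (0 = pummelo, 1 = mandarin) of one gamete. No interference: counts are
    Poisson, positions uniform along the chromosome."""
    k = rng.poisson(rate)
    bp = np.sort(rng.integers(2, length + 1, size=k))
    start = int(rng.integers(0, 2))
    return bp, start


def _gamete_labels_at(bp: np.ndarray, start: int, positions: np.ndarray) -> np.ndarray:
    """Species (0/1) carried by a gamete at each position."""
    flips = np.searchsorted(bp, positions, side="right")
    return (start + flips) % 2


def simulate_segregant(
    site_map: pd.DataFrame,
    config: SimConfig,
    segregant_index: int,
    *,
    min_tract_markers: int | None = None,
    max_redraws: int = 100_000,
) -> tuple[TrueMosaic, pd.DataFrame]:
    """Simulate one segregant: true ancestry mosaic plus genotype table.

    Each chromosome receives two gametes whose crossover breakpoints are
    drawn Poisson(crossovers_per_chromosome) with uniform positions; the
    genotype at every site combines one allele from each gamete, so the
    genotype at a fixed-difference site is a deterministic function of the
    tract label there. With ``min_tract_markers`` set, breakpoint
    configurations whose tracts would contain fewer diagnostic markers than
    that are redrawn, which constrains the simulation to long-tract mosaics.
    """
    if segregant_index < 0 or segregant_index >= config.n_segregants:
        raise ConfigError(
            f"segregant_index must be in [0, {config.n_segregants}) "
            f"(got {segregant_index})"
        )
    rng = _rng(config, _STAGE_SEGREGANT, segregant_index)
    L = chromosome_length(config)
    name = f"S{segregant_index + 1}"

    tract_rows = []
    geno_frames = []
    for chrom, sites in site_map.groupby("chrom", sort=True):
        pos = sites["pos"].to_numpy()
        marker_pos = pos[sites["is_fixed_diff"].to_numpy()]
        for _ in range(max_redraws):
            bp1, s1 = _draw_gamete_breakpoints(rng, config.crossovers_per_chromosome, L)
            bp2, s2 = _draw_gamete_breakpoints(rng, config.crossovers_per_chromosome, L)
            cuts = np.unique(np.concatenate([bp1, bp2]))
            if min_tract_markers is None:
                break
            edges = np.concatenate([[1], cuts, [L + 1]])
            counts = np.diff(np.searchsorted(marker_pos, edges, side="left"))
            if (counts >= min_tract_markers).all():
                break
        else:
            raise RuntimeError(
                f"could not draw tracts with >= {min_tract_markers} markers "
                f"on {chrom} after {max_redraws} attempts"
            )

        starts = np.concatenate([[1], cuts])
        ends = np.concatenate([cuts - 1, [L]])
        mids = starts  # label is constant on [start, end]; evaluate at start
        g1 = _gamete_labels_at(bp1, s1, mids)
        g2 = _gamete_labels_at(bp2, s2, mids)
        n_pu = (g1 == 0).astype(int) + (g2 == 0).astype(int)
        labels = np.array([LABEL_MAMA, LABEL_PUMA, LABEL_PUPU])[n_pu]

        # merge zero-length artefacts and adjacent equal labels
        keep_start, keep_end, keep_label = [], [], []
        for s, e, lab in zip(starts, ends, labels):
            if e < s:
                continue
            if keep_label and keep_label[-1] == lab:
                keep_end[-1] = e
            else:
                keep_start.append(s)
                keep_end.append(e)
                keep_label.append(lab)
        for s, e, lab in zip(keep_start, keep_end, keep_label):
            tract_rows.append((chrom, int(s), int(e), lab))

        # genotypes
        ga = _gamete_labels_at(bp1, s1, pos)
        gb = _gamete_labels_at(bp2, s2, pos)
        fixed = sites["is_fixed_diff"].to_numpy()
        a_is_ref = sites["a_is_ref"].to_numpy()
        # allele index (0=ref, 1=alt) contributed by each gamete at fixed sites
        idx1 = np.where(ga == 0, np.where(a_is_ref, 0, 1), np.where(a_is_ref, 1, 0))
        idx2 = np.where(gb == 0, np.where(a_is_ref, 0, 1), np.where(a_is_ref, 1, 0))
        lo = np.minimum(idx1, idx2)
        hi = np.maximum(idx1, idx2)
        gt_fixed = np.char.add(np.char.add(lo.astype(str), "/"), hi.astype(str))
        gt = np.where(fixed, gt_fixed, sites["shared_gt"].to_numpy())
        frame = sites[["chrom", "pos", "ref", "alt"]].copy()
        frame["gt"] = gt
        frame["dp"] = rng.poisson(config.mean_dna_depth, size=len(sites))
        geno_frames.append(frame)

    tracts = pd.DataFrame(tract_rows, columns=["chrom", "start", "end", "label"])
    genotypes = pd.concat(geno_frames, ignore_index=True)
    return TrueMosaic(name, tracts), genotypes


def simulate_gene_models(config: SimConfig) -> pd.DataFrame:
    """Random gene models (gene, chrom, start, end, strand) on the
    simulated chromosomes; bodies 1-5 kb, uniform placement."""
    rng = _rng(config, _STAGE_GENES)
    L = chromosome_length(config)
    chroms = [f"chr{c + 1}" for c in range(config.n_chromosomes)]
    chrom = rng.choice(chroms, size=config.n_genes)
    length = rng.integers(1000, 5001, size=config.n_genes)
    start = rng.integers(1, np.maximum(2, L - length), size=config.n_genes)
    strand = rng.choice(["+", "-"], size=config.n_genes)
    df = pd.DataFrame(
        {
            "gene": [f"G{i:06d}" for i in range(1, config.n_genes + 1)],
            "chrom": chrom,
            "start": start,
            "end": start + length - 1,
            "strand": strand,
        }
    )
    return df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)


@dataclass(frozen=True)
class ExpressionSim:
    """Bundle of simulated expression data plus its ground truth.

    counts: genes x samples integer matrix (sample names GROUP_rep).
    sample_groups: sample name -> group label.
    true_de: per-gene truth (is_de, direction, true_log2fc vs SCM).
    allelic_counts: long table (segregant, gene, chrom, pos, rep,
        reads_a, reads_b) of RNA reads per diagnostic site, pummelo vs
        mandarin allele, for genes in PU/MA tracts.
    true_ase: (segregant, gene, class) with class in
        {PU_only, MA_only, biallelic}.
    true_haplotypes: (segregant, gene, label) tract label of each gene body.
    """

    counts: pd.DataFrame
    sample_groups: pd.Series
    true_de: pd.DataFrame
    allelic_counts: pd.DataFrame
    true_ase: pd.DataFrame
    true_haplotypes: pd.DataFrame


def _gene_labels(mosaic: TrueMosaic, genes: pd.DataFrame) -> np.ndarray:
    """Tract label of each gene body: the tract with the largest overlap
    (vectorised per chromosome; tract counts are small)."""
    out = np.empty(len(genes), dtype=object)
    for chrom, sub in genes.groupby("chrom"):
        tr = mosaic.tracts[mosaic.tracts["chrom"] == chrom]
        gs = sub["start"].to_numpy()[:, None]
        ge = sub["end"].to_numpy()[:, None]
        ts = tr["start"].to_numpy()[None, :]
        te = tr["end"].to_numpy()[None, :]
        ov = np.clip(np.minimum(te, ge) - np.maximum(ts, gs) + 1, 0, None)
        out[sub.index.to_numpy()] = tr["label"].to_numpy()[np.argmax(ov, axis=1)]
    return out


def simulate_expression(
    config: SimConfig,
    gene_models: pd.DataFrame,
    mosaics: dict[str, TrueMosaic],
    site_map: pd.DataFrame,
    with_allelic: bool = True,
) -> ExpressionSim:
    """Simulate NB expression counts, the true-DE table, allelic RNA counts
    at diagnostic sites in PU/MA genes, and the true-ASE table.

    Counts are NB(mu, dispersion) per gene and sample; differential genes
    (fraction ``frac_de_genes``) carry log2 fold change ±``lfc_magnitude``
    in every non-reference group (ICH, S1, S2, S3) relative to SCM, i.e.
    the concordant design the consensus rule targets. For PU/MA genes the
    allelic RNA reads split Binomial(total, p) with p = 1 (PU_only),
    0 (MA_only) or 0.5 (biallelic) according to the gene-intrinsic truth.
    """
    known = {f"chr{c + 1}" for c in range(config.n_chromosomes)}
    bad = sorted(set(gene_models["chrom"]) - known)
    if bad:
        genes = gene_models.loc[gene_models["chrom"].isin(bad), "gene"].tolist()
        raise ValueError(f"genes on unknown chromosomes: {genes}")

    rng = _rng(config, _STAGE_EXPRESSION)
    genes = gene_models["gene"].to_numpy()
    n_genes = len(genes)
    reps = config.replicates_per_group
    samples = [f"{g}_{r + 1}" for g in GROUPS for r in range(reps)]
    groups = pd.Series(
        {s: s.rsplit("_", 1)[0] for s in samples}, name="group"
    )

    base_mu = rng.lognormal(
        np.log(config.mean_expression), config.expression_sdlog, size=n_genes
    )
    n_de = round(config.frac_de_genes * n_genes)
    de_idx = rng.choice(n_genes, size=n_de, replace=False)
    is_de = np.zeros(n_genes, dtype=bool)
    is_de[de_idx] = True
    sign = np.zeros(n_genes)
    sign[de_idx] = rng.choice([-1.0, 1.0], size=n_de)
    true_lfc = sign * config.lfc_magnitude

    disp = config.nb_dispersion
    size = 1.0 / disp
    cols = {}
    for g in GROUPS:
        mu = base_mu if g == "SCM" else base_mu * 2.0 ** true_lfc
        for r in range(reps):
            p = size / (size + mu)
            cols[f"{g}_{r + 1}"] = rng.negative_binomial(size, p)
    counts = pd.DataFrame(cols, index=pd.Index(genes, name="gene"))

    true_de = pd.DataFrame(
        {
            "gene": genes,
            "is_de": is_de,
            "direction": np.where(is_de, np.where(sign > 0, "up", "down"), ""),
            "true_log2fc": true_lfc,
        }
    )

    # gene-intrinsic allelic-expression truth
    ase_rng = _rng(config, _STAGE_ASE)
    u = ase_rng.random(n_genes)
    ase_class = np.where(
        u < config.frac_monoallelic / 2,
        "PU_only",
        np.where(u < config.frac_monoallelic, "MA_only", "biallelic"),
    )
    p_pu = {"PU_only": 1.0, "MA_only": 0.0, "biallelic": 0.5}

    sim_pos = {
        chrom: sub.loc[sub["is_fixed_diff"], "pos"].to_numpy()
        for chrom, sub in site_map.groupby("chrom")
    }

    gene_models = gene_models.reset_index(drop=True)
    hap_rows, allelic_rows, ase_rows = [], [], []
    for seg_name, mosaic in sorted(mosaics.items()):
        labels = _gene_labels(mosaic, gene_models)
        for i, row in enumerate(gene_models.itertuples(index=False)):
            hap_rows.append((seg_name, row.gene, labels[i]))
            if not with_allelic or labels[i] != LABEL_PUMA:
                continue
            pos = sim_pos.get(row.chrom, np.empty(0, dtype=int))
            inside = pos[np.searchsorted(pos, row.start):
                         np.searchsorted(pos, row.end, side="right")]
            if inside.size == 0:
                continue
            cls = ase_class[i]
            p = p_pu[cls]
            ase_rows.append((seg_name, row.gene, cls))
            total = ase_rng.poisson(config.mean_allelic_depth,
                                    size=(inside.size, reps))
            reads_a = ase_rng.binomial(total, p)
            for k, site in enumerate(inside):
                for r in range(reps):
                    allelic_rows.append(
                        (
                            seg_name,
                            row.gene,
                            row.chrom,
                            int(site),
                            r + 1,
                            int(reads_a[k, r]),
                            int(total[k, r] - reads_a[k, r]),
                        )
                    )

    allelic = pd.DataFrame(
        allelic_rows,
        columns=["segregant", "gene", "chrom", "pos", "rep", "reads_a", "reads_b"],
    )
    true_ase = pd.DataFrame(ase_rows, columns=["segregant", "gene", "class"])
    true_hap = pd.DataFrame(hap_rows, columns=["segregant", "gene", "label"])
    return ExpressionSim(counts, groups, true_de, allelic, true_ase, true_hap)
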