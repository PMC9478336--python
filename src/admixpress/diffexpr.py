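"""Differential expression, consensus filtering, pathway tri-state calls,
normalized expression and qPCR quantification.

The differential-expression engine is a per-gene negative-binomial Wald
contrast on size-factor-normalized counts: library sizes come from
median-of-ratios normalization, the NB dispersion is estimated per gene by
method of moments on within-group variation and shrunk 50/50 toward a
mean–dispersion trend fitted across genes, group abundances are estimated
on the log link, and the Wald statistic log2FC / SE is referred to a
moderated t distribution (residual degrees of freedom plus a prior
contribution from the cross-gene trend shrinkage) with
Benjamini–Hochberg correction across tested genes. Two published threshold presets select DEGs: soft (|log2FC| >= 0.58,
padj < 0.05) and strict (|log2FC| >= 1, padj < 0.01); the consensus rule
keeps genes significant in the same direction in all three segregant
contrasts with at least 100 reads in some replicate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CountMatrix",
    "size_factors",
    "nb_wald_test",
    "select_degs",
    "read_filter",
    "consensus_degs",
    "pathway_tristate",
    "classify_pathways",
    "normalized_tpm",
    "ddct",
]

_DISP_FLOOR = 1e-8


class NormalizationError(ValueError):
    """No gene is expressed in every sample; size factors are undefined."""


class DesignError(ValueError):
    """The sample design cannot support the requested contrast."""


@dataclass
class CountMatrix:
    """Gene-level read counts with the replicate grouping.

    counts: genes x samples non-negative integer DataFrame.
    groups: sample name -> group label (ICH, SCM, S1, S2, S3 in the study).
    """

    counts: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        missing = [s for s in self.counts.columns if s not in self.groups.index]
        if missing:
            raise DesignError(f"samples without a group: {missing}")
        values = self.counts.to_numpy()
        if (values < 0).any():
            raise ValueError("counts must be non-negative")

    def samples_of(self, group: str) -> list[str]:
        return [s for s in self.counts.columns if self.groups[s] == group]


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios library size factors.

    For genes with nonzero counts in every sample, each sample's factor is
    the median ratio of its counts to the per-gene geometric mean. A matrix
    of identical columns yields factors of exactly 1.
    """
    values = counts.to_numpy(dtype=float)
    usable = (values > 0).all(axis=1)
    if not usable.any():
        raise NormalizationError("no gene with nonzero counts in all samples")
    sub = values[usable]
    gm = np.exp(np.log(sub).mean(axis=1, keepdims=True))
    factors = np.median(sub / gm, axis=0)
    return pd.Series(factors, index=counts.columns, name="size_factor")


def _fit_dispersion_trend(mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Least-squares fit of alpha ~ a0 + a1/mu over genes, the standard
    asymptotic shape of the mean-dispersion relation; coefficients are
    clipped at zero and the fitted trend floored."""
    ok = (mu > 0) & np.isfinite(alpha)
    if ok.sum() < 2:
        return np.full_like(mu, max(_DISP_FLOOR, float(np.median(alpha[ok])) if ok.any() else _DISP_FLOOR))
    X = np.column_stack([np.ones(ok.sum()), 1.0 / mu[ok]])
    coef, *_ = np.linalg.lstsq(X, alpha[ok], rcond=None)
    coef = np.clip(coef, 0.0, None)
    with np.errstate(divide="ignore"):
        trend = coef[0] + coef[1] / np.where(mu > 0, mu, np.inf)
    return np.maximum(trend, _DISP_FLOOR)


def nb_wald_test(
    counts: CountMatrix,
    contrast: tuple[str, str],
    factors: pd.Series | None = None,
) -> pd.DataFrame:
    """Negative-binomial Wald test of one group against a reference.

    Per gene: counts are normalized by median-of-ratios size factors; the
    NB dispersion is a method-of-moments estimate from within-group
    variation pooled across the two groups, floored at 1e-8 and shrunk
    50/50 toward the fitted mean-dispersion trend; each group's abundance
    is q = sum(counts) / sum(size factors); the Wald statistic is
    log2(q_test / q_ref) over its delta-method standard error under the NB
    variance mu + alpha*mu^2. Because the per-gene dispersion rests on few
    residual degrees of freedom, the statistic is referred to a moderated
    t distribution with df = residual df + prior df, the prior df taken as
    twice the residual df to credit the information the cross-gene trend
    contributes through the shrinkage (the quasi-likelihood moderation
    argument); with three replicates per group this gives 12 df, and the
    reference approaches the normal as replication grows. P-values are
    BH-adjusted over tested genes; genes with all-zero counts in both
    groups are excluded from testing and from the BH denominator.

    Returns a DataFrame indexed by gene with columns (base_mean, log2fc,
    lfc_se, p, padj); excluded genes carry NaN statistics.
    """
    group, reference = contrast
    s_test = counts.samples_of(group)
    s_ref = counts.samples_of(reference)
    if len(s_test) < 2 or len(s_ref) < 2:
        raise DesignError(
            f"contrast {group} vs {reference} needs >= 2 replicates per group "
            f"(got {len(s_test)} and {len(s_ref)})"
        )
    if factors is None:
        factors = size_factors(counts.counts)

    y_test = counts.counts[s_test].to_numpy(dtype=float)
    y_ref = counts.counts[s_ref].to_numpy(dtype=float)
    f_test = factors[s_test].to_numpy()
    f_ref = factors[s_ref].to_numpy()

    norm_test = y_test / f_test
    norm_ref = y_ref / f_ref
    tested = (y_test.sum(axis=1) + y_ref.sum(axis=1)) > 0

    # method-of-moments dispersion from within-group variation, pooled
    m_test = norm_test.mean(axis=1)
    m_ref = norm_ref.mean(axis=1)
    ss = ((norm_test - m_test[:, None]) ** 2).sum(axis=1) + (
        (norm_ref - m_ref[:, None]) ** 2
    ).sum(axis=1)
    df = len(s_test) + len(s_ref) - 2
    s2 = ss / df
    mu_bar = np.concatenate([norm_test, norm_ref], axis=1).mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_mm = (s2 - mu_bar) / mu_bar**2
    alpha_mm = np.where(np.isfinite(alpha_mm), alpha_mm, _DISP_FLOOR)
    alpha_mm = np.maximum(alpha_mm, _DISP_FLOOR)
    trend = _fit_dispersion_trend(mu_bar[tested], alpha_mm[tested])
    alpha = alpha_mm.copy()
    alpha[tested] = 0.5 * alpha_mm[tested] + 0.5 * trend

    # group abundances with a half-read continuity correction so that a
    # group with zero counts yields a finite, strongly negative log2FC
    eps = 0.5
    q_test = (y_test.sum(axis=1) + eps) / f_test.sum()
    q_ref = (y_ref.sum(axis=1) + eps) / f_ref.sum()
    log2fc = np.log2(q_test / q_ref)

    def _var_log_q(q: np.ndarray, f: np.ndarray, a: np.ndarray) -> np.ndarray:
        mu = q[:, None] * f[None, :]
        var_sum = (mu + a[:, None] * mu**2).sum(axis=1)
        return var_sum / (q * f.sum()) ** 2

    var_ln = _var_log_q(q_test, f_test, alpha) + _var_log_q(q_ref, f_ref, alpha)
    se = np.sqrt(var_ln) / np.log(2.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(se > 0, log2fc / se, 0.0)
    # moderated reference: residual df + prior df (2x residual) from the
    # trend shrinkage; approaches the normal with increasing replication
    df_total = 3 * df
    p = 2.0 * stats.t.sf(np.abs(z), df=df_total)

    padj = np.full(len(p), np.nan)
    if tested.any():
        padj[tested] = multipletests(p[tested], method="fdr_bh")[1]

    base_mean = mu_bar
    out = pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2fc": np.where(tested, log2fc, np.nan),
            "lfc_se": np.where(tested, se, np.nan),
            "p": np.where(tested, p, np.nan),
            "padj": padj,
        },
        index=counts.counts.index,
    )
    out.index.name = "gene"
    return out


def select_degs(
    results: pd.DataFrame, lfc_threshold: float, alpha: float
) -> pd.DataFrame:
    """Select DEGs at |log2FC| >= threshold (boundary inclusive) and
    padj < alpha (strict). Returns (gene, log2fc, padj, direction)."""
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0, 1) (got {alpha!r})")
    ok = (results["log2fc"].abs() >= lfc_threshold) & (results["padj"] < alpha)
    sel = results.loc[ok.fillna(False), ["log2fc", "padj"]].copy()
    sel["direction"] = np.where(sel["log2fc"] > 0, "up", "down")
    return sel


def read_filter(
    counts: pd.DataFrame,
    genes: pd.Index | list[str],
    min_reads: int = 100,
    samples: list[str] | None = None,
) -> pd.Index:
    """Keep genes reaching ``min_reads`` raw reads in at least one of the
    given samples (all samples by default). Boundary inclusive: a maximum
    replicate count equal to ``min_reads`` passes."""
    sub = counts.loc[list(genes), samples if samples is not None else counts.columns]
    keep = sub.max(axis=1) >= min_reads
    return sub.index[keep]


def consensus_degs(
    results_s1: pd.DataFrame,
    results_s2: pd.DataFrame,
    results_s3: pd.DataFrame,
    counts: CountMatrix,
    lfc_threshold: float = 0.58,
    alpha: float = 0.05,
    min_reads: int = 100,
    groups: tuple[str, ...] = ("S1", "S2", "S3", "SCM"),
) -> pd.DataFrame:
    """Genes differentially expressed in the same direction in all three
    segregant-vs-reference contrasts, with at least ``min_reads`` raw reads
    in some replicate of the compared groups.

    Returns a DataFrame indexed by gene with per-contrast statistics,
    the shared direction and the maximum replicate read count.
    """
    tables = {"s1": results_s1, "s2": results_s2, "s3": results_s3}
    universe = results_s1.index
    for name, tab in tables.items():
        if not universe.equals(tab.index):
            missing = universe.symmetric_difference(tab.index).tolist()
            raise ValueError(
                f"result tables cover different gene universes ({name}); "
                f"disagreeing genes: {missing[:10]}"
            )
    selections = {k: select_degs(t, lfc_threshold, alpha) for k, t in tables.items()}
    common = selections["s1"].index
    for k in ("s2", "s3"):
        common = common.intersection(selections[k].index)
    concordant = [
        g
        for g in common
        if len({selections[k].loc[g, "direction"] for k in selections}) == 1
    ]
    rel_samples = [s for s in counts.counts.columns if counts.groups[s] in groups]
    kept = read_filter(counts.counts, concordant, min_reads, rel_samples)
    rows = {}
    for g in kept:
        row = {"direction": selections["s1"].loc[g, "direction"]}
        for k in ("s1", "s2", "s3"):
            row[f"log2fc_{k}"] = selections[k].loc[g, "log2fc"]
            row[f"padj_{k}"] = selections[k].loc[g, "padj"]
        row["max_replicate_reads"] = int(counts.counts.loc[g, rel_samples].max())
        rows[g] = row
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "gene"
    if out.empty:
        out = pd.DataFrame(
            columns=[
                "direction",
                "log2fc_s1", "padj_s1",
                "log2fc_s2", "padj_s2",
                "log2fc_s3", "padj_s3",
                "max_replicate_reads",
            ]
        )
        out.index.name = "gene"
    return out


@dataclass
class PathwayNodeState:
    """Tri-state expression call of one pathway node."""

    node: str
    state: str  # up / down / undetermined
    n_up: int
    n_down: int
    reads_up: int
    reads_down: int
    members: list[str] = field(default_factory=list)


def pathway_tristate(
    members: pd.DataFrame,
    min_reads: int = 100,
    node: str = "",
) -> PathwayNodeState:
    """Classify a pathway node as up, down or undetermined.

    ``members`` needs columns (gene, direction, max_replicate_reads,
    total_reads). A node whose member DEGs all share one direction takes
    that direction. With both directions present, the call is undetermined
    when each side has a gene reaching ``min_reads`` in some replicate —
    unless one direction is unequivocally higher, i.e. has strictly more
    genes AND strictly more summed raw reads, in which case it dominates.
    If only one side has a read-credible gene that side wins; if neither
    does, the dominance comparison decides, with undetermined on ties.
    """
    if members.empty:
        raise ValueError(f"pathway node {node!r} has no member genes")
    up = members[members["direction"] == "up"]
    down = members[members["direction"] == "down"]
    n_up, n_down = len(up), len(down)
    reads_up = int(up["total_reads"].sum())
    reads_down = int(down["total_reads"].sum())

    if n_up and not n_down:
        state = "up"
    elif n_down and not n_up:
        state = "down"
    else:
        cred_up = (up["max_replicate_reads"] >= min_reads).any()
        cred_down = (down["max_replicate_reads"] >= min_reads).any()
        if cred_up and not cred_down:
            state = "up"
        elif cred_down and not cred_up:
            state = "down"
        elif n_up > n_down and reads_up > reads_down:
            state = "up"
        elif n_down > n_up and reads_down > reads_up:
            state = "down"
        else:
            state = "undetermined"
    return PathwayNodeState(
        node, state, n_up, n_down, reads_up, reads_down,
        members["gene"].tolist(),
    )


def classify_pathways(
    degs: pd.DataFrame,
    counts: pd.DataFrame,
    pathway_map: pd.DataFrame,
    min_reads: int = 100,
    samples: list[str] | None = None,
) -> pd.DataFrame:
    """Tri-state call for every pathway node with at least one member DEG.

    ``degs`` is indexed by gene with a ``direction`` column;
    ``pathway_map`` has columns (gene, node). Returns one row per node.
    """
    cols = samples if samples is not None else list(counts.columns)
    rows = []
    for node, sub in pathway_map.groupby("node"):
        genes = [g for g in sub["gene"] if g in degs.index]
        if not genes:
            continue
        mem = pd.DataFrame(
            {
                "gene": genes,
                "direction": [degs.loc[g, "direction"] for g in genes],
                "max_replicate_reads": [
                    int(counts.loc[g, cols].max()) for g in genes
                ],
                "total_reads": [int(counts.loc[g, cols].sum()) for g in genes],
            }
        )
        st = pathway_tristate(mem, min_reads=min_reads, node=str(node))
        rows.append(
            (
                st.node, st.state, st.n_up, st.n_down,
                st.reads_up, st.reads_down, ",".join(st.members),
            )
        )
    return pd.DataFrame(
        rows,
        columns=["node", "state", "n_up", "n_down", "reads_up", "reads_down",
                 "members"],
    )


def normalized_tpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Size-factor-normalized counts rescaled per sample to sum to one
    million (a transcripts-per-million-like scale without a gene-length
    term)."""
    factors = size_factors(counts)
    norm = counts / factors
    return norm * (1e6 / norm.sum(axis=0))


def ddct(
    ct: pd.DataFrame,
    target: str,
    references: tuple[str, str],
    calibrator: str,
) -> pd.Series:
    """Relative expression by the ddCt method with two reference genes.

    dCt = Ct_target - mean(Ct of the two references); ddCt = dCt_sample -
    dCt_calibrator; relative expression = 2^(-ddCt). The calibrator sample
    therefore reads exactly 1.

    ``ct`` is a genes x samples table of Ct values.
    """
    for gene in (target, *references):
        if gene not in ct.index:
            raise KeyError(f"Ct table lacks gene {gene!r}")
        missing = ct.columns[ct.loc[gene].isna()]
        if len(missing):
            raise ValueError(
                f"missing Ct for gene {gene!r} in sample(s) {list(missing)}"
            )
    if calibrator not in ct.columns:
        raise KeyError(f"calibrator sample {calibrator!r} not in Ct table")
    ref_mean = ct.loc[list(references)].mean(axis=0)
    dct = ct.loc[target] - ref_mean
    dd = dct - dct[calibrator]
    out = np.power(2.0, -dd)
    out.name = "relative_expression"
    return out
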