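"""Differential expression, filters, pathway tri-state, TPM and ddCt."""

import itertools

import numpy as np
import pandas as pd
import pytest

from admixpress.config import SimConfig
from admixpress import simulate
from admixpress.diffexpr import (
    CountMatrix,
    DesignError,
    NormalizationError,
    consensus_degs,
    ddct,
    nb_wald_test,
    normalized_tpm,
    pathway_tristate,
    read_filter,
    select_degs,
    size_factors,
)


def _cm(counts, group_of):
    return CountMatrix(counts, pd.Series({s: group_of(s) for s in counts.columns}))


def _oracle_size_factors(counts):
    """Brute-force median-of-ratios."""
    rows = [g for g in counts.index if (counts.loc[g] > 0).all()]
    gm = {g: np.exp(np.mean(np.log(counts.loc[g].to_numpy(float)))) for g in rows}
    return {
        s: float(np.median([counts.loc[g, s] / gm[g] for g in rows]))
        for s in counts.columns
    }


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        col = np.array([5, 10, 200, 3])
        counts = pd.DataFrame({f"s{i}": col for i in range(4)})
        assert np.allclose(size_factors(counts), 1.0)

    def test_scaled_column_recovers_scale(self):
        rng = np.random.default_rng(2)
        a = rng.integers(1, 500, size=30)
        counts = pd.DataFrame({"A": a, "B": 2 * a})
        f = size_factors(counts)
        assert np.isclose(f["B"] / f["A"], 2.0)

    def test_matches_brute_force_oracle(self, toy_counts):
        got = size_factors(toy_counts)
        oracle = _oracle_size_factors(toy_counts)
        for s in toy_counts.columns:
            assert abs(got[s] - oracle[s]) < 1e-12

    def test_no_universally_expressed_gene_raises(self):
        counts = pd.DataFrame({"a": [0, 5], "b": [5, 0]})
        with pytest.raises(NormalizationError):
            size_factors(counts)


def _oracle_bh(pvals):
    """Textbook Benjamini-Hochberg step-up with monotonicity enforcement."""
    n = len(pvals)
    order = np.argsort(pvals)
    adj = np.empty(n)
    prev = 1.0
    for rank_from_end, i in enumerate(order[::-1]):
        rank = n - rank_from_end
        val = min(prev, pvals[i] * n / rank)
        adj[i] = val
        prev = val
    return adj


class TestNbWald:
    def test_identical_counts_give_null_result(self):
        counts = pd.DataFrame(
            {f"{g}_{r}": [50, 7, 300] for g in ("T", "R") for r in (1, 2, 3)},
            index=["g1", "g2", "g3"],
        )
        res = nb_wald_test(_cm(counts, lambda s: s.split("_")[0]), ("T", "R"))
        assert np.allclose(res["log2fc"], 0.0)
        assert np.allclose(res["p"], 1.0)

    def test_all_zero_genes_excluded_from_bh(self):
        rng = np.random.default_rng(4)
        counts = pd.DataFrame(
            rng.integers(1, 100, size=(20, 6)),
            index=[f"g{i}" for i in range(20)],
            columns=[f"{g}_{r}" for g in ("T", "R") for r in (1, 2, 3)],
        )
        counts.iloc[0] = 0
        res = nb_wald_test(_cm(counts, lambda s: s.split("_")[0]), ("T", "R"))
        assert np.isnan(res.iloc[0]["p"])
        tested = res["p"].dropna()
        assert np.allclose(
            res["padj"].dropna().to_numpy(),
            _oracle_bh(tested.to_numpy()),
        )

    def test_single_replicate_group_raises(self):
        counts = pd.DataFrame({"T_1": [5], "R_1": [5], "R_2": [6]}, index=["g"])
        with pytest.raises(DesignError):
            nb_wald_test(_cm(counts, lambda s: s.split("_")[0]), ("T", "R"))

    def test_planted_fold_change_recovered(self):
        """A 4-fold gene at mean 500 and low dispersion is estimated within
        +-0.3 of log2FC 2 with padj < 0.01."""
        cfg = SimConfig(n_chromosomes=1, sites_per_chromosome=200, n_genes=500,
                        frac_de_genes=0.2, lfc_magnitude=2.0, nb_dispersion=0.01,
                        mean_expression=500, expression_sdlog=0.0, seed=41)
        _, _, site_map = simulate.simulate_panels(cfg)
        mosaic, _ = simulate.simulate_segregant(site_map, cfg, 0)
        genes = simulate.simulate_gene_models(cfg)
        expr = simulate.simulate_expression(cfg, genes, {"S1": mosaic}, site_map)
        cm = CountMatrix(expr.counts, expr.sample_groups)
        res = nb_wald_test(cm, ("S1", "SCM"))
        truth = expr.true_de.set_index("gene")
        de = truth[truth["is_de"]].index
        err = np.abs(res.loc[de, "log2fc"] - truth.loc[de, "true_log2fc"])
        # SE at this depth/dispersion is ~0.13, so the typical gene lands
        # well inside +-0.3; allow the expected sampling tail over 100 genes
        assert np.quantile(err, 0.9) <= 0.3
        assert err.median() <= 0.15
        assert (res.loc[de, "padj"] < 0.01).all()

    def test_null_type_one_error_controlled(self):
        """Null NB simulation (dispersion 0.1, 3 vs 3): raw p < 0.05 for
        roughly a nominal fraction of 5000 genes."""
        rng = np.random.default_rng(43)
        n, size = 5000, 10.0  # dispersion 0.1
        mu = rng.lognormal(np.log(100), 1, size=n)
        cols = {
            f"{g}_{r}": rng.negative_binomial(size, size / (size + mu))
            for g in ("T", "R") for r in (1, 2, 3)
        }
        counts = pd.DataFrame(cols, index=[f"g{i}" for i in range(n)])
        res = nb_wald_test(_cm(counts, lambda s: s.split("_")[0]), ("T", "R"))
        frac = (res["p"].dropna() < 0.05).mean()
        assert 0.03 <= frac <= 0.07


class TestSelectDegs:
    RES = pd.DataFrame(
        {
            "log2fc": [0.58, -0.58, 0.4, 2.0, -3.0, 1.0],
            "padj": [0.04, 0.049, 0.001, 0.05, 0.01, np.nan],
        },
        index=[f"g{i}" for i in range(6)],
    )

    def test_boundary_semantics(self):
        sel = select_degs(self.RES, 0.58, 0.05)
        assert set(sel.index) == {"g0", "g1", "g4"}  # |lfc|>=thr, padj<alpha
        assert sel.loc["g0", "direction"] == "up"
        assert sel.loc["g1", "direction"] == "down"

    def test_exhaustive_filter_oracle(self):
        rng = np.random.default_rng(51)
        res = pd.DataFrame(
            {"log2fc": rng.normal(0, 1, 20), "padj": rng.random(20)},
            index=[f"g{i}" for i in range(20)],
        )
        sel = select_degs(res, 0.58, 0.05)
        expected = {
            g for g in res.index
            if abs(res.loc[g, "log2fc"]) >= 0.58 and res.loc[g, "padj"] < 0.05
        }
        assert set(sel.index) == expected

    def test_loosening_thresholds_is_monotone(self):
        tight = set(select_degs(self.RES, 1.0, 0.01).index)
        loose = set(select_degs(self.RES, 0.58, 0.05).index)
        assert tight <= loose

    def test_invalid_alpha(self):
        with pytest.raises(ValueError):
            select_degs(self.RES, 0.58, 1.5)


class TestReadFilter:
    def test_boundary_inclusive(self):
        counts = pd.DataFrame({"a": [99, 100], "b": [1, 1]},
                              index=["low", "edge"])
        kept = read_filter(counts, ["low", "edge"], min_reads=100)
        assert list(kept) == ["edge"]

    def test_matches_max_per_gene_oracle(self):
        rng = np.random.default_rng(53)
        counts = pd.DataFrame(
            rng.integers(0, 300, size=(10, 6)),
            index=[f"g{i}" for i in range(10)],
        )
        kept = set(read_filter(counts, counts.index, 100))
        oracle = {g for g in counts.index if counts.loc[g].max() >= 100}
        assert kept == oracle


class TestConsensus:
    def _results(self, lfcs, padjs, genes):
        return pd.DataFrame({"log2fc": lfcs, "padj": padjs}, index=genes)

    def test_concordant_gene_included_discordant_excluded(self):
        genes = ["up3", "mixed", "weak"]
        r1 = self._results([1.0, 1.0, 0.2], [0.01, 0.01, 0.01], genes)
        r2 = self._results([2.0, 1.0, 0.2], [0.01, 0.01, 0.01], genes)
        r3 = self._results([1.5, -1.0, 0.2], [0.01, 0.01, 0.01], genes)
        counts = pd.DataFrame(
            {f"{g}_{r}": [500, 500, 500] for g in ("S1", "S2", "S3", "SCM", "ICH")
             for r in (1, 2, 3)},
            index=genes,
        )
        cm = _cm(counts, lambda s: s.split("_")[0])
        cons = consensus_degs(r1, r2, r3, cm)
        assert list(cons.index) == ["up3"]
        assert cons.loc["up3", "direction"] == "up"
        assert cons.loc["up3", "max_replicate_reads"] == 500

    def test_low_read_consensus_gene_filtered(self):
        genes = ["g"]
        r = self._results([1.0], [0.001], genes)
        counts = pd.DataFrame(
            {f"{g}_{n}": [99] for g in ("S1", "S2", "S3", "SCM") for n in (1, 2, 3)},
            index=genes,
        )
        cm = _cm(counts, lambda s: s.split("_")[0])
        assert consensus_degs(r, r, r, cm).empty

    def test_mismatched_universe_raises(self):
        r1 = self._results([1.0], [0.01], ["a"])
        r2 = self._results([1.0], [0.01], ["b"])
        counts = pd.DataFrame({f"{g}_1": [1] for g in ("S1", "SCM")}, index=["a"])
        counts[[f"{g}_2" for g in ("S1", "SCM")]] = 1
        cm = _cm(counts, lambda s: s.split("_")[0])
        with pytest.raises(ValueError, match="universe"):
            consensus_degs(r1, r2, r1, cm)

    def test_consensus_is_subset_of_each_contrast(self, small_dataset):
        expr = small_dataset["expr"]
        cm = CountMatrix(expr.counts, expr.sample_groups)
        results = {g: nb_wald_test(cm, (g, "SCM")) for g in ("S1", "S2", "S3")}
        cons = consensus_degs(results["S1"], results["S2"], results["S3"], cm)
        for g in ("S1", "S2", "S3"):
            single = set(select_degs(results[g], 0.58, 0.05).index)
            assert set(cons.index) <= single


def _oracle_tristate(directions, max_reads, totals, min_reads=100):
    """Brute-force tri-state: single direction wins; with both present,
    read-credible sides gate the call and strict double dominance
    (more genes AND more reads) overrides undetermined."""
    ups = [i for i, d in enumerate(directions) if d == "up"]
    downs = [i for i, d in enumerate(directions) if d == "down"]
    if not downs:
        return "up"
    if not ups:
        return "down"
    cred_up = any(max_reads[i] >= min_reads for i in ups)
    cred_down = any(max_reads[i] >= min_reads for i in downs)
    if cred_up != cred_down:
        return "up" if cred_up else "down"
    nu, nd = len(ups), len(downs)
    ru, rd = sum(totals[i] for i in ups), sum(totals[i] for i in downs)
    if nu > nd and ru > rd:
        return "up"
    if nd > nu and rd > ru:
        return "down"
    return "undetermined"


class TestPathwayTristate:
    def _members(self, directions, max_reads, totals):
        return pd.DataFrame(
            {
                "gene": [f"g{i}" for i in range(len(directions))],
                "direction": directions,
                "max_replicate_reads": max_reads,
                "total_reads": totals,
            }
        )

    def test_single_direction(self):
        st = pathway_tristate(self._members(["up"], [500], [900]))
        assert st.state == "up"

    def test_opposite_credible_trends_undetermined(self):
        st = pathway_tristate(
            self._members(["up", "down"], [150, 150], [200, 200])
        )
        assert st.state == "undetermined"

    def test_dominance_overrides(self):
        st = pathway_tristate(
            self._members(["up", "up", "up", "down"],
                          [400, 400, 400, 150],
                          [2000, 2000, 1000, 150])
        )
        assert st.state == "up"

    def test_empty_membership_raises(self):
        with pytest.raises(ValueError):
            pathway_tristate(self._members([], [], []))

    def test_exhaustive_enumeration_matches_oracle(self):
        """All direction/read configurations with <= 4 members."""
        read_levels = [(50, 60), (150, 300)]  # (max_replicate, total)
        for n in range(1, 5):
            for dirs in itertools.product(["up", "down"], repeat=n):
                for reads in itertools.product(read_levels, repeat=n):
                    max_reads = [r[0] for r in reads]
                    totals = [r[1] for r in reads]
                    got = pathway_tristate(
                        self._members(list(dirs), max_reads, totals)
                    ).state
                    assert got == _oracle_tristate(dirs, max_reads, totals)

    def test_label_symmetry(self):
        """Flipping every direction flips up<->down, keeps undetermined."""
        rng = np.random.default_rng(59)
        flip = {"up": "down", "down": "up", "undetermined": "undetermined"}
        for _ in range(50):
            n = rng.integers(1, 5)
            dirs = list(rng.choice(["up", "down"], size=n))
            max_reads = list(rng.choice([50, 150, 400], size=n))
            totals = list(rng.choice([60, 300, 1000], size=n))
            a = pathway_tristate(self._members(dirs, max_reads, totals)).state
            b = pathway_tristate(
                self._members([flip[d] for d in dirs], max_reads, totals)
            ).state
            assert b == flip[a]


class TestNormalizedTpm:
    def test_columns_sum_to_one_million(self, toy_counts):
        tpm = normalized_tpm(toy_counts)
        assert np.allclose(tpm.sum(axis=0), 1e6)

    def test_identical_columns_identical_output(self):
        col = np.array([3, 9, 80])
        counts = pd.DataFrame({"a": col, "b": col})
        tpm = normalized_tpm(counts)
        assert np.allclose(tpm["a"], tpm["b"])

    def test_hand_computed_oracle(self):
        counts = pd.DataFrame(
            {"s1": [10, 20, 30, 40, 100], "s2": [20, 40, 60, 80, 200]}
        )
        tpm = normalized_tpm(counts)
        # s2 = 2 x s1, so normalized profiles match exactly
        expected = np.array([10, 20, 30, 40, 100]) / 200 * 1e6
        assert np.allclose(tpm["s1"], expected)
        assert np.allclose(tpm["s2"], expected)


class TestDdct:
    CT = pd.DataFrame(
        {
            "cal": [20.0, 18.0, 22.0],
            "s1": [19.0, 18.0, 22.0],
            "s2": [21.0, 17.0, 23.0],
            "s3": [20.0, 19.0, 21.0],
        },
        index=["target", "ubc1", "actin11"],
    )

    def test_calibrator_is_one(self):
        rel = ddct(self.CT, "target", ("ubc1", "actin11"), "cal")
        assert rel["cal"] == pytest.approx(1.0)

    def test_one_cycle_lower_doubles(self):
        rel = ddct(self.CT, "target", ("ubc1", "actin11"), "cal")
        assert rel["s1"] == pytest.approx(2.0)

    def test_closed_form_on_four_samples(self):
        rel = ddct(self.CT, "target", ("ubc1", "actin11"), "cal")
        ref = (self.CT.loc["ubc1"] + self.CT.loc["actin11"]) / 2
        dct = self.CT.loc["target"] - ref
        expected = 2.0 ** (-(dct - dct["cal"]))
        assert np.allclose(rel, expected)

    def test_self_calibration_is_identity(self):
        for s in self.CT.columns:
            rel = ddct(self.CT, "target", ("ubc1", "actin11"), s)
            assert rel[s] == pytest.approx(1.0)

    def test_missing_ct_raises_with_names(self):
        ct = self.CT.copy()
        ct.loc["target", "s2"] = np.nan
        with pytest.raises(ValueError, match="target.*s2"):
            ddct(ct, "target", ("ubc1", "actin11"), "cal")
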