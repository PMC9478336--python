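"""End-to-end pipeline driver: chains marker calling, ancestry painting,
differential expression, consensus filtering, pathway classification,
allele-specific expression and haplotype summaries, writing every stage's
table plus a machine-readable run manifest.

The manifest deliberately contains no wall-clock information so that two
runs with identical inputs and configuration are byte-identical; stage
timings go to the log instead.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time

import pandas as pd

from . import ancestry, ase, diffexpr, io, markers
from .config import PipelineConfig

__all__ = ["run_pipeline", "validate_inputs", "PipelineError"]

logger = logging.getLogger(__name__)

CONTRAST_GROUPS = ["ICH", "S1", "S2", "S3"]
REFERENCE_GROUP = "SCM"


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending record."""


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage(name: str):
    """Decorator-ish context: wraps stage errors with the stage name."""
    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %s done in %.2fs", name, time.perf_counter() - self.t0)
            return False

    return _Ctx()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every configured stage in order and write outputs + manifest.

    Required paths: panel_a_vcf, panel_b_vcf, segregant_vcfs (comma
    separated, in S1,S2,S3 order), counts, sample_sheet, genes_bed.
    Optional: allelic_counts (long TSV with a ``segregant`` column),
    pathway_map. Returns the manifest dictionary.
    """
    paths = config.paths
    required = ["panel_a_vcf", "panel_b_vcf", "segregant_vcfs", "counts",
                "sample_sheet", "genes_bed"]
    for key in required:
        if key not in paths:
            raise PipelineError(f"missing required input path {key!r}")
    seg_vcfs = paths["segregant_vcfs"].split(",")
    flat_inputs = [paths[k] for k in required if k != "segregant_vcfs"]
    flat_inputs += seg_vcfs
    flat_inputs += [paths[k] for k in ("allelic_counts", "pathway_map")
                    if k in paths]
    for p in flat_inputs:
        if not os.path.exists(p):
            raise PipelineError(f"input file not found: {p}")

    out = config.out_dir
    io.ensure_dir(out)
    manifest: dict = {
        "tool": "admixpress",
        "parameters": {
            "profile": config.profile,
            "lfc_threshold": config.thresholds.lfc_threshold,
            "alpha": config.thresholds.alpha,
            "window_size": config.window_size,
            "min_stable": config.min_stable,
            "min_sim_depth": config.min_sim_depth,
            "min_reads_annot": config.min_reads_annot,
            "min_reads_expressed": config.min_reads_expressed,
            "ase_min_mean_depth": config.ase_min_mean_depth,
            "ase_min_frac_pass": config.ase_min_frac_pass,
            "seed": config.seed,
        },
        "inputs": {p: _sha256(p) for p in flat_inputs},
        "records": {},
    }
    rec = manifest["records"]

    with _stage("sims"):
        panel_a = io.read_vcf(paths["panel_a_vcf"])
        panel_b = io.read_vcf(paths["panel_b_vcf"])
        sims = markers.call_sims(panel_a, panel_b, min_depth=config.min_sim_depth)
        io.write_tsv(sims, os.path.join(out, "sims.tsv"))
        rec["sims"] = len(sims)

    genes = io.read_gene_bed(paths["genes_bed"])
    haplotypes: dict[str, pd.DataFrame] = {}
    with _stage("paint"):
        for i, vcf in enumerate(seg_vcfs):
            seg = f"S{i + 1}"
            geno = io.read_vcf(vcf)
            patt = ancestry.site_patterns(geno, sims)
            wins = ancestry.infer_windows(patt.patterns, config.window_size)
            segs = ancestry.smooth_segments(wins, config.min_stable)
            io.write_segments_bed(segs, os.path.join(out, f"segments_{seg}.bed"))
            hap = ancestry.assign_gene_haplotypes(segs, genes)
            io.write_tsv(hap, os.path.join(out, f"haplotypes_{seg}.tsv"))
            haplotypes[seg] = hap
            rec[f"segments_{seg}"] = len(segs)

    with _stage("de"):
        counts_df = io.read_counts(paths["counts"])
        groups = io.read_sample_sheet(paths["sample_sheet"])
        cm = diffexpr.CountMatrix(counts_df, groups)
        factors = diffexpr.size_factors(counts_df)
        results = {}
        for grp in CONTRAST_GROUPS:
            res = diffexpr.nb_wald_test(cm, (grp, REFERENCE_GROUP), factors)
            results[grp] = res
            io.write_tsv(res.reset_index(),
                         os.path.join(out, f"de_{grp}_vs_{REFERENCE_GROUP}.tsv"))
            rec[f"de_{grp}"] = int(res["p"].notna().sum())
        tpm = diffexpr.normalized_tpm(counts_df)
        io.write_tsv(tpm.reset_index(), os.path.join(out, "tpm.tsv"))

    thr = config.thresholds
    with _stage("consensus"):
        consensus = diffexpr.consensus_degs(
            results["S1"], results["S2"], results["S3"], cm,
            lfc_threshold=thr.lfc_threshold, alpha=thr.alpha,
            min_reads=config.min_reads_annot,
        )
        io.write_tsv(consensus.reset_index(), os.path.join(out, "consensus.tsv"))
        rec["consensus"] = len(consensus)

    if "pathway_map" in paths:
        with _stage("pathway-state"):
            pmap = io.read_tsv(paths["pathway_map"])
            ich_degs = diffexpr.select_degs(results["ICH"], thr.lfc_threshold,
                                            thr.alpha)
            ich_samples = cm.samples_of("ICH") + cm.samples_of(REFERENCE_GROUP)
            states = diffexpr.classify_pathways(
                ich_degs, counts_df, pmap,
                min_reads=config.min_reads_annot, samples=ich_samples,
            )
            io.write_tsv(states, os.path.join(out, "pathway_states.tsv"))
            rec["pathway_states"] = len(states)

    if "allelic_counts" in paths:
        with _stage("ase"):
            allelic = io.read_tsv(paths["allelic_counts"])
            for seg, hap in haplotypes.items():
                sub = allelic[allelic["segregant"] == seg] \
                    if "segregant" in allelic.columns else allelic
                calls = ase.call_ase_table(
                    sub, hap,
                    min_mean_depth=config.ase_min_mean_depth,
                    min_frac_pass=config.ase_min_frac_pass,
                )
                io.write_tsv(calls, os.path.join(out, f"ase_{seg}.tsv"))
                rec[f"ase_{seg}"] = len(calls)

    with _stage("hapstats"):
        for seg, hap in haplotypes.items():
            degs = diffexpr.select_degs(results[seg], thr.lfc_threshold, thr.alpha)
            samples = cm.samples_of(seg)
            summary = ase.haplotype_expression_summary(
                hap, counts_df, degs.index,
                min_reads=config.min_reads_expressed, samples=samples,
            )
            io.write_tsv(summary, os.path.join(out, f"hapstats_{seg}.tsv"))
            rec[f"hapstats_{seg}"] = len(summary)

    manifest_path = os.path.join(out, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def validate_inputs(paths: dict[str, str]) -> list[str]:
    """Collect (rather than fail-fast) input problems: missing files,
    unsorted VCFs, malformed gene models, negative counts, sample-sheet /
    count-matrix mismatches."""
    problems: list[str] = []

    def exists(key: str) -> bool:
        p = paths.get(key)
        if p is None:
            return False
        missing = [q for q in (p.split(",") if key == "segregant_vcfs" else [p])
                   if not os.path.exists(q)]
        for q in missing:
            problems.append(f"{key}: file not found: {q}")
        return not missing

    for key in ("panel_a_vcf", "panel_b_vcf", "segregant_vcfs"):
        if not exists(key):
            continue
        vcfs = paths[key].split(",") if key == "segregant_vcfs" else [paths[key]]
        for p in vcfs:
            try:
                df = io.read_vcf(p)
            except Exception as e:  # malformed VCF
                problems.append(f"{key}: cannot parse {p}: {e}")
                continue
            for chrom, sub in df.groupby("chrom", sort=False):
                pos = sub["pos"].to_numpy()
                if (pos[1:] < pos[:-1]).any():
                    problems.append(f"{key}: {p}: positions unsorted on {chrom}")
                    break

    if exists("counts"):
        try:
            counts = io.read_counts(paths["counts"])
            if (counts.to_numpy() < 0).any():
                problems.append("counts: negative value(s) present")
            if exists("sample_sheet"):
                groups = io.read_sample_sheet(paths["sample_sheet"])
                extra = [s for s in counts.columns if s not in groups.index]
                if extra:
                    problems.append(
                        f"sample_sheet: count-matrix samples without a group: {extra}"
                    )
        except Exception as e:
            problems.append(f"counts: cannot parse: {e}")

    if exists("genes_bed"):
        try:
            genes = io.read_gene_bed(paths["genes_bed"])
            bad = genes[genes["end"] < genes["start"]]
            for g in bad["gene"]:
                problems.append(f"genes_bed: gene {g}: end < start")
        except Exception as e:
            problems.append(f"genes_bed: cannot parse: {e}")

    return problems
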