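"""Configuration objects for simulation and pipeline runs.

Every numeric default in :class:`PipelineConfig` is a published analysis
parameter of the study design this package implements (marker depth 20,
1000-marker windows, 5-window stability, the soft/strict DE threshold
profiles, the 100-read annotation filter, the 10-read expression filter and
the 10x / 80% allele-expression filters).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Any

import yaml

__all__ = [
    "ConfigError",
    "SimConfig",
    "ThresholdProfile",
    "THRESHOLD_PROFILES",
    "PipelineConfig",
]


class ConfigError(ValueError):
    """Raised when a configuration value is invalid; names the field."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic two-species admixture study.

    The defaults emulate the study design: two pure ancestral genomes
    separated by fixed homozygous differences, segregants that are
    recombinant mosaics of the two, Poisson sequencing depth, and
    negative-binomial expression counts for 5 genotype groups x 3
    biological replicates.
    """

    n_chromosomes: int = 2
    sites_per_chromosome: int = 20_000
    fixed_diff_fraction: float = 0.3
    mean_dna_depth: float = 30.0
    n_segregants: int = 3
    crossovers_per_chromosome: float = 2.0
    n_genes: int = 500
    replicates_per_group: int = 3
    nb_dispersion: float = 0.1
    frac_de_genes: float = 0.1
    lfc_magnitude: float = 2.0
    frac_monoallelic: float = 0.3
    # NB mean structure: per-gene baseline ~ LogNormal(log(mean_expression), sdlog)
    mean_expression: float = 100.0
    expression_sdlog: float = 1.0
    # expected total RNA reads per SIM per replicate in the allelic table
    mean_allelic_depth: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_chromosomes": self.n_chromosomes,
            "sites_per_chromosome": self.sites_per_chromosome,
            "n_segregants": self.n_segregants,
            "n_genes": self.n_genes,
            "replicates_per_group": self.replicates_per_group,
        }
        for name, value in counts.items():
            if int(value) != value or value < 1:
                raise ConfigError(f"{name} must be an integer >= 1 (got {value!r})")
        proportions = {
            "fixed_diff_fraction": self.fixed_diff_fraction,
            "frac_de_genes": self.frac_de_genes,
            "frac_monoallelic": self.frac_monoallelic,
        }
        for name, value in proportions.items():
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1] (got {value!r})")
        if self.nb_dispersion <= 0:
            raise ConfigError(f"nb_dispersion must be > 0 (got {self.nb_dispersion!r})")
        if self.lfc_magnitude <= 0:
            raise ConfigError(f"lfc_magnitude must be > 0 (got {self.lfc_magnitude!r})")
        if self.mean_dna_depth < 0:
            raise ConfigError(f"mean_dna_depth must be >= 0 (got {self.mean_dna_depth!r})")
        if self.mean_allelic_depth < 0:
            raise ConfigError(
                f"mean_allelic_depth must be >= 0 (got {self.mean_allelic_depth!r})"
            )
        if self.mean_expression <= 0:
            raise ConfigError(f"mean_expression must be > 0 (got {self.mean_expression!r})")
        if self.expression_sdlog < 0:
            raise ConfigError(f"expression_sdlog must be >= 0 (got {self.expression_sdlog!r})")
        if self.crossovers_per_chromosome < 0:
            raise ConfigError(
                "crossovers_per_chromosome must be >= 0 "
                f"(got {self.crossovers_per_chromosome!r})"
            )


@dataclass(frozen=True)
class ThresholdProfile:
    """A named (|log2FC|, alpha) differential-expression threshold pair."""

    name: str
    lfc_threshold: float
    alpha: float


#: The two published threshold presets.
THRESHOLD_PROFILES: dict[str, ThresholdProfile] = {
    "soft": ThresholdProfile("soft", 0.58, 0.05),
    "strict": ThresholdProfile("strict", 1.0, 0.01),
}


@dataclass
class PipelineConfig:
    """End-to-end pipeline parameters plus input/output paths.

    ``paths`` maps logical input names (panel_a_vcf, panel_b_vcf,
    segregant_vcfs, counts, sample_sheet, genes_bed, allelic_counts,
    pathway_map, ct_table) to file locations; unknown keys are rejected so a
    typo cannot silently disable a stage.
    """

    profile: str = "soft"
    window_size: int = 1000
    min_stable: int = 5
    min_sim_depth: int = 20
    min_reads_annot: int = 100
    min_reads_expressed: int = 10
    ase_min_mean_depth: float = 10.0
    ase_min_frac_pass: float = 0.8
    seed: int = 0
    paths: dict[str, str] = field(default_factory=dict)
    out_dir: str = "admixpress_out"

    _KNOWN_PATHS = {
        "panel_a_vcf",
        "panel_b_vcf",
        "segregant_vcfs",
        "counts",
        "sample_sheet",
        "genes_bed",
        "allelic_counts",
        "pathway_map",
        "ct_table",
    }

    def __post_init__(self) -> None:
        if self.profile not in THRESHOLD_PROFILES:
            raise ConfigError(
                f"profile must be one of {sorted(THRESHOLD_PROFILES)} (got {self.profile!r})"
            )
        for name in ("window_size", "min_stable", "min_sim_depth",
                     "min_reads_annot", "min_reads_expressed"):
            value = getattr(self, name)
            if int(value) != value or value < 1:
                raise ConfigError(f"{name} must be an integer >= 1 (got {value!r})")
        if self.ase_min_mean_depth < 0:
            raise ConfigError(
                f"ase_min_mean_depth must be >= 0 (got {self.ase_min_mean_depth!r})"
            )
        if not 0.0 <= self.ase_min_frac_pass <= 1.0:
            raise ConfigError(
                f"ase_min_frac_pass must lie in [0, 1] (got {self.ase_min_frac_pass!r})"
            )
        unknown = set(self.paths) - self._KNOWN_PATHS
        if unknown:
            raise ConfigError(f"unknown path keys: {sorted(unknown)}")

    @property
    def thresholds(self) -> ThresholdProfile:
        return THRESHOLD_PROFILES[self.profile]

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw: dict[str, Any] = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls) if not f.name.startswith("_")}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str) -> None:
        payload = {
            f.name: getattr(self, f.name)
            for f in fields(self)
            if not f.name.startswith("_")
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)
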