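"""Pipeline and simulation configuration.

Thresholds default to the screening rule used throughout the analysis:
a gene is called differential when P < 0.05 and |log2FC| >= 0.585
(i.e. a 1.5-fold change). The ceRNA stage additionally applies a
Spearman anti-correlation filter on miRNA-target pairs, a Pearson
co-expression filter on candidate ceRNA pairs, and a hypergeometric
gate on the number of shared miRNAs.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field


DEFAULT_GROUPS = ("Nor", "AD", "AD_HFD", "H_H")
LAYERS = ("mRNA", "RPF", "miRNA", "lncRNA", "circRNA")


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed derived from the run seed.

    Stable across platforms/processes (crc32, not hash()); < 2**31.
    """
    return (int(seed) * 0x9E3779B1 + zlib.crc32(stage.encode())) % (2**31 - 1)


@dataclass
class PipelineConfig:
    """Thresholds and knobs shared by all statistical stages."""

    p_threshold: float = 0.05
    lfc_threshold: float = 0.585
    spearman_max: float = -0.5      # miRNA-target filter: rho <= spearman_max
    pearson_min: float = 0.7        # ceRNA co-expression: r > pearson_min
    cerna_p: float = 0.05           # hypergeometric gate on shared miRNAs
    min_shared_mirnas: int = 1
    cis_window: int = 100_000       # bp, lncRNA cis pairing
    permutations: int = 1000        # trend / GSEA permutation count
    min_base_mean: float = 1.0      # independent low-count filter
    gate_on_q: bool = False         # gate significance on BH q instead of raw p
    gsea_weight: float = 1.0        # running-sum weight exponent (0 = classic KS)
    min_set_size: int = 5
    max_set_size: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.p_threshold < 1:
            raise ValueError(f"p_threshold must be in (0,1), got {self.p_threshold}")
        if self.lfc_threshold < 0:
            raise ValueError("lfc_threshold must be non-negative")
        if not -1 <= self.spearman_max <= 1:
            raise ValueError("spearman_max must be a correlation in [-1,1]")
        if not -1 <= self.pearson_min <= 1:
            raise ValueError("pearson_min must be a correlation in [-1,1]")
        if not 0 < self.cerna_p < 1:
            raise ValueError("cerna_p must be in (0,1)")
        if self.min_shared_mirnas < 1:
            raise ValueError("min_shared_mirnas must be >= 1")
        if self.cis_window < 0:
            raise ValueError("cis_window must be non-negative")
        if self.permutations < 100:
            raise ValueError("permutations must be >= 100")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in known})


@dataclass
class SimulationConfig:
    """Planted-truth multi-omics simulator settings.

    Defaults emulate the study design: four ordered diet/genotype groups
    (Nor < AD < AD_HFD < H_H) with 3 biological replicates each, NB counts
    with gene-shared dispersion, ribosome footprints with a modal length of
    28 nt and ~88% CDS occupancy, and planted fold changes / TE shifts /
    trend profiles / ceRNA triplets as recoverable ground truth.
    """

    n_genes: dict = field(default_factory=lambda: {
        "mRNA": 2000, "lncRNA": 300, "circRNA": 300, "miRNA": 150})
    groups: tuple = DEFAULT_GROUPS
    reps: int = 3
    library_size: dict = field(default_factory=lambda: {
        "mRNA": 1e6, "RPF": 1e6, "miRNA": 2e5, "lncRNA": 2e5, "circRNA": 2e5})
    nb_dispersion: float = 0.1
    n_de: int = 100                 # planted DE genes per contrast (mRNA layer)
    de_lfc: float = 2.0             # |log2FC| of planted DE genes
    n_te_shift: int = 50            # planted TE-change genes per contrast
    te_lfc: float = 1.5             # |delta log2 TE| of planted TE genes
    n_cerna_triplets: int = 20
    n_trend_genes: int = 30         # per planted trend profile
    trend_lfc: float = 1.5          # |log2| step size of planted trends
    rpf_modal_length: int = 28
    rpf_cds_fraction: float = 0.88
    baseline_log2_sd: float = 2.0   # spread of gene baseline abundances
    te_baseline_log2_sd: float = 2.3  # RPF/mRNA baseline jitter (sets level corr)
    cerna_latent_log2_sd: float = 0.5  # within-group shared factor in triplets
    n_decoy_targets: int = 400      # random miRNA->target decoy edges
    seed: int = 0

    def __post_init__(self) -> None:
        for layer, n in self.n_genes.items():
            if n <= 0:
                raise ValueError(f"n_genes[{layer}] must be positive")
        for layer, s in self.library_size.items():
            if s <= 0:
                raise ValueError(f"library_size[{layer}] must be positive")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if not 0 < self.rpf_cds_fraction <= 1:
            raise ValueError("rpf_cds_fraction must be in (0,1]")
        if self.reps < 2:
            raise ValueError("reps must be >= 2 for any statistical stage")
        if len(self.groups) < 2:
            raise ValueError("need at least 2 groups")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["groups"] = list(self.groups)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        d = {k: v for k, v in d.items() if k in known}
        if "groups" in d:
            d["groups"] = tuple(d["groups"])
        return cls(**d)
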