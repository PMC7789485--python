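"""Study design constants and the synthetic-study configuration.

The study design mirrors a diel sampling scheme on two leaf tissues:
photosynthetic "green" tip and non-photosynthetic "white" base, each
sampled at 4 am, 10 am, 4 pm and 10 pm with two biological replicates,
profiled by WGBS (per-cytosine counts) and RNA-seq (per-gene counts).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

CONTEXTS = ("CG", "CHG", "CHH")
TISSUES = ("green", "white")
TIMES = ("4am", "10am", "4pm", "10pm")
REPLICATES = (1, 2)

#: diel sign of the CHH oscillation: up in the afternoon/evening, down at
#: night/morning (applies to "green" tissue only by default).
DIEL_SIGN = {"4am": -1.0, "10am": -1.0, "4pm": +1.0, "10pm": +1.0}

#: successive diel comparisons of green tissue, each as (later, earlier);
#: "hyper" in a comparison means higher methylation at the later time.
DIEL_CHAIN = (
    ("green_4pm", "green_10am"),
    ("green_10pm", "green_4pm"),
    ("green_4am", "green_10pm"),
    ("green_10am", "green_4am"),
)

#: per-context minimum |Δm| for a window to qualify as a DMR.
DMR_THRESHOLDS = {"CG": 0.4, "CHG": 0.2, "CHH": 0.1}

#: flank used for promoters, metaplot flanks and DMR-gene association (bp).
FLANK_BP = 2000

#: FPKM above which a gene counts as expressed.
FPKM_EXPRESSED = 0.5


def sample_name(tissue: str, time: str, rep: int) -> str:
    return f"{tissue}_{time}_r{rep}"


def group_name(tissue: str, time: str) -> str:
    return f"{tissue}_{time}"


def group_samples(group: str) -> list[str]:
    """Replicate sample names belonging to a tissue_time group."""
    tissue, time = group.split("_")
    if tissue not in TISSUES or time not in TIMES:
        raise ValueError(f"unknown group {group!r}")
    return [sample_name(tissue, time, r) for r in REPLICATES]


def all_samples() -> list[str]:
    return [
        sample_name(ti, tm, r) for ti in TISSUES for tm in TIMES for r in REPLICATES
    ]


@dataclass
class SimConfig:
    """Parameters of the synthetic study generator.

    Defaults define the reference synthetic study: a 2-Mb two-chromosome
    genome with 200 genes, TE-dense pericentromeres, plant-like context
    methylation (CG > CHG > CHH), a tissue-wide CHH deficit in "white",
    a green-only afternoon/evening CHH oscillation, planted multi-window
    DMRs at the per-context calling thresholds, and negative-binomial
    RNA counts with a subset of differentially expressed genes whose
    promoters/bodies carry planted DMRs.
    """

    seed: int = 1
    # genome
    n_chrom: int = 2
    chrom_len: int = 1_000_000
    control_len: int = 20_000
    n_genes: int = 200
    gene_len_range: tuple[int, int] = (1_000, 3_000)
    max_exons: int = 4
    n_tes: int = 150
    te_len_range: tuple[int, int] = (500, 3_000)
    pericentromere_fraction: float = 0.3
    te_pericentromere_frac: float = 0.7
    # methylome
    base_levels: Mapping[str, float] = field(
        default_factory=lambda: {"CG": 0.60, "CHG": 0.35, "CHH": 0.10}
    )
    te_boost: float = 0.25
    #: sd of shared regional variation of the true level (per 1-kb tile);
    #: emulates the heterogeneity real methylomes show between windows
    regional_sd: Mapping[str, float] = field(
        default_factory=lambda: {"CG": 0.15, "CHG": 0.18, "CHH": 0.03}
    )
    regional_tile: int = 1000
    tissue_chh_delta: float = 0.03
    #: diel oscillation amplitudes; applied in "green" only, within the
    #: diel scope ("te": TE intervals, the RdDM-targeted compartment)
    diel_chh_amplitude: float = 0.06
    diel_chg_amplitude: float = 0.06
    diel_cg_amplitude: float = 0.0
    diel_scope: str = "te"
    mean_coverage: float = 20.0
    conversion_error: float = 0.012
    # planted DMRs
    n_planted_dmrs: int = 40
    planted_dmr_len: int = 500
    planted_effect: Mapping[str, float] = field(
        default_factory=lambda: dict(DMR_THRESHOLDS)
    )
    # expression
    n_de_genes: int = 120
    de_log2fc: float = 2.0
    nb_dispersion: float = 0.05
    frac_dmr_linked_degs: float = 0.85
    deg_dmr_len: int = 300
    frac_silenced: float = 0.30
    silenced_promoter_boost: float = 0.15
    silenced_expression_factor: float = 5e-5
    base_mean_count: float = 200.0
    expression_sdlog: float = 1.2
    # GO
    n_go_terms: int = 15
    planted_go_term: str = "GO:0015979"  # photosynthesis-flavoured id
    planted_go_de_frac: float = 0.9
    planted_go_bg_frac: float = 0.1

    def validate(self) -> None:
        props = {
            "pericentromere_fraction": self.pericentromere_fraction,
            "te_pericentromere_frac": self.te_pericentromere_frac,
            "conversion_error": self.conversion_error,
            "frac_dmr_linked_degs": self.frac_dmr_linked_degs,
            "frac_silenced": self.frac_silenced,
            "tissue_chh_delta": self.tissue_chh_delta,
            **{f"base_levels[{c}]": self.base_levels[c] for c in CONTEXTS},
        }
        for name, v in props.items():
            if not 0.0 <= float(v) <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        b = self.base_levels
        if not (b["CHH"] < b["CHG"] < b["CG"]):
            raise ValueError("base levels must satisfy CHH < CHG < CG")
        if self.mean_coverage < 0:
            raise ValueError("mean_coverage must be >= 0")
        for n in ("n_chrom", "chrom_len", "control_len"):
            if getattr(self, n) <= 0:
                raise ValueError(f"{n} must be positive")
        for n in ("n_genes", "n_tes", "n_planted_dmrs", "n_de_genes"):
            if getattr(self, n) < 0:
                raise ValueError(f"{n} must be >= 0")
        if self.n_de_genes > self.n_genes:
            raise ValueError("n_de_genes cannot exceed n_genes")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        cfg = cls(**dict(d))
        for key in ("gene_len_range", "te_len_range"):
            setattr(cfg, key, tuple(getattr(cfg, key)))
        return cfg
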