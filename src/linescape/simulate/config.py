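"""Simulation configuration.

The defaults define the emulated study conditions: a small aneuploid
genome biased toward three copies per locus, GC-biased overdispersed
coverage at ~20x per copy (60x at the modal triploid state), LOH blocks of
0.5-2 Mb, a 16-sample expression panel with 3 cell-line replicates, and a
handful of viral insertions.  One integer seed makes every simulated
artifact byte-identical across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field


def _default_cn_prior() -> dict[int, float]:
    # hypotriploid-like: mode at 3, heavy shoulders at 2 and 4
    return {0: 0.01, 1: 0.04, 2: 0.17, 3: 0.55, 4: 0.13, 5: 0.06, 6: 0.025, 7: 0.01, 8: 0.005}


def _default_viruses() -> list[tuple[str, str, int]]:
    # synthetic viral contigs: (name, family, length); no real viral sequence
    return [
        ("virus_alpha", "papillomavirus", 8000),
        ("virus_beta", "papillomavirus", 8000),
        ("virus_gamma", "herpesvirus", 150_000),
    ]


@dataclass
class SimulationConfig:
    seed: int = 0

    # genome
    n_chromosomes: int = 2
    chrom_length: int = 5_000_000
    bin_size: int = 10_000
    gc_mean: float = 0.45  # per-10kb-window GC composition target
    gc_sd: float = 0.07
    cn_prior: dict[int, float] = field(default_factory=_default_cn_prior)
    cn_segment_mean_bins: int = 60
    cn_segment_min_bins: int = 8

    # LOH truth (deterministic placement on one chromosome)
    loh_chrom_index: int = 0
    loh_block_sizes: tuple[int, ...] = (500_000, 1_000_000, 2_000_000)
    loh_gap: int = 1_500_000  # het stretches between LOH blocks span Mbs
    loh_first_start: int = 300_000

    # coverage forward model; 10x per copy puts CN 1..6 in the 10-60x
    # window the coverage-stratification filter expects
    mean_coverage_per_copy: float = 10.0
    gc_bias_peak: float = 0.45
    gc_bias_curvature: float = 8.0  # quadratic coefficient of the bias dip
    noise_dispersion: float | None = 0.05  # NB dispersion; None/0 = noiseless

    # SNVs
    het_snv_rate: float = 1e-3
    hom_snv_rate: float = 6e-4

    # expression
    panel_samples: int = 16
    replicate_samples: int = 3
    gene_gap: int = 2000
    expression_dispersion: float = 0.05
    tissue_lognoise_sd: float = 0.3
    n_outlier_genes: int = 30
    outlier_z_range: tuple[float, float] = (5.0, 12.0)
    n_silenced_genes: int = 30
    rna_allele_depth: float = 50.0

    # virus insertions / chimeric pairs
    viruses: list[tuple[str, str, int]] = field(default_factory=_default_viruses)
    n_insertions: int = 3
    pairs_per_insertion: int = 5
    background_pairs: int = 100
    read_length: int = 101

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        def _err(name, msg):
            raise ValueError(f"invalid SimulationConfig.{name}: {msg}")

        if not isinstance(self.seed, int):
            _err("seed", "must be an integer")
        for name in ("bin_size", "chrom_length", "n_chromosomes"):
            if getattr(self, name) <= 0:
                _err(name, "must be positive")
        for name in ("het_snv_rate", "hom_snv_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                _err(name, f"rate {v} outside [0, 1]")
        if abs(sum(self.cn_prior.values()) - 1.0) > 1e-9:
            _err("cn_prior", "probabilities must sum to 1")
        if any(cn < 0 or cn > 8 for cn in self.cn_prior):
            _err("cn_prior", "CN states must lie in 0..8")
        if self.noise_dispersion is not None and self.noise_dispersion < 0:
            _err("noise_dispersion", "must be >= 0 or None")
        if not 0.0 < self.gc_mean < 1.0:
            _err("gc_mean", "must lie in (0, 1)")
        if self.panel_samples < 2:
            _err("panel_samples", "need at least 2 panel samples")
        if self.replicate_samples < 1:
            _err("replicate_samples", "need at least 1 replicate")
        if self.read_length <= 0:
            _err("read_length", "must be positive")

    def gc_bias(self, gc):
        """Symmetric quadratic coverage bias, 1.0 at the peak GC."""
        import numpy as np

        gc = np.asarray(gc, dtype=float)
        return np.maximum(1.0 - self.gc_bias_curvature * (gc - self.gc_bias_peak) ** 2, 0.2)

    def rng(self, salt: int):
        """Independent, reproducible stream per simulation stage."""
        import numpy as np

        return np.random.default_rng([self.seed, salt])
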