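"""Forward models for coverage and SNV calls on the synthetic genome."""

from __future__ import annotations

from typing import Optional

import numpy as np

from ..expression import AllelicSite
from ..tracks import BinnedTrack
from ..variants import SnvRecord
from .config import SimulationConfig
from .genome import SyntheticGenome

__all__ = ["simulate_coverage", "simulate_snvs", "simulate_rna_allele_counts"]

_ALT = {"A": "CGT", "C": "AGT", "G": "ACT", "T": "ACG"}


def _nb_sample(rng, mu: np.ndarray, dispersion: float, n_units: int = 1) -> np.ndarray:
    """Mean of ``n_units`` iid negative-binomial draws, each with mean mu
    and variance mu + dispersion * mu^2.

    A sum of iid NB(r, p) is NB(n*r, p), so one draw per bin suffices.
    """
    mu = np.maximum(mu, 0.0)
    out = np.zeros_like(mu)
    pos = mu > 0
    r = n_units / dispersion
    p = (1.0 / dispersion) / (1.0 / dispersion + mu[pos])
    out[pos] = rng.negative_binomial(r, p) / n_units
    return out


def simulate_coverage(
    genome: SyntheticGenome,
    config: SimulationConfig,
    mappability: Optional[BinnedTrack] = None,
) -> BinnedTrack:
    """Per-bin depth: truth CN x coverage-per-copy x GC bias x mappable
    fraction, with negative-binomial noise (noiseless when dispersion is
    None or 0 — the expectation is returned exactly).

    A bin's depth is the average over ~bin_size/read_length quasi-
    independent fragment-start sites, each drawn NB with the configured
    dispersion, so the per-bin coefficient of variation lands in the
    few-percent range real 10-kb binned coverage shows at this depth.
    """
    cn = genome.truth_cn.values
    gc = genome.gc_track().values
    map_frac = mappability.values if mappability is not None else np.ones_like(cn)
    mu = cn * config.mean_coverage_per_copy * config.gc_bias(gc) * map_frac
    if config.noise_dispersion:
        n_units = max(config.bin_size // config.read_length, 1)
        mu = _nb_sample(config.rng(2), mu, config.noise_dispersion, n_units).astype(float)
    return genome.truth_cn.with_values(mu)


def _in_loh(genome: SyntheticGenome, chrom: str, pos0: int) -> bool:
    return any(c == chrom and s <= pos0 < e for c, s, e in genome.truth_loh)


def simulate_snvs(
    genome: SyntheticGenome,
    config: SimulationConfig,
    coverage: Optional[BinnedTrack] = None,
) -> list[SnvRecord]:
    """SNV calls with zygosity and CN-consistent DNA allele fractions.

    Inside truth LOH blocks every emitted call is homozygous; elsewhere
    heterozygous calls draw their alt fraction around k/CN for a uniformly
    chosen k in 1..CN-1.  Local coverage comes from the supplied coverage
    track (or the noiseless expectation).  CN-0 territory emits nothing.
    """
    rng = config.rng(3)
    if coverage is None:
        coverage = simulate_coverage(genome, config)
    cov_by_key = {
        (c, s): v
        for c, s, v in zip(
            coverage.df["chrom"], coverage.df["start"], coverage.df["value"]
        )
    }
    total_rate = config.het_snv_rate + config.hom_snv_rate
    if total_rate == 0:
        return []
    p_hom = config.hom_snv_rate / total_rate
    records: list[SnvRecord] = []
    cn_df = genome.truth_cn.df
    for name, seq in genome.chromosomes:
        n_sites = rng.binomial(len(seq), total_rate)
        positions = np.sort(rng.choice(len(seq), size=n_sites, replace=False))
        sub = cn_df[cn_df["chrom"] == name]
        cn_bins = sub["value"].to_numpy()
        for pos0 in positions:
            b = int(pos0) // config.bin_size
            cn = int(cn_bins[b])
            if cn == 0:
                continue
            cov = cov_by_key.get((name, b * config.bin_size), 0.0)
            depth = int(round(cov)) if not np.isnan(cov) else 0
            if depth <= 0:
                continue
            hom = _in_loh(genome, name, int(pos0)) or cn == 1 or rng.random() < p_hom
            ref = seq[int(pos0)]
            if ref not in _ALT:
                continue
            alt = _ALT[ref][rng.integers(0, 3)]
            if hom:
                ad = (0, depth)
            else:
                k = int(rng.integers(1, cn))
                alt_reads = int(rng.binomial(depth, k / cn))
                ad = (depth - alt_reads, alt_reads)
            records.append(
                SnvRecord(
                    chrom=name,
                    pos=int(pos0) + 1,
                    ref=ref,
                    alt=alt,
                    zygosity="hom" if hom else "het",
                    dna_allele_depths=ad,
                    local_coverage=depth,
                )
            )
    return records


def simulate_rna_allele_counts(
    snvs: list[SnvRecord],
    genome: SyntheticGenome,
    config: SimulationConfig,
    scenario: str = "proportional",
) -> list[AllelicSite]:
    """RNA allele counts at heterozygous SNVs in CN-3 regions.

    ``proportional``: the duplicated allele gets 2/3 of the reads (no
    dosage compensation).  ``silencing``: allele-specific compensation —
    most sites (70%) silence the extra copy (1:1), the rest express only
    the duplicated allele (2:0), so the site-level median sits near 1/2
    rather than 2/3.
    """
    if scenario not in ("proportional", "silencing"):
        raise ValueError(f"unknown scenario {scenario!r}")
    rng = config.rng(5)
    cn_df = genome.truth_cn.df
    cn_lookup = {
        (c, s): int(v)
        for c, s, v in zip(cn_df["chrom"], cn_df["start"], cn_df["value"])
    }
    sites: list[AllelicSite] = []
    for s in snvs:
        if s.zygosity != "het":
            continue
        b = (s.pos - 1) // config.bin_size * config.bin_size
        cn = cn_lookup.get((s.chrom, b))
        if cn != 3:
            continue
        depth = int(rng.poisson(config.rna_allele_depth))
        if depth == 0:
            continue
        if scenario == "proportional":
            p_ref = 2.0 / 3.0 if rng.random() < 0.5 else 1.0 / 3.0
        else:
            if rng.random() < 0.7:
                p_ref = 0.5  # extra copy silenced: 1:1
            else:
                p_ref = 0.98 if rng.random() < 0.5 else 0.02  # 2:0-like
        ref_reads = int(rng.binomial(depth, p_ref))
        sites.append(
            AllelicSite(
                chrom=s.chrom,
                pos=s.pos,
                rna_ref_count=ref_reads,
                rna_alt_count=depth - ref_reads,
                region_cn=cn,
            )
        )
    return sites
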