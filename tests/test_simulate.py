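"""The synthetic-data generator is first-class code: its statistical
contracts (determinism, CN-consistent allele fractions, coverage forward
model, mappability census) are tested like any pipeline stage."""

import numpy as np
import pytest

from linescape.simulate import (
    SimulationConfig,
    compute_mappability,
    generate_genome,
    simulate_coverage,
    simulate_rna_allele_counts,
    simulate_snvs,
)
from linescape.simulate.genome import SyntheticGenome, mappable_positions


def test_invalid_config_names_the_field():
    with pytest.raises(ValueError, match="het_snv_rate"):
        SimulationConfig(het_snv_rate=1.5)
    with pytest.raises(ValueError, match="bin_size"):
        SimulationConfig(bin_size=0)
    with pytest.raises(ValueError, match="cn_prior"):
        SimulationConfig(cn_prior={3: 0.5})


def test_binning_arithmetic_and_determinism():
    cfg = SimulationConfig(seed=1, n_chromosomes=2, chrom_length=1_000_000)
    g1 = generate_genome(cfg)
    assert len(g1.truth_cn) == 200  # 100 bins per 1-Mb chromosome at 10 kb
    g2 = generate_genome(SimulationConfig(seed=1, n_chromosomes=2, chrom_length=1_000_000))
    assert g1.chromosomes == g2.chromosomes
    assert (g1.truth_cn.values == g2.truth_cn.values).all()
    assert g1.truth_insertions == g2.truth_insertions


def test_cn_prior_mode_dominates():
    """The long-run CN marginal matches the hypotriploid prior: mode 3
    holds a majority of bins.  Tested on the truth-track generator at
    large n (single small genomes carry few segments and fluctuate)."""
    from linescape.simulate.genome import _piecewise_cn

    cfg = SimulationConfig(seed=0)
    rng = np.random.default_rng(0)
    vals = _piecewise_cn(200_000, cfg, rng)
    assert (vals == 3).mean() == pytest.approx(0.55, abs=0.02)
    assert (vals == 3).mean() >= 0.5
    for state, prob in cfg.cn_prior.items():
        assert (vals == state).mean() == pytest.approx(prob, abs=0.03)


def test_truth_tracks_tile_without_overlap(small_genome):
    df = small_genome.truth_cn.df
    for _, sub in df.groupby("chrom"):
        assert (sub["start"].to_numpy()[1:] == sub["end"].to_numpy()[:-1]).all()
    assert set(np.unique(small_genome.truth_cn.values)) <= set(range(9))


# ------------------------------------------------------------- mappability
def test_mappability_tiny_oracle():
    """In ACGTACGTAA with k=4, ACGT occurs twice (positions 0 and 4), so
    those start positions are unmappable; both-strand hits count too."""
    tiny = SyntheticGenome(
        chromosomes=[("c", "ACGTACGTAA")], truth_cn=None, truth_loh=[],
        truth_insertions=[], bin_size=10,
    )
    mask = mappable_positions(tiny, 4)["c"]
    assert not mask[0] and not mask[4]
    # brute-force census over both strands as an independent oracle
    seq = "ACGTACGTAA"
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    rc = "".join(comp[b] for b in reversed(seq))
    kmers = [seq[i:i + 4] for i in range(7)] + [rc[i:i + 4] for i in range(7)]
    expected = [kmers.count(seq[i:i + 4]) == 1 for i in range(7)]
    assert mask.tolist() == expected


def test_duplicated_chromosome_fully_unmappable():
    seq = "".join(np.random.default_rng(0).choice(list("ACGT"), 500))
    twin = SyntheticGenome(
        chromosomes=[("a", seq), ("b", seq)], truth_cn=None, truth_loh=[],
        truth_insertions=[], bin_size=100,
    )
    masks = mappable_positions(twin, 25)
    assert not masks["a"].any() and not masks["b"].any()


def test_random_genome_nearly_fully_mappable():
    cfg = SimulationConfig(seed=5, n_chromosomes=1, chrom_length=200_000)
    g = generate_genome(cfg)
    track = compute_mappability(g, read_length=101)
    assert np.nanmean(track.values) > 0.999


def test_mappability_rejects_bad_read_length(small_genome):
    with pytest.raises(ValueError, match="read_length"):
        compute_mappability(small_genome, 0)
    with pytest.raises(ValueError, match="exceeds"):
        compute_mappability(small_genome, 10_000_000)


# ---------------------------------------------------------------- coverage
def test_noiseless_coverage_identity():
    cfg = SimulationConfig(
        seed=2, n_chromosomes=1, chrom_length=500_000,
        cn_prior={2: 1.0}, gc_bias_curvature=0.0, noise_dispersion=None,
        mean_coverage_per_copy=30.0, loh_block_sizes=(),
    )
    g = generate_genome(cfg)
    cov = simulate_coverage(g, cfg)
    np.testing.assert_allclose(cov.values, 60.0)


def test_cn_zero_bins_have_zero_coverage():
    cfg = SimulationConfig(
        seed=3, n_chromosomes=1, chrom_length=500_000,
        cn_prior={0: 0.5, 3: 0.5}, cn_segment_mean_bins=8,
        gc_bias_curvature=0.0, noise_dispersion=None,
        loh_block_sizes=(),
    )
    g = generate_genome(cfg)
    cov = simulate_coverage(g, cfg)
    zero = g.truth_cn.values == 0
    assert zero.any()
    assert (cov.values[zero] == 0).all()


def test_injected_gc_curve_is_recoverable():
    """Regressing noiseless coverage/CN on GC recovers the quadratic dip."""
    cfg = SimulationConfig(seed=4, n_chromosomes=2, chrom_length=2_000_000,
                           noise_dispersion=None)
    g = generate_genome(cfg)
    cov = simulate_coverage(g, cfg)
    gc = g.gc_track().values
    cn = g.truth_cn.values
    ok = cn > 0
    ratio = cov.values[ok] / (cn[ok] * cfg.mean_coverage_per_copy)
    coef = np.polyfit(gc[ok] - cfg.gc_bias_peak, ratio, 2)
    assert coef[0] == pytest.approx(-cfg.gc_bias_curvature, rel=0.05)
    assert coef[2] == pytest.approx(1.0, rel=0.01)


def test_noise_magnitude_matches_model():
    cfg = SimulationConfig(seed=6, n_chromosomes=1, chrom_length=2_000_000,
                           cn_prior={3: 1.0}, gc_bias_curvature=0.0,
                           loh_block_sizes=())
    g = generate_genome(cfg)
    cov = simulate_coverage(g, cfg)
    mu = 3 * cfg.mean_coverage_per_copy
    n_units = cfg.bin_size // cfg.read_length
    expect_cv = np.sqrt((1 / mu + cfg.noise_dispersion) / n_units)
    cv = cov.values.std() / cov.values.mean()
    assert cv == pytest.approx(expect_cv, rel=0.3)


# -------------------------------------------------------------------- SNVs
def test_loh_block_snvs_all_homozygous(small_genome, small_config):
    snvs = simulate_snvs(small_genome, small_config)
    chrom, start, end = small_genome.truth_loh[0]
    inside = [s for s in snvs if s.chrom == chrom and start < s.pos <= end]
    assert len(inside) > 50
    assert all(s.zygosity == "hom" for s in inside)


def test_het_allele_fractions_mode_at_k_over_cn(small_genome, small_config):
    """Heterozygous CN-3 sites show allele-fraction modes near 1/3, 2/3."""
    snvs = simulate_snvs(small_genome, small_config)
    cn_df = small_genome.truth_cn.df
    cn_of = {(c, s): v for c, s, v in zip(cn_df["chrom"], cn_df["start"], cn_df["value"])}
    fracs = []
    for s in snvs:
        b = (s.pos - 1) // small_config.bin_size * small_config.bin_size
        if s.zygosity == "het" and cn_of.get((s.chrom, b)) == 3:
            ref, alt = s.dna_allele_depths
            if ref + alt > 0:
                fracs.append(alt / (ref + alt))
    fracs = np.array(fracs)
    assert len(fracs) > 200
    lo = ((fracs > 0.15) & (fracs < 0.48)).mean()
    hi = ((fracs > 0.52) & (fracs < 0.85)).mean()
    assert lo + hi > 0.85
    assert lo == pytest.approx(0.5, abs=0.1)


def test_zero_rates_give_empty_callset(small_genome, small_config):
    from dataclasses import replace

    cfg = replace(small_config, het_snv_rate=0.0, hom_snv_rate=0.0)
    assert simulate_snvs(small_genome, cfg) == []


def test_rna_allele_counts_pooled_ratio(small_genome, small_config):
    snvs = simulate_snvs(small_genome, small_config)
    sites = simulate_rna_allele_counts(snvs, small_genome, small_config)
    assert all(s.region_cn == 3 for s in sites)
    hi = sum(s.higher for s in sites)
    lo = sum(s.lower for s in sites)
    assert hi / lo == pytest.approx(2.0, rel=0.1)


def test_rna_scenario_validation(small_genome, small_config):
    with pytest.raises(ValueError, match="scenario"):
        simulate_rna_allele_counts([], small_genome, small_config, scenario="bogus")
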