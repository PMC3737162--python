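"""Shared fixtures: small synthetic datasets generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from linescape.simulate import SimulationConfig, generate_genome, simulate_coverage


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    # CN >= 2 everywhere so zygosity truth is exactly the designed
    # (copy-neutral) LOH blocks — CN-1 territory is hemizygous and would
    # legitimately add homozygous blocks of its own
    return SimulationConfig(
        seed=11,
        n_chromosomes=2,
        chrom_length=2_000_000,
        cn_prior={2: 0.25, 3: 0.5, 4: 0.25},
        loh_block_sizes=(600_000,),
        loh_first_start=300_000,
    )


@pytest.fixture(scope="session")
def small_genome(small_config):
    return generate_genome(small_config)


@pytest.fixture(scope="session")
def small_coverage(small_genome, small_config):
    return simulate_coverage(small_genome, small_config)


def find_cn_run(truth_df, cn_target: int, min_bins: int = 10):
    """Longest run of a given truth CN; returns (chrom, start, end) or None."""
    best, best_len = None, 0
    for chrom in truth_df["chrom"].unique():
        sub = truth_df[truth_df["chrom"] == chrom].reset_index(drop=True)
        v = sub["value"].to_numpy()
        i = 0
        while i < len(v):
            j = i
            while j < len(v) and v[j] == cn_target:
                j += 1
            if j > i and j - i > best_len:
                best_len = j - i
                best = (chrom, int(sub["start"][i]), int(sub["end"][j - 1]))
            i = j if j > i else i + 1
    return best if best_len >= min_bins else None


@pytest.fixture(scope="session")
def ones_track(small_coverage):
    return small_coverage.with_values(np.ones(len(small_coverage)))
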