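"""Shared configuration for the analysis drivers.

One synthetic cell line underlies scripts 02-08: a hypotriploid genome of
two 5-Mb chromosomes with LOH blocks, viral insertions, an expression
panel, and an SV call set — all generated deterministically from SEED.
Script 01 materializes it under results/dataset/ in standard formats.
"""

from pathlib import Path

from linescape.simulate import SimulationConfig

SEED = 17
RESULTS = Path(__file__).resolve().parent.parent / "results"
DATASET = RESULTS / "dataset"


def study_config() -> SimulationConfig:
    return SimulationConfig(
        seed=SEED,
        n_chromosomes=2,
        chrom_length=5_000_000,
        loh_block_sizes=(800_000, 1_200_000),
        cn_prior={1: 0.04, 2: 0.18, 3: 0.55, 4: 0.14, 5: 0.06, 6: 0.03},
    )
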