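"""Host-virus chimeric read-pair fixtures."""

from __future__ import annotations

import pandas as pd

from .config import SimulationConfig
from .genome import SyntheticGenome

__all__ = ["simulate_chimeric_pairs"]


def simulate_chimeric_pairs(
    genome: SyntheticGenome, config: SimulationConfig
) -> pd.DataFrame:
    """Read-pair records: chimeric pairs at each truth insertion site plus
    host-only background pairs.

    Columns: pair_id, ref1, pos1, strand1, ref2, pos2, strand2,
    read_length.  Which mate carries the virus alternates randomly, as it
    would in an alignment.
    """
    rng = config.rng(7)
    virus_len = {name: length for name, _, length in genome.virus_contigs}
    rows = []
    pid = 0

    def add(ref1, pos1, ref2, pos2):
        nonlocal pid
        pid += 1
        rows.append(
            {
                "pair_id": f"pair{pid:05d}",
                "ref1": ref1,
                "pos1": int(pos1),
                "strand1": "+" if rng.random() < 0.5 else "-",
                "ref2": ref2,
                "pos2": int(pos2),
                "strand2": "+" if rng.random() < 0.5 else "-",
                "read_length": config.read_length,
            }
        )

    for chrom, pos, virus, _family in genome.truth_insertions:
        for _ in range(config.pairs_per_insertion):
            host_pos = max(0, pos - int(rng.integers(50, 400)))
            vpos = int(rng.integers(0, max(virus_len.get(virus, 1000) - config.read_length, 1)))
            if rng.random() < 0.5:
                add(chrom, host_pos, virus, vpos)
            else:
                add(virus, vpos, chrom, host_pos)

    lengths = genome.chrom_lengths
    names = list(lengths)
    for _ in range(config.background_pairs):
        c1 = names[rng.integers(0, len(names))]
        c2 = names[rng.integers(0, len(names))]
        add(
            c1,
            rng.integers(0, lengths[c1] - config.read_length),
            c2,
            rng.integers(0, lengths[c2] - config.read_length),
        )
    return pd.DataFrame(rows)
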