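"""Synthetic expression panel: 16 tissue samples + cell-line replicates.

Gene-level counts follow a negative-binomial model around a per-gene
baseline rate (counts per kb); panel samples add tissue-to-tissue
log-normal variability, cell-line replicates scale linearly with the
gene's truth copy number.  A configured set of genes is injected with a
known z-score signal above the panel, another set is silenced below
1 count/kb, providing ground truth for the outlier detector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .genome import SyntheticGenome

__all__ = ["ExpressionSim", "simulate_expression_counts", "place_genes"]


@dataclass
class ExpressionSim:
    genes: pd.DataFrame  # gene_id, chrom, start, end, length_bp, cn
    counts: pd.DataFrame  # genes x samples
    roles: pd.Series  # sample -> {panel, cellline_replicate}
    true_depths: pd.Series
    outlier_truth: dict[str, float]  # gene_id -> injected true z
    silenced_truth: list[str]


def place_genes(genome: SyntheticGenome, config: SimulationConfig, rng) -> pd.DataFrame:
    """Tile non-overlapping genes along each chromosome; lengths are drawn
    log-uniform between 0.5 and 10 kb."""
    rows = []
    gid = 0
    for name, seq in genome.chromosomes:
        cursor = 1000
        while True:
            length = int(10 ** rng.uniform(np.log10(500), np.log10(10_000)))
            if cursor + length > len(seq) - 1000:
                break
            rows.append(
                {
                    "gene_id": f"g{gid:05d}",
                    "chrom": name,
                    "start": cursor,
                    "end": cursor + length,
                    "length_bp": length,
                }
            )
            cursor += length + config.gene_gap
            gid += 1
    genes = pd.DataFrame(rows).set_index("gene_id")
    cn_df = genome.truth_cn.df
    cn_of = {}
    for chrom, sub in cn_df.groupby("chrom", sort=False):
        cn_of[chrom] = sub["value"].to_numpy()
    mid = ((genes["start"] + genes["end"]) // 2).to_numpy()
    genes["cn"] = [
        int(cn_of[c][min(m // config.bin_size, len(cn_of[c]) - 1)])
        for c, m in zip(genes["chrom"], mid)
    ]
    return genes


def simulate_expression_counts(
    genome: SyntheticGenome, config: SimulationConfig
) -> ExpressionSim:
    if config.n_outlier_genes < 0 or config.n_silenced_genes < 0:
        raise ValueError("gene injection counts must be non-negative")
    rng = config.rng(4)
    genes = place_genes(genome, config, rng)
    n_genes = len(genes)
    len_kb = genes["length_bp"].to_numpy() / 1000.0

    # per-gene baseline expression rate (counts per kb at unit depth)
    base_rate = 10 ** rng.normal(1.3, 0.6, size=n_genes)

    panel_cols = [f"panel_{j + 1:02d}" for j in range(config.panel_samples)]
    rep_cols = [f"cellline_{j + 1}" for j in range(config.replicate_samples)]
    depths = pd.Series(
        np.concatenate(
            [
                rng.uniform(0.5, 2.0, size=config.panel_samples),
                rng.uniform(0.8, 1.2, size=config.replicate_samples),
            ]
        ),
        index=panel_cols + rep_cols,
        name="true_depth",
    )

    disp = config.expression_dispersion
    n_nb = 1.0 / disp

    def _nb(mu):
        mu = np.maximum(mu, 1e-12)
        return rng.negative_binomial(n_nb, n_nb / (n_nb + mu))

    counts = pd.DataFrame(index=genes.index, columns=panel_cols + rep_cols, dtype=float)
    for col in panel_cols:
        tissue = np.exp(rng.normal(0.0, config.tissue_lognoise_sd, size=n_genes))
        counts[col] = _nb(base_rate * len_kb * depths[col] * tissue)
    cn_scale = genes["cn"].to_numpy() / 2.0
    for col in rep_cols:
        counts[col] = _nb(base_rate * len_kb * cn_scale * depths[col])

    # ground-truth injections, defined on the variance-stabilized scale
    # of truly normalized values: log2(count / depth + 1)
    stab_panel = np.log2(counts[panel_cols].div(depths[panel_cols], axis=1) + 1.0)
    mu = stab_panel.mean(axis=1).to_numpy()
    sd = stab_panel.std(axis=1, ddof=1).to_numpy()

    candidates = [
        g
        for g, s in zip(genes.index, sd)
        if s > 0.05 and genes.loc[g, "cn"] > 0
    ]
    rng.shuffle(candidates)
    n_out = min(config.n_outlier_genes, len(candidates))
    outlier_genes = candidates[:n_out]
    silenced_genes = candidates[n_out : n_out + config.n_silenced_genes]

    outlier_truth: dict[str, float] = {}
    gene_pos = {g: i for i, g in enumerate(genes.index)}
    for g in outlier_genes:
        i = gene_pos[g]
        z_true = float(rng.uniform(*config.outlier_z_range))
        target_norm = 2.0 ** (mu[i] + z_true * sd[i]) - 1.0
        for col in rep_cols:
            counts.loc[g, col] = float(rng.poisson(target_norm * depths[col]))
        outlier_truth[g] = z_true
    for g in silenced_genes:
        for col in rep_cols:
            counts.loc[g, col] = 0.0

    roles = pd.Series(
        ["panel"] * len(panel_cols) + ["cellline_replicate"] * len(rep_cols),
        index=panel_cols + rep_cols,
        name="role",
    )
    return ExpressionSim(
        genes=genes,
        counts=counts.astype(int),
        roles=roles,
        true_depths=depths,
        outlier_truth=outlier_truth,
        silenced_truth=list(silenced_genes),
    )
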