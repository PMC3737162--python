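"""Zygosity binning and loss-of-heterozygosity segmentation.

The genome is scanned in 100-kb bins; each bin's value is the proportion of
homozygous SNV calls among all calls in the bin (NA if the bin has none).
The binned proportions are segmented with the same changepoint machinery as
the coverage track, and each segment is classified homozygous iff its mean
proportion exceeds 0.5 (strictly).  Homozygous blocks at copy number >= 2
are the candidate LOH regions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .segmentation import segment_indices
from .tracks import BinnedTrack, make_bins
from .variants import SnvRecord

__all__ = ["ZygosityBlock", "bin_homozygosity", "segment_zygosity", "bin_classifier_fraction"]

HOM_PROPORTION_THRESHOLD = 0.5  # strictly greater than ⇒ homozygous


@dataclass
class ZygosityBlock:
    chrom: str
    start: int
    end: int
    state: str  # "homozygous" | "heterozygous"
    mean_hom_proportion: float
    n_bins: int


def bin_homozygosity(
    snvs: list[SnvRecord],
    bin_size: int = 100_000,
    chrom_lengths: Optional[Mapping[str, int]] = None,
) -> BinnedTrack:
    """Per-bin proportion of homozygous calls; SNV-free bins are NA.

    Without explicit chromosome lengths the grid extends to the last SNV.
    """
    if chrom_lengths is None:
        chrom_lengths = {}
        for s in snvs:
            chrom_lengths[s.chrom] = max(chrom_lengths.get(s.chrom, 0), s.pos)
    grid = make_bins(chrom_lengths, bin_size)
    key = {(c, s): i for i, (c, s) in enumerate(zip(grid["chrom"], grid["start"]))}
    hom = np.zeros(len(grid))
    tot = np.zeros(len(grid))
    for s in snvs:
        b = ((s.pos - 1) // bin_size) * bin_size  # VCF pos is 1-based
        i = key.get((s.chrom, b))
        if i is None:
            continue
        tot[i] += 1
        if s.zygosity == "hom":
            hom[i] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        grid["value"] = np.where(tot > 0, hom / np.maximum(tot, 1), np.nan)
    return BinnedTrack(grid, validate=False)


def segment_zygosity(
    proportions: BinnedTrack,
    undo_sd: float = 2.0,
    alpha: float = 0.01,
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[list[ZygosityBlock], float]:
    """Segment binned homozygous proportions into zygosity blocks.

    Returns the blocks and the genome homozygous fraction (length-weighted
    over segmented territory).  NA bins are excluded from segmentation —
    SNV deserts carry no zygosity evidence.
    """
    blocks: list[ZygosityBlock] = []
    for chrom in proportions.chroms:
        sub = proportions.chrom_view(chrom)
        vals = sub["value"].to_numpy()
        ok = ~np.isnan(vals)
        if not ok.any():
            continue
        x = vals[ok]
        starts = sub["start"].to_numpy()[ok]
        ends = sub["end"].to_numpy()[ok]
        for i0, i1 in segment_indices(
            x, alpha=alpha, n_perm=n_perm, undo_sd=undo_sd, seed=seed
        ):
            mean_p = float(x[i0:i1].mean())
            blocks.append(
                ZygosityBlock(
                    chrom=chrom,
                    start=int(starts[i0]),
                    end=int(ends[i1 - 1]),
                    state=(
                        "homozygous"
                        if mean_p > HOM_PROPORTION_THRESHOLD
                        else "heterozygous"
                    ),
                    mean_hom_proportion=mean_p,
                    n_bins=i1 - i0,
                )
            )
    total = sum(b.end - b.start for b in blocks)
    hom_len = sum(b.end - b.start for b in blocks if b.state == "homozygous")
    fraction = hom_len / total if total else float("nan")
    return blocks, fraction


def bin_classifier_fraction(proportions: BinnedTrack) -> float:
    """Direct per-bin classifier: fraction of informative bins whose
    homozygous proportion exceeds 0.5 (no segmentation)."""
    v = proportions.values
    ok = ~np.isnan(v)
    if not ok.any():
        return float("nan")
    return float((v[ok] > HOM_PROPORTION_THRESHOLD).mean())


def blocks_to_frame(blocks: list[ZygosityBlock]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [b.chrom for b in blocks],
            "start": [b.start for b in blocks],
            "end": [b.end for b in blocks],
            "state": [b.state for b in blocks],
            "mean_hom_proportion": [b.mean_hom_proportion for b in blocks],
            "n_bins": [b.n_bins for b in blocks],
        }
    )
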