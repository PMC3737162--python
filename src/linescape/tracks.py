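"""Binned genomic tracks.

A :class:`BinnedTrack` holds one numeric value per fixed-width genomic bin
(coverage, GC fraction, mappable fraction, homozygous-call proportion, ...).
Bins are 0-based half-open, sorted, non-overlapping, and of constant width
except for the terminal bin of each chromosome, which may be shorter.
Missing values are NaN and mean "no call" (NA); no operation in the pipeline
ever turns an NA back into a number.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = ["BinnedTrack", "make_bins"]


def make_bins(chrom_lengths: Mapping[str, int], bin_size: int) -> pd.DataFrame:
    """Tile chromosomes into half-open bins of ``bin_size`` bases.

    The terminal bin of each chromosome is truncated to the chromosome end.
    """
    if bin_size <= 0:
        raise ValueError(f"bin_size must be positive, got {bin_size}")
    rows = []
    for chrom, length in chrom_lengths.items():
        starts = np.arange(0, length, bin_size, dtype=np.int64)
        ends = np.minimum(starts + bin_size, length)
        rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
    return pd.concat(rows, ignore_index=True)


class BinnedTrack:
    """Ordered genomic bins carrying one float value each (NaN = NA)."""

    def __init__(self, df: pd.DataFrame, validate: bool = True):
        required = ["chrom", "start", "end", "value"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"BinnedTrack frame missing columns: {missing}")
        self.df = df[required].reset_index(drop=True).copy()
        self.df["value"] = self.df["value"].astype(float)
        if validate:
            self._validate()

    def _validate(self) -> None:
        for chrom, sub in self.df.groupby("chrom", sort=False):
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            if np.any(ends <= starts):
                raise ValueError(f"empty or inverted bin on {chrom}")
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"overlapping or unsorted bins on {chrom}")

    # ------------------------------------------------------------------ build
    @classmethod
    def from_values(
        cls,
        chrom_lengths: Mapping[str, int],
        bin_size: int,
        values: Iterable[float],
    ) -> "BinnedTrack":
        grid = make_bins(chrom_lengths, bin_size)
        vals = np.asarray(list(values), dtype=float)
        if len(vals) != len(grid):
            raise ValueError(f"expected {len(grid)} values, got {len(vals)}")
        grid["value"] = vals
        return cls(grid, validate=False)

    def with_values(self, values: np.ndarray) -> "BinnedTrack":
        values = np.asarray(values, dtype=float)
        if len(values) != len(self.df):
            raise ValueError("value vector length does not match bin count")
        out = self.df.copy()
        out["value"] = values
        return BinnedTrack(out, validate=False)

    # ------------------------------------------------------------- accessors
    @property
    def values(self) -> np.ndarray:
        return self.df["value"].to_numpy()

    @property
    def chroms(self) -> list[str]:
        return list(dict.fromkeys(self.df["chrom"]))

    def __len__(self) -> int:
        return len(self.df)

    def same_grid(self, other: "BinnedTrack") -> bool:
        a, b = self.df, other.df
        return (
            len(a) == len(b)
            and (a["chrom"].to_numpy() == b["chrom"].to_numpy()).all()
            and (a["start"].to_numpy() == b["start"].to_numpy()).all()
            and (a["end"].to_numpy() == b["end"].to_numpy()).all()
        )

    def require_same_grid(self, other: "BinnedTrack", what: str = "track") -> None:
        if not self.same_grid(other):
            raise ValueError(f"{what}: bin grids do not match")

    def chrom_view(self, chrom: str) -> pd.DataFrame:
        return self.df[self.df["chrom"] == chrom]

    def overlap_mask(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Boolean mask of bins overlapping [start, end) on ``chrom``."""
        d = self.df
        return (
            (d["chrom"] == chrom) & (d["start"] < end) & (d["end"] > start)
        ).to_numpy()

    # ---------------------------------------------------------------- file IO
    def to_bedgraph(self, path) -> None:
        """Write 4-column BedGraph; NA bins are written with value ``NA``."""
        out = self.df.copy()
        out["value"] = out["value"].map(lambda v: "NA" if np.isnan(v) else repr(v))
        with open(path, "w") as fh:
            fh.write("# bedGraph, 0-based half-open coordinates\n")
            out.to_csv(fh, sep="\t", header=False, index=False)

    @classmethod
    def from_bedgraph(cls, path) -> "BinnedTrack":
        df = pd.read_csv(
            path,
            sep="\t",
            comment="#",
            names=["chrom", "start", "end", "value"],
            na_values=["NA"],
            dtype={"chrom": str},
        )
        return cls(df)
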