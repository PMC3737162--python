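"""Synthetic genome with known copy-number, LOH and insertion truth."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..tracks import BinnedTrack, make_bins
from .config import SimulationConfig

__all__ = ["SyntheticGenome", "generate_genome", "compute_mappability"]

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = np.zeros(256, dtype=np.uint8)
for a, b in zip(b"ACGT", b"TGCA"):
    _COMP[a] = b


@dataclass
class SyntheticGenome:
    chromosomes: list[tuple[str, str]]  # (name, sequence)
    truth_cn: BinnedTrack  # integer CN per bin
    truth_loh: list[tuple[str, int, int]]
    truth_insertions: list[tuple[str, int, str, str]]  # chrom, pos, virus, family
    virus_contigs: list[tuple[str, str, int]] = field(default_factory=list)
    bin_size: int = 10_000

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.chromosomes}

    @property
    def sequences(self) -> dict[str, str]:
        return dict(self.chromosomes)

    def gc_track(self, bin_size: int | None = None) -> BinnedTrack:
        """Per-bin GC fraction of the simulated sequence."""
        bin_size = bin_size or self.bin_size
        grid = make_bins(self.chrom_lengths, bin_size)
        values = []
        for name, seq in self.chromosomes:
            arr = np.frombuffer(seq.encode(), dtype=np.uint8)
            is_gc = (arr == ord("G")) | (arr == ord("C"))
            for start in range(0, len(seq), bin_size):
                window = is_gc[start : start + bin_size]
                values.append(window.mean())
        grid["value"] = values
        return BinnedTrack(grid, validate=False)


def _piecewise_cn(n_bins: int, config: SimulationConfig, rng) -> np.ndarray:
    states = np.array(sorted(config.cn_prior))
    probs = np.array([config.cn_prior[s] for s in states], dtype=float)
    probs = probs / probs.sum()
    out = np.empty(n_bins, dtype=int)
    i = 0
    while i < n_bins:
        length = max(
            config.cn_segment_min_bins, int(rng.geometric(1.0 / config.cn_segment_mean_bins))
        )
        # adjacent same-CN draws simply merge into a longer segment, which
        # keeps the marginal bin distribution equal to the prior
        cn = int(rng.choice(states, p=probs))
        out[i : i + length] = cn
        i += length
    return out


def generate_genome(config: SimulationConfig) -> SyntheticGenome:
    """Simulate sequence plus CN / LOH / insertion truth tracks.

    Sequence composition varies by 10-kb window (GC drawn around
    ``gc_mean``) so GC bias has something to act on.  CN truth is piecewise
    constant with the prior's mode at 3; LOH blocks are placed
    deterministically on one chromosome; insertion sites are drawn far
    apart so their read clusters stay disjoint.
    """
    config.validate()
    rng = config.rng(1)
    chroms: list[tuple[str, str]] = []
    cn_values: list[np.ndarray] = []
    window = 10_000
    for c in range(config.n_chromosomes):
        name = f"chr{c + 1}"
        parts = []
        for start in range(0, config.chrom_length, window):
            w = min(window, config.chrom_length - start)
            gc = float(np.clip(rng.normal(config.gc_mean, config.gc_sd), 0.2, 0.8))
            p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
            parts.append(rng.choice(BASES, size=w, p=p).tobytes().decode())
        seq = "".join(parts)
        chroms.append((name, seq))
        n_bins = int(np.ceil(len(seq) / config.bin_size))
        cn_values.append(_piecewise_cn(n_bins, config, rng))

    truth_cn = BinnedTrack.from_values(
        {name: len(seq) for name, seq in chroms},
        config.bin_size,
        np.concatenate(cn_values),
    )

    # LOH blocks: deterministic, non-overlapping, on one chromosome
    loh: list[tuple[str, int, int]] = []
    loh_chrom = chroms[config.loh_chrom_index][0]
    loh_len = len(chroms[config.loh_chrom_index][1])
    cursor = config.loh_first_start
    for size in config.loh_block_sizes:
        if cursor + size > loh_len:
            break
        loh.append((loh_chrom, cursor, cursor + size))
        cursor += size + config.loh_gap

    # virus insertion sites, spread far apart
    insertions: list[tuple[str, int, str, str]] = []
    if config.n_insertions > 0 and config.viruses:
        min_dist = 50_000
        attempts = 0
        while len(insertions) < config.n_insertions and attempts < 1000:
            attempts += 1
            ci = int(rng.integers(0, len(chroms)))
            name, seq = chroms[ci]
            pos = int(rng.integers(1000, len(seq) - 1000))
            if any(c == name and abs(p - pos) < min_dist for c, p, _, _ in insertions):
                continue
            virus = config.viruses[len(insertions) % len(config.viruses)]
            insertions.append((name, pos, virus[0], virus[1]))

    return SyntheticGenome(
        chromosomes=chroms,
        truth_cn=truth_cn,
        truth_loh=loh,
        truth_insertions=insertions,
        virus_contigs=list(config.viruses),
        bin_size=config.bin_size,
    )


_CODE = np.zeros(256, dtype=np.uint64)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i

# 2-bit polynomial hash modulo the Mersenne prime 2^61 - 1; the reduction
# needs only shifts and adds, which matters at genome scale
_MERSENNE = np.uint64((1 << 61) - 1)
_TWO = np.uint64(2)
_SIXTYONE = np.uint64(61)


def _kmer_hashes(codes: np.ndarray, k: int) -> np.ndarray:
    """Polynomial hash (base 4, mod 2^61 - 1) of every k-mer."""
    n = len(codes) - k + 1
    h = np.zeros(n, dtype=np.uint64)
    for j in range(k):
        h = (h << _TWO) + codes[j : j + n]  # bounded by 2^63
        h = (h & _MERSENNE) + (h >> _SIXTYONE)
    h = (h & _MERSENNE) + (h >> _SIXTYONE)
    h[h >= _MERSENNE] -= _MERSENNE
    return h


def _unique_start_masks(genome: SyntheticGenome, k: int) -> dict[str, np.ndarray]:
    """Per-chromosome boolean mask: True where the forward k-mer starting at
    that position occurs exactly once over both strands of the genome.

    The census hashes every k-mer of both strands (memory-light even for
    tens of megabases) and then verifies hash-duplicate groups at the byte
    level, so the result is exact: hash collisions cannot create false
    duplicates, and true duplicates always share a hash.
    """
    strands: list[np.ndarray] = []  # byte arrays, fwd and rc per chromosome
    fwd_slices: dict[str, slice] = {}
    seg_bounds = [0]
    hashes = []
    for name, seq in genome.chromosomes:
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        rc = _COMP[arr][::-1].copy()
        n = len(arr) - k + 1
        for strand_arr in (arr, rc):
            strands.append(strand_arr)
            hashes.append(_kmer_hashes(_CODE[strand_arr], k))
            seg_bounds.append(seg_bounds[-1] + n)
        fwd_slices[name] = slice(seg_bounds[-3], seg_bounds[-2])
    keys = np.concatenate(hashes)
    del hashes
    _, inverse, counts = np.unique(keys, return_inverse=True, return_counts=True)
    unique_here = counts[inverse] == 1

    # byte-verify hash-duplicate groups: a member is truly unique iff its
    # actual k-mer occurs once within its (hash-defined) group
    flagged = np.where(~unique_here)[0]
    if len(flagged):
        seg_starts = np.array(seg_bounds[:-1])
        seg_idx = np.searchsorted(seg_bounds, flagged, side="right") - 1
        kmers = np.empty((len(flagged), k), dtype=np.uint8)
        for row, (pos, seg) in enumerate(zip(flagged, seg_idx)):
            local = pos - seg_starts[seg]
            kmers[row] = strands[seg][local : local + k]
        records = np.ascontiguousarray(kmers).view(f"V{k}").ravel()
        _, r_inverse, r_counts = np.unique(records, return_inverse=True, return_counts=True)
        unique_here[flagged[r_counts[r_inverse] == 1]] = True
    return {name: unique_here[sl] for name, sl in fwd_slices.items()}


def compute_mappability(genome: SyntheticGenome, read_length: int = 101) -> BinnedTrack:
    """Per-bin fraction of uniquely mappable read-start positions.

    A position is mappable iff its ``read_length``-mer occurs exactly once
    among all k-mers of both strands of the whole genome (a read from that
    position has exactly one valid alignment).  Exact brute-force census —
    intended for the small genomes this simulator produces.
    """
    if read_length <= 0:
        raise ValueError(f"read_length must be positive, got {read_length}")
    shortest = min(len(seq) for _, seq in genome.chromosomes)
    if read_length > shortest:
        raise ValueError(
            f"read_length {read_length} exceeds shortest chromosome ({shortest})"
        )
    masks = _unique_start_masks(genome, read_length)
    grid = make_bins(genome.chrom_lengths, genome.bin_size)
    values = []
    for name, seq in genome.chromosomes:
        unique_mask = masks[name]
        for start in range(0, len(seq), genome.bin_size):
            stop = min(start + genome.bin_size, len(seq))
            sub = unique_mask[start : min(stop, len(unique_mask))]
            values.append(sub.mean() if len(sub) else 0.0)
    grid["value"] = values
    return BinnedTrack(grid, validate=False)


def mappable_positions(genome: SyntheticGenome, read_length: int) -> dict[str, np.ndarray]:
    """Boolean per-position mappability (read-start positions only)."""
    return _unique_start_masks(genome, read_length)
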