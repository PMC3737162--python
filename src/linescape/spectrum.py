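"""Trinucleotide-context mutational spectra.

SNVs are classified into the six pyrimidine-based substitution types
(C>A, C>G, C>T, T>A, T>C, T>G) together with the preceding and following
base, giving a 4 x 4 x 6 count matrix.  Calls whose reference base is a
purine are mapped to the pyrimidine strand by reverse complement (flanks
swap and complement).  Counts are normalized by the genomic frequency of
each source triplet and rescaled to percentages so call sets of different
sizes are comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .variants import SnvRecord

__all__ = [
    "SpectrumMatrix",
    "MUTATION_TYPES",
    "build_spectrum",
    "genome_triplet_frequencies",
    "collapse_types",
    "coverage_filter",
    "stratified_spectra",
]

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
MUTATION_TYPES = ["C>A", "C>G", "C>T", "T>A", "T>C", "T>G"]
TYPE_INDEX = {t: i for i, t in enumerate(MUTATION_TYPES)}
PYRIMIDINES = "CT"


@dataclass
class SpectrumMatrix:
    """4 x 4 x 6 matrix indexed (preceding base, following base, type)."""

    counts: np.ndarray
    triplet_freqs: np.ndarray  # 4 x 4 x 2 source-triplet frequencies (C, T center)
    normalized: Optional[np.ndarray] = None
    n_skipped_edge: int = 0
    n_skipped_ambiguous: int = 0
    ref_mismatches: list = field(default_factory=list)

    def normalize(self) -> np.ndarray:
        """Divide counts by source-triplet frequency, rescale to sum 100."""
        if self.counts.sum() == 0:
            raise ValueError("cannot normalize an empty spectrum (zero counts)")
        freq = np.empty_like(self.counts)
        freq[:, :, :3] = self.triplet_freqs[:, :, 0:1]  # C-centered types
        freq[:, :, 3:] = self.triplet_freqs[:, :, 1:2]  # T-centered types
        with np.errstate(divide="ignore", invalid="ignore"):
            rate = np.where(freq > 0, self.counts / freq, 0.0)
        self.normalized = 100.0 * rate / rate.sum()
        return self.normalized

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, pre in enumerate(BASES):
            for j, fol in enumerate(BASES):
                for k, typ in enumerate(MUTATION_TYPES):
                    rows.append(
                        {
                            "context": f"{pre}[{typ[0]}]{fol}",
                            "type": typ,
                            "count": int(self.counts[i, j, k]),
                            "normalized_percent": (
                                float(self.normalized[i, j, k])
                                if self.normalized is not None
                                else np.nan
                            ),
                        }
                    )
        return pd.DataFrame(rows)


def _pyrimidine_context(ref: str, alt: str, pre: str, fol: str):
    """Map a mutation with flanks onto the pyrimidine strand.

    Returns (preceding, following, type) or None if any base is ambiguous.
    """
    for b in (ref, alt, pre, fol):
        if b not in BASE_INDEX:
            return None
    if ref in PYRIMIDINES:
        return pre, fol, f"{ref}>{alt}"
    # purine reference: reverse complement the triplet and the substitution
    return COMPLEMENT[fol], COMPLEMENT[pre], f"{COMPLEMENT[ref]}>{COMPLEMENT[alt]}"


def genome_triplet_frequencies(reference: Mapping[str, str]) -> np.ndarray:
    """Pyrimidine-centered source-triplet frequencies of a genome.

    Returns a 4 x 4 x 2 array of (preceding, following, center in {C, T})
    relative frequencies summing to 1; purine-centered triplets contribute
    via their reverse complement.
    """
    counts = np.zeros((4, 4, 2))
    for seq in reference.values():
        s = seq.upper()
        for i in range(1, len(s) - 1):
            pre, center, fol = s[i - 1], s[i], s[i + 1]
            if center not in BASE_INDEX or pre not in BASE_INDEX or fol not in BASE_INDEX:
                continue
            if center in PYRIMIDINES:
                p, f, c = pre, fol, center
            else:
                p, f, c = COMPLEMENT[fol], COMPLEMENT[pre], COMPLEMENT[center]
            counts[BASE_INDEX[p], BASE_INDEX[f], 0 if c == "C" else 1] += 1
    total = counts.sum()
    if total == 0:
        raise ValueError("reference contains no unambiguous triplets")
    return counts / total


def build_spectrum(
    snvs: list[SnvRecord],
    reference: Mapping[str, str],
    triplet_freqs: Optional[np.ndarray] = None,
) -> SpectrumMatrix:
    """Tally SNVs into the context matrix and normalize.

    Chromosome-edge SNVs (missing flank) and ambiguous-base contexts are
    skipped and counted; reference-base mismatches are collected into
    ``ref_mismatches`` rather than silently tallied.
    """
    if triplet_freqs is None:
        triplet_freqs = genome_triplet_frequencies(reference)
    spec = SpectrumMatrix(counts=np.zeros((4, 4, 6)), triplet_freqs=triplet_freqs)
    for s in snvs:
        seq = reference.get(s.chrom)
        if seq is None:
            spec.ref_mismatches.append((s.chrom, s.pos, "unknown chromosome"))
            continue
        i = s.pos - 1  # 0-based
        if i < 1 or i >= len(seq) - 1:
            spec.n_skipped_edge += 1
            continue
        if seq[i].upper() != s.ref.upper():
            spec.ref_mismatches.append((s.chrom, s.pos, seq[i]))
            continue
        ctx = _pyrimidine_context(
            s.ref.upper(), s.alt.upper(), seq[i - 1].upper(), seq[i + 1].upper()
        )
        if ctx is None:
            spec.n_skipped_ambiguous += 1
            continue
        pre, fol, typ = ctx
        spec.counts[BASE_INDEX[pre], BASE_INDEX[fol], TYPE_INDEX[typ]] += 1
    spec.normalize()
    return spec


def collapse_types(matrix: SpectrumMatrix) -> dict[str, float]:
    """Sum the normalized matrix over contexts: six percentages, total 100."""
    if matrix.normalized is None:
        matrix.normalize()
    sums = matrix.normalized.sum(axis=(0, 1))
    return {t: float(sums[k]) for k, t in enumerate(MUTATION_TYPES)}


def coverage_filter(
    snvs: list[SnvRecord], low: int = 10, high: int = 60
) -> tuple[list[SnvRecord], float, int]:
    """Keep SNVs with local coverage in [low, high] (bounds inclusive).

    Returns (kept, retained fraction among records with coverage, number of
    records dropped for missing coverage).  Empty input gives fraction NaN.
    """
    kept: list[SnvRecord] = []
    n_missing = 0
    n_with_cov = 0
    for s in snvs:
        if s.local_coverage is None:
            n_missing += 1
            continue
        n_with_cov += 1
        if low <= s.local_coverage <= high:
            kept.append(s)
    fraction = len(kept) / n_with_cov if n_with_cov else float("nan")
    return kept, fraction, n_missing


def stratified_spectra(
    snvs: list[SnvRecord],
    reference: Mapping[str, str],
    coverage_breaks: Sequence[int],
) -> list[tuple[str, Optional[SpectrumMatrix], int]]:
    """One spectrum per local-coverage stratum.

    Breaks [b1, b2, ...] define strata <b1, [b1, b2], ..., >bk matching the
    inclusive-bounds convention of :func:`coverage_filter`.  Strata with no
    SNVs yield a None matrix (normalization needs counts).
    """
    breaks = list(coverage_breaks)
    if any(b2 <= b1 for b1, b2 in zip(breaks, breaks[1:])):
        raise ValueError("coverage breaks must be strictly increasing")
    labels = [f"<{breaks[0]}"]
    for b1, b2 in zip(breaks, breaks[1:]):
        labels.append(f"{b1}-{b2}")
    labels.append(f">{breaks[-1]}")

    def stratum_of(cov: int) -> int:
        if cov < breaks[0]:
            return 0
        for idx, (b1, b2) in enumerate(zip(breaks, breaks[1:])):
            if b1 <= cov <= b2:
                return idx + 1
        return len(labels) - 1

    groups: list[list[SnvRecord]] = [[] for _ in labels]
    for s in snvs:
        if s.local_coverage is None:
            continue
        groups[stratum_of(s.local_coverage)].append(s)
    freqs = genome_triplet_frequencies(reference)
    out = []
    for label, group in zip(labels, groups):
        matrix = build_spectrum(group, reference, freqs) if group else None
        out.append((label, matrix, len(group)))
    return out
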