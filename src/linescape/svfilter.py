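"""Structural-variant filtering cascade.

Externally produced SV calls (deletions, tandem duplications, inversions,
translocations) are filtered with the rules used for cell-line call sets:

* drop calls seen in more than 0.5% of a population panel (coordinate
  overlap defines call equivalence) or in designated germline samples;
* require paired-end support >= 2 and split-read support with the consensus
  aligning at >= 90% identity;
* remove both members of any same-type pair with >= 10% reciprocal overlap;
* drop deletions overlapping SINE or LINE repeats;
* require inversions to have paired-end support on both sides;
* call a deletion homozygous iff the median per-bin coverage over its
  interval is below 1.

Every dropped call is logged with exactly one primary reason code.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .tracks import BinnedTrack

__all__ = [
    "SvCall",
    "filter_panel_common",
    "filter_quality",
    "filter_callset",
    "annotate_deletion_zygosity",
]

SV_TYPES = {"deletion", "duplication", "inversion", "translocation"}
MAX_PANEL_FREQUENCY = 0.005
MIN_PE_SUPPORT = 2
MIN_SPLIT_READ_SUPPORT = 1
MIN_SPLIT_READ_IDENTITY = 90.0
MIN_RECIPROCAL_OVERLAP = 0.10
HOMOZYGOUS_MEDIAN_COVERAGE = 1.0


@dataclass
class SvCall:
    call_id: str
    type: str
    chrom_a: str
    pos_a: int
    chrom_b: str
    pos_b: int
    pe_support: int
    split_read_support: int
    split_read_identity: float  # percent
    sides_supported: str = "both"  # "one" | "both"
    repeat_overlap: str = "none"  # "none" | "SINE" | "LINE" | "other"
    panel_frequency: float = 0.0
    in_germline: bool = False
    zygosity: Optional[str] = None

    def __post_init__(self):
        if self.type not in SV_TYPES:
            raise ValueError(f"unknown SV type {self.type!r}")
        if not 0.0 <= self.split_read_identity <= 100.0:
            raise ValueError("split_read_identity must be in [0, 100]")
        if not 0.0 <= self.panel_frequency <= 1.0:
            raise ValueError("panel_frequency must be in [0, 1]")
        if self.chrom_a == self.chrom_b and self.pos_b < self.pos_a:
            self.pos_a, self.pos_b = self.pos_b, self.pos_a

    @property
    def is_intrachromosomal(self) -> bool:
        return self.chrom_a == self.chrom_b

    @property
    def interval(self) -> tuple[str, int, int]:
        if not self.is_intrachromosomal:
            raise ValueError("translocation has no spanned interval")
        return self.chrom_a, self.pos_a, self.pos_b


@dataclass
class DropLog:
    entries: list[tuple[str, str]] = field(default_factory=list)

    def add(self, call: SvCall, reason: str) -> None:
        self.entries.append((call.call_id, reason))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["call_id", "reason"])


def filter_panel_common(
    calls: list[SvCall],
    panel_calls: Optional[list[SvCall]] = None,
    max_freq: float = MAX_PANEL_FREQUENCY,
    drop_log: Optional[DropLog] = None,
) -> tuple[list[SvCall], DropLog]:
    """Drop calls common in the population panel or present in germline.

    When ``panel_calls`` is given, any coordinate overlap with a same-type
    panel call transfers that call's frequency (maximum over matches);
    otherwise each call's own ``panel_frequency`` field is used.  The
    boundary is inclusive: frequency <= max_freq survives ("present in at
    most 0.5%").
    """
    log = drop_log if drop_log is not None else DropLog()
    kept: list[SvCall] = []
    for call in calls:
        freq = call.panel_frequency
        if panel_calls:
            for p in panel_calls:
                if p.type != call.type:
                    continue
                if _coordinates_overlap(call, p):
                    freq = max(freq, p.panel_frequency)
            call.panel_frequency = freq
        if call.in_germline:
            log.add(call, "germline")
        elif freq > max_freq:
            log.add(call, "common")
        else:
            kept.append(call)
    return kept, log


def _coordinates_overlap(a: SvCall, b: SvCall) -> bool:
    if a.is_intrachromosomal and b.is_intrachromosomal:
        return a.chrom_a == b.chrom_a and a.pos_a < b.pos_b and b.pos_a < a.pos_b
    # breakend proximity for interchromosomal events
    return (
        a.chrom_a == b.chrom_a
        and a.chrom_b == b.chrom_b
        and abs(a.pos_a - b.pos_a) < 1000
        and abs(a.pos_b - b.pos_b) < 1000
    )


def _reciprocal_overlap(a: SvCall, b: SvCall) -> float:
    """min(overlap/len_a, overlap/len_b); 0 unless same chromosome."""
    if a.chrom_a != b.chrom_a:
        return 0.0
    ov = min(a.pos_b, b.pos_b) - max(a.pos_a, b.pos_a)
    if ov <= 0:
        return 0.0
    la = max(a.pos_b - a.pos_a, 1)
    lb = max(b.pos_b - b.pos_a, 1)
    return min(ov / la, ov / lb)


def filter_quality(
    calls: list[SvCall],
    keep_best: bool = False,
    drop_log: Optional[DropLog] = None,
) -> tuple[list[SvCall], DropLog]:
    """Support, identity, repeat, inversion-side and reciprocal-overlap rules.

    The reciprocal-overlap rule runs last, on survivors of the per-call
    rules; by default both members of an overlapping same-type pair are
    removed (``keep_best`` retains the member with higher PE support).
    """
    log = drop_log if drop_log is not None else DropLog()
    survivors: list[SvCall] = []
    for call in calls:
        if call.pe_support < MIN_PE_SUPPORT:
            log.add(call, "pe_support")
        elif call.split_read_support < MIN_SPLIT_READ_SUPPORT:
            log.add(call, "split_read")
        elif call.split_read_identity < MIN_SPLIT_READ_IDENTITY:
            log.add(call, "identity")
        elif call.type == "deletion" and call.repeat_overlap in ("SINE", "LINE"):
            log.add(call, "repeat")
        elif call.type == "inversion" and call.sides_supported != "both":
            log.add(call, "one_sided")
        else:
            survivors.append(call)

    # reciprocal-overlap removal among surviving intrachromosomal calls
    to_drop: set[str] = set()
    intra = [c for c in survivors if c.is_intrachromosomal]
    for i, a in enumerate(intra):
        for b in intra[i + 1 :]:
            if a.type != b.type:
                continue
            if _reciprocal_overlap(a, b) >= MIN_RECIPROCAL_OVERLAP:
                if keep_best:
                    worse = b if a.pe_support >= b.pe_support else a
                    to_drop.add(worse.call_id)
                else:
                    to_drop.add(a.call_id)
                    to_drop.add(b.call_id)
    kept = []
    for c in survivors:
        if c.call_id in to_drop:
            log.add(c, "reciprocal_overlap")
        else:
            kept.append(c)
    return kept, log


def filter_callset(
    calls: list[SvCall],
    panel_calls: Optional[list[SvCall]] = None,
    max_freq: float = MAX_PANEL_FREQUENCY,
    keep_best: bool = False,
) -> tuple[list[SvCall], DropLog]:
    """Full cascade: panel/germline filter, then quality filters."""
    log = DropLog()
    kept, _ = filter_panel_common(calls, panel_calls, max_freq, drop_log=log)
    kept, _ = filter_quality(kept, keep_best=keep_best, drop_log=log)
    return kept, log


def annotate_deletion_zygosity(
    deletions: list[SvCall], coverage: BinnedTrack
) -> list[SvCall]:
    """Homozygous iff the median per-bin coverage over the deleted interval
    is strictly below 1; no overlapping bins leaves zygosity NA."""
    for call in deletions:
        if call.type != "deletion":
            continue
        chrom, start, end = call.interval
        mask = coverage.overlap_mask(chrom, start, end)
        vals = coverage.values[mask]
        vals = vals[~np.isnan(vals)]
        if len(vals) == 0:
            call.zygosity = None
            continue
        med = float(np.median(vals))
        call.zygosity = (
            "homozygous" if med < HOMOZYGOUS_MEDIAN_COVERAGE else "heterozygous"
        )
    return deletions


def calls_to_frame(calls: list[SvCall]) -> pd.DataFrame:
    return pd.DataFrame([vars(c) for c in calls])


def calls_from_frame(df: pd.DataFrame) -> list[SvCall]:
    fields = [
        "call_id", "type", "chrom_a", "pos_a", "chrom_b", "pos_b",
        "pe_support", "split_read_support", "split_read_identity",
        "sides_supported", "repeat_overlap", "panel_frequency", "in_germline",
    ]
    calls = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        calls.append(SvCall(**{k: d[k] for k in fields if k in d}))
    return calls
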