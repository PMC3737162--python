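"""Personalized reference construction and coordinate translation.

High-confidence homozygous variants (SNVs, deletions, insertions) are
integrated into a reference sequence to produce a cell-line genome that
keeps chromosome count and names.  Applying the edits induces a block-wise
alignment between the two coordinate systems; the resulting
:class:`CoordinateMap` lifts positions and whole VCF call sets in either
direction.  Positions falling inside deleted (source-only) or inserted
(destination-only) spans are reported as unmapped together with the nearest
mapped coordinates on both sides — lossless and unambiguous.

All internal coordinates are 0-based half-open; VCF positions are converted
at the boundary.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Mapping, Optional, Union

import pandas as pd

__all__ = [
    "Edit",
    "EditPlan",
    "CoordinateMap",
    "Unmapped",
    "apply_edits",
    "lift_position",
    "edits_from_vcf_fields",
]

EDIT_CLASSES = {"snv", "deletion", "insertion"}


@dataclass(frozen=True)
class Edit:
    chrom: str
    start: int  # 0-based, on the source reference
    end: int  # half-open; == start for insertions
    ref: str  # bases removed ("" for insertion)
    alt: str  # bases added ("" for deletion)
    kind: str

    def __post_init__(self):
        if self.kind not in EDIT_CLASSES:
            raise ValueError(f"unknown edit class {self.kind!r}")
        if self.kind == "snv" and not (
            len(self.ref) == 1 and len(self.alt) == 1 and self.end == self.start + 1
        ):
            raise ValueError(f"malformed snv edit at {self.chrom}:{self.start}")
        if self.kind == "deletion" and (self.end <= self.start or self.alt != ""):
            raise ValueError(f"malformed deletion at {self.chrom}:{self.start}")
        if self.kind == "insertion" and (self.end != self.start or self.alt == ""):
            raise ValueError(f"malformed insertion at {self.chrom}:{self.start}")

    @property
    def length_delta(self) -> int:
        return len(self.alt) - len(self.ref)


class EditPlan:
    """Validated, per-chromosome-sorted collection of non-overlapping edits."""

    def __init__(self, edits: list[Edit]):
        self.by_chrom: dict[str, list[Edit]] = {}
        for e in edits:
            self.by_chrom.setdefault(e.chrom, []).append(e)
        for chrom, lst in self.by_chrom.items():
            lst.sort(key=lambda e: (e.start, e.end))
            for a, b in zip(lst, lst[1:]):
                # zero-length insertions at an edited position also conflict
                if b.start < a.end or b.start == a.start:
                    raise ValueError(
                        f"overlapping edits on {chrom}: "
                        f"{a.kind}@{a.start}-{a.end} vs {b.kind}@{b.start}-{b.end}"
                    )

    def validate_against(self, reference: Mapping[str, str]) -> None:
        for chrom, lst in self.by_chrom.items():
            seq = reference.get(chrom)
            if seq is None:
                raise ValueError(f"edit plan references unknown chromosome {chrom}")
            for e in lst:
                observed = seq[e.start : e.end]
                if observed.upper() != e.ref.upper():
                    raise ValueError(
                        f"ref mismatch at {chrom}:{e.start}: plan says "
                        f"{e.ref!r}, reference has {observed!r}"
                    )

    def __iter__(self):
        for lst in self.by_chrom.values():
            yield from lst


@dataclass
class Unmapped:
    """A position with no image in the other coordinate system.

    ``left_flank``/``right_flank`` are the nearest mapped coordinates in the
    target system on each side (None at a chromosome boundary).
    """

    left_flank: Optional[int]
    right_flank: Optional[int]


@dataclass
class ChromMap:
    src_len: int
    dst_len: int
    # equal-length aligned blocks (src_start, src_end, dst_start, dst_end)
    blocks: list[tuple[int, int, int, int]] = field(default_factory=list)
    # deleted source spans (src_start, src_end, dst_point)
    deletions: list[tuple[int, int, int]] = field(default_factory=list)
    # inserted destination spans (src_point, dst_start, dst_end)
    insertions: list[tuple[int, int, int]] = field(default_factory=list)


class CoordinateMap:
    def __init__(self, chrom_maps: dict[str, ChromMap]):
        self.chrom_maps = chrom_maps

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for chrom, cm in self.chrom_maps.items():
            for ss, se, ds, de in cm.blocks:
                rows.append((chrom, ss, se, ds, de, "match"))
            for ss, se, d in cm.deletions:
                rows.append((chrom, ss, se, d, d, "deletion"))
            for s, ds, de in cm.insertions:
                rows.append((chrom, s, s, ds, de, "insertion"))
        df = pd.DataFrame(
            rows, columns=["chrom", "src_start", "src_end", "dst_start", "dst_end", "class"]
        )
        return df.sort_values(["chrom", "src_start", "dst_start"]).reset_index(drop=True)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CoordinateMap":
        maps: dict[str, ChromMap] = {}
        for chrom, sub in df.groupby("chrom", sort=False):
            cm = ChromMap(src_len=0, dst_len=0)
            for row in sub.to_dict("records"):
                if row["class"] == "match":
                    cm.blocks.append(
                        (row["src_start"], row["src_end"], row["dst_start"], row["dst_end"])
                    )
                elif row["class"] == "deletion":
                    cm.deletions.append((row["src_start"], row["src_end"], row["dst_start"]))
                else:
                    cm.insertions.append((row["src_start"], row["dst_start"], row["dst_end"]))
            cm.blocks.sort()
            cm.src_len = max([b[1] for b in cm.blocks] + [d[1] for d in cm.deletions])
            cm.dst_len = max([b[3] for b in cm.blocks] + [i[2] for i in cm.insertions])
            maps[chrom] = cm
        return cls(maps)


def apply_edits(
    reference: Mapping[str, str], plan: EditPlan
) -> tuple[dict[str, str], CoordinateMap, dict]:
    """Apply a validated edit plan left-to-right; returns the modified
    sequences, the induced coordinate map, and a per-class report."""
    plan.validate_against(reference)
    out_seqs: dict[str, str] = {}
    maps: dict[str, ChromMap] = {}
    report = {"snv": 0, "deletion": 0, "insertion": 0, "length_delta": {}}
    for chrom, seq in reference.items():
        edits = plan.by_chrom.get(chrom, [])
        pieces: list[str] = []
        cm = ChromMap(src_len=len(seq), dst_len=0)
        block_src0 = 0  # start of the open aligned block
        block_dst0 = 0
        copied_to = 0  # source bases already emitted
        dst_pos = 0
        for e in edits:
            pieces.append(seq[copied_to : e.start])
            dst_pos += e.start - copied_to
            if e.kind == "snv":
                pieces.append(e.alt)
                dst_pos += 1
                copied_to = e.end
                report["snv"] += 1
                continue
            # indel: close the open aligned block
            if e.start > block_src0:
                cm.blocks.append((block_src0, e.start, block_dst0, dst_pos))
            if e.kind == "deletion":
                cm.deletions.append((e.start, e.end, dst_pos))
                copied_to = e.end
                report["deletion"] += 1
            else:
                cm.insertions.append((e.start, dst_pos, dst_pos + len(e.alt)))
                pieces.append(e.alt)
                dst_pos += len(e.alt)
                copied_to = e.start
                report["insertion"] += 1
            block_src0 = copied_to
            block_dst0 = dst_pos
        pieces.append(seq[copied_to:])
        dst_pos += len(seq) - copied_to
        if len(seq) > block_src0:
            cm.blocks.append((block_src0, len(seq), block_dst0, dst_pos))
        new_seq = "".join(pieces)
        cm.dst_len = len(new_seq)
        delta = sum(e.length_delta for e in edits)
        assert len(new_seq) == len(seq) + delta, "length accounting failed"
        report["length_delta"][chrom] = delta
        out_seqs[chrom] = new_seq
        maps[chrom] = cm
    return out_seqs, CoordinateMap(maps), report


def lift_position(
    pos: tuple[str, int],
    cmap: CoordinateMap,
    direction: str = "src2dst",
) -> Union[int, Unmapped]:
    """Translate one 0-based position between coordinate systems.

    Returns the translated coordinate, or :class:`Unmapped` with flanking
    mapped coordinates when the position lies in a deleted span (src2dst)
    or an inserted span (dst2src).
    """
    chrom, p = pos
    if chrom not in cmap.chrom_maps:
        raise KeyError(f"chromosome {chrom} not in coordinate map")
    cm = cmap.chrom_maps[chrom]
    if direction == "src2dst":
        length, lo_idx, hi_idx, out_len = cm.src_len, 0, 1, cm.dst_len
        gaps = [(ds, de, dp) for (ds, de, dp) in cm.deletions]
    elif direction == "dst2src":
        length, lo_idx, hi_idx, out_len = cm.dst_len, 2, 3, cm.src_len
        gaps = [(ds, de, sp) for (sp, ds, de) in cm.insertions]
    else:
        raise ValueError("direction must be 'src2dst' or 'dst2src'")
    if not 0 <= p < length:
        raise IndexError(f"{chrom}:{p} beyond chromosome end ({length})")
    blocks = sorted(cm.blocks, key=lambda b: b[lo_idx])
    starts = [b[lo_idx] for b in blocks]
    i = bisect.bisect_right(starts, p) - 1
    if i >= 0:
        b = blocks[i]
        if b[lo_idx] <= p < b[hi_idx]:
            return b[(lo_idx + 2) % 4] + (p - b[lo_idx])
    for gs, ge, other_point in gaps:
        if gs <= p < ge:
            left = other_point - 1 if other_point > 0 else None
            right = other_point if other_point < out_len else None
            return Unmapped(left_flank=left, right_flank=right)
    raise AssertionError(f"position {chrom}:{p} covered by neither block nor gap")


def translate_variants(
    records: list,
    cmap: CoordinateMap,
    direction: str = "src2dst",
    dest_sequences: Optional[Mapping[str, str]] = None,
) -> tuple[list, list, list]:
    """Lift VCF-style records (1-based ``pos``) between coordinate systems.

    Returns (translated sorted records, unmapped records, ref-mismatch
    records).  Records are shallow-copied with the new position.
    """
    import copy

    translated, unmapped, mismatched = [], [], []
    for rec in records:
        result = lift_position((rec.chrom, rec.pos - 1), cmap, direction)
        if isinstance(result, Unmapped):
            unmapped.append((rec, result))
            continue
        new = copy.copy(rec)
        new.pos = result + 1
        if dest_sequences is not None:
            seq = dest_sequences.get(rec.chrom, "")
            if result >= len(seq) or seq[result].upper() != rec.ref.upper():
                mismatched.append(new)
                continue
        translated.append(new)
    translated.sort(key=lambda r: (r.chrom, r.pos))
    return translated, unmapped, mismatched


def edits_from_vcf_fields(
    chrom: str, pos: int, ref: str, alt: str
) -> Edit:
    """Convert one VCF (1-based, anchor-base indel convention) record to an
    internal edit.

    SNV: lengths 1/1.  Deletion ``REF=ACG ALT=A``: bases after the anchor
    are deleted.  Insertion ``REF=A ALT=ACG``: bases are inserted after the
    anchor.  Other allele shapes are rejected.
    """
    if len(ref) == 1 and len(alt) == 1:
        return Edit(chrom, pos - 1, pos, ref, alt, "snv")
    if len(ref) > 1 and len(alt) == 1 and ref[0].upper() == alt[0].upper():
        return Edit(chrom, pos, pos + len(ref) - 1, ref[1:], "", "deletion")
    if len(alt) > 1 and len(ref) == 1 and ref[0].upper() == alt[0].upper():
        return Edit(chrom, pos, pos, "", alt[1:], "insertion")
    raise ValueError(
        f"unsupported allele shape at {chrom}:{pos} ({ref}>{alt}); "
        "only simple SNVs and anchor-base indels are integrable"
    )
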