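"""Synthetic SV call sets with per-rule truth labels.

Each generated call either satisfies every filtering rule ("keep") or
violates exactly one ("drop", with the violated rule as its truth reason),
so the filter cascade can be checked call-by-call.  Boundary calls sit
exactly on the documented thresholds (panel frequency 0.5%, identity 90%,
reciprocal overlap 10%, median interval coverage 1.0).  A companion
coverage track makes designated deletions homozygous (median interval
coverage below 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..svfilter import SvCall
from ..tracks import BinnedTrack, make_bins
from .config import SimulationConfig

__all__ = ["SvSim", "simulate_sv_callset"]

_TYPES = ["deletion", "duplication", "inversion", "translocation"]


@dataclass
class SvSim:
    calls: list[SvCall]
    truth_labels: dict[str, str]  # call_id -> "keep" | "drop"
    truth_reasons: dict[str, str]  # dropped call_id -> rule violated
    truth_zygosity: dict[str, str]  # deletion call_id -> hom/het truth
    coverage: BinnedTrack
    overlap_pairs: list[tuple[str, str]] = field(default_factory=list)


def _clean_kwargs(rng, call_id, slot_start, sv_type) -> dict:
    length = int(rng.integers(5_000, 20_000))
    inter = sv_type == "translocation"
    return dict(
        call_id=call_id,
        type=sv_type,
        chrom_a="chr1",
        pos_a=slot_start,
        chrom_b="chr2" if inter else "chr1",
        pos_b=int(rng.integers(0, 10**6)) if inter else slot_start + length,
        pe_support=int(rng.integers(2, 30)),
        split_read_support=int(rng.integers(1, 10)),
        split_read_identity=float(rng.uniform(90.0, 100.0)),
        sides_supported="both",
        repeat_overlap="none",
        panel_frequency=float(rng.choice([0.0, 0.002, 0.005])),
        in_germline=False,
    )


def simulate_sv_callset(config: SimulationConfig, n_calls: int = 200) -> SvSim:
    """Build ``n_calls`` SV calls with known keep/drop truth.

    Calls are laid out on disjoint 100-kb slots of a virtual chromosome so
    that no unintended reciprocal overlaps arise; designed overlapping
    pairs share a slot.
    """
    rng = config.rng(6)
    calls: list[SvCall] = []
    labels: dict[str, str] = {}
    reasons: dict[str, str] = {}
    zygosity: dict[str, str] = {}
    overlap_pairs: list[tuple[str, str]] = []
    hom_intervals: list[tuple[int, int]] = []

    # drop-rule schedule: (rule, how many calls violate it)
    schedule = [
        ("keep", n_calls - 62),
        ("common", 10),
        ("germline", 6),
        ("pe_support", 10),
        ("split_read", 8),
        ("identity", 10),
        ("repeat", 8),
        ("one_sided", 6),
        ("reciprocal_overlap", 4),  # generated as overlapping pairs
    ]
    slot = 0
    cid = 0

    def next_id():
        nonlocal cid
        cid += 1
        return f"sv{cid:04d}"

    for rule, count in schedule:
        made = 0
        while made < count:
            call_id = next_id()
            slot_start = 50_000 + slot * 100_000
            slot += 1
            sv_type = _TYPES[cid % 4]
            if rule == "repeat":
                sv_type = "deletion"
            elif rule == "one_sided":
                sv_type = "inversion"
            elif rule == "reciprocal_overlap":
                sv_type = "duplication"
            kw = _clean_kwargs(rng, call_id, slot_start, sv_type)
            if rule == "keep":
                if made == 0:
                    kw["panel_frequency"] = 0.005  # boundary: kept
                if made == 1:
                    kw["split_read_identity"] = 90.0  # boundary: kept
                call = SvCall(**kw)
                calls.append(call)
                labels[call_id] = "keep"
                if sv_type == "deletion":
                    hom = made % 3 == 0
                    zygosity[call_id] = "homozygous" if hom else "heterozygous"
                    if hom:
                        hom_intervals.append((kw["pos_a"], kw["pos_b"]))
            elif rule == "common":
                kw["panel_frequency"] = float(rng.uniform(0.006, 0.3))
                calls.append(SvCall(**kw))
                labels[call_id], reasons[call_id] = "drop", "common"
            elif rule == "germline":
                kw["in_germline"] = True
                calls.append(SvCall(**kw))
                labels[call_id], reasons[call_id] = "drop", "germline"
            elif rule == "pe_support":
                kw["pe_support"] = int(rng.integers(0, 2))
                calls.append(SvCall(**kw))
                labels[call_id], reasons[call_id] = "drop", "pe_support"
            elif rule == "split_read":
                kw["split_read_support"] = 0
                calls.append(SvCall(**kw))
                labels[call_id], reasons[call_id] = "drop", "split_read"
            elif rule == "identity":
                kw["split_read_identity"] = float(rng.uniform(50.0, 89.9))
                calls.append(SvCall(**kw))
                labels[call_id], reasons[call_id] = "drop", "identity"
            elif rule == "repeat":
                kw["repeat_overlap"] = "SINE" if made % 2 == 0 else "LINE"
                calls.append(SvCall(**kw))
                labels[call_id], reasons[call_id] = "drop", "repeat"
            elif rule == "one_sided":
                kw["sides_supported"] = "one"
                calls.append(SvCall(**kw))
                labels[call_id], reasons[call_id] = "drop", "one_sided"
            elif rule == "reciprocal_overlap":
                # a pair sharing one slot; second of the pair overlaps the
                # first by exactly 10% at the boundary, more otherwise
                partner_id = next_id()
                kw["pos_a"], kw["pos_b"] = slot_start, slot_start + 10_000
                a = SvCall(**kw)
                frac = 0.10 if made == 0 else float(rng.uniform(0.2, 0.9))
                ov = int(10_000 * frac)
                kw2 = _clean_kwargs(rng, partner_id, slot_start, "duplication")
                kw2["pos_a"] = slot_start + 10_000 - ov
                kw2["pos_b"] = kw2["pos_a"] + 10_000
                b = SvCall(**kw2)
                calls.extend([a, b])
                for c in (a, b):
                    labels[c.call_id] = "drop"
                    reasons[c.call_id] = "reciprocal_overlap"
                overlap_pairs.append((a.call_id, b.call_id))
                made += 1  # the pair counts as two violations
            made += 1

    # coverage over the spanned chromosome: ~CN-2 depth everywhere except
    # homozygous-deletion intervals, where it drops below 1
    span = 50_000 + slot * 100_000 + 50_000
    grid_len = {"chr1": span}
    track = make_bins(grid_len, 1000)
    vals = np.full(len(track), 40.0)
    starts = track["start"].to_numpy()
    for s, e in hom_intervals:
        vals[(starts >= s) & (starts < e)] = 0.3
    track["value"] = vals
    coverage = BinnedTrack(track, validate=False)
    return SvSim(
        calls=calls,
        truth_labels=labels,
        truth_reasons=reasons,
        truth_zygosity=zygosity,
        coverage=coverage,
        overlap_pairs=overlap_pairs,
    )
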