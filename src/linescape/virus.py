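"""Viral integration detection from chimeric read pairs.

A read pair with one mate on a host chromosome and the other on a viral
contig is evidence of an integration.  Host-side intervals of such pairs
are clustered by single linkage — intervals merge when they overlap or lie
within ``max_gap`` bases — either per virus or per virus family (related
viral genomes cross-attract reads, so family-level clustering recovers
sites whose support is split across similar references).  Clusters with
fewer than ``min_support`` pairs are discarded: a lone chimeric pair is
indistinguishable from a mapping artifact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import pandas as pd

__all__ = ["ChimericPair", "InsertionCluster", "find_chimeric_pairs", "cluster_insertions"]


@dataclass
class ChimericPair:
    pair_id: str
    host_chrom: str
    host_start: int
    host_end: int
    host_strand: str
    virus_name: str
    virus_start: int
    virus_end: int
    family: Optional[str] = None


@dataclass
class InsertionCluster:
    host_chrom: str
    start: int
    end: int
    support: int
    viruses: list[str]
    family: Optional[str]
    level: str  # "virus" | "family"
    pair_ids: list[str] = field(default_factory=list)


def find_chimeric_pairs(
    pairs: pd.DataFrame,
    host_contigs: set[str],
    virus_contigs: set[str],
    families: Optional[Mapping[str, str]] = None,
) -> tuple[list[ChimericPair], dict[str, int]]:
    """Retain pairs with exactly one mate on host and one on virus.

    ``pairs`` columns: pair_id, ref1, pos1, strand1, ref2, pos2, strand2,
    and optionally read_length (default 101).  Pairs on unknown contigs
    raise; both-host and both-virus pairs are discarded and counted.
    """
    if host_contigs & virus_contigs:
        raise ValueError("host and virus contig sets must be disjoint")
    unknown = (
        set(pairs["ref1"]).union(pairs["ref2"]) - host_contigs - virus_contigs
    )
    if unknown:
        raise ValueError(f"read pairs on unknown contigs: {sorted(unknown)}")
    read_len = (
        pairs["read_length"] if "read_length" in pairs.columns else pd.Series(101, index=pairs.index)
    )
    chimeric: list[ChimericPair] = []
    discarded = {"host_host": 0, "virus_virus": 0}
    for row, rl in zip(pairs.itertuples(index=False), read_len):
        in_host1 = row.ref1 in host_contigs
        in_host2 = row.ref2 in host_contigs
        if in_host1 == in_host2:
            discarded["host_host" if in_host1 else "virus_virus"] += 1
            continue
        if in_host1:
            h_ref, h_pos, h_str = row.ref1, row.pos1, row.strand1
            v_ref, v_pos = row.ref2, row.pos2
        else:
            h_ref, h_pos, h_str = row.ref2, row.pos2, row.strand2
            v_ref, v_pos = row.ref1, row.pos1
        chimeric.append(
            ChimericPair(
                pair_id=str(row.pair_id),
                host_chrom=h_ref,
                host_start=int(h_pos),
                host_end=int(h_pos) + int(rl),
                host_strand=str(h_str),
                virus_name=v_ref,
                virus_start=int(v_pos),
                virus_end=int(v_pos) + int(rl),
                family=families.get(v_ref) if families else None,
            )
        )
    return chimeric, discarded


def cluster_insertions(
    chimeric: list[ChimericPair],
    max_gap: int = 1000,
    min_support: int = 2,
    family_level: bool = False,
    families: Optional[Mapping[str, str]] = None,
) -> tuple[list[InsertionCluster], list[InsertionCluster]]:
    """Single-linkage clustering of host-side intervals.

    At virus level, members must share the viral contig; at family level,
    the family.  Returns (clusters meeting ``min_support``, sub-threshold
    clusters) so discarded candidates remain inspectable.
    """
    level = "family" if family_level else "virus"
    if family_level:
        fam_of: dict[str, str] = dict(families or {})
        for p in chimeric:
            if p.family is not None:
                fam_of.setdefault(p.virus_name, p.family)
        missing = {p.virus_name for p in chimeric if p.virus_name not in fam_of}
        if missing:
            raise ValueError(f"no family annotation for viruses: {sorted(missing)}")
        key = lambda p: (p.host_chrom, fam_of[p.virus_name])
    else:
        key = lambda p: (p.host_chrom, p.virus_name)

    groups: dict[tuple, list[ChimericPair]] = {}
    for p in chimeric:
        groups.setdefault(key(p), []).append(p)

    kept: list[InsertionCluster] = []
    dropped: list[InsertionCluster] = []
    for (chrom, label), members in sorted(groups.items()):
        members.sort(key=lambda p: p.host_start)
        current: list[ChimericPair] = []
        runs: list[list[ChimericPair]] = []
        end = None
        for p in members:
            if current and p.host_start <= end + max_gap:
                current.append(p)
                end = max(end, p.host_end)
            else:
                if current:
                    runs.append(current)
                current = [p]
                end = p.host_end
        if current:
            runs.append(current)
        for run in runs:
            cluster = InsertionCluster(
                host_chrom=chrom,
                start=min(p.host_start for p in run),
                end=max(p.host_end for p in run),
                support=len(run),
                viruses=sorted({p.virus_name for p in run}),
                family=label if family_level else run[0].family,
                level=level,
                pair_ids=[p.pair_id for p in run],
            )
            (kept if cluster.support >= min_support else dropped).append(cluster)
    return kept, dropped


def clusters_to_frame(clusters: list[InsertionCluster]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "host_chrom": [c.host_chrom for c in clusters],
            "start": [c.start for c in clusters],
            "end": [c.end for c in clusters],
            "support": [c.support for c in clusters],
            "viruses": [",".join(c.viruses) for c in clusters],
            "family": [c.family for c in clusters],
            "level": [c.level for c in clusters],
        }
    )
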