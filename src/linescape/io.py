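"""File-format helpers shared by the CLI and the analysis drivers."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import pandas as pd


def read_fasta(path) -> dict[str, str]:
    from pyfaidx import Fasta

    with Fasta(str(path)) as fa:
        return {name: str(fa[name][:]) for name in fa.keys()}


def write_fasta(sequences: Mapping[str, str], path, width: int = 70) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    seqio_write(records, str(path), "fasta")


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)


def parse_region(text: str) -> tuple[str, int, int]:
    """Parse 'chrom:start-end' (1-based inclusive, as printed in headers)
    into 0-based half-open coordinates."""
    chrom, _, span = text.partition(":")
    start_s, _, end_s = span.partition("-")
    start = int(start_s.replace(",", "")) - 1
    end = int(end_s.replace(",", ""))
    if not chrom or start < 0 or end <= start:
        raise ValueError(f"malformed region {text!r}; expected chrom:start-end")
    return chrom, start, end
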