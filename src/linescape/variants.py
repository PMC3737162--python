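"""SNV records and VCF input/output.

The pipeline's exchange unit for small variants is :class:`SnvRecord`, a
position with ref/alt alleles, a zygosity class, and optional DNA/RNA allele
depths and local coverage.  On disk this is VCF 4.2 with 1-based positions;
internally positions stay 1-based as well (the VCF convention), while every
binned track and edit plan uses 0-based half-open coordinates — conversions
happen only at the module boundaries that need them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import pysam

__all__ = ["SnvRecord", "read_vcf", "write_vcf"]

# allele-fraction fallback when a VCF record carries no genotype call
HOM_AF_THRESHOLD = 0.9


@dataclass
class SnvRecord:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    zygosity: str  # "hom" | "het"
    dna_allele_depths: Optional[tuple[int, int]] = None  # (ref, alt)
    local_coverage: Optional[int] = None
    rna_allele_depths: Optional[tuple[int, int]] = None

    def __post_init__(self):
        if self.zygosity not in ("hom", "het"):
            raise ValueError(f"zygosity must be 'hom' or 'het', got {self.zygosity!r}")
        for depths in (self.dna_allele_depths, self.rna_allele_depths):
            if depths is not None and (depths[0] < 0 or depths[1] < 0):
                raise ValueError("allele depths must be non-negative")


def _zygosity_from_record(rec) -> Optional[str]:
    """hom for 1/1-type genotypes, het for 0/1-type; AD fallback without GT."""
    if rec.samples:
        sample = rec.samples[0]
        gt = sample.get("GT")
        if gt is not None and any(a is not None for a in gt):
            alleles = [a for a in gt if a is not None]
            return "hom" if all(a == 1 for a in alleles) else "het"
    ad = None
    if rec.samples:
        ad = rec.samples[0].get("AD")
    if ad is not None and sum(ad) > 0:
        af = ad[1] / (ad[0] + ad[1])
        return "hom" if af >= HOM_AF_THRESHOLD else "het"
    return None


def read_vcf(path) -> list[SnvRecord]:
    """Read SNVs (single-base ref and alt) from a VCF file."""
    out: list[SnvRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if len(rec.ref) != 1 or rec.alts is None or len(rec.alts[0]) != 1:
                continue
            zyg = _zygosity_from_record(rec)
            if zyg is None:
                continue
            ad = rec.samples[0].get("AD") if rec.samples else None
            if ad is not None and (len(ad) < 2 or any(a is None for a in ad)):
                ad = None  # '.' placeholder
            dp = rec.samples[0].get("DP") if rec.samples else None
            out.append(
                SnvRecord(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=rec.alts[0],
                    zygosity=zyg,
                    dna_allele_depths=tuple(ad[:2]) if ad is not None else None,
                    local_coverage=int(dp) if dp is not None else None,
                )
            )
    return out


def write_vcf(records: Iterable[SnvRecord], path, contig_lengths: dict[str, int]) -> None:
    """Write SNVs as minimal single-sample VCF 4.2 (GT, AD, DP)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=linescape\n")
        for chrom, length in contig_lengths.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">\n'
        )
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsample\n")
        for r in records:
            gt = "1/1" if r.zygosity == "hom" else "0/1"
            ad = r.dna_allele_depths
            dp = r.local_coverage
            if dp is None and ad is not None:
                dp = ad[0] + ad[1]
            ad_s = f"{ad[0]},{ad[1]}" if ad is not None else "."
            dp_s = str(dp) if dp is not None else "."
            fh.write(
                f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\tPASS\t.\t"
                f"GT:AD:DP\t{gt}:{ad_s}:{dp_s}\n"
            )
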