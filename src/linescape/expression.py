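"""Expression quantification, CN–expression dependence, allele-specific
dosage compensation, and outlier detection against a tissue panel.

Expression is proxied by reads per kilobase of gene after median-of-ratios
size-factor normalization; log10 of that value is the working scale.  A
cell line's expression is compared with a reference panel (16 tissues in
the emulated design) through per-gene z-scores on variance-stabilized
values, z = (x - mean) / sd, with z > 3 flagging overexpression and a mean
below 1 count per kilobase flagging a gene as not expressed.  At
heterozygous sites in copy-number-3 regions, the RNA higher:lower allele
ratio tests allele-specific dosage compensation: 2:1 means both remaining
alleles are transcribed proportionally, 1:1 or 2:0 would indicate silencing
of specific copies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AllelicSite",
    "size_factors",
    "expression_per_kb",
    "expression_by_cn",
    "allelic_ratio_cn3",
    "panel_zscores",
]


@dataclass
class AllelicSite:
    chrom: str
    pos: int
    rna_ref_count: int
    rna_alt_count: int
    region_cn: int

    @property
    def higher(self) -> int:
        return max(self.rna_ref_count, self.rna_alt_count)

    @property
    def lower(self) -> int:
        return min(self.rna_ref_count, self.rna_alt_count)


def size_factors(counts: pd.DataFrame, allow_pseudo_reference: bool = False) -> pd.Series:
    """Median-of-ratios size factors (genes x samples count matrix).

    The reference is the per-gene geometric mean across samples; each
    sample's factor is the median ratio of its counts to that reference over
    genes expressed in every sample.  ``allow_pseudo_reference`` falls back
    to the geometric mean over positive entries when no gene is expressed
    everywhere.
    """
    mat = counts.to_numpy(dtype=float)
    all_pos = (mat > 0).all(axis=1)
    if all_pos.any():
        ref = np.exp(np.log(mat[all_pos]).mean(axis=1))
        sub = mat[all_pos]
    elif allow_pseudo_reference:
        pos = mat > 0
        with np.errstate(divide="ignore"):
            logs = np.where(pos, np.log(np.maximum(mat, 1e-300)), np.nan)
        ref = np.exp(np.nanmean(logs, axis=1))
        keep = ~np.isnan(ref) & (ref > 0)
        ref, sub = ref[keep], mat[keep]
    else:
        raise ValueError(
            "no gene has nonzero counts in all samples; "
            "set allow_pseudo_reference=True to use a positive-entry reference"
        )
    factors = np.median(sub / ref[:, None], axis=0)
    if (factors <= 0).any():
        raise ValueError("non-positive size factor; counts too sparse")
    return pd.Series(factors, index=counts.columns, name="size_factor")


def expression_per_kb(
    counts: pd.Series | pd.DataFrame,
    lengths_bp: pd.Series,
    factors: Optional[pd.Series] = None,
) -> pd.DataFrame:
    """Normalized counts per kilobase of gene, with the log10 proxy.

    Returns a frame with columns ``per_kb`` and ``log10_per_kb`` (NaN where
    the value is zero) for a Series, or the per-kb matrix for a DataFrame.
    """
    if (lengths_bp <= 0).any():
        bad = lengths_bp.index[lengths_bp <= 0][0]
        raise ValueError(f"gene {bad} has non-positive length")
    if isinstance(counts, pd.DataFrame):
        norm = counts.div(factors, axis=1) if factors is not None else counts
        return norm.div(lengths_bp / 1000.0, axis=0)
    norm = counts / (factors if factors is not None else 1.0)
    per_kb = norm / (lengths_bp / 1000.0)
    with np.errstate(divide="ignore"):
        log10 = np.where(per_kb > 0, np.log10(per_kb), np.nan)
    return pd.DataFrame({"per_kb": per_kb, "log10_per_kb": log10})


def _ecdf(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.sort(values)
    return x, np.arange(1, len(x) + 1) / len(x)


def expression_by_cn(
    per_gene_log10: pd.Series,
    gene_cn: pd.Series,
    min_group: int = 10,
) -> tuple[dict[int, tuple[np.ndarray, np.ndarray]], pd.DataFrame]:
    """ECDF of log10 expression per CN group plus adjacent-pair rank tests.

    Two-sided Wilcoxon rank-sum (Mann-Whitney) p-values compare each pair
    of adjacent CN groups; groups below ``min_group`` expressed genes are
    skipped.  Returns ({cn: (x, F)}, test table).
    """
    df = pd.DataFrame({"v": per_gene_log10, "cn": gene_cn}).dropna()
    groups = {
        int(cn): sub["v"].to_numpy()
        for cn, sub in df.groupby("cn")
        if len(sub) >= min_group
    }
    ecdfs = {cn: _ecdf(v) for cn, v in groups.items()}
    cns = sorted(groups)
    rows = []
    for a, b in zip(cns, cns[1:]):
        na, nb = len(groups[a]), len(groups[b])
        method = "exact" if min(na, nb) < 20 else "asymptotic"
        try:
            res = stats.mannwhitneyu(
                groups[a], groups[b], alternative="two-sided", method=method
            )
            p = float(res.pvalue)
        except ValueError:  # exact method refuses ties
            res = stats.mannwhitneyu(
                groups[a], groups[b], alternative="two-sided", method="asymptotic"
            )
            p = float(res.pvalue)
        rows.append({"cn_low": a, "cn_high": b, "n_low": na, "n_high": nb, "pvalue": p})
    return ecdfs, pd.DataFrame(rows)


def allelic_ratio_cn3(
    sites: Sequence[AllelicSite],
    min_total: int = 10,
    n_boot: int = 10_000,
    seed: int = 0,
) -> dict:
    """Higher-allele fraction summary at heterozygous CN-3 sites.

    Per site: higher / (higher + lower).  Reports the median with a seeded
    95% bootstrap CI and the distances of the median to 2/3 (no
    compensation: both copies of the duplicated allele transcribed) and to
    1/2 (allele-specific silencing of the extra copy).
    """
    fracs = np.array(
        [
            s.higher / (s.higher + s.lower)
            for s in sites
            if s.region_cn == 3 and (s.higher + s.lower) >= min_total
        ]
    )
    if len(fracs) == 0:
        return {"n_sites": 0}
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(fracs), size=(n_boot, len(fracs)))
    boot_medians = np.median(fracs[idx], axis=1)
    lo, hi = np.quantile(boot_medians, [0.025, 0.975])
    med = float(np.median(fracs))
    return {
        "n_sites": int(len(fracs)),
        "median_higher_fraction": med,
        "ci95": (float(lo), float(hi)),
        "distance_to_2_3": abs(med - 2.0 / 3.0),
        "distance_to_1_2": abs(med - 0.5),
        "fractions": fracs,
    }


def panel_zscores(
    counts: pd.DataFrame,
    lengths_bp: pd.Series,
    sample_roles: pd.Series,
    z_cutoff: float = 3.0,
    low_cutoff: float = 1.0,
    normalize_low_rule: bool = True,
) -> pd.DataFrame:
    """Per-gene z-scores of cell-line expression against the panel.

    ``sample_roles`` maps each column of ``counts`` to ``panel`` or
    ``cellline_replicate``.  Values are size-factor normalized and variance
    stabilized as log2(normalized + 1); the panel yields the per-gene mean
    and SD (n-1 denominator), the replicates their mean x, and
    z = (x - mean) / sd.  Status: ``overexpressed`` if z > z_cutoff,
    ``non_expressed`` if the replicates' mean normalized counts/kb is below
    ``low_cutoff``, ``indeterminate`` where the panel SD is zero, else
    ``within_range``.
    """
    roles = sample_roles.reindex(counts.columns)
    if roles.isna().any():
        missing = list(counts.columns[roles.isna()])
        raise ValueError(f"samples without role labels: {missing}")
    panel_cols = list(roles.index[roles == "panel"])
    rep_cols = list(roles.index[roles == "cellline_replicate"])
    if len(panel_cols) < 2 or not rep_cols:
        raise ValueError("need >= 2 panel samples and >= 1 cell-line replicate")
    factors = size_factors(counts, allow_pseudo_reference=True)
    norm = counts.div(factors, axis=1)
    stab = np.log2(norm + 1.0)
    mu = stab[panel_cols].mean(axis=1)
    sigma = stab[panel_cols].std(axis=1, ddof=1)
    x = stab[rep_cols].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (x - mu) / sigma
    z = z.where(sigma > 0)
    rep_counts = norm[rep_cols] if normalize_low_rule else counts[rep_cols]
    per_kb = rep_counts.div(lengths_bp / 1000.0, axis=0).mean(axis=1)
    status = np.where(
        sigma == 0,
        "indeterminate",
        np.where(
            z > z_cutoff,
            "overexpressed",
            np.where(per_kb < low_cutoff, "non_expressed", "within_range"),
        ),
    )
    return pd.DataFrame(
        {
            "panel_mean": mu,
            "panel_sd": sigma,
            "x": x,
            "z": z,
            "replicate_counts_per_kb": per_kb,
            "status": status,
        }
    )
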