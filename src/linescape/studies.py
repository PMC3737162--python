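"""End-to-end study runs on synthetic data with known ground truth.

Each function simulates one dataset under the study conditions, runs the
relevant pipeline stage(s), and returns the measured quantities together
with the problem size.  The analysis drivers and the acceptance machinery
are thin callers of these functions, so every reported number is
recomputed from scratch on each run.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from . import cn as cn_mod
from .expression import allelic_ratio_cn3, panel_zscores
from .loh import bin_homozygosity, segment_zygosity
from .refbuild import Edit, EditPlan, Unmapped, apply_edits, lift_position
from .simulate import (
    SimulationConfig,
    generate_genome,
    simulate_chimeric_pairs,
    simulate_coverage,
    simulate_expression_counts,
    simulate_rna_allele_counts,
    simulate_snvs,
    simulate_sv_callset,
)
from .spectrum import build_spectrum, collapse_types
from .svfilter import annotate_deletion_zygosity, filter_callset
from .variants import SnvRecord
from .virus import cluster_insertions, find_chimeric_pairs

# CN states 1..5 with the hypotriploid shape, for the read-depth chain study
CN_CHAIN_PRIOR = {1: 0.06, 2: 0.20, 3: 0.50, 4: 0.16, 5: 0.08}


def find_truth_cn_region(truth_df, cn_target: int, min_bins: int = 10):
    """Longest truth run of a CN state, as a calibration region."""
    best, best_len = None, 0
    for chrom in truth_df["chrom"].unique():
        sub = truth_df[truth_df["chrom"] == chrom].reset_index(drop=True)
        v = sub["value"].to_numpy()
        i = 0
        while i < len(v):
            j = i
            while j < len(v) and v[j] == cn_target:
                j += 1
            if j > i and j - i > best_len:
                best_len = j - i
                best = (chrom, int(sub["start"][i]), int(sub["end"][j - 1]))
            i = j if j > i else i + 1
    return (best, best_len) if best_len >= min_bins else (None, 0)


def study_cn_chain(seed: int, dispersion: float | None) -> dict:
    """Full read-depth CN chain vs truth on a 2 x 5 Mb genome, CN 1..5.

    Calibration uses the longest truth CN-2 run (falling back to CN 3
    with rescaling if the drawn genome lacks a long CN-2 region).
    Returns bin-level concordance overall and restricted to called
    segments of at least 5 bins.
    """
    config = SimulationConfig(
        seed=seed,
        n_chromosomes=2,
        chrom_length=5_000_000,
        cn_prior=CN_CHAIN_PRIOR,
        noise_dispersion=dispersion,
    )
    genome = generate_genome(config)
    coverage = simulate_coverage(genome, config)
    gc = genome.gc_track()
    mappability = coverage.with_values(np.ones(len(coverage)))
    region, _ = find_truth_cn_region(genome.truth_cn.df, 2)
    region_cn = 2
    if region is None:
        region, _ = find_truth_cn_region(genome.truth_cn.df, 3)
        region_cn = 3
    segments, model, _ = cn_mod.call_copy_number(
        coverage, gc, mappability, region, calibration_cn=region_cn, seed=0
    )
    bin_size = config.bin_size
    assigned: dict = {}
    seg_bins: dict = {}
    for s in segments:
        for b in range(s.start // bin_size, s.end // bin_size):
            assigned[(s.chrom, b)] = s.assigned_cn
            seg_bins[(s.chrom, b)] = s.n_bins
    df = genome.truth_cn.df
    truth = {
        (c, st // bin_size): int(v)
        for c, st, v in zip(df["chrom"], df["start"], df["value"])
    }
    n = len(truth)
    correct = sum(1 for k, t in truth.items() if assigned.get(k) == t)
    ge5 = [(k, t) for k, t in truth.items() if seg_bins.get(k, 0) >= 5]
    correct5 = sum(1 for k, t in ge5 if assigned.get(k) == t)
    return {
        "n_bins": n,
        "concordance": correct / n,
        "concordance_ge5": correct5 / max(len(ge5), 1),
        "n_bins_ge5": len(ge5),
        "n_segments": len(segments),
        "x0": model.calibration_x0,
    }


def study_mixture_recovery(seed: int, n: int = 2000) -> dict:
    """EM recovery of known weights (0.6/0.3/0.1 at means 3/2/5, sd 0.1)."""
    rng = np.random.default_rng(seed)
    comps = rng.choice([3.0, 2.0, 5.0], p=[0.6, 0.3, 0.1], size=n)
    data = rng.normal(comps, 0.1)
    segments = [
        cn_mod.CnSegment("c", i, i + 1, mean_log2=np.log2(v) - 1, n_bins=1)
        for i, v in enumerate(data)
    ]
    model = cn_mod.fit_cn_mixture(segments, m=8)
    target_w = {3: 0.6, 2: 0.3, 5: 0.1}
    weight_err = max(abs(model.weights[k - 1] - w) for k, w in target_w.items())
    sd_err = max(abs(model.sds[k - 1] - 0.1) for k in target_w)
    diffs = np.diff(model.loglik_trace)
    return {
        "n": n,
        "max_weight_error": float(weight_err),
        "max_sd_error": float(sd_err),
        "loglik_monotone": bool((diffs >= -1e-6).all()),
    }


def study_classifier_boundary() -> dict:
    """Exact Bayes boundary behavior: midpoint ties give NA, estimates
    below 0.5 give CN 0."""
    model = cn_mod.CnMixtureModel(
        m=8,
        weights=np.array([0.0, 0.5, 0.5, 0.0, 0.0, 0.0, 0.0, 0.0]),
        sds=np.full(8, 0.2),
        loglik=0.0,
    )
    mid = cn_mod.CnSegment("c", 0, 10, mean_log2=np.log2(2.5) - 1, n_bins=5)
    low = cn_mod.CnSegment("c", 10, 20, mean_log2=np.log2(0.3) - 1, n_bins=5)
    cn_mod.assign_copy_number([mid, low], model)
    return {
        "midpoint_posterior": float(mid.posterior),
        "midpoint_assigned_na": mid.assigned_cn is None,
        "low_assigned_cn": low.assigned_cn,
    }


def study_loh(seed: int) -> dict:
    """LOH block recovery on a copy-neutral genome with three truth
    blocks (0.5 / 1 / 2 Mb), plus a heterozygous-rich control."""
    config = SimulationConfig(
        seed=seed,
        n_chromosomes=2,
        chrom_length=10_000_000,
        cn_prior={2: 0.25, 3: 0.50, 4: 0.25},
        loh_block_sizes=(500_000, 1_000_000, 2_000_000),
    )
    genome = generate_genome(config)
    snvs = simulate_snvs(genome, config)
    track = bin_homozygosity(snvs, bin_size=100_000, chrom_lengths=genome.chrom_lengths)
    blocks, fraction = segment_zygosity(track, seed=0)
    hom = [b for b in blocks if b.state == "homozygous"]
    max_offset = np.inf
    if len(hom) == len(genome.truth_loh):
        offsets = []
        for (chrom, start, end), block in zip(genome.truth_loh, hom):
            if block.chrom != chrom:
                offsets.append(np.inf)
                continue
            offsets.append(max(abs(block.start - start), abs(block.end - end)))
        max_offset = max(offsets)
    state_accuracy = float(len(hom) == len(genome.truth_loh) and max_offset < np.inf)

    control_cfg = replace(config, loh_block_sizes=(), seed=seed + 101)
    control = generate_genome(control_cfg)
    c_snvs = simulate_snvs(control, control_cfg)
    c_track = bin_homozygosity(
        c_snvs, bin_size=100_000, chrom_lengths=control.chrom_lengths
    )
    c_blocks, _ = segment_zygosity(c_track, seed=0)
    control_hom = sum(1 for b in c_blocks if b.state == "homozygous")
    return {
        "n_truth_blocks": len(genome.truth_loh),
        "n_recovered_blocks": len(hom),
        "max_boundary_offset_bins": (
            float(max_offset / 100_000) if np.isfinite(max_offset) else float("inf")
        ),
        "state_accuracy": state_accuracy,
        "genome_hom_fraction": fraction,
        "control_hom_blocks": control_hom,
    }


def study_spectrum(seed: int, n_snvs: int = 50_000) -> dict:
    """Spectrum conservation, composition invariance, strand symmetry."""
    rng = np.random.default_rng(seed)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    seq = rng.choice(bases, size=2_000_000).tobytes().decode()
    reference = {"c": seq}
    positions = rng.choice(
        np.arange(2, len(seq) - 1), size=n_snvs, replace=False
    )
    snvs = []
    alt_map = {"A": "CGT", "C": "AGT", "G": "ACT", "T": "ACG"}
    for pos in map(int, np.sort(positions)):
        ref = seq[pos - 1]
        alt = alt_map[ref][rng.integers(0, 3)]
        snvs.append(SnvRecord("c", pos, ref, alt, "het"))
    spec = build_spectrum(snvs, reference)
    six = collapse_types(spec)

    # strand symmetry: reverse complement genome and calls
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    rc_seq = "".join(comp[b] for b in reversed(seq))
    n = len(seq)
    rc_snvs = [
        SnvRecord("c", n - s.pos + 1, comp[s.ref], comp[s.alt], "het") for s in snvs
    ]
    rc_spec = build_spectrum(rc_snvs, {"c": rc_seq})
    strand_exact = bool((spec.counts == rc_spec.counts).all())

    # composition doubling: enrich one source triplet, fixed per-triplet
    # mutation probability; its normalized cell must not move
    from .spectrum import BASE_INDEX, TYPE_INDEX

    cell = (BASE_INDEX["A"], BASE_INDEX["A"], TYPE_INDEX["C>T"])
    bg_cell = (BASE_INDEX["A"], BASE_INDEX["A"], TYPE_INDEX["T>A"])

    def composition_run(n_blocks: int) -> float:
        # the percent normalization couples all cells, so the clean
        # invariant is the rate RATIO against a fixed-rate background
        # cell; every genome-wide ACA occurrence is mutated at the same
        # probability so the per-triplet rate really is fixed
        filler = rng.choice(bases, size=500_000).tobytes().decode()
        s2 = filler + "ACA" * n_blocks
        arr = np.frombuffer(s2.encode(), dtype=np.uint8)
        is_aca = (arr[:-2] == ord("A")) & (arr[1:-1] == ord("C")) & (arr[2:] == ord("A"))
        # the pyrimidine-centered source triplet pools ACA with its
        # reverse-complement image TGT, so both must carry the fixed rate
        is_tgt = (arr[:-2] == ord("T")) & (arr[1:-1] == ord("G")) & (arr[2:] == ord("T"))
        calls = [
            SnvRecord("c", int(p) + 1, "C", "T", "het")
            for p in np.where(is_aca)[0] + 1
            if rng.random() < 0.5
        ] + [
            SnvRecord("c", int(p) + 1, "G", "A", "het")
            for p in np.where(is_tgt)[0] + 1
            if rng.random() < 0.5
        ]
        # background restricted to A/T references: their pyrimidine-strand
        # images are T-centered types, which never leak into the C>T cells
        bg_alt = {"A": "C", "T": "A"}
        for pos in map(int, rng.integers(2, len(filler) - 1, size=120_000)):
            ref = s2[pos - 1]
            if ref in bg_alt:
                calls.append(SnvRecord("c", pos, ref, bg_alt[ref], "het"))
        m = build_spectrum(calls, {"c": s2}).normalized
        return float(m[cell] / m[bg_cell])

    v1 = composition_run(20_000)
    v2 = composition_run(40_000)
    return {
        "n_snvs": n_snvs,
        "normalized_sum": float(spec.normalized.sum()),
        "six_type_sum": float(sum(six.values())),
        "strand_symmetry_exact": strand_exact,
        "composition_rel_change": abs(v2 - v1) / v1,
    }


def study_sv_filter(seed: int, n_calls: int = 200) -> dict:
    """Filter cascade vs per-call truth labels, plus threshold boundaries."""
    config = SimulationConfig(seed=seed)
    sim = simulate_sv_callset(config, n_calls=n_calls)
    kept, log = filter_callset(sim.calls)
    kept_ids = {c.call_id for c in kept}
    agree = sum(
        1
        for cid, label in sim.truth_labels.items()
        if (cid in kept_ids) == (label == "keep")
    )
    dels = [c for c in kept if c.type == "deletion"]
    annotate_deletion_zygosity(dels, sim.coverage)
    zyg_ok = all(c.zygosity == sim.truth_zygosity[c.call_id] for c in dels)

    # boundary: median interval coverage exactly 1.0 -> heterozygous
    from .svfilter import SvCall
    from .tracks import BinnedTrack

    boundary = SvCall("b", "deletion", "chrZ", 0, "chrZ", 10_000, 5, 2, 99.0)
    flat = BinnedTrack.from_values({"chrZ": 10_000}, 1000, [1.0] * 10)
    annotate_deletion_zygosity([boundary], flat)
    return {
        "n_calls": len(sim.calls),
        "label_agreement": agree / len(sim.truth_labels),
        "zygosity_agreement": bool(zyg_ok),
        "coverage_boundary_het": boundary.zygosity == "heterozygous",
        "n_kept": len(kept),
        "n_dropped": len(log.entries),
    }


def study_liftover(seed: int, n_positions: int = 1000) -> dict:
    """Edit application and coordinate round trip on a 10-kb chromosome."""
    rng = np.random.default_rng(seed)
    seq = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=10_000)
    seq = seq.tobytes().decode()
    slots = rng.choice(np.arange(100, 9_800, 60), size=13, replace=False)
    slots.sort()
    edits = []
    del_total = ins_total = 0
    for i, pos in enumerate(map(int, slots)):
        if i < 10:
            alt = "A" if seq[pos] != "A" else "C"
            edits.append(Edit("c", pos, pos + 1, seq[pos], alt, "snv"))
        elif i < 12:
            length = int(rng.integers(3, 30))
            edits.append(Edit("c", pos, pos + length, seq[pos : pos + length], "", "deletion"))
            del_total += length
        else:
            ins = "".join(rng.choice(list("ACGT"), size=12))
            edits.append(Edit("c", pos, pos, "", ins, "insertion"))
            ins_total += len(ins)
    dst, cmap, report = apply_edits({"c": seq}, EditPlan(edits))
    length_error = abs(len(dst["c"]) - (10_000 - del_total + ins_total))

    deleted = set()
    for e in edits:
        if e.kind == "deletion":
            deleted.update(range(e.start, e.end))
    candidates = [int(p) for p in rng.integers(0, 10_000, 3 * n_positions)
                  if int(p) not in deleted][:n_positions]
    mismatches = 0
    for p in candidates:
        fwd = lift_position(("c", p), cmap, "src2dst")
        if isinstance(fwd, Unmapped) or lift_position(("c", fwd), cmap, "dst2src") != p:
            mismatches += 1

    # positions inside a deleted span return UNMAPPED with adjacent flanks
    first_del = next(e for e in edits if e.kind == "deletion")
    inside = lift_position(("c", first_del.start), cmap, "src2dst")
    flanks_ok = (
        isinstance(inside, Unmapped)
        and inside.right_flank == inside.left_flank + 1
    )
    return {
        "n_positions": len(candidates),
        "length_error": int(length_error),
        "roundtrip_mismatches": mismatches,
        "deleted_span_unmapped_with_flanks": bool(flanks_ok),
        "report": report,
    }


def study_allelic_ratio(seed: int, n_sites: int = 1000, depth: float = 50.0) -> dict:
    """Dosage-compensation statistic under 2:1 transcription and under
    allele-specific silencing, at CN-3 heterozygous sites."""
    config = SimulationConfig(
        seed=seed,
        n_chromosomes=1,
        chrom_length=2_000_000,
        cn_prior={3: 1.0},
        loh_block_sizes=(),
        het_snv_rate=2e-3,
        hom_snv_rate=0.0,
        rna_allele_depth=depth,
    )
    genome = generate_genome(config)
    snvs = simulate_snvs(genome, config)
    sites = simulate_rna_allele_counts(snvs, genome, config)[:n_sites]
    out = allelic_ratio_cn3(sites, seed=seed)
    silenced = simulate_rna_allele_counts(
        snvs, genome, config, scenario="silencing"
    )[:n_sites]
    out_sil = allelic_ratio_cn3(silenced, seed=seed)
    lo, hi = out["ci95"]
    slo, shi = out_sil["ci95"]
    return {
        "n_sites": out["n_sites"],
        "median_higher_fraction": out["median_higher_fraction"],
        "ci_low": lo,
        "ci_high": hi,
        "ci_covers_two_thirds": bool(lo <= 2 / 3 <= hi),
        "silencing_ci_excludes_two_thirds": not (slo <= 2 / 3 <= shi),
        "silencing_median": out_sil["median_higher_fraction"],
    }


def study_zscore_pipeline(seed: int, n_genes: int = 10_000) -> dict:
    """Outlier sensitivity and null false-positive rate of the panel
    z-score pipeline at ~n_genes simulated genes.

    The genome is diploid so null genes carry no CN signal; injected
    outliers have true z >= 5.
    """
    # ~5.2 kb per gene+gap: size chromosomes to hold n_genes
    chrom_length = int(n_genes * 5_200 / 2)
    config = SimulationConfig(
        seed=seed,
        n_chromosomes=2,
        chrom_length=chrom_length,
        cn_prior={2: 1.0},
        loh_block_sizes=(),
        n_outlier_genes=50,
        n_silenced_genes=50,
    )
    genome = generate_genome(config)
    sim = simulate_expression_counts(genome, config)
    status = panel_zscores(sim.counts, sim.genes["length_bp"], sim.roles)
    outliers = list(sim.outlier_truth)
    sensitivity = float(
        (status.loc[outliers, "status"] == "overexpressed").mean()
    )
    null_genes = status.index.difference(outliers).difference(sim.silenced_truth)
    null_z = status.loc[null_genes, "z"].dropna()
    fpr = float((null_z > 3).mean())
    exact_zero = float(
        np.nanmax(np.abs((status["x"] - status["panel_mean"]) / status["panel_sd"]
                         - status["z"]))
    )
    return {
        "n_genes": len(status),
        "n_outliers": len(outliers),
        "sensitivity": sensitivity,
        "null_fpr": fpr,
        "z_definition_max_dev": exact_zero,
    }


def study_virus(seed: int) -> dict:
    """Cluster recovery of planted insertions and family-level merging."""
    config = SimulationConfig(seed=seed, n_chromosomes=2, chrom_length=2_000_000)
    genome = generate_genome(config)
    pairs = simulate_chimeric_pairs(genome, config)
    host = set(genome.chrom_lengths)
    vir = {v for v, _, _ in genome.virus_contigs}
    fams = {v: f for v, f, _ in genome.virus_contigs}
    chimeric, discarded = find_chimeric_pairs(pairs, host, vir, fams)
    clusters, _ = cluster_insertions(chimeric, min_support=2)
    loci_ok = 0
    for chrom, pos, virus, _fam in genome.truth_insertions:
        hits = [
            c for c in clusters
            if c.host_chrom == chrom and c.start - 1000 <= pos <= c.end + 1000
            and virus in c.viruses
        ]
        loci_ok += len(hits) == 1

    # two same-family viruses at one locus: one family-level cluster
    from .simulate.genome import SyntheticGenome

    twin = SyntheticGenome(
        chromosomes=genome.chromosomes,
        truth_cn=genome.truth_cn,
        truth_loh=[],
        truth_insertions=[
            ("chr1", 500_000, "virus_alpha", "papillomavirus"),
            ("chr1", 500_200, "virus_beta", "papillomavirus"),
        ],
        virus_contigs=genome.virus_contigs,
        bin_size=genome.bin_size,
    )
    twin_cfg = replace(config, background_pairs=0)
    twin_pairs = simulate_chimeric_pairs(twin, twin_cfg)
    twin_chim, _ = find_chimeric_pairs(twin_pairs, host, vir, fams)
    v_level, _ = cluster_insertions(twin_chim, min_support=2)
    f_level, _ = cluster_insertions(
        twin_chim, min_support=2, family_level=True, families=fams
    )
    return {
        "n_truth_insertions": len(genome.truth_insertions),
        "n_clusters": len(clusters),
        "loci_recovered": loci_ok,
        "n_background_discarded": discarded["host_host"],
        "family_merge_virus_level": len(v_level),
        "family_merge_family_level": len(f_level),
    }
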