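import numpy as np
import pytest

from linescape.refbuild import (
    CoordinateMap,
    Edit,
    EditPlan,
    Unmapped,
    apply_edits,
    edits_from_vcf_fields,
    lift_position,
    translate_variants,
)
from linescape.variants import SnvRecord


def test_snv_edit_substitutes_in_place():
    ref = {"c": "ACGTACGT"}
    plan = EditPlan([Edit("c", 2, 3, "G", "T", "snv")])
    seqs, cmap, report = apply_edits(ref, plan)
    assert seqs["c"] == "ACTTACGT"
    assert report["snv"] == 1 and report["length_delta"]["c"] == 0


def test_deletion_edit_shortens_sequence():
    ref = {"c": "ACGTACGT"}
    plan = EditPlan([Edit("c", 2, 4, "GT", "", "deletion")])
    seqs, cmap, report = apply_edits(ref, plan)
    assert seqs["c"] == "ACACGT"
    assert len(seqs["c"]) == 6


def test_insertion_edit_lengthens_sequence():
    ref = {"c": "ACGT"}
    plan = EditPlan([Edit("c", 2, 2, "", "TTT", "insertion")])
    seqs, _, report = apply_edits(ref, plan)
    assert seqs["c"] == "ACTTTGT"
    assert report["length_delta"]["c"] == 3


def test_length_accounting_on_mixed_plan():
    """10 SNVs + 2 deletions + 1 insertion: dst length must equal
    src - deleted + inserted exactly."""
    rng = np.random.default_rng(0)
    seq = "".join(rng.choice(list("ACGT"), size=10_000))
    ref = {"c": seq}
    edits = []
    positions = rng.choice(np.arange(100, 9_900, 50), size=13, replace=False)
    positions.sort()
    for i, pos in enumerate(map(int, positions)):
        if i < 10:
            alt = "A" if seq[pos] != "A" else "C"
            edits.append(Edit("c", pos, pos + 1, seq[pos], alt, "snv"))
        elif i < 12:
            edits.append(Edit("c", pos, pos + 7, seq[pos : pos + 7], "", "deletion"))
        else:
            edits.append(Edit("c", pos, pos, "", "GATTACA", "insertion"))
    seqs, cmap, report = apply_edits(ref, EditPlan(edits))
    assert len(seqs["c"]) == 10_000 - 14 + 7
    cm = cmap.chrom_maps["c"]
    # block/gap coverage of the destination is exact
    dst_covered = sum(de - ds for _, _, ds, de in cm.blocks) + sum(
        de - ds for _, ds, de in cm.insertions
    )
    assert dst_covered == cm.dst_len


def test_overlapping_edits_rejected_with_pair():
    with pytest.raises(ValueError, match="overlapping"):
        EditPlan(
            [Edit("c", 2, 4, "GT", "", "deletion"), Edit("c", 3, 4, "T", "A", "snv")]
        )


def test_insertion_at_snv_position_rejected():
    with pytest.raises(ValueError, match="overlapping"):
        EditPlan(
            [Edit("c", 2, 3, "G", "T", "snv"), Edit("c", 2, 2, "", "AA", "insertion")]
        )


def test_ref_mismatch_rejected_with_position():
    ref = {"c": "ACGT"}
    plan = EditPlan([Edit("c", 1, 2, "G", "T", "snv")])
    with pytest.raises(ValueError, match="c:1"):
        apply_edits(ref, plan)


# ---------------------------------------------------------------- liftover
def test_identity_plan_is_identity_both_ways():
    ref = {"c": "ACGTACGT"}
    _, cmap, _ = apply_edits(ref, EditPlan([]))
    for p in range(8):
        assert lift_position(("c", p), cmap, "src2dst") == p
        assert lift_position(("c", p), cmap, "dst2src") == p


def test_lift_across_deletion():
    ref = {"c": "ACGTACGT"}
    _, cmap, _ = apply_edits(ref, EditPlan([Edit("c", 2, 4, "GT", "", "deletion")]))
    assert lift_position(("c", 5), cmap, "src2dst") == 3
    result = lift_position(("c", 2), cmap, "src2dst")
    assert isinstance(result, Unmapped)
    assert (result.left_flank, result.right_flank) == (1, 2)


def test_lift_across_insertion():
    ref = {"c": "ACGT"}
    _, cmap, _ = apply_edits(ref, EditPlan([Edit("c", 2, 2, "", "TTT", "insertion")]))
    assert lift_position(("c", 3), cmap, "src2dst") == 6
    back = lift_position(("c", 3), cmap, "dst2src")  # inside inserted span
    assert isinstance(back, Unmapped)
    assert (back.left_flank, back.right_flank) == (1, 2)


def test_lift_out_of_range_and_unknown_chrom():
    ref = {"c": "ACGT"}
    _, cmap, _ = apply_edits(ref, EditPlan([]))
    with pytest.raises(IndexError):
        lift_position(("c", 4), cmap, "src2dst")
    with pytest.raises(KeyError):
        lift_position(("zz", 0), cmap)


def test_round_trip_over_random_positions():
    """1,000 random mappable positions lift src->dst->src to identity."""
    rng = np.random.default_rng(1)
    seq = "".join(rng.choice(list("ACGT"), size=10_000))
    edits = [
        Edit("c", 1000, 1050, seq[1000:1050], "", "deletion"),
        Edit("c", 5000, 5000, "", "TACGA" * 4, "insertion"),
        Edit("c", 7000, 7010, seq[7000:7010], "", "deletion"),
    ]
    _, cmap, _ = apply_edits({"c": seq}, EditPlan(edits))
    deleted = set(range(1000, 1050)) | set(range(7000, 7010))
    positions = [p for p in rng.integers(0, 10_000, 1200) if p not in deleted][:1000]
    assert len(positions) == 1000
    for p in positions:
        fwd = lift_position(("c", int(p)), cmap, "src2dst")
        assert not isinstance(fwd, Unmapped)
        assert lift_position(("c", fwd), cmap, "dst2src") == p


def test_coordinate_map_frame_roundtrip():
    rng = np.random.default_rng(2)
    seq = "".join(rng.choice(list("ACGT"), size=500))
    edits = [
        Edit("c", 100, 120, seq[100:120], "", "deletion"),
        Edit("c", 300, 300, "", "AAAA", "insertion"),
    ]
    _, cmap, _ = apply_edits({"c": seq}, EditPlan(edits))
    back = CoordinateMap.from_frame(cmap.to_frame())
    for p in (0, 50, 150, 299, 400):
        assert lift_position(("c", p), back, "src2dst") == lift_position(
            ("c", p), cmap, "src2dst"
        )


# --------------------------------------------------------- variant translation
def test_translate_variants_routes_and_verifies():
    seq = "ACGTACGTAC"
    edits = [Edit("c", 2, 4, "GT", "", "deletion")]
    dst, cmap, _ = apply_edits({"c": seq}, EditPlan(edits))

    def rec(pos, ref):
        return SnvRecord(chrom="c", pos=pos, ref=ref, alt="T" if ref != "T" else "A",
                         zygosity="hom")

    records = [rec(6, seq[5]), rec(3, seq[2]), rec(1, seq[0])]
    translated, unmapped, mismatched = translate_variants(
        records, cmap, "src2dst", dest_sequences=dst
    )
    assert [r.pos for r in translated] == [1, 4]  # sorted, deletion-shifted
    assert len(unmapped) == 1 and unmapped[0][0].pos == 3
    assert mismatched == []


def test_translate_flags_ref_mismatch():
    seq = "ACGTACGT"
    plan = EditPlan([Edit("c", 4, 5, "A", "G", "snv")])
    dst, cmap, _ = apply_edits({"c": seq}, plan)
    rec = SnvRecord(chrom="c", pos=5, ref="A", alt="C", zygosity="hom")
    translated, unmapped, mismatched = translate_variants(
        [rec], cmap, "src2dst", dest_sequences=dst
    )
    assert translated == [] and len(mismatched) == 1


# ----------------------------------------------------------- VCF conversion
@pytest.mark.parametrize(
    "pos,ref,alt,expected",
    [
        (3, "G", "T", Edit("c", 2, 3, "G", "T", "snv")),
        (2, "CGT", "C", Edit("c", 2, 4, "GT", "", "deletion")),
        (2, "C", "CAA", Edit("c", 2, 2, "", "AA", "insertion")),
    ],
)
def test_vcf_anchor_convention(pos, ref, alt, expected):
    assert edits_from_vcf_fields("c", pos, ref, alt) == expected


def test_vcf_rejects_complex_alleles():
    with pytest.raises(ValueError, match="allele shape"):
        edits_from_vcf_fields("c", 5, "AT", "GC")


def test_validation_idempotence_after_apply():
    """Re-validating lifted edits against the modified genome verifies the
    alt alleles in place."""
    rng = np.random.default_rng(3)
    seq = "".join(rng.choice(list("ACGT"), size=2000))
    edits = [
        Edit("c", 100, 101, seq[100], "A" if seq[100] != "A" else "G", "snv"),
        Edit("c", 500, 510, seq[500:510], "", "deletion"),
    ]
    dst, cmap, _ = apply_edits({"c": seq}, EditPlan(edits))
    lifted_snv_pos = lift_position(("c", 100), cmap, "src2dst")
    assert dst["c"][lifted_snv_pos] == edits[0].alt
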