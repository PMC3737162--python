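"""Call integer copy number from the simulated coverage and compare with
truth.

Reads the binned coverage, GC and mappability tracks from
results/dataset/, runs the full chain (mappability masking, GC
adjustment, log2 calibration against a truth CN-2 region, segmentation,
m=8 fixed-mean mixture, Bayes assignment at posterior >= 0.95), and
writes the segment table, the fitted mixture and the genome-fraction
histogram under results/copy_number/.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import DATASET, RESULTS  # noqa: E402

import pandas as pd  # noqa: E402

from linescape.cn import call_copy_number, cn_histogram, segments_to_frame  # noqa: E402
from linescape.studies import find_truth_cn_region  # noqa: E402
from linescape.tracks import BinnedTrack  # noqa: E402


def run() -> None:
    out = RESULTS / "copy_number"
    out.mkdir(parents=True, exist_ok=True)
    coverage = BinnedTrack.from_bedgraph(DATASET / "coverage.bedgraph")
    gc = BinnedTrack.from_bedgraph(DATASET / "gc.bedgraph")
    mapp = BinnedTrack.from_bedgraph(DATASET / "mappability.bedgraph")
    truth = json.loads((DATASET / "truth.json").read_text())
    truth_df = pd.DataFrame(
        truth["truth_cn"], columns=["chrom", "start", "end", "value"]
    )
    region, n_bins = find_truth_cn_region(truth_df, 2)
    region_cn = 2
    if region is None:
        region, n_bins = find_truth_cn_region(truth_df, 3)
        region_cn = 3
    print(f"calibration region: {region} (truth CN {region_cn}, {n_bins} bins)")
    segments, model, log2_track = call_copy_number(
        coverage, gc, mapp, region, calibration_cn=region_cn, seed=0
    )
    seg_df = segments_to_frame(segments)
    seg_df.to_csv(out / "cn_segments.tsv", sep="\t", index=False)
    (out / "cn_model.json").write_text(json.dumps(model.to_dict(), indent=1))
    hist = cn_histogram(segments)
    (out / "cn_histogram.json").write_text(
        json.dumps({str(k): v for k, v in hist.items()}, indent=1)
    )

    # bin-level concordance against truth
    assigned = {}
    for s in segments:
        for b in range(s.start // 10_000, s.end // 10_000):
            assigned[(s.chrom, b)] = s.assigned_cn
    truth_bins = {
        (c, st // 10_000): int(v)
        for c, st, v in zip(truth_df["chrom"], truth_df["start"], truth_df["value"])
    }
    correct = sum(1 for k, t in truth_bins.items() if assigned.get(k) == t)
    print(f"{len(segments)} segments; mixture x0 = {model.calibration_x0:.2f}")
    print("genome fraction by CN:",
          {k: round(v, 3) for k, v in sorted(hist.items(), key=str)})
    print(f"bin-level concordance with truth: {correct / len(truth_bins):.1%} "
          f"({correct}/{len(truth_bins)} bins)")


if __name__ == "__main__":
    run()
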