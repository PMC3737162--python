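"""Run the SV filtering cascade on the simulated call set and check every
keep/drop decision against the generator's per-call truth labels.

Writes the kept calls, the drop log and a per-rule summary under
results/sv_filter/.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import DATASET, RESULTS  # noqa: E402

import pandas as pd  # noqa: E402

from linescape.svfilter import (  # noqa: E402
    annotate_deletion_zygosity,
    calls_from_frame,
    calls_to_frame,
    filter_callset,
)
from linescape.tracks import BinnedTrack  # noqa: E402


def run() -> None:
    out = RESULTS / "sv_filter"
    out.mkdir(parents=True, exist_ok=True)
    calls = calls_from_frame(pd.read_csv(DATASET / "sv_calls.tsv", sep="\t"))
    coverage = BinnedTrack.from_bedgraph(DATASET / "sv_coverage.bedgraph")
    truth = json.loads((DATASET / "truth.json").read_text())["sv_truth_labels"]

    kept, log = filter_callset(calls)
    dels = [c for c in kept if c.type == "deletion"]
    annotate_deletion_zygosity(dels, coverage)
    calls_to_frame(kept).to_csv(out / "sv_kept.tsv", sep="\t", index=False)
    log.to_frame().to_csv(out / "sv_drop_log.tsv", sep="\t", index=False)
    reasons = log.to_frame()["reason"].value_counts()
    reasons.rename_axis("reason").reset_index(name="count").to_csv(
        out / "drop_reasons.tsv", sep="\t", index=False
    )

    kept_ids = {c.call_id for c in kept}
    agree = sum(
        1 for cid, label in truth.items() if (cid in kept_ids) == (label == "keep")
    )
    hom = sum(1 for c in dels if c.zygosity == "homozygous")
    print(f"kept {len(kept)} / {len(calls)} calls; drops by reason:")
    for reason, count in reasons.items():
        print(f"  {reason}: {count}")
    print(f"truth-label agreement: {agree}/{len(truth)} "
          f"({agree / len(truth):.1%})")
    print(f"deletion zygosity: {hom} homozygous / {len(dels)} kept deletions")


if __name__ == "__main__":
    run()
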