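"""Detect viral integration sites from the simulated chimeric read pairs
and compare the clusters with the planted insertion truth.

Writes virus-level and family-level cluster tables under results/virus/.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import DATASET, RESULTS  # noqa: E402

import pandas as pd  # noqa: E402

from linescape.virus import (  # noqa: E402
    cluster_insertions,
    clusters_to_frame,
    find_chimeric_pairs,
)


def run() -> None:
    out = RESULTS / "virus"
    out.mkdir(parents=True, exist_ok=True)
    pairs = pd.read_csv(DATASET / "read_pairs.tsv", sep="\t")
    contigs = pd.read_csv(DATASET / "contigs.tsv", sep="\t")
    truth = json.loads((DATASET / "truth.json").read_text())["truth_insertions"]

    host = set(contigs.loc[contigs["role"] == "host", "contig"])
    vir = set(contigs.loc[contigs["role"] == "virus", "contig"])
    fams = dict(zip(contigs.loc[contigs["role"] == "virus", "contig"],
                    contigs.loc[contigs["role"] == "virus", "family"]))
    chimeric, discarded = find_chimeric_pairs(pairs, host, vir, fams)
    v_clusters, v_dropped = cluster_insertions(chimeric, min_support=2)
    f_clusters, _ = cluster_insertions(chimeric, min_support=2, family_level=True,
                                       families=fams)
    clusters_to_frame(v_clusters).to_csv(out / "virus_clusters.tsv", sep="\t",
                                         index=False)
    clusters_to_frame(f_clusters).to_csv(out / "family_clusters.tsv", sep="\t",
                                         index=False)

    print(f"{len(pairs)} read pairs: {len(chimeric)} chimeric, "
          f"{discarded['host_host']} host-host discarded")
    print(f"{len(v_clusters)} virus-level clusters "
          f"({len(v_dropped)} below support threshold), "
          f"{len(f_clusters)} family-level")
    for chrom, pos, virus, fam in truth:
        hits = [c for c in v_clusters
                if c.host_chrom == chrom and c.start - 1000 <= pos <= c.end + 1000]
        status = "recovered" if hits else "MISSED"
        print(f"  planted {virus} ({fam}) at {chrom}:{pos}: {status}")


if __name__ == "__main__":
    run()
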