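"""Generate the synthetic cell-line dataset all downstream analyses use.

Writes genome FASTA, coverage/GC/mappability BedGraphs, SNV VCF, SV call
TSV, chimeric read-pair TSV, expression count matrix and truth JSON to
results/dataset/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import DATASET, SEED, study_config  # noqa: E402

from click.testing import CliRunner  # noqa: E402

from linescape.cli import main  # noqa: E402


def run() -> None:
    config = study_config()
    import yaml

    DATASET.mkdir(parents=True, exist_ok=True)
    cfg_path = DATASET / "sim_config.yaml"
    fields = {
        "n_chromosomes": config.n_chromosomes,
        "chrom_length": config.chrom_length,
        "loh_block_sizes": list(config.loh_block_sizes),
        "cn_prior": config.cn_prior,
    }
    cfg_path.write_text(yaml.safe_dump(fields))
    result = CliRunner().invoke(
        main,
        ["simulate", "--config", str(cfg_path), "--outdir", str(DATASET),
         "--seed", str(SEED)],
        catch_exceptions=False,
    )
    print(result.output)
    print(f"dataset written to {DATASET} (seed {SEED})")


if __name__ == "__main__":
    run()
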