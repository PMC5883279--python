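"""Run the full selection + convergence pipeline on a study config."""

import argparse
from pathlib import Path

from chloroselect.pipeline import PipelineConfig, run_pipeline

ap = argparse.ArgumentParser()
ap.add_argument("--config", type=Path,
                default=Path("analysis/output/fixture/config.yaml"))
args = ap.parse_args()

config = PipelineConfig.from_yaml(args.config)
bundle = run_pipeline(config)
print(f"analyzed: {bundle.analyzed}")
print(f"excluded: {bundle.excluded}  filtered: {bundle.filtered}")
print(f"failures: {[g for g, _ in bundle.failures]}")
for fg, genes in bundle.psg.items():
    print(f"positively selected ({fg}): {sorted(genes)}")
print(f"convergence-flagged: {sorted(bundle.convergent_genes)}")
print(f"conservative adaptive genes: {sorted(bundle.conservative_genes)}")
print(f"tables written under {bundle.out_dir}")
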