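"""Write the bundled 6-gene synthetic study (alignments, tree, config)."""

import argparse
from pathlib import Path

from chloroselect.simdata import write_pipeline_fixture

ap = argparse.ArgumentParser()
ap.add_argument("--seed", type=int, default=101)
ap.add_argument("--out", type=Path, default=Path("analysis/output/fixture"))
args = ap.parse_args()

truth = write_pipeline_fixture(args.out, master_seed=args.seed)
print(f"wrote study under {args.out}")
print(f"planted positively selected gene(s): {sorted(truth['psg'])}")
print(f"planted convergent gene(s):          {sorted(truth['convergent'])}")
print(f"planted convergent sites (1-based):  {truth['planted_sites']}")
print(f"config: {truth['config_file']}")
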