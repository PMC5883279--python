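"""Print a short human-readable report from a pipeline summary.json."""

import argparse
import json
from pathlib import Path

ap = argparse.ArgumentParser()
ap.add_argument("--summary", type=Path,
                default=Path("analysis/output/fixture/out/summary.json"))
args = ap.parse_args()

s = json.loads(args.summary.read_text())
print(f"genes analyzed ({len(s['analyzed'])}): {', '.join(s['analyzed'])}")
if s["excluded"]:
    print(f"excluded: {', '.join(s['excluded'])}")
if s["filtered"]:
    print(f"filtered (dS): {', '.join(s['filtered'])}")
if s["failures"]:
    print(f"failed: {', '.join(g for g, _ in s['failures'])}")
for fg, genes in s["psg"].items():
    print(f"positive selection on {fg}: {', '.join(genes) or 'none'}")
print(f"convergence-flagged genes: {', '.join(s['convergent_genes']) or 'none'}")
print("conservative adaptive genes: "
      f"{', '.join(s['conservative_genes']) or 'none'}")
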