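"""Null calibration of the pairwise convergence test (observed vs expected)."""

import argparse

import numpy as np

from chloroselect.convergence import (analyze_pair_convergence,
                                      reconstruct_ancestors)
from chloroselect.simdata import (CONVERGENCE_PAIR, scenario_presets,
                                  simulate_aa_alignment)

ap = argparse.ArgumentParser()
ap.add_argument("--seed", type=int, default=1)
ap.add_argument("--reps", type=int, default=30)
args = ap.parse_args()

rng = np.random.default_rng(args.seed)
obs = exp = 0.0
n_sig = 0
for s in rng.integers(0, 2**31, size=args.reps):
    sc = scenario_presets("convergence_null", seed=int(s))
    aln, _ = simulate_aa_alignment(sc)
    asr = reconstruct_ancestors(aln, sc.tree, model=sc.aa_model)
    res = analyze_pair_convergence(asr, CONVERGENCE_PAIR)
    obs += res.observed_parallel + res.observed_convergent
    exp += res.expected_parallel + res.expected_convergent
    n_sig += res.p_value < 0.05

print(f"pair: {' vs '.join(CONVERGENCE_PAIR)}")
print(f"replicates: {args.reps}")
print(f"total observed: {obs:.0f}   total expected: {exp:.2f}")
print(f"observed/expected ratio: {obs / exp:.3f}")
print(f"replicates with p < 0.05: {n_sig}/{args.reps}")
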