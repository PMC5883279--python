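# Methods

This document describes the statistical machinery implemented in
`chloroselect`. The package tests chloroplast protein-coding genes for
positive selection on designated extremophile lineages and for convergent
amino-acid evolution between extremophile pairs.

## Codon substitution model

Codon evolution follows the Goldman–Yang style model on the 61 sense codons
(universal code; alignments with terminal stop codons are trimmed, internal
stops are rejected). The instantaneous rate from codon *i* to codon *j* is

- 0 if *i* and *j* differ at more than one nucleotide position,
- `pi_j` for a synonymous transversion,
- `kappa * pi_j` for a synonymous transition,
- `omega * pi_j` for a nonsynonymous transversion,
- `omega * kappa * pi_j` for a nonsynonymous transition,

where `pi_j` are the equilibrium codon frequencies and
`omega = dN/dS`. Frequencies default to F3×4: the product of empirical
nucleotide frequencies at the three codon positions, renormalised over
sense codons. The generator is scaled so that the expected number of
substitutions per codon site is one at `t = 1`.

### Site-class mixtures

All fitted models are mixtures of such generators over site classes:

- **M0** — a single `omega` for all sites and branches.
- **Branch (two-ratio)** — one `omega` for background branches, another for
  the tagged foreground branches.
- **M8a / M8** — a proportion `p0` of sites draws `omega` from a discretised
  Beta(p, q) on (0, 1) (10 equal-probability categories represented by their
  medians); the remainder sits at `omega_s = 1` (M8a, the null) or
  `omega_s >= 1` (M8).
- **Branch-site model A** — four classes: (0) `omega0 < 1` everywhere,
  (1) neutral everywhere, (2a) `omega0` background / `omega2` foreground,
  (2b) neutral background / `omega2` foreground, with proportions
  `(p0, p1, p2a, p2b)` tied as `p2a = p0/(p0+p1) * (1-p0-p1)` etc. The null
  fixes `omega2 = 1`; the alternative allows `omega2 >= 1`.

Within a mixture the class generators share one overall scale: each class
matrix is divided by the mixture-average substitution rate (computed
separately for background and foreground branch types), so branch lengths
are expected substitutions per codon averaged over classes, and fast
classes correctly evolve faster than slow ones. Proportion parameters are
optimised in a triangle parameterisation (`a = p0 + p1`,
`b = p0/(p0+p1)`) to keep the simplex constraint implicit.

## Likelihood computation

Likelihoods are computed by Felsenstein's pruning algorithm on the unrooted
tree (a bifurcating root in the input newick is collapsed into a basal
multifurcation; under reversible models root placement does not change the
likelihood). Per-node scaling of partial likelihoods in log space prevents
underflow on low-rate genes; alignment columns are compressed to unique
patterns. Analytic branch-length gradients (one upward and one downward
pass per class) feed L-BFGS-B, which jointly optimises branch lengths and
model parameters from one or more deterministic starting points. Fits
record convergence status, boundary hits (e.g. `omega2` at its upper
bound), and an identifiability flag for degenerate data such as constant
alignments.

## Hypothesis tests

Nested model pairs (M0 vs branch, M8a vs M8, branch-site null vs
alternative) are compared with the likelihood-ratio statistic
`2 * (lnL_alt - lnL_null)` against chi-squared with df = 1. The 50:50
boundary mixture `0.5*chi2(0) + 0.5*chi2(1)` is available behind a flag;
the plain chi-squared default is conservative for the boundary tests.
P-values are corrected per test family (all genes for one comparison type
and one foreground lineage) with the Benjamini–Hochberg procedure; genes
with q < 0.05 are reported as positively selected.

## Site identification (BEB)

Sites under positive selection in the branch-site alternative are located
with Bayes empirical Bayes: the posterior probability that a site belongs
to class 2a or 2b is averaged over a uniform prior grid on the proportion
parameters `(a, b)` and on `omega2` (10 points per axis by default), with
grid-point weights proportional to the data likelihood. `kappa`, `omega0`,
branch lengths, and the class rate multipliers stay at their maximum
likelihood estimates, so the whole grid needs only `2 + 2 * n_grid`
pruning passes. Sites with posterior probability >= 0.95 are flagged.
Naive empirical Bayes (posteriors at the MLEs only) is provided for
comparison.

## Convergent and parallel substitutions

Amino-acid alignments (translated from the codon data) are analysed with
an empirical rate matrix (cpREV by default; WAG and JTT are bundled)
combined with gene-specific amino-acid frequencies. Marginal ancestral
states are reconstructed at every internal node after re-estimating branch
lengths; the maximum-a-posteriori residue is taken per node and site, with
ties broken alphabetically.

For a designated species pair, a site counts as a *parallel* substitution
when both tips share a residue that differs from both parents' MAP states
and the two parent states agree, and as *convergent* when the parent
states differ. The model-expected count accumulates, per site, the
probability that both terminal branches end in the same state distinct
from both ancestral states, using the reconstructed parent states and the
fitted terminal branch lengths. Observed totals are compared with expected
totals by a direction-aware Poisson tail test (upper tail
`P(X >= obs)` when observed exceeds expected, lower tail otherwise), and
Benjamini–Hochberg correction is applied across genes; only upper-tail
excesses are flagged. Genes flagged by both the branch-site test and the
convergence test form the conservative adaptive set.

## dS filtering

From each gene's M0 fit, per-branch `dS` is obtained by decomposing the
branch length into synonymous and nonsynonymous substitution flow. Genes
with any branch `dS > 1` (saturation) are excluded from downstream
reporting; the exclusion is logged with the offending branch.

## Simulation

The simulator evolves codons (or amino acids) down the tree by sampling
from exact transition matrices; each site keeps one mixture class across
the whole tree, matching the branch-site model's assumption. Scenario
presets cover branch-site null and power studies, M8-style site variation,
null amino-acid evolution for convergence calibration, and a paper-like
strongly purifying regime. Convergent substitutions can be planted
post-hoc at chosen sites of a species pair; planting happens after all
random draws, so unplanted columns are bit-identical between planted and
unplanted runs at the same seed. A bundled 6-gene fixture with one planted
positively-selected gene and one planted convergent gene exercises the
whole pipeline.
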