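"""Ancestral amino-acid reconstruction and convergent/parallel substitution tests.

For each gene, branch lengths are re-estimated by maximum likelihood under an
empirical amino-acid model (default cpREV exchangeabilities with gene-specific
frequencies) and marginal ancestral states are reconstructed by up/down
pruning. For a species pair (A, B), a site carries a pair substitution when
both tips share a residue that differs from the MAP state at each tip's
parent node: parallel if the two parent states agree, convergent if they
differ. Expected counts under the substitution model are summed per site from
the parent states and terminal branch lengths, and observed counts are
compared with a two-direction Poisson tail test; q-values are BH-adjusted
across genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.stats import poisson

from .alnio import AminoAcidAlignment
from .genetic_code import AMINO_ACIDS, THREE_LETTER
from .ctmc import (PruningEngine, RateMatrix, build_aa_q,
                   gene_aa_frequencies, load_empirical_matrix)
from .model_fit import BL_BOUNDS
from .selection_tests import fdr_bh
from .trees import Phylogeny

#: columns of the posterior arrays reordered alphabetically, for MAP tie-breaks
_ALPHA_ORDER = np.argsort(list(AMINO_ACIDS))


@dataclass
class AncestralStates:
    aln: AminoAcidAlignment
    tree: Phylogeny                  # with re-estimated branch lengths
    model: RateMatrix
    posteriors: np.ndarray           # (n_nodes, n_sites, 20); NaN rows at leaves
    map_states: np.ndarray           # (n_nodes, n_sites); tip rows = observed
    lnL: float

    @property
    def n_sites(self) -> int:
        return self.aln.n_sites


@dataclass
class PairConvergenceResult:
    gene: str
    pair: tuple[str, str]
    parallel_sites: list[tuple[int, str]]     # (1-based site, "Anc-Der" label)
    convergent_sites: list[tuple[int, str]]
    observed_parallel: int
    observed_convergent: int
    expected_parallel: float
    expected_convergent: float
    p_value: float
    tail: str
    q_value: float | None = None
    #: (p, tail) per category when tested separately rather than pooled
    separate: dict | None = None


def default_aa_model(aln: AminoAcidAlignment, matrix: str = "cprev") -> RateMatrix:
    """Empirical exchangeabilities + gene amino-acid frequencies (+f_gene)."""
    S, _ = load_empirical_matrix(matrix)
    return build_aa_q(S, gene_aa_frequencies(aln))


def _map_with_alpha_ties(post: np.ndarray) -> np.ndarray:
    """Argmax over residues, ties broken by alphabetical one-letter code."""
    reordered = post[..., _ALPHA_ORDER]
    return _ALPHA_ORDER[np.argmax(reordered, axis=-1)]


def optimize_branch_lengths(engine: PruningEngine, model: RateMatrix,
                            t0: np.ndarray | None = None):
    """ML branch lengths for a single-class model; returns (t, lnL)."""
    spec = [(1.0, model, model)]
    if t0 is None:
        t0 = np.full(len(engine.edges), 0.1)
    t0 = np.clip(t0, BL_BOUNDS[0], BL_BOUNDS[1])

    def f(t):
        res = engine.loglik(spec, t, want_grad=True)
        return -res["loglik"], -res["gradient"]

    res = minimize(f, t0, jac=True, method="L-BFGS-B",
                   bounds=[BL_BOUNDS] * len(t0),
                   options={"maxfun": 1000, "ftol": 1e-10, "gtol": 1e-6})
    return res.x, -float(res.fun)


def reconstruct_ancestors(aa_aln: AminoAcidAlignment, tree: Phylogeny,
                          model: RateMatrix | None = None, *,
                          optimize_bl: bool = True) -> AncestralStates:
    """Marginal ML ancestral reconstruction with branch-length re-estimation."""
    if (aa_aln.residues < 0).any():
        raise ValueError(f"{aa_aln.gene_name}: alignment has sentinel residues; "
                         "clean before reconstruction")
    if model is None:
        model = default_aa_model(aa_aln)
    engine = PruningEngine.for_aa_alignment(aa_aln, tree)
    if optimize_bl:
        t, lnl = optimize_branch_lengths(engine, model, tree.edge_lengths())
    else:
        t = tree.edge_lengths()
        lnl = engine.loglik([(1.0, model, model)], t)["loglik"]
    fitted = tree.with_branch_lengths(t)
    post = engine.node_posteriors([(1.0, model, model)], t)
    map_states = np.empty((tree.n_nodes, aa_aln.n_sites), dtype=np.int8)
    for i in range(tree.n_nodes):
        if tree.is_leaf(i):
            map_states[i] = aa_aln.row(tree.labels[i])
        else:
            map_states[i] = _map_with_alpha_ties(post[i])
    return AncestralStates(aa_aln, fitted, model, post, map_states, lnl)


def _pair_parents(asr: AncestralStates, pair: tuple[str, str]):
    tree = asr.tree
    leaves = []
    for taxon in pair:
        leaf = tree.leaf_index(taxon)
        if not tree.is_leaf(leaf):
            raise ValueError(f"{taxon!r} is not a leaf")
        leaves.append(leaf)
    a, b = leaves
    if tree.parent[a] < 0 or tree.parent[b] < 0 or a == b:
        raise ValueError("pair must name two distinct terminal branches")
    return a, b


def _label(anc: str, der: str) -> str:
    return f"{THREE_LETTER[anc]}-{THREE_LETTER[der]}"


def find_pair_substitution_sites(asr: AncestralStates, pair: tuple[str, str]):
    """(parallel, convergent) site lists for a species pair.

    A site qualifies when both tips share residue x and each tip's parent
    MAP state differs from x; parallel if the parent states agree (label
    "Anc-Der"), convergent otherwise (label "AncA/AncB-Der").
    """
    a, b = _pair_parents(asr, pair)
    tree = asr.tree
    tip_a, tip_b = asr.map_states[a], asr.map_states[b]
    anc_a = asr.map_states[tree.parent[a]]
    anc_b = asr.map_states[tree.parent[b]]
    parallel, convergent = [], []
    hits = np.nonzero((tip_a == tip_b) & (anc_a != tip_a) & (anc_b != tip_b))[0]
    for s in hits:
        der = AMINO_ACIDS[tip_a[s]]
        ra, rb = AMINO_ACIDS[anc_a[s]], AMINO_ACIDS[anc_b[s]]
        if anc_a[s] == anc_b[s]:
            parallel.append((int(s) + 1, _label(ra, der)))
        else:
            convergent.append((int(s) + 1,
                               f"{THREE_LETTER[ra]}/{THREE_LETTER[rb]}-{THREE_LETTER[der]}"))
    return parallel, convergent


def expected_pair_convergence(asr: AncestralStates, pair: tuple[str, str],
                              model: RateMatrix | None = None,
                              branch_lengths: tuple[float, float] | None = None):
    """Model-expected (parallel, convergent) counts for the pair.

    Site contributions use the MAP parent states a_A, a_B and the terminal
    branch transition matrices: parallel (a_A = a_B = a) contributes
    sum_{x != a} P_tA(a,x) P_tB(a,x); convergent (a_A != a_B) contributes
    sum over x distinct from both ancestors of P_tA(a_A,x) P_tB(a_B,x).
    """
    a, b = _pair_parents(asr, pair)
    tree = asr.tree
    model = model or asr.model
    if branch_lengths is None:
        t_a, t_b = tree.branch_lengths[a], tree.branch_lengths[b]
    else:
        t_a, t_b = branch_lengths
    Pa, Pb = model.transition(t_a), model.transition(t_b)
    anc_a = asr.map_states[tree.parent[a]]
    anc_b = asr.map_states[tree.parent[b]]
    prod = Pa[anc_a] * Pb[anc_b]                  # (n_sites, n_states)
    exp_par = exp_conv = 0.0
    same = anc_a == anc_b
    cols = np.arange(Pa.shape[1])
    for s in range(asr.n_sites):
        mask = (cols != anc_a[s]) & (cols != anc_b[s])
        contrib = float(prod[s, mask].sum())
        if same[s]:
            exp_par += contrib
        else:
            exp_conv += contrib
    return exp_par, exp_conv


def poisson_convergence_test(observed: int, expected: float):
    """Direction-aware Poisson tail probability, (p, tail).

    Upper tail P(X >= observed) when observed exceeds the expectation,
    lower tail P(X <= observed) when below, p = 1 at equality.
    """
    if observed < 0 or expected < 0:
        raise ValueError("observed and expected must be nonnegative")
    if int(observed) != observed:
        raise ValueError("observed count must be an integer")
    observed = int(observed)
    if observed > expected:
        return float(poisson.sf(observed - 1, expected)), "upper"
    if observed < expected:
        return float(poisson.cdf(observed, expected)), "lower"
    return 1.0, "none"


def analyze_pair_convergence(asr: AncestralStates, pair: tuple[str, str], *,
                             mode: str = "pooled") -> PairConvergenceResult:
    """Observed vs expected pair substitutions for one gene.

    ``mode='pooled'`` tests parallel + convergent together (one p per gene);
    ``'separate'`` additionally records per-category tests.
    """
    if mode not in ("pooled", "separate"):
        raise ValueError(f"unknown mode {mode!r}")
    parallel, convergent = find_pair_substitution_sites(asr, pair)
    exp_par, exp_conv = expected_pair_convergence(asr, pair)
    obs_par, obs_conv = len(parallel), len(convergent)
    p, tail = poisson_convergence_test(obs_par + obs_conv, exp_par + exp_conv)
    separate = None
    if mode == "separate":
        separate = {"parallel": poisson_convergence_test(obs_par, exp_par),
                    "convergent": poisson_convergence_test(obs_conv, exp_conv)}
    return PairConvergenceResult(
        asr.aln.gene_name, pair, parallel, convergent, obs_par, obs_conv,
        exp_par, exp_conv, p, tail, separate=separate)


def attach_convergence_fdr(results: list[PairConvergenceResult],
                           alpha: float = 0.05) -> set[str]:
    """BH across genes (in place); returns genes with excess at q < alpha."""
    if not results:
        return set()
    q = fdr_bh([r.p_value for r in results])
    for r, qv in zip(results, q):
        r.q_value = float(qv)
    return {r.gene for r in results if r.q_value < alpha and r.tail == "upper"}


def conservative_adaptive_genes(psg: set[str], conv: set[str]):
    """Intersection of positively-selected and convergence-flagged genes.

    Returns (genes, provenance) where provenance records which test
    supplied each membership across the union.
    """
    genes = set(psg) & set(conv)
    provenance = {}
    for g in set(psg) | set(conv):
        tests = []
        if g in psg:
            tests.append("positive_selection")
        if g in conv:
            tests.append("convergence")
        provenance[g] = tests
    return genes, provenance


def convergence_report(results: list[PairConvergenceResult]) -> str:
    """TSV mirroring the per-pair table: gene, positions, AA changes, P, Q."""
    header = ["gene", "pair", "parallel_positions", "parallel_changes",
              "convergent_positions", "convergent_changes",
              "observed", "expected", "p_value", "tail", "q_value"]
    lines = ["\t".join(header)]
    for r in results:
        q = "" if r.q_value is None else f"{r.q_value:.6g}"
        lines.append("\t".join([
            r.gene, f"{r.pair[0]} vs {r.pair[1]}",
            ", ".join(str(s) for s, _ in r.parallel_sites),
            ", ".join(lab for _, lab in r.parallel_sites),
            ", ".join(str(s) for s, _ in r.convergent_sites),
            ", ".join(lab for _, lab in r.convergent_sites),
            str(r.observed_parallel + r.observed_convergent),
            f"{r.expected_parallel + r.expected_convergent:.4f}",
            f"{r.p_value:.6g}", r.tail, q]))
    return "\n".join(lines) + "\n"
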