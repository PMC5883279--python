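import numpy as np
import pytest
from scipy.linalg import expm
from scipy.stats import poisson

from chloroselect.alnio import AminoAcidAlignment
from chloroselect.convergence import (AncestralStates, analyze_pair_convergence,
                                      attach_convergence_fdr,
                                      conservative_adaptive_genes,
                                      convergence_report, default_aa_model,
                                      expected_pair_convergence,
                                      find_pair_substitution_sites,
                                      poisson_convergence_test,
                                      reconstruct_ancestors)
from chloroselect.ctmc import RateMatrix, build_aa_q, load_empirical_matrix
from chloroselect.genetic_code import AA_INDEX
from chloroselect.simdata import (SimulationScenario, scenario_presets,
                                  simulate_aa_alignment)
from chloroselect.trees import Phylogeny, TreeError

TOY_NEWICK = "((A:0.1,B:0.15):0.08,(C:0.12,D:0.2):0.05);"


def _aa(letter):
    return AA_INDEX[letter]


@pytest.fixture(scope="module")
def toy_tree():
    return Phylogeny.from_newick(TOY_NEWICK)


def _fabricated_asr(tree, tip_states, parent_states):
    """AncestralStates with hand-chosen MAP states for one site."""
    n = tree.n_nodes
    map_states = np.zeros((n, 1), dtype=np.int8)
    taxa = tree.taxa
    for taxon, s in tip_states.items():
        map_states[tree.leaf_index(taxon), 0] = s
    for taxon, s in parent_states.items():
        map_states[tree.parent[tree.leaf_index(taxon)], 0] = s
    residues = np.array([[tip_states[t]] for t in taxa], dtype=np.int8)
    aln = AminoAcidAlignment("toy", list(taxa), residues)
    S, f = load_empirical_matrix("cprev")
    return AncestralStates(aln, tree, build_aa_q(S, f),
                           np.full((n, 1, 20), np.nan), map_states, 0.0)


# ---------------------------------------------------------------------------
# ancestral reconstruction
# ---------------------------------------------------------------------------

def test_three_taxon_star_posterior_matches_bayes_oracle():
    tree = Phylogeny.from_newick("(A:0.2,B:0.35,C:0.1);")
    S, f = load_empirical_matrix("cprev")
    model = build_aa_q(S, f)
    obs = {"A": _aa("L"), "B": _aa("V"), "C": _aa("L")}
    residues = np.array([[obs[t]] for t in tree.taxa], dtype=np.int8)
    aln = AminoAcidAlignment("g", list(tree.taxa), residues)
    asr = reconstruct_ancestors(aln, tree, model, optimize_bl=False)
    # direct Bayes: post(x) propto pi_x * prod_leaf P_t(x -> obs)
    w = model.pi.copy()
    for taxon in tree.taxa:
        t = tree.branch_lengths[tree.leaf_index(taxon)]
        w *= expm(model.Q * t)[:, obs[taxon]]
    want = w / w.sum()
    got = asr.posteriors[tree.root, 0]
    assert np.allclose(got, want, atol=1e-10)
    assert asr.map_states[tree.root, 0] == np.argmax(want)


def test_invariant_column_reconstructs_dominant_state(toy_tree):
    residues = np.full((4, 3), _aa("L"), dtype=np.int8)
    aln = AminoAcidAlignment("g", list(toy_tree.taxa), residues)
    asr = reconstruct_ancestors(aln, toy_tree, default_aa_model(aln),
                                optimize_bl=False)
    for node in range(toy_tree.n_nodes):
        if toy_tree.is_leaf(node):
            continue
        assert (asr.map_states[node] == _aa("L")).all()
        assert (asr.posteriors[node, :, _aa("L")] > 0.9).all()
        assert np.allclose(asr.posteriors[node].sum(axis=1), 1.0, atol=1e-8)


def test_reconstruction_recovers_simulated_ancestors():
    sc = scenario_presets("convergence_null", seed=3)
    aln, truth = simulate_aa_alignment(sc)
    asr = reconstruct_ancestors(aln, sc.tree, sc.aa_model)
    accs = [np.mean(asr.map_states[node] == truth[node]) for node in truth]
    assert np.mean(accs) > 0.9
    assert asr.lnL < 0
    # branch lengths were re-estimated, not copied
    assert asr.tree.edge_lengths().sum() > 0


def test_reconstruct_rejects_sentinel_residues(toy_tree):
    residues = np.full((4, 2), -1, dtype=np.int8)
    aln = AminoAcidAlignment("g", list(toy_tree.taxa), residues)
    with pytest.raises(ValueError, match="sentinel"):
        reconstruct_ancestors(aln, toy_tree)


# ---------------------------------------------------------------------------
# pair substitution sites
# ---------------------------------------------------------------------------

def test_parallel_site_classification(toy_tree):
    asr = _fabricated_asr(
        toy_tree,
        {"A": _aa("S"), "B": _aa("R"), "C": _aa("S"), "D": _aa("R")},
        {"A": _aa("R"), "C": _aa("R")})
    parallel, convergent = find_pair_substitution_sites(asr, ("A", "C"))
    assert parallel == [(1, "Arg-Ser")]
    assert convergent == []


def test_convergent_site_classification(toy_tree):
    asr = _fabricated_asr(
        toy_tree,
        {"A": _aa("L"), "B": _aa("M"), "C": _aa("L"), "D": _aa("T")},
        {"A": _aa("M"), "C": _aa("T")})
    parallel, convergent = find_pair_substitution_sites(asr, ("A", "C"))
    assert parallel == []
    assert convergent == [(1, "Met/Thr-Leu")]


def test_no_change_yields_empty_lists(toy_tree):
    asr = _fabricated_asr(
        toy_tree,
        {"A": _aa("L"), "B": _aa("L"), "C": _aa("L"), "D": _aa("L")},
        {"A": _aa("L"), "C": _aa("L")})
    assert find_pair_substitution_sites(asr, ("A", "C")) == ([], [])


def test_pair_counts_symmetric_in_order(toy_tree):
    asr = _fabricated_asr(
        toy_tree,
        {"A": _aa("L"), "B": _aa("M"), "C": _aa("L"), "D": _aa("T")},
        {"A": _aa("M"), "C": _aa("T")})
    p1, c1 = find_pair_substitution_sites(asr, ("A", "C"))
    p2, c2 = find_pair_substitution_sites(asr, ("C", "A"))
    assert len(p1) == len(p2) and len(c1) == len(c2)
    assert c2 == [(1, "Thr/Met-Leu")]  # ancestors swap with the pair order
    e1 = expected_pair_convergence(asr, ("A", "C"))
    e2 = expected_pair_convergence(asr, ("C", "A"))
    assert e1 == pytest.approx(e2)


def test_pair_requires_leaves(toy_tree):
    asr = _fabricated_asr(
        toy_tree,
        {"A": 0, "B": 0, "C": 0, "D": 0}, {"A": 0, "C": 0})
    with pytest.raises(TreeError):
        find_pair_substitution_sites(asr, ("A", "nope"))
    with pytest.raises(ValueError):
        find_pair_substitution_sites(asr, ("A", "A"))


# ---------------------------------------------------------------------------
# expected counts
# ---------------------------------------------------------------------------

def _three_state_model():
    S = np.array([[0.0, 1.0, 2.0], [1.0, 0.0, 0.5], [2.0, 0.5, 0.0]])
    pi = np.array([0.5, 0.3, 0.2])
    Q = S * pi[None, :]
    np.fill_diagonal(Q, 0.0)
    Q[np.diag_indices(3)] = -Q.sum(axis=1)
    scale = -float(pi @ np.diag(Q))
    return RateMatrix(Q / scale, pi, scale)


def test_expected_counts_three_state_hand_oracle(toy_tree):
    model = _three_state_model()
    asr = _fabricated_asr(toy_tree, {"A": 0, "B": 0, "C": 0, "D": 0},
                          {"A": 1, "C": 2})
    asr.model = model
    tA = toy_tree.branch_lengths[toy_tree.leaf_index("A")]
    tB = toy_tree.branch_lengths[toy_tree.leaf_index("C")]
    PA, PB = expm(model.Q * tA), expm(model.Q * tB)
    # parents 1 and 2 differ: convergent contribution sums x not in {1, 2}
    want_conv = PA[1, 0] * PB[2, 0]
    exp_par, exp_conv = expected_pair_convergence(asr, ("A", "C"))
    assert exp_par == 0.0
    assert exp_conv == pytest.approx(want_conv, rel=1e-10)
    # equal parents: parallel contribution sums x != 1
    asr2 = _fabricated_asr(toy_tree, {"A": 0, "B": 0, "C": 0, "D": 0},
                           {"A": 1, "C": 1})
    asr2.model = model
    want_par = PA[1, 0] * PB[1, 0] + PA[1, 2] * PB[1, 2]
    exp_par2, exp_conv2 = expected_pair_convergence(asr2, ("A", "C"))
    assert exp_conv2 == 0.0
    assert exp_par2 == pytest.approx(want_par, rel=1e-10)


def test_expected_counts_zero_branch_lengths(toy_tree):
    asr = _fabricated_asr(toy_tree, {"A": 0, "B": 0, "C": 0, "D": 0},
                          {"A": 1, "C": 1})
    exp_par, exp_conv = expected_pair_convergence(asr, ("A", "C"),
                                                  branch_lengths=(0.0, 0.0))
    assert exp_par == pytest.approx(0.0, abs=1e-12)
    assert exp_conv == pytest.approx(0.0, abs=1e-12)


def test_expected_counts_monotone_in_branch_length(toy_tree):
    asr = _fabricated_asr(toy_tree, {"A": 0, "B": 0, "C": 0, "D": 0},
                          {"A": 1, "C": 1})
    values = [expected_pair_convergence(asr, ("A", "C"),
                                        branch_lengths=(t, t))[0]
              for t in (0.05, 0.1, 0.2, 0.4)]
    assert all(a < b for a, b in zip(values, values[1:]))


# ---------------------------------------------------------------------------
# Poisson test
# ---------------------------------------------------------------------------

def test_poisson_test_pmf_summation_oracles():
    p, tail = poisson_convergence_test(4, 0.5)
    want = 1.0 - sum(poisson.pmf(k, 0.5) for k in range(4))
    assert tail == "upper" and p == pytest.approx(want, rel=1e-12)
    p, tail = poisson_convergence_test(1, 5.0)
    want = sum(poisson.pmf(k, 5.0) for k in range(2))
    assert tail == "lower" and p == pytest.approx(want, rel=1e-12)


def test_poisson_test_boundaries_and_errors():
    assert poisson_convergence_test(0, 0.0) == (1.0, "none")
    assert poisson_convergence_test(3, 3.0) == (1.0, "none")
    with pytest.raises(ValueError):
        poisson_convergence_test(-1, 0.5)
    with pytest.raises(ValueError):
        poisson_convergence_test(2, -0.5)
    with pytest.raises(ValueError):
        poisson_convergence_test(1.5, 0.5)


# ---------------------------------------------------------------------------
# per-gene analysis, FDR, intersection
# ---------------------------------------------------------------------------

def test_analyze_pair_modes(toy_tree):
    asr = _fabricated_asr(
        toy_tree,
        {"A": _aa("S"), "B": _aa("R"), "C": _aa("S"), "D": _aa("R")},
        {"A": _aa("R"), "C": _aa("R")})
    res = analyze_pair_convergence(asr, ("A", "C"), mode="separate")
    assert res.observed_parallel == 1 and res.observed_convergent == 0
    assert res.separate is not None and set(res.separate) == {"parallel",
                                                              "convergent"}
    assert 0 <= res.p_value <= 1
    with pytest.raises(ValueError, match="mode"):
        analyze_pair_convergence(asr, ("A", "C"), mode="bogus")


def test_attach_convergence_fdr_requires_upper_tail(toy_tree):
    def res(gene, p, tail):
        from chloroselect.convergence import PairConvergenceResult
        return PairConvergenceResult(gene, ("A", "B"), [], [], 0, 0, 0.0, 0.0,
                                     p, tail)

    results = [res("up", 0.001, "upper"), res("down", 0.001, "lower"),
               res("flat", 0.9, "none")]
    flagged = attach_convergence_fdr(results, alpha=0.05)
    assert flagged == {"up"}
    assert all(r.q_value is not None for r in results)
    assert attach_convergence_fdr([], 0.05) == set()


def test_conservative_adaptive_genes_examples():
    genes, prov = conservative_adaptive_genes(
        {"atpB", "psaB", "rbcL"}, {"atpB", "atpI", "petA", "psaB", "rbcL"})
    assert genes == {"atpB", "psaB", "rbcL"}
    assert prov["atpB"] == ["positive_selection", "convergence"]
    assert prov["atpI"] == ["convergence"]
    assert conservative_adaptive_genes({"a"}, {"b"})[0] == set()
    assert conservative_adaptive_genes({"a"}, {"a"})[0] == {"a"}


def test_convergence_report_layout(toy_tree):
    asr = _fabricated_asr(
        toy_tree,
        {"A": _aa("S"), "B": _aa("R"), "C": _aa("S"), "D": _aa("R")},
        {"A": _aa("R"), "C": _aa("R")})
    res = analyze_pair_convergence(asr, ("A", "C"))
    text = convergence_report([res])
    lines = text.strip().split("\n")
    assert len(lines) == 2
    row = dict(zip(lines[0].split("\t"), lines[1].split("\t")))
    assert row["gene"] == "toy"
    assert row["parallel_changes"] == "Arg-Ser"
    assert row["parallel_positions"] == "1"
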