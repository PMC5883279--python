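import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.linalg import expm

from helpers import enum_class_site_likelihoods, enum_loglik

from chloroselect.alnio import CodonAlignment
from chloroselect.ctmc import (CodonFrequencies, NumericalError, PruningEngine,
                               RateMatrix, SiteClassMixture,
                               beta_category_rates, build_aa_q, build_codon_q,
                               f3x4_frequencies, gene_aa_frequencies,
                               load_empirical_matrix, substitution_flow,
                               transition_matrix, tree_loglik)
from chloroselect.genetic_code import code_tables
from chloroselect.trees import Phylogeny

CODONS, CODON_INDEX, _, _ = code_tables(1)


# ---------------------------------------------------------------------------
# frequencies
# ---------------------------------------------------------------------------

def test_uniform_frequencies():
    f = CodonFrequencies.uniform()
    assert f.pi.size == 61
    assert np.allclose(f.pi, 1.0 / 61)


def test_f3x4_hand_tally():
    # codons ATG, TTT pooled over one row: position counts tallied by hand
    mat = np.array([[CODON_INDEX["ATG"], CODON_INDEX["TTT"]]], dtype=np.int16)
    f = f3x4_frequencies(CodonAlignment("g", ["a"], mat))
    # pos1: A=0.5, T=0.5; pos2: T=1; pos3: G=0.5, T=0.5 (TCAG order)
    assert np.allclose(f.pos_freqs[0], [0.5, 0.0, 0.5, 0.0])
    assert np.allclose(f.pos_freqs[1], [1.0, 0.0, 0.0, 0.0])
    assert np.allclose(f.pos_freqs[2], [0.5, 0.0, 0.0, 0.5])
    # only TTT, TTG, ATT, ATG get mass, each 1/8 before renormalising -> 1/4
    for cod in ("TTT", "TTG", "ATT", "ATG"):
        assert f.pi[CODON_INDEX[cod]] == pytest.approx(0.25)
    assert f.pi.sum() == pytest.approx(1.0)


def test_f3x4_skips_gaps_and_rejects_empty():
    mat = np.array([[CODON_INDEX["ATG"], -1]], dtype=np.int16)
    f = f3x4_frequencies(CodonAlignment("g", ["a"], mat))
    assert f.pos_freqs[0, 2] == 1.0  # only A observed at position 1
    with pytest.raises(ValueError, match="no unambiguous"):
        f3x4_frequencies(CodonAlignment(
            "g", ["a"], np.array([[-1, -1]], dtype=np.int16)))


def test_degenerate_position_frequencies_raise():
    # all mass on stop codons (TAA): no sense codon has positive mass
    pf = np.array([[1, 0, 0, 0], [0, 0, 1, 0], [0, 0, 1, 0.0]])
    with pytest.raises(ValueError, match="degenerate"):
        CodonFrequencies.from_pos_freqs(pf)


# ---------------------------------------------------------------------------
# codon generator
# ---------------------------------------------------------------------------

def test_codon_q_entries_by_hand(default_freqs):
    kappa, omega = 3.0, 0.2
    m = build_codon_q(kappa, omega, default_freqs)
    Q_un = m.Q * m.scale  # undo the mean-rate-1 normalisation
    pi = default_freqs.pi
    i, j = CODON_INDEX["TTT"], CODON_INDEX["TTC"]  # synonymous transition
    assert Q_un[i, j] == pytest.approx(kappa * pi[j])
    i, j = CODON_INDEX["TTT"], CODON_INDEX["TTA"]  # nonsyn transversion
    assert Q_un[i, j] == pytest.approx(omega * pi[j])
    i, j = CODON_INDEX["TTT"], CODON_INDEX["TCC"]  # two nucleotide changes
    assert Q_un[i, j] == 0.0


def test_codon_q_rows_mean_rate_and_detailed_balance(default_freqs):
    m = build_codon_q(2.0, 0.5, default_freqs)
    assert np.allclose(m.Q.sum(axis=1), 0.0, atol=1e-12)
    assert -np.dot(m.pi, np.diag(m.Q)) == pytest.approx(1.0)
    flux = m.pi[:, None] * m.Q
    assert np.allclose(flux, flux.T, atol=1e-12)


def test_codon_q_argument_errors(default_freqs):
    with pytest.raises(ValueError):
        build_codon_q(0.0, 0.5, default_freqs)
    with pytest.raises(ValueError):
        build_codon_q(2.0, -0.1, default_freqs)


def test_substitution_flow_shares(default_freqs):
    rho_n, rho_s = substitution_flow(2.0, 1.0, default_freqs)
    assert rho_n + rho_s == pytest.approx(1.0)
    # purifying selection shrinks the nonsynonymous share
    rho_n_low, _ = substitution_flow(2.0, 0.1, default_freqs)
    assert rho_n_low < rho_n


# ---------------------------------------------------------------------------
# transition matrices
# ---------------------------------------------------------------------------

def test_transition_matches_scipy_expm(default_freqs):
    m = build_codon_q(2.0, 0.3, default_freqs)
    for t in (0.01, 0.2, 1.5):
        P = transition_matrix(m, t)
        assert np.allclose(P, expm(m.Q * t), atol=1e-10)
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-10)
        assert (P >= 0).all()


def test_transition_identity_and_semigroup(default_freqs):
    m = build_codon_q(1.5, 0.4, default_freqs)
    assert np.allclose(m.transition(0.0), np.eye(61), atol=1e-12)
    assert np.allclose(m.transition(0.5), m.transition(0.2) @ m.transition(0.3),
                       atol=1e-10)


def test_negative_branch_length_raises(default_freqs):
    m = build_codon_q(2.0, 0.3, default_freqs)
    with pytest.raises(ValueError):
        transition_matrix(m, -0.1)


def test_transition_preserves_stationary_distribution(default_freqs):
    m = build_codon_q(2.0, 0.3, default_freqs)
    assert np.allclose(m.pi @ m.transition(0.7), m.pi, atol=1e-10)


def test_dtransition_matches_finite_difference(default_freqs):
    m = build_codon_q(2.0, 0.3, default_freqs)
    t, h = 0.3, 1e-6
    fd = (m.transition(t + h) - m.transition(t - h)) / (2 * h)
    assert np.allclose(m.dtransition_batch(np.array([t]))[0], fd, atol=1e-6)


# ---------------------------------------------------------------------------
# amino-acid machinery
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("name", ["cprev", "wag", "jtt"])
def test_load_empirical_matrix(name):
    S, f = load_empirical_matrix(name)
    assert S.shape == (20, 20)
    assert np.allclose(S, S.T)
    assert np.allclose(np.diag(S), 0.0)
    assert (S >= 0).all()
    assert f.sum() == pytest.approx(1.0)
    assert (f > 0).all()


def test_build_aa_q_properties():
    S, f = load_empirical_matrix("cprev")
    m = build_aa_q(S, f)
    assert np.allclose(m.Q.sum(axis=1), 0.0, atol=1e-12)
    assert -np.dot(f, np.diag(m.Q)) == pytest.approx(1.0)
    flux = f[:, None] * m.Q
    assert np.allclose(flux, flux.T, atol=1e-12)


def test_build_aa_q_validation():
    S, f = load_empirical_matrix("cprev")
    bad = S.copy()
    bad[0, 1] += 1.0
    with pytest.raises(ValueError, match="symmetric"):
        build_aa_q(bad, f)
    with pytest.raises(ValueError, match="sum to 1"):
        build_aa_q(S, f * 2)


def test_gene_aa_frequencies_pseudocount():
    from chloroselect.alnio import AminoAcidAlignment
    aln = AminoAcidAlignment("g", ["a"], np.zeros((1, 4), dtype=np.int8))
    f = gene_aa_frequencies(aln, pseudocount=0.1)
    assert f.sum() == pytest.approx(1.0)
    assert (f > 0).all()           # unseen residues keep positive mass
    assert f[0] == pytest.approx((4 + 0.1) / (4 + 2.0))


# ---------------------------------------------------------------------------
# beta discretisation and mixtures
# ---------------------------------------------------------------------------

@given(st.floats(0.05, 20), st.floats(0.05, 20))
def test_beta_category_rates_property(p, q):
    rates = beta_category_rates(p, q, 10)
    assert rates.shape == (10,)
    # medians lie in (0, 1); extreme shapes can round to 1.0 in floats
    assert ((rates > 0) & (rates <= 1)).all()
    assert (np.diff(rates) >= 0).all()


def test_beta_category_rates_errors():
    with pytest.raises(ValueError):
        beta_category_rates(0.0, 1.0)
    with pytest.raises(ValueError):
        beta_category_rates(1.0, -2.0)


def test_mixture_validation():
    with pytest.raises(ValueError, match="kappa"):
        SiteClassMixture(0.0, [(1.0, 0.5, 0.5)])
    with pytest.raises(ValueError, match="sum to 1"):
        SiteClassMixture(2.0, [(0.5, 0.5, 0.5)])


def test_branch_site_class_proportions_by_hand():
    mix = SiteClassMixture.branch_site(2.0, 0.6, 0.2, 0.1, 3.0)
    props = [c[0] for c in mix.classes]
    # remaining 0.2 split in the 0.6 : 0.2 ratio -> 0.15 and 0.05
    assert props == pytest.approx([0.6, 0.2, 0.15, 0.05])
    assert mix.classes[2][1:] == (0.1, 3.0)
    assert mix.classes[3][1:] == (1.0, 3.0)


def test_branch_site_domain_errors():
    with pytest.raises(ValueError, match="omega0"):
        SiteClassMixture.branch_site(2.0, 0.5, 0.3, 1.5, 2.0)
    with pytest.raises(ValueError, match="omega2"):
        SiteClassMixture.branch_site(2.0, 0.5, 0.3, 0.1, 0.5)
    with pytest.raises(ValueError, match="p0"):
        SiteClassMixture.branch_site(2.0, 0.9, 0.3, 0.1, 2.0)


def test_m8_class_structure():
    mix = SiteClassMixture.m8(2.0, 0.8, 0.5, 2.0, 3.0, ncat=10)
    assert len(mix.classes) == 11
    assert sum(c[0] for c in mix.classes) == pytest.approx(1.0)
    assert mix.classes[-1] == (pytest.approx(0.2), 3.0, 3.0)
    assert all(0 < c[1] < 1 for c in mix.classes[:-1])


def test_mixture_rate_multipliers_mean_one(default_freqs):
    specs = SiteClassMixture.branch_site(
        2.0, 0.5, 0.25, 0.05, 8.0).matrices(default_freqs)
    props = np.array([s.prop for s in specs])
    assert props @ [s.r_bg for s in specs] == pytest.approx(1.0)
    assert props @ [s.r_fg for s in specs] == pytest.approx(1.0)
    # high-omega foreground classes evolve faster than purifying ones
    assert specs[2].r_fg > specs[0].r_fg
    # single-class models keep the plain normalised generator
    single = SiteClassMixture.m0(2.0, 0.3).matrices(default_freqs)
    assert single[0].r_bg == single[0].r_fg == 1.0


def test_mixture_generator_objects_are_shared(default_freqs):
    s1 = SiteClassMixture.branch_site(2.0, 0.5, 0.25, 0.05, 8.0).matrices(
        default_freqs)
    s2 = SiteClassMixture.branch_site(2.0, 0.6, 0.20, 0.05, 8.0).matrices(
        default_freqs)
    # same (kappa, omega) reuses the identical generator object
    assert s1[0].q_bg is s2[0].q_bg
    assert s1[2].q_fg is s2[2].q_fg


# ---------------------------------------------------------------------------
# pruning likelihood
# ---------------------------------------------------------------------------

def test_loglik_matches_enumeration_m0(toy4_aln, toy4_tree, default_freqs):
    mix = SiteClassMixture.m0(2.0, 0.4)
    got, got_sites = tree_loglik(toy4_aln, toy4_tree, mixture=mix,
                                 freqs=default_freqs, return_site=True)
    want, want_sites = enum_loglik(toy4_aln, toy4_tree, mix, default_freqs)
    assert got == pytest.approx(want, rel=1e-10)
    assert np.allclose(got_sites, want_sites, rtol=1e-10)
    assert got_sites.sum() == pytest.approx(got)


def test_loglik_long_branches_no_underflow(toy4_aln, toy4_tree, default_freqs):
    long_bl = np.full(len(toy4_tree.edge_nodes), 15.0)
    mix = SiteClassMixture.m0(2.0, 0.4)
    got = tree_loglik(toy4_aln, toy4_tree, mixture=mix, freqs=default_freqs,
                      branch_lengths=long_bl)
    want, _ = enum_loglik(toy4_aln, toy4_tree, mix, default_freqs,
                          branch_lengths=long_bl)
    assert np.isfinite(got)
    assert got == pytest.approx(want, rel=1e-8)


def test_branch_length_gradient_matches_fd(toy4_aln, toy4_tree, default_freqs):
    tree = toy4_tree.with_foreground({"A"})
    engine = PruningEngine.for_codon_alignment(toy4_aln, tree)
    specs = SiteClassMixture.branch_site(2.0, 0.5, 0.3, 0.1, 4.0).matrices(
        default_freqs)
    t = np.linspace(0.05, 0.4, len(engine.edges))
    grad = engine.loglik(specs, t, want_grad=True)["gradient"]
    h = 1e-6
    for e in range(len(t)):
        tp, tm = t.copy(), t.copy()
        tp[e] += h
        tm[e] -= h
        fd = (engine.loglik(specs, tp)["loglik"]
              - engine.loglik(specs, tm)["loglik"]) / (2 * h)
        assert grad[e] == pytest.approx(fd, rel=1e-4, abs=1e-6)


def test_node_posteriors_normalised(toy4_aln, toy4_tree, default_freqs):
    engine = PruningEngine.for_codon_alignment(toy4_aln, toy4_tree)
    specs = SiteClassMixture.m0(2.0, 0.5).matrices(default_freqs)
    post = engine.node_posteriors(specs, toy4_tree.edge_lengths())
    for node in range(toy4_tree.n_nodes):
        if toy4_tree.is_leaf(node):
            assert np.isnan(post[node]).all()
        else:
            assert np.allclose(post[node].sum(axis=1), 1.0, atol=1e-8)
            assert (post[node] >= 0).all()


def test_zero_class_likelihood_in_mixture_is_tolerated(default_freqs):
    # one site with a nonsynonymous difference: impossible under omega = 0,
    # fine once a neutral class carries the pattern
    tree = Phylogeny.from_newick("((A:0.1,B:0.1):0.05,(C:0.1,D:0.1):0.05);")
    mat = np.array([[CODON_INDEX["AAA"]], [CODON_INDEX["GAA"]],
                    [CODON_INDEX["AAA"]], [CODON_INDEX["AAA"]]], dtype=np.int16)
    aln = CodonAlignment("g", ["A", "B", "C", "D"], mat)
    mix = SiteClassMixture(2.0, [(0.5, 0.0, 0.0), (0.5, 1.0, 1.0)])
    ll = tree_loglik(aln, tree, mixture=mix, freqs=default_freqs)
    assert np.isfinite(ll)
    with pytest.raises(NumericalError):
        tree_loglik(aln, tree, mixture=SiteClassMixture.m0(2.0, 0.0),
                    freqs=default_freqs)


def test_engine_rejects_uncleaned_alignment(toy4_tree):
    mat = np.array([[-1, 0], [0, 0], [0, 0], [0, 0]], dtype=np.int16)
    aln = CodonAlignment("g", ["A", "B", "C", "D"], mat)
    with pytest.raises(ValueError, match="cleaned"):
        PruningEngine.for_codon_alignment(aln, toy4_tree)


def test_tree_loglik_argument_errors(toy4_aln, toy4_tree):
    with pytest.raises(ValueError, match="SiteClassMixture"):
        tree_loglik(toy4_aln, toy4_tree)
    aa = toy4_aln.to_amino_acids()
    with pytest.raises(ValueError, match="RateMatrix"):
        tree_loglik(aa, toy4_tree)
    with pytest.raises(TypeError):
        tree_loglik("not an alignment", toy4_tree)


def test_aa_loglik_matches_enumeration(toy4_aln, toy4_tree):
    aa = toy4_aln.to_amino_acids()
    S, _ = load_empirical_matrix("cprev")
    model = build_aa_q(S, gene_aa_frequencies(aa))
    got = tree_loglik(aa, toy4_tree, rate_matrix=model)
    want = np.log(enum_class_site_likelihoods(
        aa.residues, aa.taxa, toy4_tree, (1.0, model, model),
        toy4_tree.edge_lengths())).sum()
    assert got == pytest.approx(float(want), rel=1e-10)
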