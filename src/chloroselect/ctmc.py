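"""Reversible CTMC machinery shared by the codon and amino-acid analyses.

Codon substitution follows the Goldman–Yang form: the rate from codon i to a
single-nucleotide neighbour j is pi_j, multiplied by kappa for transitions
and by omega for nonsynonymous changes. Amino-acid substitution uses an
empirical exchangeability matrix combined with gene-specific frequencies.
All generators are normalised to mean rate 1, so branch lengths are expected
substitutions per codon (or per residue).

Likelihoods are computed by Felsenstein pruning over compressed site
patterns with per-node log scaling; site-class mixtures (M8, branch-site
model A) share the machinery, with foreground branches switching to the
foreground generator of each class. Analytic branch-length gradients are
provided via the standard up/down (pre-order) pass, which keeps joint
optimisation of branch lengths cheap.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from functools import lru_cache
from typing import NamedTuple

import numpy as np
from scipy.linalg import eigh
from scipy.special import logsumexp
from scipy.stats import beta as _beta

from .alnio import AminoAcidAlignment, CodonAlignment
from .genetic_code import AMINO_ACIDS, code_tables, codon_pair_structure
from .trees import Phylogeny, validate_tree_against_alignment


class NumericalError(ArithmeticError):
    pass


# ---------------------------------------------------------------------------
# frequencies
# ---------------------------------------------------------------------------

@dataclass
class CodonFrequencies:
    """F3x4 codon frequencies: position-specific nucleotide composition."""

    pos_freqs: np.ndarray  # (3, 4) rows sum to 1, columns in TCAG order
    pi: np.ndarray         # (61,) sense-codon frequencies, sums to 1
    table_id: int = 1

    @classmethod
    def uniform(cls, table_id: int = 1) -> "CodonFrequencies":
        n = len(code_tables(table_id)[0])
        return cls(np.full((3, 4), 0.25), np.full(n, 1.0 / n), table_id)

    @classmethod
    def from_pos_freqs(cls, pos_freqs: np.ndarray, table_id: int = 1) -> "CodonFrequencies":
        pos_freqs = np.asarray(pos_freqs, dtype=float)
        pos_freqs = pos_freqs / pos_freqs.sum(axis=1, keepdims=True)
        codons, _, _, _ = code_tables(table_id)
        from .genetic_code import NUC_INDEX
        pi = np.array([
            pos_freqs[0, NUC_INDEX[c[0]]]
            * pos_freqs[1, NUC_INDEX[c[1]]]
            * pos_freqs[2, NUC_INDEX[c[2]]]
            for c in codons])
        total = pi.sum()
        if total <= 0:
            raise ValueError("degenerate position frequencies: all sense codons have mass 0")
        return cls(pos_freqs, pi / total, table_id)


def f3x4_frequencies(aln: CodonAlignment) -> CodonFrequencies:
    """Observed position-specific nucleotide frequencies -> codon frequencies.

    Counts are pooled over taxa; gap/ambiguous codons are skipped. The
    product over positions is restricted to sense codons and renormalised.
    """
    codons, _, _, _ = code_tables(aln.table_id)
    from .genetic_code import NUC_INDEX
    counts = np.zeros((3, 4))
    valid = aln.codons[aln.codons >= 0]
    if valid.size == 0:
        raise ValueError(f"{aln.gene_name}: no unambiguous codons")
    cod_counts = np.bincount(valid, minlength=len(codons))
    for ci, c in enumerate(codons):
        if cod_counts[ci]:
            for pos in range(3):
                counts[pos, NUC_INDEX[c[pos]]] += cod_counts[ci]
    if (counts.sum(axis=1) == 0).any():
        raise ValueError(f"{aln.gene_name}: a codon position has no observed nucleotides")
    return CodonFrequencies.from_pos_freqs(counts, aln.table_id)


# ---------------------------------------------------------------------------
# rate matrices
# ---------------------------------------------------------------------------

@dataclass
class RateMatrix:
    """Normalised reversible generator with a cached spectral decomposition."""

    Q: np.ndarray
    pi: np.ndarray
    scale: float                      # mean rate of the unnormalised generator
    _spec: tuple | None = field(default=None, repr=False, compare=False)

    @property
    def states(self) -> int:
        return self.Q.shape[0]

    def _decompose(self):
        if self._spec is None:
            active = self.pi > 0
            d = np.sqrt(self.pi[active])
            Qa = self.Q[np.ix_(active, active)]
            B = Qa * d[:, None] / d[None, :]
            evals, V = eigh((B + B.T) / 2.0)
            n = self.states
            U = np.zeros((n, evals.size))
            Vinv = np.zeros((evals.size, n))
            U[active] = V / d[:, None]
            Vinv[:, active] = V.T * d[None, :]
            self._spec = (evals, U, Vinv, active)
        return self._spec

    def _expm_batch(self, ts: np.ndarray, weights=None) -> np.ndarray:
        evals, U, Vinv, active = self._decompose()
        E = np.exp(np.multiply.outer(ts, evals))
        if weights is not None:
            E = E * weights[None, :]
        P = np.einsum("ik,tk,kj->tij", U, E, Vinv, optimize=True)
        if not active.all() and weights is None:
            idx = np.nonzero(~active)[0]
            P[:, idx, :] = 0.0
            P[:, idx, idx] = 1.0
        return P

    def transition_batch(self, ts: np.ndarray) -> np.ndarray:
        """P(t) = exp(Qt) for each t, via the symmetric eigendecomposition."""
        ts = np.asarray(ts, dtype=float)
        if (ts < 0).any():
            raise ValueError("branch lengths must be nonnegative")
        P = self._expm_batch(ts)
        np.clip(P, 0.0, None, out=P)
        return P

    def transition(self, t: float) -> np.ndarray:
        return self.transition_batch(np.array([t]))[0]

    def dtransition_batch(self, ts: np.ndarray) -> np.ndarray:
        """dP/dt = Q exp(Qt) for each t."""
        evals, _, _, _ = self._decompose()
        return self._expm_batch(np.asarray(ts, dtype=float), weights=evals)


def transition_matrix(Q: RateMatrix, t: float) -> np.ndarray:
    """Row-stochastic transition-probability matrix P(t) = exp(Qt)."""
    if t < 0:
        raise ValueError("branch length must be >= 0")
    return Q.transition(t)


def build_codon_q(kappa: float, omega: float, freqs: CodonFrequencies) -> RateMatrix:
    """Goldman–Yang codon generator with target-codon frequencies.

    q_ij = pi_j * kappa^[transition] * omega^[nonsynonymous] for single
    nucleotide changes, 0 otherwise; normalised to mean rate 1.
    """
    if kappa <= 0:
        raise ValueError("kappa must be > 0")
    if omega < 0:
        raise ValueError("omega must be >= 0")
    ii, jj, ts, nonsyn = codon_pair_structure(freqs.table_id)
    n = len(freqs.pi)
    Q = np.zeros((n, n))
    rates = freqs.pi[jj] * np.where(ts, kappa, 1.0) * np.where(nonsyn, omega, 1.0)
    Q[ii, jj] = rates
    np.fill_diagonal(Q, 0.0)
    Q[np.arange(n), np.arange(n)] = -Q.sum(axis=1)
    scale = float(-np.dot(freqs.pi, np.diag(Q)))
    if scale <= 0:
        raise ValueError("degenerate codon generator (zero mean rate)")
    return RateMatrix(Q / scale, freqs.pi.copy(), scale)


def substitution_flow(kappa: float, omega: float, freqs: CodonFrequencies):
    """(rho_N, rho_S): shares of nonsynonymous/synonymous flow at mean rate 1."""
    ii, jj, ts, nonsyn = codon_pair_structure(freqs.table_id)
    rates = freqs.pi[ii] * freqs.pi[jj] * np.where(ts, kappa, 1.0) \
        * np.where(nonsyn, omega, 1.0)
    total = rates.sum()
    rho_n = rates[nonsyn].sum() / total
    return rho_n, 1.0 - rho_n


def build_aa_q(exchangeabilities: np.ndarray, f_gene: np.ndarray) -> RateMatrix:
    """Empirical amino-acid generator: q_ij = S_ij * f_j, mean rate 1."""
    S = np.asarray(exchangeabilities, dtype=float)
    f = np.asarray(f_gene, dtype=float)
    if S.shape != (20, 20) or not np.allclose(S, S.T):
        raise ValueError("exchangeability matrix must be symmetric 20x20")
    if (f < 0).any() or not np.isclose(f.sum(), 1.0):
        raise ValueError("f_gene must be nonnegative and sum to 1")
    Q = S * f[None, :]
    np.fill_diagonal(Q, 0.0)
    Q[np.arange(20), np.arange(20)] = -Q.sum(axis=1)
    scale = float(-np.dot(f, np.diag(Q)))
    if scale <= 0:
        raise ValueError("degenerate amino-acid generator")
    return RateMatrix(Q / scale, f.copy(), scale)


@lru_cache(maxsize=8)
def load_empirical_matrix(name: str = "cprev"):
    """Load a bundled PAML-layout empirical matrix.

    Returns (S, freqs): symmetric 20x20 exchangeabilities (zero diagonal) and
    the published equilibrium frequencies. Bundled: cprev (default; estimated
    from chloroplast-encoded proteins), wag, jtt.
    """
    if "/" in name or name.endswith(".dat"):
        text = open(name).read()
    else:
        text = (importlib.resources.files("chloroselect") / "data" /
                f"{name.lower()}.dat").read_text()
    values = [float(x) for line in text.splitlines()
              if line.strip() and not line.startswith("#")
              for x in line.split()]
    if len(values) != 190 + 20:
        raise ValueError(f"matrix file {name!r}: expected 210 numbers, got {len(values)}")
    S = np.zeros((20, 20))
    k = 0
    for i in range(1, 20):
        for j in range(i):
            S[i, j] = S[j, i] = values[k]
            k += 1
    freqs = np.array(values[190:])
    return S, freqs / freqs.sum()


def gene_aa_frequencies(aa_aln: AminoAcidAlignment, pseudocount: float = 0.1) -> np.ndarray:
    """Observed amino-acid frequencies of a gene with a small pseudocount."""
    counts = np.bincount(aa_aln.residues.ravel(), minlength=20).astype(float)
    counts += pseudocount
    return counts / counts.sum()


# ---------------------------------------------------------------------------
# site-class mixtures
# ---------------------------------------------------------------------------

class ClassSpec(NamedTuple):
    """One mixture class: proportion, generators and relative rates.

    ``r_bg``/``r_fg`` rescale branch lengths for this class so that the
    proportion-weighted mean rate over classes is 1 on each branch type
    (codeml convention: branch lengths are expected substitutions per codon
    averaged over site classes, and high-omega classes evolve faster).
    """

    prop: float
    q_bg: "RateMatrix"
    q_fg: "RateMatrix"
    r_bg: float = 1.0
    r_fg: float = 1.0


def _as_class_spec(spec) -> ClassSpec:
    return spec if isinstance(spec, ClassSpec) else ClassSpec(*spec)


@dataclass
class SiteClassMixture:
    """omega-class structure shared by M0/branch/M8/branch-site models.

    Each class is (proportion, background omega, foreground omega); on trees
    without tagged foreground branches only the background omega is used.
    """

    kappa: float
    classes: list[tuple[float, float, float]]
    name: str = "custom"
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        props = np.array([c[0] for c in self.classes])
        if (props < -1e-12).any() or not np.isclose(props.sum(), 1.0, atol=1e-8):
            raise ValueError("class proportions must be nonnegative and sum to 1")

    @classmethod
    def m0(cls, kappa: float, omega: float) -> "SiteClassMixture":
        return cls(kappa, [(1.0, omega, omega)], "M0", {"omega": omega})

    @classmethod
    def branch_two_ratio(cls, kappa: float, omega_bg: float, omega_fg: float):
        return cls(kappa, [(1.0, omega_bg, omega_fg)], "branch",
                   {"omega_bg": omega_bg, "omega_fg": omega_fg})

    @classmethod
    def m8(cls, kappa: float, p0: float, p: float, q: float, omega_s: float,
           ncat: int = 10) -> "SiteClassMixture":
        """p0 of sites with omega ~ discretised Beta(p, q), 1-p0 at omega_s."""
        cats = beta_category_rates(p, q, ncat)
        classes = [(p0 / ncat, w, w) for w in cats] + [(1.0 - p0, omega_s, omega_s)]
        return cls(kappa, classes, "M8",
                   {"p0": p0, "p": p, "q": q, "omega_s": omega_s, "ncat": ncat})

    @classmethod
    def m8a(cls, kappa: float, p0: float, p: float, q: float, ncat: int = 10):
        mix = cls.m8(kappa, p0, p, q, 1.0, ncat)
        mix.name = "M8a"
        return mix

    @classmethod
    def branch_site(cls, kappa: float, p0: float, p1: float, omega0: float,
                    omega2: float) -> "SiteClassMixture":
        """Branch-site model A class structure.

        Classes 0 and 1 are purifying (omega0) and neutral everywhere;
        classes 2a/2b switch to omega2 on foreground branches, with
        proportions (1-p0-p1) split in the p0:p1 ratio.
        """
        if not (0 <= omega0 <= 1):
            raise ValueError("omega0 must lie in [0, 1]")
        if omega2 < 1:
            raise ValueError("omega2 must be >= 1")
        psum = p0 + p1
        if psum <= 0 or psum > 1 + 1e-12:
            raise ValueError("p0 + p1 must lie in (0, 1]")
        rest = max(0.0, 1.0 - psum)
        p2a = rest * p0 / psum
        p2b = rest * p1 / psum
        classes = [(p0, omega0, omega0), (p1, 1.0, 1.0),
                   (p2a, omega0, omega2), (p2b, 1.0, omega2)]
        return cls(kappa, classes, "branch-site",
                   {"p0": p0, "p1": p1, "p2a": p2a, "p2b": p2b,
                    "omega0": omega0, "omega2": omega2})

    def matrices(self, freqs: CodonFrequencies) -> list[ClassSpec]:
        """Class specs with one shared Q per (kappa, omega).

        Generators are cached across calls, so repeated evaluations at the
        same parameters reuse one eigendecomposition, and unchanged classes
        keep identical matrix objects (which downstream caches key on).
        For multi-class mixtures, per-class rate multipliers renormalise the
        proportion-weighted mean rate to 1 on each branch type, so that
        branch lengths are expected substitutions per codon averaged over
        site classes (codeml convention) and high-omega classes evolve
        proportionally faster.
        """
        def get(w):
            key = (id(freqs), self.kappa, w)
            hit = _codon_q_cache.get(key)
            if hit is not None and hit[0] is freqs:
                return hit[1]
            q = build_codon_q(self.kappa, w, freqs)
            if len(_codon_q_cache) > 1024:
                _codon_q_cache.clear()
            _codon_q_cache[key] = (freqs, q)
            return q

        qs = [(p, get(wb), get(wf)) for p, wb, wf in self.classes]
        if len(qs) == 1:
            p, qb, qf = qs[0]
            return [ClassSpec(p, qb, qf)]
        props = np.array([p for p, _, _ in qs])
        s_bg = np.array([qb.scale for _, qb, _ in qs])
        s_fg = np.array([qf.scale for _, _, qf in qs])
        mean_bg = float(props @ s_bg)
        mean_fg = float(props @ s_fg)
        return [ClassSpec(p, qb, qf, sb / mean_bg, sf / mean_fg)
                for (p, qb, qf), sb, sf in zip(qs, s_bg, s_fg)]


_codon_q_cache: dict = {}


def beta_category_rates(p: float, q: float, ncat: int = 10) -> np.ndarray:
    """Median rates of ncat equal-probability Beta(p, q) categories."""
    if p <= 0 or q <= 0:
        raise ValueError("beta shapes must be positive")
    quantiles = (2 * np.arange(ncat) + 1) / (2 * ncat)
    return _beta.ppf(quantiles, p, q)


# ---------------------------------------------------------------------------
# pruning likelihood
# ---------------------------------------------------------------------------

class PruningEngine:
    """Pruning likelihoods over compressed site patterns for one dataset.

    Holds the (taxa x sites) state matrix and the tree structure; models are
    supplied per call as class specifications, so one engine serves every
    model fitted to the same alignment.
    """

    def __init__(self, states: np.ndarray, taxa: list[str], tree: Phylogeny,
                 n_states: int):
        validate_tree_against_alignment(tree, taxa)
        states = np.asarray(states)
        if (states < 0).any():
            raise ValueError("alignment must be cleaned before likelihood computation")
        self.tree = tree
        self.n_states = n_states
        patterns, inverse, counts = np.unique(
            states.T, axis=0, return_inverse=True, return_counts=True)
        self.patterns = patterns.T  # (n_taxa, n_patterns)
        self.site_to_pattern = inverse
        self.weights = counts.astype(float)
        self.n_sites = states.shape[1]
        self.n_patterns = self.patterns.shape[1]
        self.leaf_row = {tree.leaf_index(t): taxa.index(t) for t in taxa}
        self.fg_mask = tree.foreground_mask()
        self.edges = tree.edge_nodes  # nodes with an edge above, postorder

    @classmethod
    def for_codon_alignment(cls, aln: CodonAlignment, tree: Phylogeny):
        n = len(code_tables(aln.table_id)[0])
        return cls(aln.codons, aln.taxa, tree, n)

    @classmethod
    def for_aa_alignment(cls, aln: AminoAcidAlignment, tree: Phylogeny):
        return cls(aln.residues, aln.taxa, tree, 20)

    # -- transition matrices ------------------------------------------------
    def _cached_matrices(self, mat, rate, t_by_node, derivative, cache):
        """Full per-node P (and QP) for one generator at one relative rate.

        P is exp(Q · rate · t); the derivative entry is d/dt = rate · Q · P,
        so downstream gradients are with respect to the nominal branch length.
        """
        key = (id(mat), rate)
        entry = cache.get(key) if cache is not None else None
        if entry is None or (derivative and entry[1] is None):
            ts = rate * t_by_node[self.edges]
            P = np.empty((self.tree.n_nodes, self.n_states, self.n_states))
            P[self.edges] = mat.transition_batch(ts)
            QP = None
            if derivative:
                QP = np.empty_like(P)
                QP[self.edges] = rate * mat.dtransition_batch(ts)
            entry = (P, QP)
            if cache is not None:
                cache[key] = entry
        return entry

    def _edge_matrices(self, spec, t_by_node, derivative=False, cache=None):
        """P (and optionally QP) per node for one class spec."""
        spec = _as_class_spec(spec)
        _, q_bg, q_fg, r_bg, r_fg = spec
        if (q_bg is q_fg and r_bg == r_fg) or not self.fg_mask.any():
            P, QP = self._cached_matrices(q_bg, r_bg, t_by_node, derivative, cache)
            return P, QP
        Pb, QPb = self._cached_matrices(q_bg, r_bg, t_by_node, derivative, cache)
        Pf, QPf = self._cached_matrices(q_fg, r_fg, t_by_node, derivative, cache)
        fg_nodes = np.nonzero(self.fg_mask)[0]
        P = Pb.copy()
        P[fg_nodes] = Pf[fg_nodes]
        QP = None
        if derivative:
            QP = QPb.copy()
            QP[fg_nodes] = QPf[fg_nodes]
        return P, QP

    # -- post-order ----------------------------------------------------------
    def _class_post_order(self, spec, t_by_node, derivative=False,
                          keep_partials=False, cache=None):
        """Post-order partials for one class.

        Returns (site_ll, contribs, D, logscale, P, QP): per-pattern class
        log-likelihood; per-node child contribution arrays (pattern x state);
        scaled node partials; accumulated per-pattern log scalers.
        """
        tree = self.tree
        P, QP = self._edge_matrices(spec, t_by_node, derivative, cache)
        contribs: list = [None] * tree.n_nodes
        D: list = [None] * tree.n_nodes
        logscale = np.zeros(self.n_patterns)
        for node in tree.postorder:
            if tree.is_leaf(node):
                continue
            prod = None
            for c in tree.children[node]:
                if tree.is_leaf(c):
                    contrib = P[c][:, self.patterns[self.leaf_row[c]]].T
                else:
                    contrib = D[c] @ P[c].T
                contribs[c] = contrib
                prod = contrib if prod is None else prod * contrib
            m = prod.max(axis=1)
            bad = m <= 0
            if bad.any():
                m = np.where(bad, 1.0, m)
            prod = prod / m[:, None]
            logscale += np.log(m)
            D[node] = prod
            if not (derivative or keep_partials):
                for c in tree.children[node]:
                    if not tree.is_leaf(c):
                        D[c] = None  # free memory
        pi = spec[1].pi
        root_lik = D[tree.root] @ pi
        if not np.isfinite(root_lik).all():
            site = int(np.nonzero(~np.isfinite(root_lik))[0][0])
            raise NumericalError(f"non-finite site likelihood at pattern {site}")
        # a class may assign zero likelihood to a pattern (e.g. omega = 0
        # forbids nonsynonymous change); only a zero mixture total is an error
        with np.errstate(divide="ignore"):
            site_ll = np.log(root_lik) + logscale
        return site_ll, contribs, D, P, QP

    # -- public likelihood ----------------------------------------------------
    def loglik(self, class_specs, edge_lengths, *, want_sites=False,
               want_grad=False, want_class_sites=False):
        """Mixture log-likelihood, optionally per-site values and d/d(branch).

        ``edge_lengths`` are in ``tree.edge_nodes`` order. The gradient is
        computed analytically via pre-order (up/down) partials and returned
        in the same edge order.
        """
        t_by_node = np.zeros(self.tree.n_nodes)
        t_by_node[self.edges] = edge_lengths
        props = np.array([s[0] for s in class_specs])
        with np.errstate(divide="ignore"):
            logprops = np.log(props)

        # merge classes that share both generators (e.g. 1 and 2b at omega2=1)
        groups: dict[tuple[int, int], int] = {}
        group_of = np.empty(len(class_specs), dtype=int)
        uniq_specs: list = []
        uniq_props: list[float] = []
        for k, spec in enumerate(class_specs):
            spec = _as_class_spec(spec)
            key = (id(spec.q_bg), id(spec.q_fg), spec.r_bg, spec.r_fg)
            if key in groups:
                g = groups[key]
                uniq_props[g] += props[k]
            else:
                g = groups[key] = len(uniq_specs)
                uniq_specs.append(spec)
                uniq_props.append(props[k])
            group_of[k] = g
        uniq_props = np.array(uniq_props)

        cache: dict = {}
        uniq_site = np.empty((len(uniq_specs), self.n_patterns))
        kept = []
        for g, spec in enumerate(uniq_specs):
            if uniq_props[g] == 0 and not want_class_sites:
                uniq_site[g] = -np.inf
                kept.append(None)
                continue
            site_ll, contribs, D, P, QP = self._class_post_order(
                spec, t_by_node, derivative=want_grad, cache=cache)
            uniq_site[g] = site_ll
            kept.append((contribs, D, P, QP) if want_grad else None)

        with np.errstate(divide="ignore"):
            lup = np.log(uniq_props)[:, None]
        mix_ll = logsumexp(uniq_site + lup, axis=0) \
            if len(uniq_specs) > 1 else uniq_site[0] + lup[0]
        if not np.isfinite(mix_ll).all():
            site = int(np.nonzero(~np.isfinite(mix_ll))[0][0])
            raise NumericalError(f"non-positive site likelihood at pattern {site}")
        total = float(np.dot(self.weights, mix_ll))

        out = {"loglik": total}
        if want_sites:
            out["site_loglik"] = mix_ll[self.site_to_pattern]
        if want_class_sites:
            class_site = uniq_site[group_of]
            out["class_site_loglik"] = class_site[:, self.site_to_pattern]
            out["class_site_pattern_loglik"] = class_site
        if want_grad:
            post = np.exp(uniq_site + lup - mix_ll[None, :])
            grad = np.zeros(len(self.edges))
            for g, spec in enumerate(uniq_specs):
                if kept[g] is None:
                    continue
                contribs, D, P, QP = kept[g]
                ratios = self._edge_ratios(spec, contribs, D, P, QP)
                grad += ratios @ (self.weights * post[g])
            out["gradient"] = grad
        return out

    def _edge_ratios(self, spec, contribs, D, P, QP):
        """d(log class-site-likelihood)/dt per edge: (n_edges, n_patterns)."""
        tree = self.tree
        pi = spec[1].pi
        # pre-order "above" partials A[node]: outside-subtree likelihood rows
        A: list = [None] * tree.n_nodes
        A[tree.root] = np.broadcast_to(pi, (self.n_patterns, self.n_states))
        ratios = np.zeros((len(self.edges), self.n_patterns))
        edge_pos = {int(n): e for e, n in enumerate(self.edges)}
        for node in reversed(tree.postorder):
            if tree.is_leaf(node):
                continue
            kids = tree.children[node]
            cons = [contribs[c] for c in kids]
            # prefix/suffix products over siblings
            n_k = len(kids)
            prefix = [None] * (n_k + 1)
            prefix[0] = A[node]
            for i in range(n_k):
                prefix[i + 1] = prefix[i] * cons[i]
            suffix = np.ones_like(cons[0])
            for i in range(n_k - 1, -1, -1):
                G = prefix[i] * suffix
                c = kids[i]
                if tree.is_leaf(c):
                    dcon = QP[c][:, self.patterns[self.leaf_row[c]]].T
                else:
                    dcon = D[c] @ QP[c].T
                denom = np.einsum("hi,hi->h", G, cons[i])
                numer = np.einsum("hi,hi->h", G, dcon)
                with np.errstate(divide="ignore", invalid="ignore"):
                    r = np.where(denom > 0, numer / np.where(denom > 0, denom, 1.0), 0.0)
                ratios[edge_pos[c]] = r
                if not tree.is_leaf(c):
                    Anew = G @ P[c]
                    m = Anew.max(axis=1)
                    m = np.where(m <= 0, 1.0, m)
                    A[c] = Anew / m[:, None]
                suffix = suffix * cons[i]
        return ratios

    def node_posteriors(self, class_specs, edge_lengths):
        """Marginal state posteriors at every internal node, per site.

        Mixture classes are integrated with their proportions. Returns an
        array (n_nodes, n_sites, n_states) with NaN rows at leaves.
        """
        t_by_node = np.zeros(self.tree.n_nodes)
        t_by_node[self.edges] = edge_lengths
        tree = self.tree
        props = np.array([s[0] for s in class_specs])
        with np.errstate(divide="ignore"):
            logprops = np.log(props)
        # pass 1: class posterior weights per pattern
        class_ll = np.full((len(class_specs), self.n_patterns), -np.inf)
        for k, spec in enumerate(class_specs):
            if props[k] > 0:
                class_ll[k] = self._class_post_order(spec, t_by_node)[0]
        mix = logsumexp(class_ll + logprops[:, None], axis=0)
        class_post = np.exp(class_ll + logprops[:, None] - mix[None, :])
        # pass 2: state posteriors per node, weighted by class posteriors
        post_sum = np.zeros((tree.n_nodes, self.n_patterns, self.n_states))
        for k, spec in enumerate(class_specs):
            if props[k] == 0:
                continue
            _, contribs, D, P, _ = self._class_post_order(
                spec, t_by_node, derivative=False, keep_partials=True)
            pi = spec[1].pi
            A: list = [None] * tree.n_nodes
            A[tree.root] = np.broadcast_to(pi, (self.n_patterns, self.n_states))
            class_w = class_post[k]
            for node in reversed(tree.postorder):
                if tree.is_leaf(node):
                    continue
                joint = A[node] * D[node]
                norm = joint.sum(axis=1, keepdims=True)
                post_sum[node] += class_w[:, None] * joint / np.where(norm > 0, norm, 1.0)
                kids = tree.children[node]
                cons = [contribs[c] for c in kids]
                n_k = len(kids)
                prefix = [None] * (n_k + 1)
                prefix[0] = A[node]
                for i in range(n_k):
                    prefix[i + 1] = prefix[i] * cons[i]
                suffix = np.ones_like(cons[0])
                for i in range(n_k - 1, -1, -1):
                    c = kids[i]
                    if not tree.is_leaf(c):
                        G = prefix[i] * suffix
                        Anew = G @ P[c]
                        m = Anew.max(axis=1)
                        m = np.where(m <= 0, 1.0, m)
                        A[c] = Anew / m[:, None]
                    suffix = suffix * cons[i]
        post = post_sum
        full = np.full((tree.n_nodes, self.n_sites, self.n_states), np.nan)
        internal = [i for i in range(tree.n_nodes) if not tree.is_leaf(i)]
        for i in internal:
            full[i] = post[i][self.site_to_pattern]
        return full


def tree_loglik(aln, tree: Phylogeny, *, mixture: SiteClassMixture | None = None,
                rate_matrix: RateMatrix | None = None,
                freqs: CodonFrequencies | None = None,
                branch_lengths: np.ndarray | None = None,
                return_site: bool = False):
    """Total (and optionally per-site) log-likelihood on a fixed tree.

    Codon alignments require a :class:`SiteClassMixture` (frequencies default
    to F3x4 from the data); amino-acid alignments require a single
    :class:`RateMatrix`.
    """
    if isinstance(aln, CodonAlignment):
        if mixture is None:
            raise ValueError("codon alignments need a SiteClassMixture")
        if freqs is None:
            freqs = f3x4_frequencies(aln)
        engine = PruningEngine.for_codon_alignment(aln, tree)
        specs = mixture.matrices(freqs)
    elif isinstance(aln, AminoAcidAlignment):
        if rate_matrix is None:
            raise ValueError("amino-acid alignments need a RateMatrix")
        engine = PruningEngine.for_aa_alignment(aln, tree)
        specs = [(1.0, rate_matrix, rate_matrix)]
    else:
        raise TypeError(f"unsupported alignment type {type(aln).__name__}")
    t = tree.edge_lengths() if branch_lengths is None else np.asarray(branch_lengths)
    res = engine.loglik(specs, t, want_sites=return_site)
    if return_site:
        return res["loglik"], res["site_loglik"]
    return res["loglik"]


def amino_acid_label(index: int) -> str:
    return AMINO_ACIDS[index]
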