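"""Independent oracles used by the test suite.

These deliberately avoid the package's pruning/FDR code paths: likelihoods
are computed by brute-force enumeration over internal-node states, and
Benjamini-Hochberg by the textbook step-up recursion.
"""

from __future__ import annotations

import itertools

import numpy as np

from chloroselect.ctmc import _as_class_spec


def enum_class_site_likelihoods(states, taxa, tree, spec, branch_lengths):
    """Per-site likelihood of one mixture class by exhaustive enumeration.

    ``states`` is the (n_taxa, n_sites) integer matrix; every assignment of
    states to internal nodes is summed explicitly.
    """
    spec = _as_class_spec(spec)
    fg = tree.foreground_mask()
    edges = [int(e) for e in tree.edge_nodes]
    t_by_node = np.zeros(tree.n_nodes)
    t_by_node[tree.edge_nodes] = np.asarray(branch_lengths, dtype=float)
    P = {}
    for node in edges:
        mat, rate = (spec.q_fg, spec.r_fg) if fg[node] else (spec.q_bg, spec.r_bg)
        P[node] = mat.transition(rate * t_by_node[node])
    pi = spec.q_bg.pi
    n_states = pi.size
    internal = [i for i in range(tree.n_nodes) if not tree.is_leaf(i)]
    leaf_row = {i: taxa.index(tree.labels[i]) for i in tree.leaves}
    parent = tree.parent
    n_sites = states.shape[1]
    out = np.zeros(n_sites)
    for s in range(n_sites):
        leaf_state = {leaf: int(states[row, s]) for leaf, row in leaf_row.items()}
        lik = 0.0
        for assign in itertools.product(range(n_states), repeat=len(internal)):
            node_state = dict(zip(internal, assign))
            node_state.update(leaf_state)
            p = pi[node_state[tree.root]]
            for node in edges:
                p *= P[node][node_state[parent[node]], node_state[node]]
            lik += p
        out[s] = lik
    return out


def enum_loglik(aln, tree, mixture, freqs, branch_lengths=None):
    """Total and per-site mixture log-likelihood by exhaustive enumeration."""
    specs = [_as_class_spec(s) for s in mixture.matrices(freqs)]
    t = tree.edge_lengths() if branch_lengths is None \
        else np.asarray(branch_lengths, dtype=float)
    site_lik = np.zeros(aln.n_sites)
    for spec in specs:
        if spec.prop == 0.0:
            continue
        site_lik += spec.prop * enum_class_site_likelihoods(
            aln.codons, aln.taxa, tree, spec, t)
    site_ll = np.log(site_lik)
    return float(site_ll.sum()), site_ll


def bh_textbook(p_values):
    """Benjamini-Hochberg step-up q-values via the textbook recursion."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        prev = min(prev, p[i] * m / rank)
        q[i] = prev
    return q
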