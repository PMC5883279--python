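"""Likelihood-ratio tests, FDR correction, and empirical-Bayes site inference.

Nested model pairs (one-ratio vs branch, M8a vs M8, branch-site null vs
alternative) are compared with 2δ(lnL) against a χ² distribution (df = 1 by
default, plain χ² rather than the 50:50 boundary mixture; the mixture
p-value is available behind a flag). Benjamini–Hochberg FDR is applied per
test family — all genes tested for one comparison type and foreground
lineage. Positively selected sites come from Bayes empirical Bayes (BEB):
the posterior probability of the positive-selection class(es) is averaged
over a uniform-prior grid of the proportion parameters and omega2, holding
kappa, omega0 and branch lengths at their MLEs. Naive empirical Bayes (NEB)
evaluates the same posterior at the MLEs only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from .alnio import CodonAlignment
from .genetic_code import AMINO_ACIDS, translate_codon_indices
from .ctmc import ClassSpec, PruningEngine, SiteClassMixture, f3x4_frequencies
from .model_fit import FitResult, OMEGA_MAX
from .trees import Phylogeny

#: default upper edge of the omega2 BEB grid (the grid covers (1, bound])
BEB_OMEGA2_BOUND = 11.0


class NestingViolationError(ValueError):
    """Alternative model fits worse than its null beyond tolerance."""


@dataclass
class LRTRecord:
    dataset_id: str
    comparison: str               # "branch" | "M8-vs-M8a" | "branch-site"
    foreground: str               # foreground label(s) or "" for site tests
    lnL_null: float
    lnL_alt: float
    stat: float
    df: int
    p_value: float
    q_value: float | None = None
    significant: bool | None = None


@dataclass
class BEBSiteRecord:
    dataset_id: str
    site: int                     # 1-based alignment position
    pp_positive: float
    flagged: bool
    map_residue: str


def lrt(lnl_null: float, lnl_alt: float, df: int, *, mixture: bool = False,
        tol: float = 1e-6):
    """Likelihood-ratio statistic and χ² p-value for nested models.

    Inputs are maximized log-likelihoods (callers holding −lnL negate
    first). A statistic negative beyond ``tol`` raises
    NestingViolationError; within tolerance it is clamped to 0. With
    ``mixture`` the 50:50 boundary mixture χ²(df−1):χ²(df) is used instead
    of plain χ²(df).
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    stat = 2.0 * (lnl_alt - lnl_null)
    if stat < -tol:
        raise NestingViolationError(
            f"alternative lnL {lnl_alt} below null lnL {lnl_null} "
            f"(2dlnL = {stat:.6g})")
    stat = max(stat, 0.0)
    if mixture:
        lower = 1.0 if stat <= 0 else (
            chi2.sf(stat, df - 1) if df > 1 else 0.0)
        p = 0.5 * lower + 0.5 * chi2.sf(stat, df)
    else:
        p = float(chi2.sf(stat, df))
    if stat == 0.0:
        p = 1.0
    return stat, min(p, 1.0)


def fdr_bh(p_values) -> np.ndarray:
    """Benjamini–Hochberg adjusted q-values, order-preserving."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def lrt_record(dataset_id: str, comparison: str, null_fit: FitResult,
               alt_fit: FitResult, *, df: int = 1, foreground: str = "",
               mixture: bool = False) -> LRTRecord:
    stat, p = lrt(null_fit.lnL, alt_fit.lnL, df, mixture=mixture)
    return LRTRecord(dataset_id, comparison, foreground,
                     null_fit.lnL, alt_fit.lnL, stat, df, p)


def attach_fdr(records: list[LRTRecord], alpha: float = 0.05) -> list[LRTRecord]:
    """Fill q_value/significant across one test family (in place)."""
    if records:
        q = fdr_bh([r.p_value for r in records])
        for r, qv in zip(records, q):
            r.q_value = float(qv)
            r.significant = bool(qv < alpha)
    return records


# ---------------------------------------------------------------------------
# empirical Bayes site inference
# ---------------------------------------------------------------------------

def _positive_class_indices(mixture: SiteClassMixture) -> list[int]:
    if mixture.name == "branch-site":
        return [2, 3]
    if mixture.name == "M8":
        return [len(mixture.classes) - 1]
    raise ValueError(
        f"site inference requires an M8 or branch-site model, got {mixture.name!r}")


def _mixture_from_fit(fit: FitResult) -> SiteClassMixture:
    p = fit.params
    if fit.model_id in ("BS_alt", "BS_null"):
        return SiteClassMixture.branch_site(
            p["kappa"], p["p0"], p["p1"], p["omega0"], p.get("omega2", 1.0))
    if fit.model_id == "M8":
        return SiteClassMixture.m8(p["kappa"], p["p0"], p["p"], p["q"],
                                   p["omega_s"])
    if fit.model_id == "M8a":
        return SiteClassMixture.m8a(p["kappa"], p["p0"], p["p"], p["q"])
    raise ValueError(f"no site-class mixture for model {fit.model_id!r}")


def _class_posteriors(engine: PruningEngine, mixture, freqs, t):
    """(class posteriors per pattern, class log-likelihood matrix)."""
    specs = mixture.matrices(freqs)
    res = engine.loglik(specs, t, want_class_sites=True)
    class_ll = res["class_site_pattern_loglik"]
    props = np.array([c[0] for c in mixture.classes])
    with np.errstate(divide="ignore"):
        lp = np.log(props)[:, None]
    mix = logsumexp(class_ll + lp, axis=0)
    post = np.exp(class_ll + lp - mix[None, :])
    return post, class_ll, mix


def naive_eb_sites(fit: FitResult, aln: CodonAlignment, tree: Phylogeny,
                   foreground: set[str] | None = None) -> np.ndarray:
    """NEB: per-site class posteriors at the MLEs (n_sites x n_classes)."""
    mixture = _mixture_from_fit(fit)
    fg = foreground or set(fit.params.get("_foreground", ()))
    engine = PruningEngine.for_codon_alignment(
        aln, tree.with_foreground(fg) if fg else tree)
    freqs = f3x4_frequencies(aln)
    post, _, _ = _class_posteriors(engine, mixture, freqs, fit.branch_lengths)
    return post.T[engine.site_to_pattern]


def _foreground_residues(aln: CodonAlignment, foreground: set[str]) -> list[str]:
    """Most-probable (observed) amino acid of the foreground taxon per site."""
    taxa = [t for t in sorted(foreground) if t in aln.taxa]
    if not taxa:
        return [""] * aln.n_sites
    codons = aln.row(taxa[0])
    out = []
    for c in codons:
        if c < 0:
            out.append("-")
        else:
            out.append(AMINO_ACIDS[translate_codon_indices(
                np.array([c]), aln.table_id)[0]])
    return out


def beb_sites(bs_alt: FitResult, aln: CodonAlignment, tree: Phylogeny,
              foreground: set[str] | None = None, *, pp_threshold: float = 0.95,
              n_grid: int = 10, omega2_bound: float = BEB_OMEGA2_BOUND,
              ) -> list[BEBSiteRecord]:
    """Bayes empirical Bayes site posteriors for the branch-site alternative.

    The grid places ``n_grid`` uniform-prior values on each of the triangle
    proportion coordinates a = p0 + p1 and b = p0/(p0 + p1) (category
    midpoints on (0, 1)) and on omega2 over (1, omega2_bound]; kappa, omega0
    and branch lengths stay at their MLEs. Grid weights are proportional to
    the data likelihood; the reported pp is the weighted average posterior
    of the foreground positive-selection classes (2a + 2b).
    """
    if bs_alt.model_id != "BS_alt":
        raise ValueError(f"beb_sites requires a branch-site alternative fit, "
                         f"got {bs_alt.model_id!r}")
    fg = foreground or set(bs_alt.params.get("_foreground", ()))
    engine = PruningEngine.for_codon_alignment(aln, tree.with_foreground(fg))
    freqs = f3x4_frequencies(aln)
    t = bs_alt.branch_lengths
    kappa = bs_alt.params["kappa"]
    omega0 = bs_alt.params["omega0"]

    mids = (2 * np.arange(n_grid) + 1) / (2 * n_grid)
    omega2_grid = 1.0 + mids * (omega2_bound - 1.0)

    # Class relative rates are held at the MLE mixture's values (like kappa,
    # omega0 and branch lengths), so class log-likelihoods depend only on
    # (omega_bg, omega_fg): the classes are (w0,w0), (1,1), (w0,w2), (1,w2),
    # and 2 + 2*n_grid pruning passes cover the whole (a, b, w2) grid.
    mle_specs = _mixture_from_fit(bs_alt).matrices(freqs)
    class_rates = [(s.r_bg, s.r_fg) for s in mle_specs]
    t_by_node = np.zeros(engine.tree.n_nodes)
    t_by_node[engine.edges] = t
    ll_cache: dict = {}
    cache: dict = {}

    def class_ll(wb, wf, rates):
        key = (wb, wf, rates)
        if key not in ll_cache:
            q = SiteClassMixture(kappa, [(1.0, wb, wf)]).matrices(freqs)[0]
            spec = ClassSpec(1.0, q.q_bg, q.q_fg, *rates)
            ll_cache[key] = engine._class_post_order(spec, t_by_node,
                                                     cache=cache)[0]
        return ll_cache[key]

    weights = engine.weights
    log_w = []
    post_pos = []
    for w2 in omega2_grid:
        L = np.vstack([class_ll(omega0, omega0, class_rates[0]),
                       class_ll(1.0, 1.0, class_rates[1]),
                       class_ll(omega0, w2, class_rates[2]),
                       class_ll(1.0, w2, class_rates[3])])
        for a in mids:
            for b in mids:
                props = np.array([a * b, a * (1 - b),
                                  (1 - a) * b, (1 - a) * (1 - b)])
                lp = np.log(props)[:, None]
                mix = logsumexp(L + lp, axis=0)
                log_w.append(float(np.dot(weights, mix)))
                post_pos.append(np.exp(logsumexp(L[2:] + lp[2:], axis=0) - mix))
    log_w = np.array(log_w)
    gw = np.exp(log_w - logsumexp(log_w))
    pp_pattern = gw @ np.vstack(post_pos)
    pp = pp_pattern[engine.site_to_pattern]

    residues = _foreground_residues(aln, fg)
    return [BEBSiteRecord(bs_alt.dataset_id, i + 1, float(p),
                          bool(p >= pp_threshold), residues[i])
            for i, p in enumerate(pp)]


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def format_beb_sites(records: list[BEBSiteRecord]) -> str:
    """Flagged sites as 'site–pp' to 3 decimals, comma-separated."""
    return ", ".join(f"{r.site}–{r.pp_positive:.3f}"
                     for r in records if r.flagged)


def family_report(records: list[LRTRecord],
                  beb_by_dataset: dict[str, list[BEBSiteRecord]] | None = None,
                  omega_summaries: dict[str, str] | None = None) -> str:
    """TSV table for one test family (gene, lnL pair, 2δ(lnL), p, q, sites)."""
    header = ["gene", "comparison", "foreground", "lnL_null", "lnL_alt",
              "2dlnL", "df", "p_value", "q_value", "significant",
              "omega_summary", "beb_sites"]
    lines = ["\t".join(header)]
    for r in records:
        beb = format_beb_sites((beb_by_dataset or {}).get(r.dataset_id, []))
        omega = (omega_summaries or {}).get(r.dataset_id, "")
        q = "" if r.q_value is None else f"{r.q_value:.6g}"
        sig = "" if r.significant is None else str(r.significant)
        lines.append("\t".join([
            r.dataset_id, r.comparison, r.foreground,
            f"{r.lnL_null:.6f}", f"{r.lnL_alt:.6f}", f"{r.stat:.6f}",
            str(r.df), f"{r.p_value:.6g}", q, sig, omega, beb]))
    return "\n".join(lines) + "\n"
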