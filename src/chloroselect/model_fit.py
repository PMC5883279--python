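"""Maximum-likelihood fitting of codon models (M0, branch, M8/M8a, branch-site).

All models are fitted by bounded quasi-Newton (L-BFGS-B) jointly over the
substitution parameters and all branch lengths. Branch-length gradients are
analytic (up/down pruning); gradients of the handful of substitution
parameters use forward finite differences. Each model is optimised from the
configured starting omega values (default 0.5, 1, 2) and the best
log-likelihood wins, ties broken by the lowest start for determinism.

Per-branch dN and dS follow the codeml convention: the normalised generator
splits branch length into synonymous and nonsynonymous flow, and the
proportions of synonymous/nonsynonymous sites come from the omega = 1
counterpart matrix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.optimize import minimize

from .alnio import CodonAlignment
from .ctmc import (CodonFrequencies, PruningEngine, SiteClassMixture,
                   f3x4_frequencies, substitution_flow)
from .trees import Phylogeny

BL_BOUNDS = (1e-6, 50.0)
OMEGA_MAX = 999.0
KAPPA_BOUNDS = (0.05, 99.0)
DEFAULT_STARTS = (0.5, 1.0, 2.0)


@dataclass
class FitResult:
    model_id: str
    dataset_id: str
    lnL: float
    params: dict
    branch_names: list[str]
    branch_lengths: np.ndarray
    per_branch_dnds: dict | None = None
    starts_used: list[float] = field(default_factory=list)
    converged: bool = True
    boundary_flags: list[str] = field(default_factory=list)
    identifiable: bool = True
    n_evaluations: int = 0

    def to_json(self) -> str:
        d = asdict(self)
        d["branch_lengths"] = [float(x) for x in self.branch_lengths]
        if self.per_branch_dnds is not None:
            d["per_branch_dnds"] = {k: {kk: float(vv) for kk, vv in v.items()}
                                    for k, v in self.per_branch_dnds.items()}
        return json.dumps(d, indent=1)

    def summary(self) -> str:
        lines = [f"model {self.model_id}  dataset {self.dataset_id}",
                 f"lnL = {self.lnL:.6f}   (starts {self.starts_used}, "
                 f"converged={self.converged})"]
        lines.append("params: " + ", ".join(f"{k}={v:.6g}" for k, v in self.params.items()))
        if self.boundary_flags:
            lines.append("boundary: " + ", ".join(self.boundary_flags))
        for name, t in zip(self.branch_names, self.branch_lengths):
            lines.append(f"  {name}: t={t:.5f}")
        return "\n".join(lines)


class _Objective:
    """Negative log-likelihood over [model params..., branch lengths...].

    Branch-length gradients are analytic. Substitution-parameter gradients
    use forward differences, recomputing pruning only for the mixture
    classes whose generator actually changed under the perturbation;
    parameters that move class proportions alone cost nothing extra.
    """

    def __init__(self, engine: PruningEngine, freqs: CodonFrequencies,
                 build_mixture, n_model: int, fd_step: float = 1e-5):
        self.engine = engine
        self.freqs = freqs
        self.build_mixture = build_mixture
        self.n_model = n_model
        self.fd_step = fd_step
        self.n_eval = 0

    def _mixture(self, theta) -> SiteClassMixture:
        return self.build_mixture(np.asarray(theta, dtype=float))

    def _combine(self, props, class_ll):
        with np.errstate(divide="ignore"):
            lp = np.log(np.maximum(props, 0.0))[:, None]
        if class_ll.shape[0] == 1:
            mix = class_ll[0] + lp[0]
        else:
            from scipy.special import logsumexp
            mix = logsumexp(class_ll + lp, axis=0)
        return float(np.dot(self.engine.weights, mix)), mix

    def _class_ll(self, mixture, t, cache=None):
        """Per-class pattern log-likelihoods, deduplicating identical classes.

        ``cache`` holds transition matrices keyed by generator; within one
        objective call (fixed branch lengths) it is shared across classes and
        across finite-difference perturbations.
        """
        specs = mixture.matrices(self.freqs)
        t_by_node = np.zeros(self.engine.tree.n_nodes)
        t_by_node[self.engine.edges] = t
        out = np.empty((len(specs), self.engine.n_patterns))
        done: dict = {}
        for k, spec in enumerate(specs):
            key = (id(spec.q_bg), id(spec.q_fg), spec.r_bg, spec.r_fg)
            if key in done:
                out[k] = out[done[key]]
                continue
            out[k] = self.engine._class_post_order(spec, t_by_node, cache=cache)[0]
            done[key] = k
            self.n_eval += 1
        return out

    def value(self, x):
        theta, t = x[:self.n_model], x[self.n_model:]
        mixture = self._mixture(theta)
        class_ll = self._class_ll(mixture, t)
        props = np.array([c[0] for c in mixture.classes])
        return -self._combine(props, class_ll)[0]

    def _param_grad(self, theta, t, bounds, mixture, class_ll, f0, mix, cache):
        """Forward-difference gradient over the substitution parameters.

        Parameters that only move class proportions get the analytic gradient
        from the per-class likelihoods; otherwise only the classes whose
        generator changed are re-pruned, against the shared transition cache.
        """
        grad = np.empty(self.n_model)
        props = np.array([c[0] for c in mixture.classes])
        dl_dp = (np.exp(class_ll - mix[None, :]) * self.engine.weights).sum(axis=1)

        def spec_keys(specs):
            return [(id(s.q_bg), id(s.q_fg), s.r_bg, s.r_fg) for s in specs]

        base_keys = spec_keys(mixture.matrices(self.freqs))
        t_by_node = np.zeros(self.engine.tree.n_nodes)
        t_by_node[self.engine.edges] = t
        for i in range(self.n_model):
            lo, hi = bounds[i]
            if hi - lo < 1e-9:
                grad[i] = 0.0
                continue
            h = self.fd_step * max(1.0, abs(theta[i]))
            if theta[i] + h > hi:
                h = -h
            theta_p = np.array(theta, dtype=float)
            theta_p[i] = theta[i] + h
            mix_p = self._mixture(theta_p)
            specs_p = mix_p.matrices(self.freqs)
            props_p = np.array([c[0] for c in mix_p.classes])
            keys_p = spec_keys(specs_p)
            if keys_p == base_keys:  # only the mixing proportions moved
                grad[i] = -float(np.dot(dl_dp, (props_p - props) / h))
                continue
            if len(keys_p) == len(base_keys):
                ll_p = class_ll.copy()
                done: dict = {}
                for k, key in enumerate(keys_p):
                    if key == base_keys[k]:
                        continue
                    if key in done:
                        ll_p[k] = ll_p[done[key]]
                        continue
                    ll_p[k] = self.engine._class_post_order(
                        specs_p[k], t_by_node, cache=cache)[0]
                    done[key] = k
                    self.n_eval += 1
            else:
                ll_p = self._class_ll(mix_p, t, cache=cache)
            grad[i] = (-self._combine(props_p, ll_p)[0] - f0) / h
        return grad

    def value_and_grad(self, x, bounds):
        theta, t = x[:self.n_model], x[self.n_model:]
        mixture = self._mixture(theta)
        specs = mixture.matrices(self.freqs)
        res = self.engine.loglik(specs, t, want_grad=True, want_class_sites=True)
        self.n_eval += len(specs)
        f0 = -res["loglik"]
        class_ll = res["class_site_pattern_loglik"]
        props = np.array([c[0] for c in mixture.classes])
        _, mix = self._combine(props, class_ll)
        grad = np.empty_like(x)
        grad[self.n_model:] = -res["gradient"]
        grad[:self.n_model] = self._param_grad(theta, t, bounds, mixture,
                                               class_ll, f0, mix, cache={})
        return f0, grad

    def model_only_value_and_grad(self, theta, t, bounds):
        """Objective restricted to substitution parameters at fixed branch lengths."""
        cache: dict = {}
        mixture = self._mixture(theta)
        class_ll = self._class_ll(mixture, t, cache=cache)
        props = np.array([c[0] for c in mixture.classes])
        f0_pos, mix = self._combine(props, class_ll)
        f0 = -f0_pos
        grad = self._param_grad(theta, t, bounds, mixture, class_ll, f0, mix, cache)
        return f0, grad


def _run_lbfgs(obj: _Objective, x0, bounds, maxfun=2000, two_stage=False):
    """Quasi-Newton fit; optionally a cheap model-parameter stage first.

    The model-only stage moves the handful of substitution parameters at
    fixed branch lengths (no gradient pruning passes), after which the joint
    stage usually needs far fewer iterations.
    """
    if two_stage and obj.n_model > 0:
        nm = obj.n_model
        t_fixed = np.array(x0[nm:])
        stage1 = minimize(
            lambda th: obj.model_only_value_and_grad(th, t_fixed, bounds[:nm]),
            x0[:nm], jac=True, method="L-BFGS-B", bounds=bounds[:nm],
            options={"maxfun": maxfun, "ftol": 1e-10, "gtol": 1e-6})
        x0 = np.concatenate([stage1.x, t_fixed])
    res = minimize(lambda x: obj.value_and_grad(x, bounds), x0, jac=True,
                   method="L-BFGS-B", bounds=bounds,
                   options={"maxfun": maxfun, "ftol": 1e-10, "gtol": 1e-6})
    return res


def _fit_family(aln: CodonAlignment, tree: Phylogeny, *, model_id, dataset_id,
                param_defs, build_mixture, starts, freqs=None,
                init_bl=None, init_overrides=None, maxfun=2000,
                two_stage=False) -> FitResult:
    """Shared multi-start driver.

    param_defs: list of (name, bounds, start_fn) where start_fn(omega_start)
    gives the initial value of that parameter for a given starting omega.
    """
    if freqs is None:
        freqs = f3x4_frequencies(aln)
    engine = PruningEngine.for_codon_alignment(aln, tree)
    n_model = len(param_defs)
    obj = _Objective(engine, freqs, build_mixture, n_model)
    t0 = tree.edge_lengths(default=0.1) if init_bl is None else np.asarray(init_bl, float)
    t0 = np.clip(t0, BL_BOUNDS[0], BL_BOUNDS[1])
    bounds = [pd[1] for pd in param_defs] + [BL_BOUNDS] * len(t0)

    variable = engine.n_patterns > 1 or np.ptp(engine.patterns[:, 0]) > 0
    best = None
    best_start = None
    any_converged = False
    for w_start in starts:
        x0 = np.array([pd[2](w_start) for pd in param_defs] + list(t0))
        if init_overrides:
            for i, v in init_overrides.items():
                x0[i] = v
        x0 = np.clip(x0, [b[0] for b in bounds], [b[1] for b in bounds])
        res = _run_lbfgs(obj, x0, bounds, maxfun=maxfun, two_stage=two_stage)
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun - 1e-9:
            best, best_start = res, w_start
    x = best.x
    params = {pd[0]: float(v) for pd, v in zip(param_defs, x[:n_model])}
    flags = []
    for (name, (lo, hi), _), v in zip(param_defs, x[:n_model]):
        if hi - v < 1e-6 * max(1.0, abs(hi)) and np.isfinite(hi):
            flags.append(f"{name} at upper bound {hi}")
        if name.startswith("omega") and v - lo < 1e-7 and lo > 0:
            flags.append(f"{name} at lower bound {lo}")
    bl = x[n_model:]
    names = [tree.edge_name(i) for i in tree.edge_nodes]
    return FitResult(model_id, dataset_id, -float(best.fun), params, names, bl,
                     starts_used=list(starts), converged=any_converged,
                     boundary_flags=flags, identifiable=bool(variable),
                     n_evaluations=obj.n_eval), best_start


def fit_m0(aln: CodonAlignment, tree: Phylogeny, *, starts=DEFAULT_STARTS,
           freqs=None, dataset_id=None, maxfun=2000) -> FitResult:
    """One omega for all sites and branches; joint kappa/omega/branch-length ML."""
    defs = [("kappa", KAPPA_BOUNDS, lambda w: 2.0),
            ("omega", (1e-6, OMEGA_MAX), lambda w: w)]
    fit, _ = _fit_family(
        aln, tree, model_id="M0", dataset_id=dataset_id or aln.gene_name,
        param_defs=defs,
        build_mixture=lambda th: SiteClassMixture.m0(th[0], th[1]),
        starts=starts, freqs=freqs, maxfun=maxfun)
    fit.per_branch_dnds = decompose_dnds(fit, freqs or f3x4_frequencies(aln))
    return fit


def decompose_dnds(fit: FitResult, freqs: CodonFrequencies) -> dict:
    """Per-branch (dN, dS, omega) from the normalised generator.

    t * rho_N substitutions per codon are nonsynonymous; dividing by three
    times the nonsynonymous site fraction (from the omega = 1 matrix) gives
    dN per nonsynonymous site, and likewise dS.
    """
    kappa = fit.params["kappa"]
    f_n, f_s = substitution_flow(kappa, 1.0, freqs)
    out = {}
    for name, t in zip(fit.branch_names, fit.branch_lengths):
        omega = fit.params.get("omega")
        if omega is None:  # branch model: foreground branches get omega_fg
            omega = fit.params["omega_fg"] if name in fit.params.get(
                "_foreground", ()) else fit.params["omega_bg"]
        rho_n, rho_s = substitution_flow(kappa, omega, freqs)
        dn = t * rho_n / (3.0 * f_n)
        ds = t * rho_s / (3.0 * f_s)
        out[name] = {"t": float(t), "dN": float(dn), "dS": float(ds),
                     "omega": float(omega),
                     "dNdS": float(dn / ds) if ds > 0 else float("nan")}
    return out


def filter_genes_by_ds(fits: list[FitResult], threshold: float = 1.0):
    """Retain genes whose maximum per-branch dS is below the threshold.

    Genes with saturated synonymous divergence are discarded to avoid dN/dS
    misestimation; the offending branch is recorded for each discard.
    """
    retained, discarded = [], []
    for fit in fits:
        if not fit.per_branch_dnds:
            raise ValueError(f"{fit.dataset_id}: fit has no per-branch dN/dS")
        worst = max(fit.per_branch_dnds.items(), key=lambda kv: kv[1]["dS"])
        if worst[1]["dS"] < threshold:
            retained.append(fit.dataset_id)
        else:
            discarded.append((fit.dataset_id, worst[0], worst[1]["dS"]))
    return retained, discarded


def fit_branch_model(aln: CodonAlignment, tree: Phylogeny, foreground: set[str],
                     *, starts=DEFAULT_STARTS, freqs=None, dataset_id=None,
                     m0: FitResult | None = None, maxfun=2000):
    """Two-ratio branch model versus the one-ratio null (M0).

    Returns (null, alternative). The alternative gives the foreground
    branches their own omega.
    """
    if not foreground:
        raise ValueError("foreground branch set is empty")
    fg_tree = tree.with_foreground(foreground)
    if fg_tree.foreground_mask()[fg_tree.edge_nodes].all():
        raise ValueError("foreground covers every branch; model collapses to M0")
    if freqs is None:
        freqs = f3x4_frequencies(aln)
    null = m0 if m0 is not None else fit_m0(
        aln, tree, starts=starts, freqs=freqs, dataset_id=dataset_id, maxfun=maxfun)
    defs = [("kappa", KAPPA_BOUNDS, lambda w: null.params["kappa"]),
            ("omega_bg", (1e-6, OMEGA_MAX), lambda w: null.params["omega"]),
            ("omega_fg", (1e-6, OMEGA_MAX), lambda w: w)]
    alt, _ = _fit_family(
        aln, fg_tree, model_id="branch", dataset_id=dataset_id or aln.gene_name,
        param_defs=defs,
        build_mixture=lambda th: SiteClassMixture.branch_two_ratio(th[0], th[1], th[2]),
        starts=starts, freqs=freqs, init_bl=null.branch_lengths, maxfun=maxfun)
    alt.params["_foreground"] = sorted(foreground)
    alt.per_branch_dnds = decompose_dnds(alt, freqs)
    return null, alt


def fit_site_models(aln: CodonAlignment, tree: Phylogeny, *, starts=DEFAULT_STARTS,
                    freqs=None, dataset_id=None, ncat: int = 10, maxfun=2000,
                    m0: FitResult | None = None):
    """Site models M8a (null, omega_s = 1) and M8 (omega_s >= 1).

    Returns (m8a, m8). Under M8 a proportion p0 of sites draws omega from a
    discretised Beta(p, q) on [0, 1] and the rest sit at omega_s.
    """
    if freqs is None:
        freqs = f3x4_frequencies(aln)
    dataset_id = dataset_id or aln.gene_name
    init_bl = m0.branch_lengths if m0 is not None else None
    k0 = m0.params["kappa"] if m0 is not None else 2.0

    null_defs = [("kappa", KAPPA_BOUNDS, lambda w: k0),
                 ("p0", (1e-4, 1.0), lambda w: 0.9),
                 ("p", (0.005, 99.0), lambda w: 0.5),
                 ("q", (0.005, 99.0), lambda w: 2.0)]
    m8a, _ = _fit_family(
        aln, tree, model_id="M8a", dataset_id=dataset_id, param_defs=null_defs,
        build_mixture=lambda th: SiteClassMixture.m8a(th[0], th[1], th[2], th[3], ncat),
        starts=(1.0,), freqs=freqs, init_bl=init_bl, maxfun=maxfun,
        two_stage=True)

    alt_defs = null_defs + [("omega_s", (1.0, OMEGA_MAX), lambda w: max(w, 1.0))]
    m8, _ = _fit_family(
        aln, tree, model_id="M8", dataset_id=dataset_id, param_defs=alt_defs,
        build_mixture=lambda th: SiteClassMixture.m8(th[0], th[1], th[2], th[3],
                                                     th[4], ncat),
        starts=starts, freqs=freqs, init_bl=m8a.branch_lengths,
        init_overrides={0: m8a.params["kappa"], 1: m8a.params["p0"],
                        2: m8a.params["p"], 3: m8a.params["q"]},
        maxfun=maxfun, two_stage=True)
    return m8a, m8


def _bs_mixture(th):
    kappa, a, b, w0, w2 = th
    p0 = a * b
    p1 = a * (1.0 - b)
    return SiteClassMixture.branch_site(kappa, p0, p1, w0, w2)


def fit_branch_site(aln: CodonAlignment, tree: Phylogeny, foreground: set[str],
                    *, starts=DEFAULT_STARTS, freqs=None, dataset_id=None,
                    m0: FitResult | None = None, maxfun=2000):
    """Branch-site model A: null (omega2 = 1) versus alternative (omega2 >= 1).

    Returns (null, alternative). Proportions are optimised in the triangle
    parameterisation a = p0 + p1, b = p0 / (p0 + p1).
    """
    if not foreground:
        raise ValueError("foreground branch set is empty")
    fg_tree = tree.with_foreground(foreground)
    if fg_tree.foreground_mask()[fg_tree.edge_nodes].all():
        raise ValueError("foreground covers every branch")
    if freqs is None:
        freqs = f3x4_frequencies(aln)
    dataset_id = dataset_id or aln.gene_name
    init_bl = m0.branch_lengths if m0 is not None else None
    k0 = m0.params["kappa"] if m0 is not None else 2.0
    w0_init = min(m0.params["omega"], 1.0) if m0 is not None else 0.1

    base_defs = [("kappa", KAPPA_BOUNDS, lambda w: k0),
                 ("prop_01", (1e-3, 0.999), lambda w: 0.85),
                 ("prop_ratio", (1e-3, 0.999), lambda w: 0.8),
                 ("omega0", (1e-6, 1.0), lambda w: w0_init)]
    bs_null, _ = _fit_family(
        aln, fg_tree, model_id="BS_null", dataset_id=dataset_id,
        param_defs=base_defs,
        build_mixture=lambda th: _bs_mixture(np.append(th, 1.0)),
        starts=(1.0,), freqs=freqs, init_bl=init_bl, maxfun=maxfun,
        two_stage=True)
    bs_null.params["omega2"] = 1.0

    alt_defs = base_defs + [("omega2", (1.0, OMEGA_MAX), lambda w: max(w, 1.0))]
    bs_alt, _ = _fit_family(
        aln, fg_tree, model_id="BS_alt", dataset_id=dataset_id,
        param_defs=alt_defs, build_mixture=_bs_mixture,
        starts=starts, freqs=freqs, init_bl=bs_null.branch_lengths,
        init_overrides={0: bs_null.params["kappa"],
                        1: bs_null.params["prop_01"],
                        2: bs_null.params["prop_ratio"],
                        3: bs_null.params["omega0"]},
        maxfun=maxfun, two_stage=True)
    for fit in (bs_null, bs_alt):
        a, b = fit.params["prop_01"], fit.params["prop_ratio"]
        fit.params.update(p0=a * b, p1=a * (1 - b),
                          p2a=(1 - a) * b, p2b=(1 - a) * (1 - b))
        fit.params["_foreground"] = sorted(foreground)
    return bs_null, bs_alt
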