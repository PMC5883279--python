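"""End-to-end selection/convergence workflow with config, logging and reports.

The pipeline mirrors the study design: read and clean per-gene codon
alignments, fit M0 per gene and discard genes with saturated synonymous
divergence (max per-branch dS >= threshold), fit branch, site (M8a/M8) and
branch-site models (per foreground lineage, and optionally on concatenations
by functional class), apply LRTs with BH FDR per test family, run BEB on
significant branch-site fits, then translate to amino acids, re-estimate
branch lengths, reconstruct ancestors and test pair convergence with the
Poisson test and FDR across genes. The final report intersects the
positively-selected and convergence-flagged gene sets. Failures are
per-gene (fail-soft): one pathological alignment is logged and skipped.
"""

from __future__ import annotations

import json
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .alnio import (CodonAlignment, clean_alignment, concatenate_by_class,
                    read_class_map, read_gene_alignment)
from .convergence import (analyze_pair_convergence, attach_convergence_fdr,
                          conservative_adaptive_genes, convergence_report,
                          default_aa_model, reconstruct_ancestors)
from .model_fit import (DEFAULT_STARTS, fit_branch_model, fit_branch_site,
                        fit_m0, fit_site_models, filter_genes_by_ds)
from .selection_tests import (attach_fdr, beb_sites, family_report,
                              format_beb_sites, lrt_record)
from .trees import Phylogeny, validate_tree_against_alignment

DEFAULT_FOREGROUNDS = ["Chlamydomonas_sp_ICE-L", "Coccomyxa_subellipsoidea",
                       "Chlorella_sp_ArM0029B", "Dunaliella_salina"]
DEFAULT_PAIRS = [("Chlamydomonas_sp_ICE-L", "Dunaliella_salina")]


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    gene_dir: str
    tree_file: str
    out_dir: str
    foregrounds: list[str] = field(default_factory=lambda: list(DEFAULT_FOREGROUNDS))
    class_map_file: str | None = None
    exclude: list[str] = field(default_factory=list)
    ds_threshold: float = 1.0
    fdr_level: float = 0.05
    pp_threshold: float = 0.95
    starts: list[float] = field(default_factory=lambda: list(DEFAULT_STARTS))
    convergence_pairs: list[tuple[str, str]] = field(
        default_factory=lambda: [tuple(p) for p in DEFAULT_PAIRS])
    convergence_mode: str = "pooled"
    aa_matrix: str = "cprev"
    run_site_models: bool = True
    run_branch_models: bool = True
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.fdr_level < 1):
            raise ConfigError("fdr_level must lie in (0, 1)")
        if not (0 < self.pp_threshold <= 1):
            raise ConfigError("pp_threshold must lie in (0, 1]")
        if self.ds_threshold <= 0:
            raise ConfigError("ds_threshold must be positive")
        if not self.starts:
            raise ConfigError("starts must be nonempty")
        self.convergence_pairs = [tuple(p) for p in self.convergence_pairs]

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        missing = {"gene_dir", "tree_file", "out_dir"} - set(raw)
        if missing:
            raise ConfigError(f"missing required config fields: {sorted(missing)}")
        return cls(**raw)


@dataclass
class ReportBundle:
    out_dir: str
    tables: dict[str, str]            # table name -> file path
    analyzed: list[str]
    excluded: list[str]
    filtered: list[tuple[str, str]]   # (gene, reason)
    failures: list[tuple[str, str]]   # (gene, error)
    psg: dict[str, set[str]]          # foreground -> significant gene set
    convergent_genes: set[str]
    conservative_genes: set[str]
    log: list[str]

    def accounting(self, n_input: int) -> bool:
        return n_input == (len(self.analyzed) + len(self.excluded)
                           + len(self.filtered) + len(self.failures))


def _find_gene_files(gene_dir: str) -> list[Path]:
    d = Path(gene_dir)
    if not d.is_dir():
        raise ConfigError(f"gene directory {gene_dir!r} does not exist")
    files = sorted(p for p in d.iterdir()
                   if p.suffix.lower() in (".fasta", ".fa", ".fna", ".phy",
                                           ".phylip"))
    if not files:
        raise ConfigError(f"no alignment files found in {gene_dir!r}")
    return files


def _write(out: Path, name: str, text: str) -> str:
    path = out / name
    path.write_text(text)
    return str(path)


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = [f"chloroselect {__version__}",
                      f"python {sys.version.split()[0]}",
                      f"numpy {np.__version__}",
                      f"seed {config.seed}",
                      f"starts {list(config.starts)}"]
    files = _find_gene_files(config.gene_dir)
    tree = Phylogeny.from_newick(config.tree_file, is_path=True)
    starts = tuple(config.starts)

    # ---- stage 1: read, exclude, clean -----------------------------------
    genes: dict[str, CodonAlignment] = {}
    excluded, failures = [], []
    for path in files:
        name = path.stem
        if name in config.exclude:
            excluded.append(name)
            log.append(f"{name}: excluded by config")
            continue
        fmt = "phylip" if path.suffix.lower() in (".phy", ".phylip") else "fasta"
        try:
            raw = read_gene_alignment(str(path), fmt=fmt, gene_name=name)
            aln = clean_alignment(raw)
            validate_tree_against_alignment(tree, aln.taxa)
            genes[name] = aln
            log.append(f"{name}: {aln.n_taxa} taxa x {aln.n_sites} codons "
                       f"({raw.n_sites - aln.n_sites} columns cleaned)")
        except Exception as exc:  # fail-soft per gene
            failures.append((name, str(exc)))
            log.append(f"{name}: FAILED ({exc})")
    n_input = len(files)

    # ---- stage 2: M0 per gene + dS filter --------------------------------
    m0_fits = {}
    for name, aln in sorted(genes.items()):
        try:
            m0_fits[name] = fit_m0(aln, tree, starts=starts, dataset_id=name)
            log.append(f"{name}: M0 lnL {m0_fits[name].lnL:.4f} "
                       f"omega {m0_fits[name].params['omega']:.5f}")
        except Exception as exc:
            failures.append((name, f"M0 fit: {exc}"))
            genes.pop(name)
            log.append(f"{name}: M0 FAILED ({exc})")
    retained, discarded = filter_genes_by_ds(
        list(m0_fits.values()), config.ds_threshold)
    filtered = [(g, f"max branch dS {ds:.3f} on {br} >= {config.ds_threshold}")
                for g, br, ds in discarded]
    for g, reason in filtered:
        log.append(f"{g}: filtered ({reason})")
    analyzed = sorted(set(retained))

    m0_rows = ["\t".join(["gene", "lnL", "kappa", "omega", "max_dS", "status"])]
    for name, fit in sorted(m0_fits.items()):
        max_ds = max(v["dS"] for v in fit.per_branch_dnds.values())
        status = "analyzed" if name in analyzed else "filtered"
        m0_rows.append("\t".join([
            name, f"{fit.lnL:.6f}", f"{fit.params['kappa']:.5f}",
            f"{fit.params['omega']:.6f}", f"{max_ds:.5f}", status]))
    tables = {"m0_ds": _write(out, "m0_ds.tsv", "\n".join(m0_rows) + "\n")}

    # ---- stage 3: model fits + LRT families ------------------------------
    branch_records, site_records, bs_records = [], [], []
    beb_by_dataset = {}
    omega_summ = {}
    for name in analyzed:
        aln = genes[name]
        m0 = m0_fits[name]
        try:
            if config.run_branch_models:
                for fg in config.foregrounds:
                    null, alt = fit_branch_model(aln, tree, {fg},
                                                 starts=starts, m0=m0,
                                                 dataset_id=name)
                    branch_records.append(lrt_record(
                        name, "branch", null, alt, foreground=fg))
            if config.run_site_models:
                m8a, m8 = fit_site_models(aln, tree, starts=starts, m0=m0,
                                          dataset_id=name)
                site_records.append(lrt_record(name, "M8-vs-M8a", m8a, m8))
            for fg in config.foregrounds:
                bs_null, bs_alt = fit_branch_site(aln, tree, {fg},
                                                  starts=starts, m0=m0,
                                                  dataset_id=name)
                rec = lrt_record(name, "branch-site", bs_null, bs_alt,
                                 foreground=fg)
                bs_records.append((rec, bs_alt))
                omega_summ[name] = (f"w0={bs_alt.params['omega0']:.3f}, "
                                    f"w2={bs_alt.params['omega2']:.3f}, "
                                    f"p2={bs_alt.params['p2a'] + bs_alt.params['p2b']:.3f}")
                if bs_alt.boundary_flags:
                    log.append(f"{name}/{fg}: boundary {bs_alt.boundary_flags}")
        except Exception as exc:
            log.append(f"{name}: model fitting FAILED ({exc})")
            failures.append((name, f"model fits: {exc}"))
            analyzed = [g for g in analyzed if g != name]

    # FDR families: one per (comparison x foreground)
    for fg in config.foregrounds:
        attach_fdr([r for r in branch_records if r.foreground == fg],
                   config.fdr_level)
        attach_fdr([r for r, _ in bs_records if r.foreground == fg],
                   config.fdr_level)
    attach_fdr(site_records, config.fdr_level)

    # BEB on significant branch-site alternatives
    psg: dict[str, set[str]] = {fg: set() for fg in config.foregrounds}
    for rec, bs_alt in bs_records:
        if rec.significant:
            psg[rec.foreground].add(rec.dataset_id)
            beb = beb_sites(bs_alt, genes[rec.dataset_id], tree,
                            {rec.foreground}, pp_threshold=config.pp_threshold)
            beb_by_dataset[rec.dataset_id] = beb
            log.append(f"{rec.dataset_id}/{rec.foreground}: significant "
                       f"(q={rec.q_value:.4g}), BEB sites: "
                       f"{format_beb_sites(beb) or 'none'}")

    if config.run_branch_models:
        tables["branch_tests"] = _write(out, "branch_tests.tsv",
                                        family_report(branch_records))
    if config.run_site_models:
        tables["site_tests"] = _write(out, "site_tests.tsv",
                                      family_report(site_records))
    tables["branch_site_tests"] = _write(
        out, "branch_site_tests.tsv",
        family_report([r for r, _ in bs_records], beb_by_dataset, omega_summ))

    # ---- stage 4: concatenated-by-class branch-site fits -----------------
    if config.class_map_file:
        class_map = read_class_map(config.class_map_file)
        class_records = []
        concatenated = concatenate_by_class(
            [genes[name] for name in analyzed],
            {g: class_map.get(g, "unassigned") for g in analyzed})
        for cls_name, concat in sorted(concatenated.items()):
            try:
                c_m0 = fit_m0(concat, tree, starts=starts, dataset_id=cls_name)
                for fg in config.foregrounds:
                    bs_null, bs_alt = fit_branch_site(
                        concat, tree, {fg}, starts=starts, m0=c_m0,
                        dataset_id=cls_name)
                    class_records.append(lrt_record(
                        cls_name, "branch-site", bs_null, bs_alt, foreground=fg))
            except Exception as exc:
                log.append(f"class {cls_name}: FAILED ({exc})")
        for fg in config.foregrounds:
            attach_fdr([r for r in class_records if r.foreground == fg],
                       config.fdr_level)
        tables["branch_site_by_class"] = _write(
            out, "branch_site_by_class.tsv", family_report(class_records))

    # ---- stage 5: convergence --------------------------------------------
    convergent_genes: set[str] = set()
    for pair in config.convergence_pairs:
        results = []
        for name in analyzed:
            try:
                aa = genes[name].to_amino_acids()
                asr = reconstruct_ancestors(
                    aa, tree, default_aa_model(aa, config.aa_matrix))
                results.append(analyze_pair_convergence(
                    asr, pair, mode=config.convergence_mode))
            except Exception as exc:
                log.append(f"{name}: convergence FAILED ({exc})")
        flagged = attach_convergence_fdr(results, config.fdr_level)
        convergent_genes |= flagged
        pair_tag = f"{pair[0]}__{pair[1]}"
        tables[f"convergence_{pair_tag}"] = _write(
            out, f"convergence_{pair_tag}.tsv", convergence_report(results))
        log.append(f"pair {pair}: convergence-flagged genes "
                   f"{sorted(flagged) or 'none'}")

    # ---- stage 6: intersection -------------------------------------------
    psg_union = set().union(*psg.values()) if psg else set()
    conservative, provenance = conservative_adaptive_genes(
        psg_union, convergent_genes)
    cons_rows = ["\t".join(["gene", "tests"])]
    for g in sorted(provenance):
        cons_rows.append(f"{g}\t{','.join(provenance[g])}")
    tables["conservative_genes"] = _write(
        out, "conservative_genes.tsv", "\n".join(cons_rows) + "\n")
    log.append(f"positively selected: "
               f"{ {fg: sorted(s) for fg, s in psg.items()} }")
    log.append(f"convergence-flagged: {sorted(convergent_genes)}")
    log.append(f"conservative adaptive genes: {sorted(conservative)}")

    bundle = ReportBundle(str(out), tables, analyzed, excluded, filtered,
                          failures, psg, convergent_genes, conservative, log)
    summary = {
        "analyzed": bundle.analyzed, "excluded": bundle.excluded,
        "filtered": bundle.filtered, "failures": bundle.failures,
        "psg": {fg: sorted(s) for fg, s in psg.items()},
        "convergent_genes": sorted(convergent_genes),
        "conservative_genes": sorted(conservative),
    }
    tables["summary"] = _write(out, "summary.json",
                               json.dumps(summary, indent=1) + "\n")
    _write(out, "run_log.txt", "\n".join(log) + "\n")
    if not bundle.accounting(n_input):
        log.append("WARNING: gene accounting mismatch")
    return bundle
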