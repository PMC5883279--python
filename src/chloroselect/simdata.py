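"""Synthetic codon and amino-acid alignments with the structure the analysis assumes.

The default tree is a 13-taxon green-algal topology shaped like the study
system: a Chlamydomonadalean clade (including the psychrophile ICE-L and the
halotolerant Dunaliella salina) sister to a Trebouxiophycean clade, with
branch lengths of 0.02-0.3 expected substitutions per codon — short enough
that synonymous divergence stays below the dS < 1 filter. Background
selection is strongly purifying (omega around 0.03, the regime observed for
chloroplast genes), with presets adding site-specific or branch-site
positive selection, or planted convergent amino-acid substitutions.

Site classes are drawn once per site and held fixed across the tree, the
branch-site model's own assumption. Random streams are per gene
(seed = master seed + gene index) so gene sets are reproducible
independently of ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .alnio import AminoAcidAlignment, CodonAlignment
from .ctmc import (CodonFrequencies, RateMatrix, SiteClassMixture, build_aa_q,
                   load_empirical_matrix)
from .trees import Phylogeny

DEFAULT_TREE_NEWICK = (
    "((((Chlamydomonas_sp_ICE-L:0.08,Microglena_monadina:0.09):0.05,"
    "Chlamydomonas_applanata:0.12):0.04,"
    "((Chlamydomonas_reinhardtii:0.10,Volvox_carteri:0.11):0.06,"
    "Dunaliella_salina:0.16):0.05):0.08,"
    "(((Coccomyxa_subellipsoidea:0.13,Paradoxia_multiseta:0.12):0.04,"
    "Choricystis_parasitica:0.11):0.05,"
    "((Chlorella_sp_ArM0029B:0.10,Parachlorella_kessleri:0.09):0.05,"
    "(Chlorella_vulgaris:0.10,Dicloster_acuatus:0.12):0.04):0.05):0.08);")

#: 7-taxon subset of the default tree for large replicate studies
REDUCED_TREE_NEWICK = (
    "(((Chlamydomonas_sp_ICE-L:0.08,Microglena_monadina:0.09):0.05,"
    "((Chlamydomonas_reinhardtii:0.10,Volvox_carteri:0.11):0.06,"
    "Dunaliella_salina:0.16):0.05):0.12,"
    "(Coccomyxa_subellipsoidea:0.13,Chlorella_sp_ArM0029B:0.14):0.08);")

EXTREMOPHILE_FOREGROUNDS = (
    "Chlamydomonas_sp_ICE-L", "Coccomyxa_subellipsoidea",
    "Chlorella_sp_ArM0029B", "Dunaliella_salina")

CONVERGENCE_PAIR = ("Chlamydomonas_sp_ICE-L", "Dunaliella_salina")

#: slightly AT-rich composition typical of chloroplast coding sequence (TCAG)
DEFAULT_POS_FREQS = np.array([
    [0.22, 0.18, 0.32, 0.28],
    [0.30, 0.22, 0.30, 0.18],
    [0.34, 0.16, 0.32, 0.18]])


def default_tree(foreground: set[str] | None = None) -> Phylogeny:
    return Phylogeny.from_newick(DEFAULT_TREE_NEWICK, foreground=foreground)


def default_codon_frequencies() -> CodonFrequencies:
    return CodonFrequencies.from_pos_freqs(DEFAULT_POS_FREQS)


@dataclass
class SimulationScenario:
    tree: Phylogeny
    n_sites: int
    seed: int
    mixture: SiteClassMixture | None = None        # codon scenarios
    freqs: CodonFrequencies | None = None
    aa_model: RateMatrix | None = None             # amino-acid scenarios
    replicates: int = 1
    name: str = "custom"
    #: forced convergent events: (0-based site, (taxonA, taxonB), residue index)
    planted_events: list[tuple[int, tuple[str, str], int]] = field(default_factory=list)

    def with_seed(self, seed: int) -> "SimulationScenario":
        return replace(self, seed=seed)


def _sample_children(P: np.ndarray, parent_states: np.ndarray, rng) -> np.ndarray:
    cum = P.cumsum(axis=1)
    u = rng.random(parent_states.size)
    return np.minimum((u[:, None] > cum[parent_states]).sum(axis=1), P.shape[1] - 1)


def simulate_codon_alignment(scenario: SimulationScenario) -> CodonAlignment:
    """Evolve codons on the scenario tree under its site-class mixture.

    Each site keeps one class across the whole tree; foreground branches use
    the class's foreground omega. The true class per site is stored in
    ``aln.site_classes``; identical seeds give bit-identical output.
    """
    if scenario.mixture is None:
        raise ValueError("codon simulation needs a SiteClassMixture")
    rng = np.random.default_rng(scenario.seed)
    tree = scenario.tree
    freqs = scenario.freqs or default_codon_frequencies()
    specs = scenario.mixture.matrices(freqs)
    props = np.array([s[0] for s in specs])
    n = scenario.n_sites
    site_class = rng.choice(len(specs), size=n, p=props / props.sum())
    fg = tree.foreground_mask()

    states = {tree.root: rng.choice(len(freqs.pi), size=n, p=freqs.pi)}
    for node in reversed(tree.postorder):
        if node == tree.root:
            continue
        t = tree.branch_lengths[node]
        parent_states = states[tree.parent[node]]
        child = np.empty(n, dtype=np.int16)
        for k, spec in enumerate(specs):
            idx = np.nonzero(site_class == k)[0]
            if idx.size == 0:
                continue
            mat, rate = ((spec.q_fg, spec.r_fg) if fg[node]
                         else (spec.q_bg, spec.r_bg))
            child[idx] = _sample_children(mat.transition(rate * t),
                                          parent_states[idx], rng)
        states[node] = child
    X = np.vstack([states[tree.leaf_index(t)] for t in tree.taxa])
    aln = CodonAlignment(f"{scenario.name}_s{scenario.seed}", list(tree.taxa), X)
    aln.site_classes = site_class
    aln.true_tree = tree
    return aln


def simulate_aa_alignment(scenario: SimulationScenario):
    """Evolve amino acids on the scenario tree; returns (alignment, truth).

    ``truth`` maps internal node index -> true state vector, so ancestral
    reconstruction accuracy is measurable. Planted events force both tips of
    the designated pair to the target residue at the given sites (terminal
    branches only), creating convergent substitutions.
    """
    if scenario.aa_model is None:
        raise ValueError("amino-acid simulation needs a RateMatrix")
    rng = np.random.default_rng(scenario.seed)
    tree = scenario.tree
    model = scenario.aa_model
    n = scenario.n_sites
    states = {tree.root: rng.choice(20, size=n, p=model.pi)}
    for node in reversed(tree.postorder):
        if node == tree.root:
            continue
        P = model.transition(tree.branch_lengths[node])
        states[node] = _sample_children(P, states[tree.parent[node]], rng).astype(np.int8)
    for site, (ta, tb), residue in scenario.planted_events:
        for taxon in (ta, tb):
            leaf = tree.leaf_index(taxon)
            if tree.parent[leaf] < 0:
                raise ValueError("planted events require terminal branches")
            states[leaf][site] = residue
    X = np.vstack([states[tree.leaf_index(t)] for t in tree.taxa]).astype(np.int8)
    aln = AminoAcidAlignment(f"{scenario.name}_s{scenario.seed}", list(tree.taxa), X)
    truth = {i: states[i] for i in range(tree.n_nodes) if not tree.is_leaf(i)}
    return aln, truth


def scenario_presets(name: str, seed: int = 0, **overrides) -> SimulationScenario:
    """Named study scenarios.

    bs_null          branch-site data with omega2 = 1 (type-I error studies)
    bs_null_small    same model on the reduced 7-taxon tree
    bs_power         15% of foreground sites at omega2 = 4
    m8_null          purifying sites only (beta-distributed omega)
    convergence_null amino-acid data with no planted convergence
    paper_like       strongly purifying single-class genes (omega ~ 0.03)
    """
    tree = default_tree()
    fg = {"Chlamydomonas_sp_ICE-L"}
    if name == "bs_null":
        sc = SimulationScenario(
            tree=tree.with_foreground(fg), n_sites=300, seed=seed,
            mixture=SiteClassMixture.branch_site(2.0, 0.7, 0.3, 0.03, 1.0),
            name=name)
    elif name == "bs_null_small":
        small = Phylogeny.from_newick(REDUCED_TREE_NEWICK, foreground=fg)
        sc = SimulationScenario(
            tree=small, n_sites=300, seed=seed,
            mixture=SiteClassMixture.branch_site(2.0, 0.7, 0.3, 0.03, 1.0),
            name=name)
    elif name == "bs_power":
        sc = SimulationScenario(
            tree=tree.with_foreground(fg), n_sites=600, seed=seed,
            mixture=SiteClassMixture.branch_site(2.0, 0.595, 0.255, 0.03, 4.0),
            name=name)
    elif name == "m8_null":
        sc = SimulationScenario(
            tree=tree, n_sites=400, seed=seed,
            mixture=SiteClassMixture.m8a(2.0, 1.0 - 1e-9, 0.2, 2.0),
            name=name)
    elif name == "convergence_null":
        S, _ = load_empirical_matrix("cprev")
        f = np.full(20, 0.05)
        sc = SimulationScenario(tree=tree, n_sites=300, seed=seed,
                                aa_model=build_aa_q(S, f), name=name)
    elif name == "paper_like":
        sc = SimulationScenario(
            tree=tree, n_sites=400, seed=seed,
            mixture=SiteClassMixture.m0(2.0, 0.03), name=name)
    else:
        raise ValueError(f"unknown scenario preset {name!r}")
    return replace(sc, **overrides) if overrides else sc


#: fixture tree: reduced taxon set with a long ICE-L branch so planted
#: branch-site selection on that lineage is detectable at desk scale
FIXTURE_TREE_NEWICK = (
    "(((Chlamydomonas_sp_ICE-L:0.35,Microglena_monadina:0.09):0.05,"
    "((Chlamydomonas_reinhardtii:0.10,Volvox_carteri:0.11):0.06,"
    "Dunaliella_salina:0.16):0.05):0.12,"
    "(Coccomyxa_subellipsoidea:0.13,Chlorella_sp_ArM0029B:0.14):0.08);")


def _plant_convergent_codons(aln: CodonAlignment, pair: tuple[str, str],
                             sites: list[int]) -> list[int]:
    """Force both pair tips to share a derived residue at the given sites.

    The target codon's amino acid is chosen to differ from every other
    taxon's residue at the site, so ancestral reconstruction sees a change
    on both terminal branches. Returns the planted (0-based) sites.
    """
    from .genetic_code import code_tables
    _, _, _, aa_of = code_tables(aln.table_id)
    rows = [aln.taxa.index(t) for t in pair]
    other = [i for i in range(aln.n_taxa) if i not in rows]
    for s in sites:
        present = {aa_of[c] for c in aln.codons[other, s]}
        target = next(c for c in range(len(aa_of)) if aa_of[c] not in present)
        aln.codons[rows, s] = target
    return sites


def write_pipeline_fixture(base_dir, master_seed: int = 101) -> dict:
    """Write the bundled 6-gene synthetic pipeline fixture.

    One gene carries branch-site positive selection on the ICE-L lineage
    (gene_psg), one carries planted convergent substitutions for the
    ICE-L / D. salina pair (gene_conv), and four are plain purifying genes.
    Writes FASTA alignments, the tree, a class map and a ready-to-run YAML
    config; returns the planted truth and key paths.
    """
    from pathlib import Path

    import yaml

    from .alnio import write_gene_alignment
    from .trees import Phylogeny

    base = Path(base_dir)
    gene_dir = base / "genes"
    gene_dir.mkdir(parents=True, exist_ok=True)
    tree = Phylogeny.from_newick(FIXTURE_TREE_NEWICK)
    fg = "Chlamydomonas_sp_ICE-L"
    pair = CONVERGENCE_PAIR

    def sim(name, mixture, n_sites, offset, foreground=None):
        t = tree.with_foreground({foreground}) if foreground else tree
        sc = SimulationScenario(tree=t, n_sites=n_sites,
                                seed=master_seed + offset, mixture=mixture,
                                name=name)
        aln = simulate_codon_alignment(sc)
        aln.gene_name = name
        return aln

    genes = [
        sim("gene_psg", SiteClassMixture.branch_site(2.0, 0.5, 0.25, 0.05, 10.0),
            500, 1, foreground=fg),
        sim("gene_conv", SiteClassMixture.m0(2.0, 0.05), 400, 2),
        sim("gene_a", SiteClassMixture.m0(2.0, 0.02), 250, 3),
        sim("gene_b", SiteClassMixture.m0(2.0, 0.03), 300, 4),
        sim("gene_c", SiteClassMixture.m0(2.0, 0.04), 350, 5),
        sim("gene_d", SiteClassMixture.m0(2.0, 0.05), 280, 6),
    ]
    planted_sites = _plant_convergent_codons(genes[1], pair, [30, 120, 210, 300])
    for aln in genes:
        write_gene_alignment(aln, gene_dir / f"{aln.gene_name}.fasta")
    tree_file = base / "tree.nwk"
    tree_file.write_text(tree.to_newick() + "\n")
    class_map_file = base / "class_map.tsv"
    class_map_file.write_text(
        "gene_psg\tphotosynthesis\ngene_conv\tphotosynthesis\n"
        "gene_a\tphotosynthesis\ngene_b\tgenetic_system\n"
        "gene_c\tgenetic_system\ngene_d\tgenetic_system\n")
    config = {
        "gene_dir": str(gene_dir),
        "tree_file": str(tree_file),
        "out_dir": str(base / "out"),
        "foregrounds": [fg],
        "class_map_file": str(class_map_file),
        "starts": [1.0],
        "convergence_pairs": [list(pair)],
        "seed": master_seed,
    }
    config_file = base / "config.yaml"
    config_file.write_text(yaml.safe_dump(config))
    return {"psg": {"gene_psg"}, "convergent": {"gene_conv"},
            "planted_sites": [s + 1 for s in planted_sites],
            "config_file": str(config_file), "gene_dir": str(gene_dir),
            "tree_file": str(tree_file)}


def paper_like_gene_set(master_seed: int, n_genes: int = 46,
                        min_codons: int = 150, max_codons: int = 700):
    """Gene set emulating the study's 46 retained chloroplast genes.

    Gene-specific omegas span the purifying range reported for such genes
    (0.001-0.06); lengths are uniform over [min_codons, max_codons]. Streams
    are per gene: gene i uses seed master_seed + i.
    """
    meta_rng = np.random.default_rng(master_seed)
    omegas = meta_rng.uniform(0.001, 0.06, size=n_genes)
    lengths = meta_rng.integers(min_codons, max_codons + 1, size=n_genes)
    genes = []
    for i in range(n_genes):
        sc = scenario_presets("paper_like", seed=master_seed + i,
                              n_sites=int(lengths[i]),
                              mixture=SiteClassMixture.m0(2.0, float(omegas[i])))
        aln = simulate_codon_alignment(sc)
        aln.gene_name = f"gene{i + 1:02d}"
        aln.true_omega = float(omegas[i])
        genes.append(aln)
    return genes
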