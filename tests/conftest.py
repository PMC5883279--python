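import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from chloroselect.model_fit import fit_branch_site
from chloroselect.simdata import (FIXTURE_TREE_NEWICK, SimulationScenario,
                                  default_codon_frequencies,
                                  simulate_codon_alignment)
from chloroselect.ctmc import SiteClassMixture
from chloroselect.trees import Phylogeny

settings.register_profile(
    "suite", derandomize=True, deadline=None, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")

FG = "Chlamydomonas_sp_ICE-L"


@pytest.fixture(scope="session")
def default_freqs():
    return default_codon_frequencies()


@pytest.fixture(scope="session")
def toy4_tree():
    return Phylogeny.from_newick("((A:0.3,B:0.2):0.1,(C:0.15,D:0.4):0.05);")


@pytest.fixture(scope="session")
def toy4_aln(toy4_tree, default_freqs):
    sc = SimulationScenario(tree=toy4_tree, n_sites=12, seed=5,
                            mixture=SiteClassMixture.m0(2.0, 0.5),
                            freqs=default_freqs, name="toy4")
    return simulate_codon_alignment(sc)


@pytest.fixture(scope="session")
def strong_bs_data(default_freqs):
    """Branch-site data with strong positive selection on the ICE-L lineage."""
    tree = Phylogeny.from_newick(FIXTURE_TREE_NEWICK)
    sc = SimulationScenario(
        tree=tree.with_foreground({FG}), n_sites=400, seed=7,
        mixture=SiteClassMixture.branch_site(2.0, 0.5, 0.25, 0.05, 10.0),
        freqs=default_freqs, name="strong")
    return simulate_codon_alignment(sc), tree


@pytest.fixture(scope="session")
def strong_bs_fits(strong_bs_data):
    aln, tree = strong_bs_data
    null, alt = fit_branch_site(aln, tree, {FG}, starts=(1.0,))
    return null, alt
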