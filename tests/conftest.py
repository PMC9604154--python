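import numpy as np
import pytest

from glomesieve import fixtures as fx
from glomesieve.phylo import Tree


@pytest.fixture(scope="session")
def small_bundle():
    """8-taxon reference with pairwise divergence above the 0.02 cluster
    radius and the 6% placement-recovery floor."""
    return fx.simulate_reference(8, seed=1, min_divergence=0.06)


@pytest.fixture(scope="session")
def tiny_design():
    return fx.StudyDesign(replicates=3)


@pytest.fixture(scope="session")
def two_genus_bundle():
    """Hand-built 4-leaf reference: two genera in two families.

    ((SpA,SpB) = genus G1 / family F1, (SpC,SpD) = genus G2 / family F2.)
    """
    tree = Tree.from_newick(
        "((SpA:0.05,SpB:0.05):0.2,(SpC:0.05,SpD:0.05):0.2);")
    taxonomy = {
        "SpA": "Glomeromycota;Glomeromycetes;O1;F1;G1;SpA",
        "SpB": "Glomeromycota;Glomeromycetes;O1;F1;G1;SpB",
        "SpC": "Glomeromycota;Glomeromycetes;O1;F2;G2;SpC",
        "SpD": "Glomeromycota;Glomeromycetes;O1;F2;G2;SpD",
    }
    rng = np.random.default_rng(11)
    from glomesieve.phylo import GTRModel, simulate_alignment
    model = GTRModel.jukes_cantor(gamma_shape=1.0)
    aln = simulate_alignment(tree, model, 300, rng)
    return fx.ReferenceBundle(tree, aln, model, taxonomy)


@pytest.fixture(scope="session")
def study_result():
    """One full synthetic study shared by the integration-level tests."""
    from glomesieve.workflow import run_synthetic_study
    return run_synthetic_study(n_taxa=16, seed=1, depth=250,
                               error_rate=0.005)
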