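"""Shared fixtures: small trees, alignments and simulated datasets."""

import numpy as np
import pytest

import codonbench as cb


@pytest.fixture(scope="session")
def code():
    return cb.universal_code()


@pytest.fixture(scope="session")
def space(code):
    return cb.sense_codon_space(code)


@pytest.fixture(scope="session")
def quartet_tree():
    return cb.PhyloTree.from_newick("(A:0.1,B:0.25,(C:0.3,D:0.12):0.08);")


@pytest.fixture(scope="session")
def random_model():
    """A 3-class model with asymmetric biases and skewed frequencies."""
    rng = np.random.default_rng(20)
    assignment = cb.random_assignment(3, seed=6)
    rho = rng.uniform(0.2, 2.5, 3)
    theta = np.concatenate([[rng.uniform(0.3, 2.0)], [1.0], rng.uniform(0.3, 2.0, 4)])
    pi = rng.dirichlet(np.full(4, 8.0), size=3)
    return cb.build_q(assignment, rho, theta, pi)


@pytest.fixture(scope="session")
def quartet_alignment(quartet_tree):
    spec = cb.SimulationSpec(
        tree=quartet_tree,
        assignment=cb.sr_assignment(),
        rho=np.array([0.5]),
        theta=np.ones(6),
        pi=cb.uniform_pi(),
        n_sites=30,
        seed=11,
    )
    return cb.simulate_alignment(spec).alignment


@pytest.fixture(scope="session")
def small_dataset():
    """6 taxa, 300 codons simulated under SR (omega=0.4): quick-fit fixture."""
    tree = cb.random_tree(6, seed=31, mean_branch_length=0.12)
    spec = cb.SimulationSpec(
        tree=tree,
        assignment=cb.sr_assignment(),
        rho=np.array([0.4]),
        theta=np.ones(6),
        pi=cb.uniform_pi(),
        n_sites=300,
        seed=13,
    )
    sim = cb.simulate_alignment(spec)
    return tree, sim.alignment


@pytest.fixture(scope="session")
def small_sr_fit(small_dataset):
    tree, aln = small_dataset
    return cb.fit(tree, aln, cb.sr_assignment())
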