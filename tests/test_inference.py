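"""Pruning likelihood and maximum-likelihood fitting."""

import itertools

import numpy as np
import pytest

import codonbench as cb
from codonbench.inference import FitOptions, MISSING


def brute_force_loglik(tree, aln, model):
    """Exhaustive summation over all unobserved-node state combinations.

    Independent oracle: for every site, sums stationary[root] times the
    product of per-edge transition probabilities over every joint
    assignment of states to nodes without data (internal nodes, plus any
    node whose observation is missing at that site).
    """
    n = model.n_states
    n_nodes = len(tree.parent)
    observed_row = {
        v: aln.taxa.index(tree.labels[v])
        for v in range(n_nodes)
        if tree.labels[v] is not None
    }
    P = {
        v: model.transition_matrix(tree.lengths[v])
        for v in range(n_nodes)
        if tree.parent[v] != -1
    }
    total = 0.0
    for site in range(aln.n_sites):
        fixed = {
            v: aln.codon_states[row, site]
            for v, row in observed_row.items()
            if aln.codon_states[row, site] != MISSING
        }
        free = [v for v in range(n_nodes) if v not in fixed]
        lik = 0.0
        for combo in itertools.product(range(n), repeat=len(free)):
            state = dict(fixed)
            state.update(zip(free, combo))
            term = model.stationary[state[tree.root]]
            for v in range(n_nodes):
                if tree.parent[v] != -1:
                    term *= P[v][state[tree.parent[v]], state[v]]
            lik += term
        total += np.log(lik)
    return total


class TestLogLikelihood:
    def test_single_taxon_stationary_only(self, random_model):
        tree = cb.PhyloTree.from_newick("A;")
        states = np.array([[0, 5, 60, 17]])
        aln = cb.CodonAlignment(taxa=("A",), codon_states=states)
        ll = cb.log_likelihood(tree, aln, random_model)
        assert ll == pytest.approx(np.log(random_model.stationary[states[0]]).sum())

    def test_matches_exhaustive_summation_two_and_three_taxa(self, random_model):
        rng = np.random.default_rng(3)
        for newick, names in [
            ("(A:0.2,B:0.5);", ("A", "B")),
            ("(A:0.1,B:0.3,C:0.22);", ("A", "B", "C")),
        ]:
            tree = cb.PhyloTree.from_newick(newick)
            states = rng.integers(0, 61, size=(len(names), 5))
            aln = cb.CodonAlignment(taxa=names, codon_states=states)
            ll = cb.log_likelihood(tree, aln, random_model)
            assert ll == pytest.approx(brute_force_loglik(tree, aln, random_model), abs=1e-8)

    def test_matches_exhaustive_with_missing_data(self, quartet_tree, random_model):
        rng = np.random.default_rng(9)
        states = rng.integers(0, 61, size=(4, 4))
        states[1, 2] = MISSING
        states[3, 0] = MISSING
        aln = cb.CodonAlignment(taxa=("A", "B", "C", "D"), codon_states=states)
        ll = cb.log_likelihood(quartet_tree, aln, random_model)
        assert ll == pytest.approx(brute_force_loglik(quartet_tree, aln, random_model), abs=1e-8)

    def test_pattern_compression_scales_duplicated_columns(self, quartet_tree, random_model, quartet_alignment):
        ll = cb.log_likelihood(quartet_tree, quartet_alignment, random_model)
        doubled = cb.CodonAlignment(
            taxa=quartet_alignment.taxa,
            codon_states=np.hstack([quartet_alignment.codon_states] * 2),
        )
        assert cb.log_likelihood(quartet_tree, doubled, random_model) == pytest.approx(2 * ll)

    def test_rerooting_invariance(self, random_model, quartet_alignment):
        t1 = cb.PhyloTree.from_newick("(A:0.1,B:0.25,(C:0.3,D:0.12):0.08);")
        t2 = cb.PhyloTree.from_newick("(C:0.3,D:0.12,(A:0.1,B:0.25):0.08);")
        t3 = cb.PhyloTree.from_newick("((A:0.1,B:0.25):0.05,(C:0.3,D:0.12):0.03);")
        lls = [cb.log_likelihood(t, quartet_alignment, random_model) for t in (t1, t2, t3)]
        assert lls[0] == pytest.approx(lls[1], abs=1e-8)
        assert lls[0] == pytest.approx(lls[2], abs=1e-8)

    def test_taxon_mismatch_rejected(self, quartet_tree, random_model):
        aln = cb.CodonAlignment(taxa=("A", "B", "C", "X"), codon_states=np.zeros((4, 2), dtype=int))
        with pytest.raises(ValueError, match="mismatch"):
            cb.log_likelihood(quartet_tree, aln, random_model)


class TestFit:
    def test_sr_parameter_recovery(self):
        """omega estimated within +-0.05 of truth on 2,000 codons, 8 taxa."""
        tree = cb.random_tree(8, seed=11, mean_branch_length=0.15)
        spec = cb.SimulationSpec(
            tree=tree, assignment=cb.sr_assignment(), rho=np.array([0.3]),
            theta=np.ones(6), pi=cb.uniform_pi(), n_sites=2000, seed=5,
        )
        sim = cb.simulate_alignment(spec)
        res = cb.fit(tree, sim.alignment, cb.sr_assignment())
        assert res.converged
        assert abs(res.estimates["rho"][0] - 0.3) < 0.05

    def test_random_k_nests_sr(self, small_dataset, small_sr_fit):
        tree, aln = small_dataset
        a = cb.random_assignment(3, seed=77)
        opts = cb.warm_start_options(FitOptions(), small_sr_fit, a.n_classes)
        alt = cb.fit(tree, aln, a, opts)
        assert alt.log_likelihood >= small_sr_fit.log_likelihood - 1e-6

    def test_fit_beats_initialization(self, small_dataset):
        tree, aln = small_dataset
        opts = FitOptions(init={"rho": np.array([3.0]), "theta": np.full(6, 2.0)})
        res = cb.fit(tree, aln, cb.sr_assignment(), opts)
        init_model = cb.build_q(
            cb.sr_assignment(), np.array([3.0]), np.full(6, 2.0),
            cb.observed_positional_frequencies(aln),
        )
        ll_init = cb.log_likelihood(tree, aln, init_model)
        assert res.log_likelihood >= ll_init

    def test_zero_variation_flagged_boundary(self):
        tree = cb.PhyloTree.from_newick("(A:0.1,B:0.1,(C:0.1,D:0.1):0.1);")
        states = np.tile(np.arange(8), (4, 1))  # identical rows: no variation
        aln = cb.CodonAlignment(taxa=("A", "B", "C", "D"), codon_states=states)
        res = cb.fit(tree, aln, cb.sr_assignment())
        assert res.converged
        assert res.boundary  # branch lengths collapse to the lower bound
        assert np.isfinite(res.log_likelihood)

    def test_tree_without_lengths_initialized_from_p_distance(self, small_dataset):
        import re

        tree, aln = small_dataset
        topo = re.sub(r":[0-9.eE+-]+", "", tree.to_newick())
        bare = cb.PhyloTree.from_newick(topo)
        assert not bare.has_branch_lengths()
        res = cb.fit(bare, aln, cb.sr_assignment(), FitOptions(max_cycles=3))
        assert np.isfinite(res.log_likelihood)

    def test_ml_frequencies_improve_on_observed_under_skew(self):
        rng = np.random.default_rng(2)
        tree = cb.random_tree(5, seed=21, mean_branch_length=0.1)
        pi = rng.dirichlet(np.full(4, 6.0), size=3)
        spec = cb.SimulationSpec(
            tree=tree, assignment=cb.sr_assignment(), rho=np.array([0.5]),
            theta=np.ones(6), pi=pi, n_sites=400, seed=8,
        )
        sim = cb.simulate_alignment(spec)
        obs = cb.fit(tree, sim.alignment, cb.sr_assignment(), FitOptions(freq_mode="observed"))
        ml = cb.fit(tree, sim.alignment, cb.sr_assignment(), FitOptions(freq_mode="ml"))
        assert ml.log_likelihood >= obs.log_likelihood - 1e-6
        assert ml.n_free_parameters == obs.n_free_parameters + 9


class TestParameterCount:
    def test_sr_13_taxa_ml_frequencies(self):
        tree = cb.random_tree(13, seed=1)
        counts = cb.count_free_parameters(
            cb.sr_assignment(), tree, FitOptions(freq_mode="ml", bias_mode="rev")
        )
        assert tree.n_edges == 23  # 2n - 3
        assert (counts.branches, counts.biases, counts.frequencies, counts.rates) == (
            23, 5, 9, 1,
        )
        assert counts.total == 38

    def test_rev_has_75_rate_parameters(self):
        tree = cb.random_tree(6, seed=2)
        counts = cb.count_free_parameters(cb.rev_assignment(), tree)
        assert counts.rates == 75

    def test_empty_class_reduces_effective_count(self):
        keys = list(cb.sr_assignment().class_of)
        class_of = {k: 0 for k in keys}
        class_of[keys[0]] = 2  # classes 0 and 2 occupied, 1, 3, 4 empty
        a = cb.RateClassAssignment(n_classes=5, class_of=class_of)
        tree = cb.random_tree(4, seed=3)
        assert cb.count_free_parameters(a, tree).rates == 2

    def test_hky_and_fixed_branches(self):
        tree = cb.random_tree(7, seed=4)
        counts = cb.count_free_parameters(
            cb.sr_assignment(), tree,
            FitOptions(bias_mode="hky", optimize_branch_lengths=False),
        )
        assert counts.biases == 1 and counts.branches == 0
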