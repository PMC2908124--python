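"""Sequence evolution simulator and random-tree generator.

Produces codon alignments under any model in the SR / multi-rate / REV
family on a fixed or randomly generated tree: root states are drawn from
the stationary distribution and propagated along each edge with the
exact transition probabilities exp(Qt).  An optional event-logging mode
replaces the exact sampler with a Gillespie walk so individual
substitution events (and their synonymous status) can be counted, which
makes expected substitution flows directly observable in tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .gencode import universal_code
from .inference import CodonAlignment, PhyloTree
from .ratematrix import CodonRateMatrix, QBuilder, RateClassAssignment


@dataclass(frozen=True)
class SimulationSpec:
    """Everything needed to generate one alignment reproducibly."""

    tree: PhyloTree
    assignment: RateClassAssignment
    rho: np.ndarray
    theta: np.ndarray
    pi: np.ndarray
    n_sites: int
    seed: int

    def __post_init__(self):
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")


@dataclass
class SubstitutionRecord:
    """One logged substitution event on an edge (Gillespie mode only)."""

    edge_node: int
    site: int
    source_state: int
    target_state: int
    synonymous: bool


@dataclass
class SimulationResult:
    alignment: CodonAlignment
    spec: SimulationSpec
    model: CodonRateMatrix
    node_states: dict[int, np.ndarray] = field(repr=False, default_factory=dict)
    events: list[SubstitutionRecord] | None = None

    def ground_truth(self) -> dict:
        return {
            "seed": self.spec.seed,
            "n_sites": self.spec.n_sites,
            "rho": np.asarray(self.spec.rho, dtype=float).tolist(),
            "theta": np.asarray(self.spec.theta, dtype=float).tolist(),
            "pi": np.asarray(self.spec.pi, dtype=float).tolist(),
            "assignment": self.spec.assignment.to_json(),
            "newick": self.spec.tree.to_newick(),
        }


def _draw_children(P: np.ndarray, parent_states: np.ndarray, u: np.ndarray) -> np.ndarray:
    cdf = np.cumsum(P, axis=1)
    cdf[:, -1] = 1.0  # guard against rounding shortfall
    return (cdf[parent_states] < u[:, None]).sum(axis=1)


def simulate_alignment(
    spec: SimulationSpec, log_events: bool = False
) -> SimulationResult:
    """Evolve codon states down the tree under the specified model.

    The single RNG stream is seeded once and consumed node by node in
    preorder (all sites of a node drawn together), so output is
    bit-reproducible for a given spec.  With ``log_events`` the sampler
    switches to a Gillespie walk per (edge, site) and records each
    substitution with its synonymous flag.
    """
    code = universal_code()
    qb = QBuilder(spec.assignment, code)
    model = qb.build(
        np.asarray(spec.rho, dtype=float),
        np.asarray(spec.theta, dtype=float),
        np.asarray(spec.pi, dtype=float),
    )
    tree = spec.tree
    if not tree.has_branch_lengths():
        raise ValueError("simulation requires branch lengths on every edge")
    rng = np.random.default_rng(spec.seed)
    n = model.n_states

    node_states: dict[int, np.ndarray] = {}
    events: list[SubstitutionRecord] | None = [] if log_events else None
    syn_lookup = _synonymy_matrix(qb)

    preorder = tree.postorder[::-1]
    root = tree.root
    node_states[root] = rng.choice(n, size=spec.n_sites, p=model.stationary)
    for node in preorder:
        if node == root:
            continue
        parent_states = node_states[tree.parent[node]]
        t = tree.lengths[node]
        if not log_events:
            if t == 0:
                node_states[node] = parent_states.copy()
            else:
                P = model.transition_matrix(t)
                u = rng.random(spec.n_sites)
                node_states[node] = _draw_children(P, parent_states, u)
        else:
            states = parent_states.copy()
            for site in range(spec.n_sites):
                s = states[site]
                elapsed = 0.0
                while True:
                    out_rate = -model.Q[s, s]
                    if out_rate <= 0:
                        break
                    elapsed += rng.exponential(1.0 / out_rate)
                    if elapsed >= t:
                        break
                    probs = model.Q[s].copy()
                    probs[s] = 0.0
                    probs /= probs.sum()
                    nxt = rng.choice(n, p=probs)
                    events.append(
                        SubstitutionRecord(
                            edge_node=node,
                            site=site,
                            source_state=s,
                            target_state=int(nxt),
                            synonymous=bool(syn_lookup[s, nxt]),
                        )
                    )
                    s = int(nxt)
                states[site] = s
            node_states[node] = states

    leaf_rows = sorted(tree.leaf_node.items())
    aln = CodonAlignment(
        taxa=tuple(name for name, _ in leaf_rows),
        codon_states=np.array([node_states[idx] for _, idx in leaf_rows]),
        code_table_id=code.table_id,
    )
    return SimulationResult(
        alignment=aln, spec=spec, model=model, node_states=node_states, events=events
    )


def _synonymy_matrix(qb: QBuilder) -> np.ndarray:
    tab = qb.table
    m = np.zeros((tab.space.n_states, tab.space.n_states), dtype=bool)
    m[tab.src[tab.synonymous], tab.dst[tab.synonymous]] = True
    return m


def random_tree(
    n_taxa: int, seed: int, mean_branch_length: float = 0.1
) -> PhyloTree:
    """Random unrooted binary topology with exponential branch lengths.

    Built by uniform random sequential joining of lineages until three
    remain, which then meet at the (trifurcating) traversal root; a
    2-taxon request yields the single-edge tree.  Deterministic given
    the seed.
    """
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    if mean_branch_length <= 0:
        raise ValueError("mean_branch_length must be positive")
    rng = np.random.default_rng(seed)
    labels: list[str | None] = [f"t{i + 1}" for i in range(n_taxa)]
    children: list[list[int]] = [[] for _ in range(n_taxa)]
    parent: list[int] = [-2] * n_taxa  # -2: unattached lineage
    lineages = list(range(n_taxa))

    if n_taxa == 2:
        lengths = [0.0, float(rng.exponential(mean_branch_length))]
        return PhyloTree(
            children=[[1], []], parent=[-1, 0], lengths=lengths, labels=labels
        )

    while len(lineages) > 3:
        i, j = sorted(rng.choice(len(lineages), size=2, replace=False))
        a, b = lineages[i], lineages[j]
        new = len(labels)
        labels.append(None)
        children.append([a, b])
        parent.append(-2)
        parent[a] = parent[b] = new
        lineages = [x for x in lineages if x not in (a, b)] + [new]

    root = len(labels)
    labels.append(None)
    children.append(list(lineages))
    parent.append(-1)
    for x in lineages:
        parent[x] = root

    n_nodes = len(labels)
    lengths = [0.0] * n_nodes
    # edge lengths drawn in node-index order for determinism
    draws = rng.exponential(mean_branch_length, size=n_nodes)
    for node in range(n_nodes):
        if node != root:
            lengths[node] = float(draws[node])
    return PhyloTree(children=children, parent=parent, lengths=lengths, labels=labels)
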