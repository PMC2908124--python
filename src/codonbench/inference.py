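"""Phylogenetic likelihood and maximum-likelihood fitting.

The likelihood of a codon alignment on a fixed unrooted tree is computed
by Felsenstein pruning over compressed site patterns, with the root term
weighted by the model's stationary distribution.  Because every model in
the family is time reversible, the choice of traversal root does not
change the likelihood.

Fitting alternates quasi-Newton (L-BFGS-B) steps over coordinate blocks:
branch lengths (with the eigendecomposition of Q cached), then the
substitution-model block (class exchangeabilities, nucleotide biases and
optionally position-specific frequencies), until the log-likelihood gain
per cycle falls below a relative tolerance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Sequence

import dendropy
import numpy as np
from scipy.optimize import minimize

from .gencode import GeneticCode, sense_codon_space, universal_code
from .ratematrix import (
    AG_INDEX,
    CodonRateMatrix,
    QBuilder,
    RateClassAssignment,
)

MISSING = -1

# Optimization bounds (natural scale); rate-like parameters are optimized
# in log space inside these limits, hits are flagged as boundary solutions.
RATE_BOUNDS = (1e-6, 100.0)
BRANCH_BOUNDS = (1e-8, 50.0)
_LOGIT_BOUND = 12.0
_PENALTY = 1e10  # returned for non-finite likelihoods so line searches backtrack


# --------------------------------------------------------------------------
# Alignment


@dataclass(frozen=True)
class CodonAlignment:
    """Aligned codon sequences encoded as integer states.

    ``codon_states`` is (n_taxa, n_sites) with entries indexing the
    sense-codon state space, or ``MISSING`` (-1) for codons containing
    gaps or ambiguity.
    """

    taxa: tuple[str, ...]
    codon_states: np.ndarray
    code_table_id: int = 1

    def __post_init__(self):
        if self.codon_states.shape[0] != len(self.taxa):
            raise ValueError("one state row per taxon required")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("taxon names must be unique")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_sites(self) -> int:
        return self.codon_states.shape[1]

    @classmethod
    def from_sequences(
        cls, named_seqs: Sequence[tuple[str, str]], code: GeneticCode | None = None
    ) -> "CodonAlignment":
        """Build from (name, nucleotide sequence) pairs.

        Sequences must share a length divisible by 3 and contain no stop
        codons; codons with any non-ACGT character become MISSING.
        """
        code = code or universal_code()
        space = sense_codon_space(code)
        taxa, rows = [], []
        lengths = {len(s) for _, s in named_seqs}
        if len(lengths) > 1:
            raise ValueError(f"ragged alignment: sequence lengths {sorted(lengths)}")
        (length,) = lengths or {0}
        if length % 3:
            raise ValueError(f"alignment length {length} is not divisible by 3")
        for name, seq in named_seqs:
            seq = seq.upper().replace("U", "T")
            states = []
            for k in range(0, length, 3):
                codon = seq[k : k + 3]
                if codon in space.index:
                    states.append(space.index[codon])
                elif set(codon) <= set("ACGT"):
                    if code.is_stop(codon):
                        raise ValueError(
                            f"stop codon {codon} in sequence {name!r} "
                            f"at codon site {k // 3 + 1}"
                        )
                    states.append(MISSING)
                else:
                    states.append(MISSING)
            taxa.append(name)
            rows.append(states)
        return cls(
            taxa=tuple(taxa),
            codon_states=np.array(rows, dtype=np.int64).reshape(len(taxa), -1),
            code_table_id=code.table_id,
        )

    def sequences(self, code: GeneticCode | None = None) -> list[tuple[str, str]]:
        """Decode back to (name, nucleotide string) pairs; MISSING -> '---'."""
        code = code or universal_code()
        space = sense_codon_space(code)
        out = []
        for t, row in zip(self.taxa, self.codon_states):
            out.append(
                (t, "".join("---" if s == MISSING else space.states[s] for s in row))
            )
        return out


def observed_positional_frequencies(aln: CodonAlignment) -> np.ndarray:
    """Per-codon-position nucleotide proportions from non-missing codons.

    A half-count pseudofrequency keeps all entries strictly positive.
    """
    code = universal_code()
    space = sense_codon_space(code)
    counts = np.full((3, 4), 0.5)
    nuc_index = {n: i for i, n in enumerate("ACGT")}
    flat = aln.codon_states[aln.codon_states >= 0]
    for s in flat:
        codon = space.states[s]
        for k in range(3):
            counts[k, nuc_index[codon[k]]] += 1
    return counts / counts.sum(axis=1, keepdims=True)


# --------------------------------------------------------------------------
# Tree


class PhyloTree:
    """Fixed unrooted tree topology with branch lengths.

    Internally rooted at an arbitrary (trifurcating, for >= 3 taxa) node
    purely for traversal; reversibility makes the likelihood independent
    of that choice.  Branch lengths live on non-root nodes, enumerated in
    postorder — that enumeration is the parameter-vector order used by
    the optimizer.
    """

    def __init__(
        self,
        children: list[list[int]],
        parent: list[int],
        lengths: list[float],
        labels: list[str | None],
    ):
        self.children = children
        self.parent = parent
        self.lengths = np.array(lengths, dtype=float)
        self.labels = labels
        self.root = parent.index(-1)
        order: list[int] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            order.append(node)
            stack.extend(children[node])
        self.postorder = order[::-1]  # children before parents, root last
        self.edge_nodes = [n for n in self.postorder if n != self.root]
        # any labelled node carries observed data (the root is labelled in
        # the 2-taxon single-edge layout)
        self.leaf_node = {
            labels[n]: n for n in range(len(parent)) if labels[n] is not None
        }

    # -- construction ------------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        tree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
        return cls.from_dendropy(tree)

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "PhyloTree":
        n_leaves = len(tree.leaf_nodes())
        root = tree.seed_node
        if len(root._child_nodes) == 2 and n_leaves > 2:
            # collapse the degree-2 root: traversal root becomes trifurcating
            tree.deroot()
            root = tree.seed_node
        if len(root._child_nodes) == 2 and n_leaves == 2:
            # a 2-taxon unrooted tree is a single edge: root at one leaf
            a, b = root._child_nodes
            total = (a.edge.length or 0.0) + (b.edge.length or 0.0)
            return cls(
                children=[[1], []],
                parent=[-1, 0],
                lengths=[0.0, total],
                labels=[a.taxon.label, b.taxon.label],
            )
        nodes = list(tree.preorder_node_iter())
        index = {id(n): i for i, n in enumerate(nodes)}
        children = [[index[id(c)] for c in n._child_nodes] for n in nodes]
        parent = [
            -1 if n.parent_node is None else index[id(n.parent_node)] for n in nodes
        ]
        lengths = [
            0.0 if n.parent_node is None else
            (float(n.edge.length) if n.edge.length is not None else np.nan)
            for n in nodes
        ]
        labels = [n.taxon.label if n.taxon is not None else None for n in nodes]
        return cls(children, parent, lengths, labels)

    # -- basic accessors ---------------------------------------------------

    @property
    def taxa(self) -> tuple[str, ...]:
        return tuple(sorted(self.leaf_node))

    @property
    def n_taxa(self) -> int:
        return len(self.leaf_node)

    @property
    def n_edges(self) -> int:
        return len(self.edge_nodes)

    @property
    def branch_lengths(self) -> np.ndarray:
        """Edge lengths in postorder edge enumeration."""
        return self.lengths[self.edge_nodes].copy()

    def with_branch_lengths(self, values: np.ndarray) -> "PhyloTree":
        values = np.asarray(values, dtype=float)
        if values.shape != (self.n_edges,):
            raise ValueError(f"expected {self.n_edges} branch lengths")
        clone = PhyloTree(
            [list(c) for c in self.children],
            list(self.parent),
            list(self.lengths),
            list(self.labels),
        )
        clone.lengths[clone.edge_nodes] = values
        return clone

    def has_branch_lengths(self) -> bool:
        return not np.isnan(self.lengths[self.edge_nodes]).any()

    def total_length(self) -> float:
        return float(self.lengths[self.edge_nodes].sum())

    def to_newick(self) -> str:
        def render(node: int) -> str:
            if not self.children[node]:
                body = self.labels[node]
            else:
                body = "(" + ",".join(render(c) for c in self.children[node]) + ")"
            if node == self.root:
                return f"{body};"
            return f"{body}:{self.lengths[node]:.10g}"

        return render(self.root)


# --------------------------------------------------------------------------
# Pruning likelihood


class PruningEngine:
    """Felsenstein pruning over compressed site patterns for one (tree, alignment).

    Compresses identical alignment columns once at construction; each
    :meth:`loglik` call reuses the pattern table and the tree traversal.
    """

    def __init__(self, tree: PhyloTree, aln: CodonAlignment):
        tree_taxa = set(tree.leaf_node)
        aln_taxa = set(aln.taxa)
        if tree_taxa != aln_taxa:
            only_t = sorted(tree_taxa - aln_taxa)
            only_a = sorted(aln_taxa - tree_taxa)
            raise ValueError(
                f"taxon mismatch between tree and alignment: "
                f"tree-only={only_t}, alignment-only={only_a}"
            )
        self.tree = tree
        self.aln = aln
        patterns, inverse, counts = np.unique(
            aln.codon_states, axis=1, return_inverse=True, return_counts=True
        )
        self.patterns = patterns            # (n_taxa, n_patterns)
        self.pattern_weights = counts.astype(float)
        self.site_to_pattern = inverse
        self.taxon_row = {t: i for i, t in enumerate(aln.taxa)}

    @property
    def n_patterns(self) -> int:
        return self.patterns.shape[1]

    def loglik(
        self, model: CodonRateMatrix, branch_lengths: np.ndarray | None = None
    ) -> float:
        tree = self.tree
        lengths = tree.lengths.copy()
        if branch_lengths is not None:
            lengths[tree.edge_nodes] = branch_lengths
        n_states = model.n_states
        n_pat = self.n_patterns
        w, B, C = model.eigendecomposition()

        partial: dict[int, np.ndarray] = {}
        logscale = np.zeros(n_pat)
        for node in tree.postorder:
            is_leaf = not tree.children[node]
            if is_leaf:
                L = None  # folded into the parent via a column gather
            else:
                L = np.ones((n_states, n_pat))
                for child in tree.children[node]:
                    t = lengths[child]
                    P = (B * np.exp(w * t)) @ C
                    np.clip(P, 0.0, None, out=P)
                    if not tree.children[child]:
                        states = self.patterns[self.taxon_row[tree.labels[child]]]
                        down = P[:, np.where(states >= 0, states, 0)]
                        down[:, states < 0] = 1.0
                    else:
                        down = P @ partial.pop(child)
                    L *= down
                m = L.max(axis=0)
                m[m == 0] = 1.0
                L /= m
                logscale += np.log(m)
            partial[node] = L

        root = tree.root
        L_root = partial[root]
        if L_root is None:  # single-node tree: root is the only leaf
            L_root = np.ones((n_states, n_pat))
        if tree.labels[root] in self.taxon_row:
            # root carries an observed state (single-taxon or 2-taxon layout)
            states = self.patterns[self.taxon_row[tree.labels[root]]]
            mask = np.zeros((n_states, n_pat))
            mask[np.where(states >= 0, states, 0), np.arange(n_pat)] = 1.0
            mask[:, states < 0] = 1.0
            L_root = L_root * mask
        site_lik = model.stationary @ L_root
        if np.any(site_lik <= 0):
            return -np.inf
        per_pattern = np.log(site_lik) + logscale
        return float(per_pattern @ self.pattern_weights)


def log_likelihood(
    tree: PhyloTree, aln: CodonAlignment, model: CodonRateMatrix
) -> float:
    """Pruning log-likelihood of ``aln`` on ``tree`` under ``model``."""
    return PruningEngine(tree, aln).loglik(model)


# --------------------------------------------------------------------------
# Maximum-likelihood fitting


@dataclass(frozen=True)
class FitOptions:
    """Controls for :func:`fit`.

    freq_mode
        "ml" (default): position-specific frequencies optimized by
        maximum likelihood (9 free parameters); "observed": fixed at
        alignment proportions (0 free parameters, faster, but the
        plug-in can distort likelihood-ratio comparisons).
    bias_mode
        "rev": 5 free nucleotide biases (A<->G fixed at 1);
        "hky": transitions fixed at 1, a single transversion bias.
    """

    freq_mode: str = "ml"
    bias_mode: str = "rev"
    optimize_branch_lengths: bool = True
    tol: float = 1e-8
    max_cycles: int = 25
    block_maxiter: int = 60
    restarts: int = 0
    seed: int = 0
    init: dict | None = None

    def __post_init__(self):
        if self.freq_mode not in ("observed", "ml"):
            raise ValueError(f"freq_mode must be 'observed' or 'ml': {self.freq_mode}")
        if self.bias_mode not in ("rev", "hky"):
            raise ValueError(f"bias_mode must be 'rev' or 'hky': {self.bias_mode}")


@dataclass
class ParameterCount:
    branches: int
    biases: int
    frequencies: int
    rates: int

    @property
    def total(self) -> int:
        return self.branches + self.biases + self.frequencies + self.rates


def count_free_parameters(
    assignment: RateClassAssignment,
    tree: PhyloTree,
    options: FitOptions | None = None,
) -> ParameterCount:
    """Free-parameter accounting for degrees of freedom and BIC.

    Branch lengths (2n-3 on an unrooted binary tree) count when they are
    optimized; empty rate classes are excluded — only the effective
    (occupied) class count is estimable.
    """
    options = options or FitOptions()
    return ParameterCount(
        branches=tree.n_edges if options.optimize_branch_lengths else 0,
        biases=5 if options.bias_mode == "rev" else 1,
        frequencies=9 if options.freq_mode == "ml" else 0,
        rates=assignment.n_effective_classes,
    )


@dataclass
class FitResult:
    """Outcome of a maximum-likelihood fit."""

    log_likelihood: float
    estimates: dict
    n_free_parameters: int
    n_rate_parameters: int
    converged: bool
    boundary: bool
    model_descriptor: dict
    assignment: RateClassAssignment = field(repr=False)
    seed: int = 0
    n_cycles: int = 0

    def to_json(self) -> str:
        estimates = dict(self.estimates)
        if "rho" in estimates:  # empty classes carry no estimate
            estimates["rho"] = [
                None if r is None or (isinstance(r, float) and np.isnan(r)) else r
                for r in estimates["rho"]
            ]
        payload = {
            "log_likelihood": self.log_likelihood,
            "estimates": estimates,
            "n_free_parameters": self.n_free_parameters,
            "n_rate_parameters": self.n_rate_parameters,
            "converged": self.converged,
            "boundary": self.boundary,
            "model_descriptor": self.model_descriptor,
            "seed": self.seed,
            "n_cycles": self.n_cycles,
        }
        return json.dumps(payload, indent=1)


def _theta_from_free(free: np.ndarray, bias_mode: str) -> np.ndarray:
    theta = np.ones(6)
    if bias_mode == "rev":
        idx = [i for i in range(6) if i != AG_INDEX]
        theta[idx] = free
    else:  # hky: transitions (A<->G, C<->T) at 1, one transversion bias
        theta[[0, 2, 3, 5]] = free[0]
    return theta


def _pi_from_logits(logits: np.ndarray) -> np.ndarray:
    z = logits.reshape(3, 3)
    full = np.concatenate([z, np.zeros((3, 1))], axis=1)
    e = np.exp(full - full.max(axis=1, keepdims=True))
    return e / e.sum(axis=1, keepdims=True)


def _logits_from_pi(pi: np.ndarray) -> np.ndarray:
    ref = np.log(pi[:, 3:4])
    return (np.log(pi[:, :3]) - ref).ravel()


def _mean_p_distance(aln: CodonAlignment) -> float:
    states = aln.codon_states
    n = aln.n_taxa
    if n < 2:
        return 0.1
    total, count = 0.0, 0
    for i in range(n):
        for j in range(i + 1, n):
            ok = (states[i] >= 0) & (states[j] >= 0)
            if ok.sum():
                total += (states[i][ok] != states[j][ok]).mean()
                count += 1
    return total / count if count else 0.1


def fit(
    tree: PhyloTree,
    aln: CodonAlignment,
    assignment: RateClassAssignment,
    options: FitOptions | None = None,
) -> FitResult:
    """Jointly optimize branch lengths, biases, frequencies and class rates.

    Uses block-coordinate ascent with L-BFGS-B per block; rate-like
    parameters are optimized in log space inside ``RATE_BOUNDS``.  The
    returned log-likelihood is never below the value at the
    initialization point, so warm-starting a richer model from a nested
    fit preserves likelihood ordering.
    """
    options = options or FitOptions()
    init = dict(options.init or {})
    qb = QBuilder(assignment, universal_code())
    engine = PruningEngine(tree, aln)
    occ = list(assignment.occupied_classes)
    n_occ = len(occ)
    n_bias = 5 if options.bias_mode == "rev" else 1

    # --- initialization ---------------------------------------------------
    if "branch_lengths" in init:
        b0 = np.asarray(init["branch_lengths"], dtype=float)
    elif tree.has_branch_lengths():
        b0 = tree.branch_lengths
    else:
        b0 = np.full(tree.n_edges, np.clip(_mean_p_distance(aln) / 2, 0.01, 5.0))
    b0 = np.clip(b0, *BRANCH_BOUNDS)

    pi_obs = observed_positional_frequencies(aln)
    pi0 = np.asarray(init.get("pi", pi_obs), dtype=float)
    theta0 = np.asarray(init.get("theta", np.ones(6)), dtype=float)
    rho_full0 = np.asarray(init.get("rho", np.ones(assignment.n_classes)), dtype=float)
    rho0 = np.clip(rho_full0[occ], *RATE_BOUNDS)
    if options.bias_mode == "rev":
        th_free0 = theta0[[i for i in range(6) if i != AG_INDEX]]
    else:
        th_free0 = np.array([theta0[0]])
    th_free0 = np.clip(th_free0, *RATE_BOUNDS)

    log_lo, log_hi = np.log(RATE_BOUNDS[0]), np.log(RATE_BOUNDS[1])
    blog_lo, blog_hi = np.log(BRANCH_BOUNDS[0]), np.log(BRANCH_BOUNDS[1])

    rng = np.random.default_rng(options.seed)

    def run_once(b, rho_occ, th_free, pi):
        rho_full = rho_full0.copy()

        def current_model():
            rho_full[occ] = rho_occ
            theta = _theta_from_free(th_free, options.bias_mode)
            return qb.build(rho_full, theta, pi)

        ll = engine.loglik(current_model(), b)
        converged = False
        n_cycles = 0
        for _ in range(options.max_cycles):
            n_cycles += 1
            ll_start = ll

            if options.optimize_branch_lengths and tree.n_edges:
                model = current_model()
                model.eigendecomposition()  # cache once for the whole block

                def nll_b(x):
                    v = engine.loglik(model, np.exp(x))
                    return -v if np.isfinite(v) else _PENALTY

                res = minimize(
                    nll_b,
                    np.log(b),
                    method="L-BFGS-B",
                    bounds=[(blog_lo, blog_hi)] * len(b),
                    options={"maxiter": options.block_maxiter},
                )
                if -res.fun >= ll:
                    b, ll = np.exp(res.x), -res.fun

            # substitution-model block: rho, theta (and pi when ML)
            ml_pi = options.freq_mode == "ml"
            x0 = np.concatenate(
                [np.log(rho_occ), np.log(th_free)]
                + ([_logits_from_pi(pi)] if ml_pi else [])
            )
            bounds = [(log_lo, log_hi)] * (n_occ + n_bias) + (
                [(-_LOGIT_BOUND, _LOGIT_BOUND)] * 9 if ml_pi else []
            )

            def nll_m(x):
                r = np.exp(x[:n_occ])
                tf = np.exp(x[n_occ : n_occ + n_bias])
                p = _pi_from_logits(x[n_occ + n_bias :]) if ml_pi else pi
                rho_full[occ] = r
                theta = _theta_from_free(tf, options.bias_mode)
                v = engine.loglik(qb.build(rho_full, theta, p), b)
                return -v if np.isfinite(v) else _PENALTY

            res = minimize(
                nll_m,
                x0,
                method="L-BFGS-B",
                bounds=bounds,
                options={"maxiter": options.block_maxiter},
            )
            if -res.fun >= ll:
                ll = -res.fun
                rho_occ = np.exp(res.x[:n_occ])
                th_free = np.exp(res.x[n_occ : n_occ + n_bias])
                if ml_pi:
                    pi = _pi_from_logits(res.x[n_occ + n_bias :])

            if ll - ll_start <= options.tol * max(abs(ll), 1.0):
                converged = True
                break
        return ll, b, rho_occ, th_free, pi, converged, n_cycles

    best = run_once(b0.copy(), rho0.copy(), th_free0.copy(), pi0.copy())
    for _ in range(options.restarts):
        jitter = lambda v: np.clip(v * rng.lognormal(0.0, 0.5, size=v.shape), *RATE_BOUNDS)
        cand = run_once(
            np.clip(b0 * rng.lognormal(0.0, 0.3, size=b0.shape), *BRANCH_BOUNDS),
            jitter(rho0),
            jitter(th_free0),
            pi0.copy(),
        )
        if cand[0] > best[0]:
            best = cand

    ll, b, rho_occ, th_free, pi, converged, n_cycles = best
    rho_full = np.full(assignment.n_classes, np.nan)
    rho_full[occ] = rho_occ
    theta = _theta_from_free(th_free, options.bias_mode)

    eps = 1e-4
    # a branch below 1e-6 expected substitutions is an effectively-zero
    # (degenerate) estimate, reported as a boundary solution
    at_bound = (
        np.any(rho_occ <= RATE_BOUNDS[0] * (1 + eps))
        or np.any(rho_occ >= RATE_BOUNDS[1] * (1 - eps))
        or np.any(th_free <= RATE_BOUNDS[0] * (1 + eps))
        or np.any(th_free >= RATE_BOUNDS[1] * (1 - eps))
        or np.any(b <= 1e-6)
        or np.any(b >= BRANCH_BOUNDS[1] * (1 - eps))
    )

    counts = count_free_parameters(assignment, tree, options)
    return FitResult(
        log_likelihood=ll,
        estimates={
            "branch_lengths": b.tolist(),
            "rho": rho_full.tolist(),
            "theta": theta.tolist(),
            "pi": pi.tolist(),
        },
        n_free_parameters=counts.total,
        n_rate_parameters=counts.rates,
        converged=bool(converged),
        boundary=bool(at_bound),
        model_descriptor={
            "label": assignment.label,
            "n_classes": assignment.n_classes,
            "n_effective_classes": assignment.n_effective_classes,
            "freq_mode": options.freq_mode,
            "bias_mode": options.bias_mode,
            "optimize_branch_lengths": options.optimize_branch_lengths,
        },
        assignment=assignment,
        seed=options.seed,
        n_cycles=n_cycles,
    )


def warm_start_options(base: FitOptions, from_fit: FitResult, n_classes: int) -> FitOptions:
    """Options whose starting point is a nested fit's optimum.

    All classes of the richer model start at the nested model's single
    shared rate (or at the matching class rates), which guarantees the
    optimized likelihood can only improve on the nested one.
    """
    rho_prev = np.asarray(from_fit.estimates["rho"], dtype=float)
    base_rate = np.nanmean(rho_prev) if rho_prev.size else 1.0
    init = {
        "branch_lengths": from_fit.estimates["branch_lengths"],
        "theta": from_fit.estimates["theta"],
        "pi": np.asarray(from_fit.estimates["pi"], dtype=float),
        "rho": np.full(n_classes, base_rate),
    }
    return replace(base, init=init)
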