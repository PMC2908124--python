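"""Codon rate matrices for the SR / multi-rate / REV model family.

The instantaneous rate between two sense codons that differ at exactly
one nucleotide position is a product of three multipliers:

* an amino-acid exchangeability ``rho`` shared by all codon pairs whose
  residue pair falls in the same rate class (1 for synonymous changes,
  so every ``rho`` is a non-synonymous/synonymous rate ratio — the
  classical omega when there is a single class);
* a symmetric nucleotide mutational bias ``theta`` for the unordered
  pair of exchanged nucleotides (A<->G fixed at 1 for identifiability);
* the frequency of the target nucleotide at the codon position being
  substituted, ``pi[position][nucleotide]``.

Rates between codons differing at more than one position are zero.  The
stationary distribution of this family is the product of the positional
nucleotide frequencies restricted to sense codons, and the chain is time
reversible by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .gencode import (
    NUCLEOTIDES,
    GeneticCode,
    CodonStateSpace,
    exchangeable_residue_pairs,
    one_step_events,
    sense_codon_space,
    universal_code,
)

#: Unordered nucleotide pairs, in fixed order; index 1 (A<->G) is the
#: reference bias fixed at 1.
NUC_PAIRS: tuple[tuple[str, str], ...] = (
    ("A", "C"),
    ("A", "G"),
    ("A", "T"),
    ("C", "G"),
    ("C", "T"),
    ("G", "T"),
)
AG_INDEX = 1
_NUC_PAIR_INDEX = {frozenset(p): i for i, p in enumerate(NUC_PAIRS)}
_NUC_INDEX = {n: i for i, n in enumerate(NUCLEOTIDES)}

PairKey = tuple[str, str]


def _pair_key(pair) -> PairKey:
    a, b = sorted(pair)
    return (a, b)


@dataclass(frozen=True)
class RateClassAssignment:
    """Partition of the one-step residue pairs into K exchangeability classes.

    The assignment is over residue *pairs*, not residues, so no
    transitivity is implied: {A,S} and {S,T} may share a class while
    {A,T} sits elsewhere (indeed {A,T}-like two-step pairs are not in
    the domain at all).
    """

    n_classes: int
    class_of: dict[PairKey, int] = field(repr=False)
    label: str = "custom"

    def __post_init__(self) -> None:
        if self.n_classes < 1:
            raise ValueError("n_classes must be >= 1")
        bad = [c for c in self.class_of.values() if not 0 <= c < self.n_classes]
        if bad:
            raise ValueError(f"class indices out of range [0, {self.n_classes}): {bad[:5]}")

    @property
    def occupied_classes(self) -> tuple[int, ...]:
        return tuple(sorted(set(self.class_of.values())))

    @property
    def n_effective_classes(self) -> int:
        """Number of non-empty classes — the estimable rate-parameter count."""
        return len(set(self.class_of.values()))

    def refines(self, other: "RateClassAssignment") -> bool:
        """True if this partition refines ``other`` (``other`` nested in self).

        Every class of this assignment must map into a single class of
        ``other`` over the shared pair domain.
        """
        if set(self.class_of) != set(other.class_of):
            return False
        image: dict[int, int] = {}
        for pair, c in self.class_of.items():
            o = other.class_of[pair]
            if image.setdefault(c, o) != o:
                return False
        return True

    def to_json(self) -> str:
        classes = {f"{a}:{b}": c for (a, b), c in sorted(self.class_of.items())}
        return json.dumps(
            {"n_classes": self.n_classes, "label": self.label, "classes": classes},
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "RateClassAssignment":
        obj = json.loads(text)
        class_of = {
            _pair_key(key.split(":")): int(c) for key, c in obj["classes"].items()
        }
        return cls(
            n_classes=int(obj["n_classes"]),
            class_of=class_of,
            label=obj.get("label", "custom"),
        )


@lru_cache(maxsize=8)
def _pair_keys_for_table(table_id: int) -> tuple[PairKey, ...]:
    from .gencode import build_genetic_code

    code = build_genetic_code(table_id)
    return tuple(
        _pair_key(p) for p in exchangeable_residue_pairs(code).sorted_pairs()
    )


def _pair_keys(code: GeneticCode) -> list[PairKey]:
    return list(_pair_keys_for_table(code.table_id))


def sr_assignment(code: GeneticCode | None = None) -> RateClassAssignment:
    """Single-rate model: all one-step residue pairs share one class (omega)."""
    code = code or universal_code()
    return RateClassAssignment(
        n_classes=1, class_of={p: 0 for p in _pair_keys(code)}, label="SR"
    )


def rev_assignment(code: GeneticCode | None = None) -> RateClassAssignment:
    """General reversible model: each one-step pair gets its own class."""
    code = code or universal_code()
    keys = _pair_keys(code)
    return RateClassAssignment(
        n_classes=len(keys), class_of={p: i for i, p in enumerate(keys)}, label="REV"
    )


def random_assignment(
    K: int, seed: int, code: GeneticCode | None = None
) -> RateClassAssignment:
    """Assign each one-step pair independently and uniformly to one of K classes.

    Classes may end up empty under independent draws; the effective
    (non-empty) class count is what enters degrees-of-freedom and BIC
    accounting downstream.
    """
    code = code or universal_code()
    keys = _pair_keys(code)
    if not 1 <= K <= len(keys):
        raise ValueError(f"K must be in 1..{len(keys)}, got {K}")
    rng = np.random.default_rng(seed)
    draws = rng.integers(0, K, size=len(keys))
    return RateClassAssignment(
        n_classes=K,
        class_of={p: int(c) for p, c in zip(keys, draws)},
        label=f"random-K{K}-seed{seed}",
    )


# --------------------------------------------------------------------------
# Event table: vectorised description of all one-step transitions, cached
# per translation table.

@dataclass(frozen=True)
class _EventTable:
    space: CodonStateSpace
    src: np.ndarray        # state index of source codon
    dst: np.ndarray        # state index of target codon
    pos: np.ndarray        # codon position 0..2
    pair_idx: np.ndarray   # index into NUC_PAIRS
    tgt_nuc: np.ndarray    # index into NUCLEOTIDES of the target nucleotide
    synonymous: np.ndarray  # bool
    residue_pair: tuple[PairKey, ...]  # key per event ("", "") if synonymous
    codon_nuc: np.ndarray  # (n_states, 3) nucleotide index at each position


@lru_cache(maxsize=8)
def _event_table(table_id: int) -> _EventTable:
    from .gencode import build_genetic_code

    code = build_genetic_code(table_id)
    space = sense_codon_space(code)
    events = one_step_events(code)
    src = np.array([space.index[e.source_codon] for e in events])
    dst = np.array([space.index[e.target_codon] for e in events])
    pos = np.array([e.position - 1 for e in events])
    pair_idx = np.array([_NUC_PAIR_INDEX[e.nucleotide_pair] for e in events])
    tgt = np.array(
        [_NUC_INDEX[e.target_codon[e.position - 1]] for e in events]
    )
    syn = np.array([e.synonymous for e in events])
    rp = tuple(
        _pair_key(e.residue_pair) if not e.synonymous else ("", "")
        for e in events
    )
    codon_nuc = np.array(
        [[_NUC_INDEX[c[k]] for k in range(3)] for c in space.states]
    )
    return _EventTable(space, src, dst, pos, pair_idx, tgt, syn, rp, codon_nuc)


# --------------------------------------------------------------------------
# Rate matrix


@dataclass
class CodonRateMatrix:
    """A 61x61 (universal code) instantaneous codon rate matrix.

    ``scale`` is the expected number of substitutions per unit time at
    stationarity *before* normalisation; when built with
    ``normalize=True`` the matrix itself yields one expected substitution
    per unit branch length.
    """

    Q: np.ndarray
    stationary: np.ndarray
    scale: float
    space: CodonStateSpace
    _decomp: tuple[np.ndarray, np.ndarray, np.ndarray] | None = field(
        default=None, repr=False, compare=False
    )

    @property
    def n_states(self) -> int:
        return self.Q.shape[0]

    def eigendecomposition(self):
        """Symmetric-similarity eigendecomposition, cached.

        Reversibility makes ``S = D^{1/2} Q D^{-1/2}`` symmetric
        (D = diag(stationary)); P(t) then follows from one ``eigh``.
        """
        if self._decomp is None:
            d = np.sqrt(self.stationary)
            S = (self.Q * d[:, None]) / d[None, :]
            S = 0.5 * (S + S.T)  # symmetrise away rounding noise
            w, U = np.linalg.eigh(S)
            # columns of left/right transforms: P(t) = B exp(wt) C
            B = U / d[:, None]
            C = U.T * d[None, :]
            self._decomp = (w, B, C)
        return self._decomp

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt); rows sum to 1, entries clipped at 0."""
        if t < 0:
            raise ValueError(f"branch length must be >= 0, got {t}")
        w, B, C = self.eigendecomposition()
        P = (B * np.exp(w * t)) @ C
        np.clip(P, 0.0, None, out=P)
        return P


def stationary_distribution(
    pi: np.ndarray, code: GeneticCode | None = None
) -> np.ndarray:
    """Stationary codon distribution from position-specific frequencies.

    ``stationary[c1 c2 c3]`` is proportional to
    ``pi[0][c1] * pi[1][c2] * pi[2][c3]``, renormalised over the sense
    codons.  This product form is the exact stationary law of the matrix
    family built by :func:`build_q` (a consequence of detailed balance).
    """
    code = code or universal_code()
    pi = _validate_pi(pi)
    space = sense_codon_space(code)
    vec = np.array(
        [
            pi[0, _NUC_INDEX[c[0]]] * pi[1, _NUC_INDEX[c[1]]] * pi[2, _NUC_INDEX[c[2]]]
            for c in space.states
        ]
    )
    return vec / vec.sum()


def _validate_pi(pi: np.ndarray) -> np.ndarray:
    pi = np.asarray(pi, dtype=float)
    if pi.shape != (3, 4):
        raise ValueError(f"pi must be 3x4 (positions x ACGT), got {pi.shape}")
    if np.any(pi <= 0):
        raise ValueError("positional frequencies must be strictly positive")
    if not np.allclose(pi.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("each position's frequencies must sum to 1")
    return pi


class QBuilder:
    """Repeated rate-matrix assembly for one (code, assignment) pair.

    Precomputes the per-event class lookup so optimizers can rebuild Q
    thousands of times without re-touching the genetic code.
    """

    def __init__(
        self, assignment: RateClassAssignment, code: GeneticCode | None = None
    ):
        self.code = code or universal_code()
        self.assignment = assignment
        self.table = _event_table(self.code.table_id)
        self.class_ids = np.array(
            [
                assignment.class_of[rp] if not syn else -1
                for rp, syn in zip(self.table.residue_pair, self.table.synonymous)
            ]
        )

    def stationary(self, pi: np.ndarray) -> np.ndarray:
        cn = self.table.codon_nuc
        vec = pi[0, cn[:, 0]] * pi[1, cn[:, 1]] * pi[2, cn[:, 2]]
        return vec / vec.sum()

    def build(
        self,
        rho: np.ndarray,
        theta: np.ndarray,
        pi: np.ndarray,
        normalize: bool = True,
    ) -> CodonRateMatrix:
        tab = self.table
        n = tab.space.n_states
        mult = np.where(tab.synonymous, 1.0, rho[self.class_ids])
        rates = mult * theta[tab.pair_idx] * pi[tab.pos, tab.tgt_nuc]

        Q = np.zeros((n, n))
        Q[tab.src, tab.dst] = rates
        np.fill_diagonal(Q, -Q.sum(axis=1))

        stat = self.stationary(pi)
        scale = float(-(stat * np.diag(Q)).sum())
        if normalize:
            if scale <= 0:
                raise ValueError("cannot normalize a zero rate matrix")
            Q = Q / scale
        return CodonRateMatrix(Q=Q, stationary=stat, scale=scale, space=tab.space)


def build_q(
    assignment: RateClassAssignment,
    rho: np.ndarray,
    theta: np.ndarray,
    pi: np.ndarray,
    code: GeneticCode | None = None,
    normalize: bool = True,
) -> CodonRateMatrix:
    """Assemble the codon rate matrix from its three multipliers.

    Parameters
    ----------
    assignment
        Partition of the one-step residue pairs into rate classes.
    rho
        One exchangeability per class (length ``assignment.n_classes``),
        relative to the synonymous baseline of 1.
    theta
        Six symmetric nucleotide biases in :data:`NUC_PAIRS` order;
        ``theta[1]`` is the A<->G reference (conventionally 1).
    pi
        3x4 position-specific nucleotide frequencies (rows sum to 1).
    normalize
        Rescale so the stationary expected substitution rate is exactly 1.
    """
    code = code or universal_code()
    rho = np.asarray(rho, dtype=float)
    theta = np.asarray(theta, dtype=float)
    pi = _validate_pi(pi)
    if rho.shape != (assignment.n_classes,):
        raise ValueError(
            f"rho must have length {assignment.n_classes}, got {rho.shape}"
        )
    if np.any(rho < 0):
        raise ValueError("exchangeabilities must be >= 0")
    if theta.shape != (6,):
        raise ValueError(f"theta must have 6 entries, got {theta.shape}")
    if np.any(theta < 0):
        raise ValueError("nucleotide biases must be >= 0")
    return QBuilder(assignment, code).build(rho, theta, pi, normalize=normalize)


def transition_matrix(model: CodonRateMatrix, t: float) -> np.ndarray:
    """Transition probabilities over a branch of length ``t`` (see method)."""
    return model.transition_matrix(t)


def uniform_pi() -> np.ndarray:
    """Uniform position-specific frequencies (each nucleotide 1/4)."""
    return np.full((3, 4), 0.25)
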