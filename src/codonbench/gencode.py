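"""Genetic-code machinery for codon substitution models.

Defines the sense-codon state space, the single-nucleotide neighbour
relation between sense codons, and the set of amino-acid residue pairs
that are exchangeable through a single nucleotide substitution.  Under
the universal (standard) code there are 61 sense codons and exactly 75
such one-step residue pairs, out of the 190 unordered pairs of the 20
residues.  That set of 75 pairs is the index set over which multi-rate
codon models assign exchangeability classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

from Bio.Data import CodonTable

NUCLEOTIDES = "ACGT"
STOP = "*"

#: Translation-table aliases accepted by :func:`build_genetic_code`.
_TABLE_ALIASES = {
    "universal": 1,
    "standard": 1,
}


@dataclass(frozen=True)
class GeneticCode:
    """A complete 64-entry codon -> residue map for one translation table.

    ``codon_to_residue`` maps every codon (DNA alphabet, e.g. ``"TGG"``)
    to a one-letter residue code, with ``"*"`` marking stop codons.
    """

    table_id: int
    codon_to_residue: dict[str, str]

    def __post_init__(self) -> None:
        if len(self.codon_to_residue) != 64:
            raise ValueError(
                f"genetic code must map all 64 codons, got {len(self.codon_to_residue)}"
            )

    @property
    def stop_codons(self) -> tuple[str, ...]:
        return tuple(
            sorted(c for c, aa in self.codon_to_residue.items() if aa == STOP)
        )

    def translate(self, codon: str) -> str:
        return self.codon_to_residue[codon]

    def is_stop(self, codon: str) -> bool:
        return self.codon_to_residue[codon] == STOP


@dataclass(frozen=True)
class CodonStateSpace:
    """Ordered sense-codon state space with a codon <-> integer bijection.

    Ordering is lexicographic with nucleotide order A < C < G < T, so all
    rate matrices and frequency vectors built on top of this space are
    reproducible without further convention.
    """

    states: tuple[str, ...]
    index: dict[str, int] = field(repr=False)

    @property
    def n_states(self) -> int:
        return len(self.states)

    def __len__(self) -> int:
        return len(self.states)

    def codon(self, i: int) -> str:
        return self.states[i]


@dataclass(frozen=True)
class SubstitutionEvent:
    """A single-nucleotide change between two sense codons.

    ``position`` is the codon position (1, 2 or 3) at which the codons
    differ; ``nucleotide_pair`` is the unordered pair of nucleotides
    exchanged; ``synonymous`` is True when both codons encode the same
    residue.
    """

    source_codon: str
    target_codon: str
    position: int
    nucleotide_pair: frozenset[str]
    synonymous: bool
    source_residue: str
    target_residue: str

    @property
    def residue_pair(self) -> frozenset[str]:
        return frozenset((self.source_residue, self.target_residue))


@dataclass(frozen=True)
class ResiduePairSet:
    """Unordered residue pairs reachable by one nucleotide substitution."""

    pairs: frozenset[frozenset[str]]

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, pair) -> bool:
        return frozenset(pair) in self.pairs

    def sorted_pairs(self) -> list[tuple[str, str]]:
        """Pairs as sorted 2-tuples, in deterministic lexicographic order."""
        return sorted(tuple(sorted(p)) for p in self.pairs)


def build_genetic_code(table_id: int | str = 1) -> GeneticCode:
    """Build a :class:`GeneticCode` from a standard NCBI translation table.

    Parameters
    ----------
    table_id
        NCBI translation-table number, or one of the aliases
        ``"universal"`` / ``"standard"`` for table 1.

    Raises
    ------
    ValueError
        If the table identifier is not a known translation table.
    """
    if isinstance(table_id, str):
        key = table_id.strip().lower()
        if key in _TABLE_ALIASES:
            table_id = _TABLE_ALIASES[key]
        elif key.isdigit():
            table_id = int(key)
        else:
            raise ValueError(f"unsupported translation table: {table_id!r}")
    try:
        table = CodonTable.unambiguous_dna_by_id[int(table_id)]
    except KeyError as exc:
        raise ValueError(f"unsupported translation table: {table_id!r}") from exc

    mapping = dict(table.forward_table)
    for codon in table.stop_codons:
        mapping[codon] = STOP
    # some tables list codons as both start and sense; forward_table + stops
    # covers all 64 for unambiguous DNA tables
    return GeneticCode(table_id=int(table_id), codon_to_residue=mapping)


def sense_codon_space(code: GeneticCode) -> CodonStateSpace:
    """Ordered state space of sense (non-stop) codons."""
    states = tuple(
        sorted(c for c, aa in code.codon_to_residue.items() if aa != STOP)
    )
    return CodonStateSpace(states=states, index={c: i for i, c in enumerate(states)})


def one_step_events(code: GeneticCode) -> list[SubstitutionEvent]:
    """All ordered sense->sense codon pairs differing at exactly one position.

    Each event is annotated with the codon position of the change, the
    unordered nucleotide pair, and whether the change is synonymous.  The
    listing is symmetric: ``i -> j`` is present iff ``j -> i`` is.
    """
    space = sense_codon_space(code)
    events: list[SubstitutionEvent] = []
    for source in space.states:
        for pos in range(3):
            for nuc in NUCLEOTIDES:
                if nuc == source[pos]:
                    continue
                target = source[:pos] + nuc + source[pos + 1 :]
                if code.is_stop(target):
                    continue
                aa_s = code.translate(source)
                aa_t = code.translate(target)
                events.append(
                    SubstitutionEvent(
                        source_codon=source,
                        target_codon=target,
                        position=pos + 1,
                        nucleotide_pair=frozenset((source[pos], nuc)),
                        synonymous=aa_s == aa_t,
                        source_residue=aa_s,
                        target_residue=aa_t,
                    )
                )
    return events


def exchangeable_residue_pairs(code: GeneticCode) -> ResiduePairSet:
    """Distinct residue pairs among the non-synonymous one-step events.

    Under the universal code this set has exactly 75 members.  Pairs are
    unordered: the models built on top of this set are time reversible,
    so the exchangeability of (a, b) equals that of (b, a).
    """
    pairs = frozenset(
        ev.residue_pair for ev in one_step_events(code) if not ev.synonymous
    )
    return ResiduePairSet(pairs=pairs)


@lru_cache(maxsize=8)
def _cached_code(table_id: int = 1) -> GeneticCode:
    return build_genetic_code(table_id)


def universal_code() -> GeneticCode:
    """The universal (standard) genetic code, cached."""
    return _cached_code(1)
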