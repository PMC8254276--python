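"""Molecular formulae, the valence model, and hydrogen distribution.

A constitutional-isomer generator takes nothing but a molecular formula such
as ``C10H16O``.  This module turns the formula into the combinatorial inputs
of the matrix generator:

* a fixed lowest-valence table (C=4, N=3, P=3, O=2, S=2, halogens=1, H=1);
* a deterministic ordering of the heavy (non-hydrogen) atoms together with
  the initial ordered partition grouping interchangeable atoms;
* the exhaustive, duplicate-free list of ways to distribute the hydrogens
  onto the heavy atoms.

Hydrogens are distributed up front because an H atom has valence 1 and can
only ever be a pendant neighbour: once each heavy atom knows its hydrogen
count, the hydrogens can be dropped from the generation entirely and the
generator works on a p×p matrix over heavy atoms only (a 6×6 instead of a
12×12 matrix for C6H6).  Each distribution fixes a *degree state*: the
residual valence each heavy atom must realise through heavy-heavy bonds.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

from .errors import GraphNonexistent, InvalidInput, ParseError, UnsupportedElement
from .partitions import OrderedPartition

__all__ = [
    "SUPPORTED_VALENCES",
    "MolecularFormula",
    "DegreeState",
    "parse_formula",
    "canonical_atom_order",
    "graph_exists",
    "distribute_hydrogens",
]

#: Lowest valence states only; higher oxidation states of N, P and S are out
#: of scope of this generator.
SUPPORTED_VALENCES: dict[str, int] = {
    "C": 4,
    "N": 3,
    "P": 3,
    "O": 2,
    "S": 2,
    "F": 1,
    "Cl": 1,
    "Br": 1,
    "I": 1,
    "H": 1,
}

# Element token followed by an optional count; counts may be wrapped in
# underscores (the tolerant CLI dialect, e.g. "C_2_OH_4_").
_TOKEN = re.compile(r"([A-Z][a-z]?)(?:_(\d+)_|(\d+))?")


@dataclass(frozen=True)
class MolecularFormula:
    """An element → count map together with the valence table.

    ``counts`` only contains elements with a positive count; every element is
    guaranteed to have a valence entry.
    """

    counts: Mapping[str, int]
    valences: Mapping[str, int] = field(default_factory=lambda: dict(SUPPORTED_VALENCES))

    def __post_init__(self) -> None:
        for sym, n in self.counts.items():
            if sym not in self.valences:
                raise UnsupportedElement(f"element {sym!r} has no valence entry")
            if n < 0:
                raise InvalidInput(f"negative count for element {sym!r}")

    @property
    def heavy_count(self) -> int:
        """Number of non-hydrogen atoms p."""
        return sum(n for sym, n in self.counts.items() if sym != "H")

    @property
    def hydrogen_count(self) -> int:
        return self.counts.get("H", 0)

    def full_degree_sequence(self) -> list[int]:
        """Valence of every atom, hydrogens included (input existence test)."""
        out: list[int] = []
        for sym, _valence in sorted(
            ((s, self.valences[s]) for s in self.counts), key=lambda t: (-t[1], t[0])
        ):
            out.extend([self.valences[sym]] * self.counts[sym])
        return out

    def __str__(self) -> str:
        # Hill-ish ordering: C, H, then alphabetical.
        def key(sym: str) -> tuple[int, str]:
            return ({"C": 0, "H": 1}.get(sym, 2), sym)

        parts = []
        for sym in sorted(self.counts, key=key):
            n = self.counts[sym]
            parts.append(sym + (str(n) if n > 1 else ""))
        return "".join(parts)


@dataclass(frozen=True)
class DegreeState:
    """Residual heavy-atom degrees after one hydrogen distribution.

    Invariants: ``degrees[i] + hydrogens[i]`` equals the valence of atom
    ``i``; within every partition block the pair (element, degree) is
    constant; the degree sum is even.
    """

    elements: tuple[str, ...]
    degrees: tuple[int, ...]
    hydrogens: tuple[int, ...]
    partition: OrderedPartition

    @property
    def p(self) -> int:
        return len(self.degrees)

    def profile(self) -> tuple[tuple[str, int, int], ...]:
        """(element, degree, hydrogens) per atom — the duplicate-free identity."""
        return tuple(zip(self.elements, self.degrees, self.hydrogens))


def parse_formula(text: str) -> MolecularFormula:
    """Parse a molecular formula string such as ``"C6H6"`` or ``"C_2_OH_4_"``.

    Element order in the string is irrelevant; repeated element tokens are
    summed; whitespace is ignored; counts may be wrapped in underscores.
    Raises :class:`UnsupportedElement` for unknown symbols and
    :class:`ParseError` for anything that is not a valid token stream.
    """
    if not isinstance(text, str) or not text.strip():
        raise ParseError("empty molecular formula")
    stripped = re.sub(r"\s+", "", text)
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(stripped):
        m = _TOKEN.match(stripped, pos)
        if m is None:
            raise ParseError(f"malformed formula {text!r} at position {pos}")
        sym = m.group(1)
        if sym not in SUPPORTED_VALENCES:
            raise UnsupportedElement(f"unsupported element {sym!r} in formula {text!r}")
        n = int(m.group(2) or m.group(3) or 1)
        if n == 0:
            raise ParseError(f"zero count for element {sym!r} in formula {text!r}")
        counts[sym] = counts.get(sym, 0) + n
        pos = m.end()
    return MolecularFormula(counts)


def _as_formula(formula: "MolecularFormula | str") -> MolecularFormula:
    return parse_formula(formula) if isinstance(formula, str) else formula


def canonical_atom_order(
    formula: "MolecularFormula | str",
) -> tuple[list[tuple[str, int]], OrderedPartition]:
    """Deterministic heavy-atom order plus the induced element partition.

    Heavy atoms are sorted by descending valence, ties broken alphabetically
    (C, N, P, O, S, Br, Cl, F, I); hydrogens are excluded.  The partition
    blocks are the maximal runs of equal element.
    """
    formula = _as_formula(formula)
    atoms: list[tuple[str, int]] = []
    blocks: list[int] = []
    for sym in sorted(
        (s for s in formula.counts if s != "H"),
        key=lambda s: (-formula.valences[s], s),
    ):
        n = formula.counts[sym]
        atoms.extend([(sym, formula.valences[sym])] * n)
        blocks.append(n)
    return atoms, OrderedPartition(blocks)


def graph_exists(degrees: Sequence[int]) -> bool:
    """Existence test for a degree sequence: even sum and sum ≥ 2(p−1).

    A connected graph on p nodes needs at least p−1 edges and every edge
    contributes 2 to the degree sum.
    """
    if degrees is None or len(degrees) == 0:
        raise InvalidInput("empty degree sequence")
    total = sum(degrees)
    return total % 2 == 0 and total >= 2 * (len(degrees) - 1)


def _bounded_nondecreasing(total: int, slots: int, cap: int) -> Iterator[tuple[int, ...]]:
    """Non-decreasing sequences of length ``slots`` with entries ≤ cap summing
    to ``total`` — i.e. partitions of ``total`` into at most ``slots`` parts
    each at most ``cap``, padded with leading zeros."""

    def rec(remaining: int, slots_left: int, minimum: int) -> Iterator[tuple[int, ...]]:
        if slots_left == 0:
            if remaining == 0:
                yield ()
            return
        # Each later entry must be >= current; prune impossible branches.
        for h in range(minimum, cap + 1):
            rest = remaining - h
            if rest < 0:
                break
            if rest > (slots_left - 1) * cap:
                continue
            for tail in rec(rest, slots_left - 1, h):
                yield (h, *tail)

    yield from rec(total, slots, 0)


def distribute_hydrogens(formula: "MolecularFormula | str") -> list[DegreeState]:
    """Enumerate every duplicate-free hydrogen distribution as a DegreeState.

    Within each element block the per-atom hydrogen counts form a
    non-decreasing sequence, which makes the enumeration duplicate-free by
    construction.  The per-atom cap is valence−1 for p ≥ 2 (an atom saturated
    by hydrogens could never connect to the rest of the molecule) and the
    full valence for p = 1.  States whose residual degree sequence has an odd
    sum, or cannot support a connected heavy graph, are discarded.

    A hydrogen count exceeding the total capacity yields an empty list.
    """
    formula = _as_formula(formula)
    atoms, _elem_partition = canonical_atom_order(formula)
    p = len(atoms)
    n_h = formula.hydrogen_count
    if p == 0:
        return []
    # Element blocks in canonical order: (symbol, count, valence).
    blocks: list[tuple[str, int, int]] = []
    for sym, valence in atoms:
        if blocks and blocks[-1][0] == sym:
            blocks[-1] = (sym, blocks[-1][1] + 1, valence)
        else:
            blocks.append((sym, 1, valence))

    cap = (lambda v: v) if p == 1 else (lambda v: v - 1)
    states: list[DegreeState] = []

    def assign(b: int, remaining: int, chosen: list[tuple[int, ...]]) -> None:
        if b == len(blocks):
            if remaining == 0:
                state = _build_state(blocks, chosen, p)
                if state is not None:
                    states.append(state)
            return
        sym, count, valence = blocks[b]
        c = cap(valence)
        tail_capacity = sum(cap(v) * n for _s, n, v in blocks[b + 1 :])
        lo = max(0, remaining - tail_capacity)
        hi = min(remaining, c * count)
        for m in range(lo, hi + 1):
            for seq in _bounded_nondecreasing(m, count, c):
                assign(b + 1, remaining - m, chosen + [seq])

    assign(0, n_h, [])
    return states


def _build_state(
    blocks: list[tuple[str, int, int]],
    chosen: list[tuple[int, ...]],
    p: int,
) -> DegreeState | None:
    elements: list[str] = []
    degrees: list[int] = []
    hydrogens: list[int] = []
    part_blocks: list[int] = []
    for (sym, _count, valence), seq in zip(blocks, chosen):
        # Non-decreasing hydrogens => non-increasing residual degrees, so the
        # matrix fill starts from the highest-degree atoms of each block.
        degs = [valence - h for h in seq]
        hyds = list(seq)
        elements.extend([sym] * len(seq))
        degrees.extend(degs)
        hydrogens.extend(hyds)
        run = 1
        for a, b in zip(degs, degs[1:]):
            if a == b:
                run += 1
            else:
                part_blocks.append(run)
                run = 1
        part_blocks.append(run)
    total = sum(degrees)
    if total % 2 != 0:
        return None
    if p == 1:
        if degrees[0] != 0:
            return None
    elif not graph_exists(degrees):
        return None
    return DegreeState(
        elements=tuple(elements),
        degrees=tuple(degrees),
        hydrogens=tuple(hydrogens),
        partition=OrderedPartition(part_blocks),
    )
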