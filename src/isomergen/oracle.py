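"""Brute-force ground truth for small formulae.

The oracle enumerates, without any of the orderly-generation machinery,
every connected multigraph on the heavy atoms whose degrees are exact
(valence minus assigned hydrogens), with bond orders 1–3, and counts
isomorphism classes via an exhaustive canonical key.  It is deliberately
naive — its only job is to be obviously correct at small sizes so the
generator can be validated against it.

Isomorphism here is colour-preserving: two structures are the same
constitutional isomer exactly when a bijection of heavy atoms preserves
element symbols, per-atom hydrogen counts and all bond orders.  The
canonical key is the minimum, over all colour-class-preserving
permutations, of the flattened upper triangle — feasible because the class
sizes stay tiny at oracle scale.
"""

from __future__ import annotations

import itertools
from typing import Iterator, Sequence

from .errors import CapacityError
from .formula import MolecularFormula, canonical_atom_order, parse_formula
from .partitions import OrderedPartition, young_subgroup_elements

__all__ = ["CanonicalKey", "canonical_key", "brute_force_count", "naive_maximality"]

#: A canonical key: colour sequence plus the minimal upper-triangle tuple.
CanonicalKey = tuple[tuple[tuple[str, int], ...], tuple[int, ...]]

_MAX_ORDER = 3


def canonical_key(
    colors: Sequence[tuple[str, int]], matrix: Sequence[Sequence[int]]
) -> CanonicalKey:
    """Total-order invariant identifying a coloured multigraph up to
    colour-preserving isomorphism.

    ``colors`` pairs each node with its colour (element symbol, hydrogen
    count); nodes are first relabelled so equal colours are contiguous in
    sorted colour order, then the flattened upper triangle is minimised over
    all within-class permutations.
    """
    p = len(colors)
    order = sorted(range(p), key=lambda a: colors[a])
    sorted_colors = tuple(colors[a] for a in order)
    # Class blocks in the sorted order.
    blocks: list[int] = []
    for idx, col in enumerate(sorted_colors):
        if idx and col == sorted_colors[idx - 1]:
            blocks[-1] += 1
        else:
            blocks.append(1)
    base = [order[a] for a in range(p)]
    best: tuple[int, ...] | None = None
    for sigma in young_subgroup_elements(OrderedPartition(blocks), max_size=50_000):
        relabel = [base[sigma[a]] for a in range(p)]
        flat = tuple(
            matrix[relabel[i]][relabel[j]] for i in range(p) for j in range(i + 1, p)
        )
        if best is None or flat < best:
            best = flat
    assert best is not None
    return (sorted_colors, best)


def _hydrogen_assignments(
    atoms: Sequence[tuple[str, int]], n_h: int
) -> Iterator[tuple[int, ...]]:
    """All hydrogen-count vectors (0..valence per atom) summing to ``n_h``,
    unordered duplicates removed within runs of identical elements."""
    runs: list[tuple[int, int]] = []  # (length, valence) per element run
    prev = None
    for sym, val in atoms:
        if prev == (sym, val):
            runs[-1] = (runs[-1][0] + 1, val)
        else:
            runs.append((1, val))
        prev = (sym, val)

    def rec(ri: int, remaining: int) -> Iterator[tuple[int, ...]]:
        if ri == len(runs):
            if remaining == 0:
                yield ()
            return
        length, val = runs[ri]
        for combo in itertools.combinations_with_replacement(range(val + 1), length):
            s = sum(combo)
            if s > remaining:
                continue
            for tail in rec(ri + 1, remaining - s):
                yield combo + tail

    yield from rec(0, n_h)


def _iter_matrices(degrees: Sequence[int]) -> Iterator[list[list[int]]]:
    """Every symmetric matrix with entries ≤ 3, zero diagonal and exact row
    sums equal to ``degrees``."""
    p = len(degrees)
    A = [[0] * p for _ in range(p)]
    rem = list(degrees)
    cells = [(i, j) for i in range(p - 1) for j in range(i + 1, p)]

    def rec(c: int) -> Iterator[list[list[int]]]:
        if c == len(cells):
            if all(r == 0 for r in rem):
                yield A
            return
        i, j = cells[c]
        # Row i closes after its last cell; prune on exact completion.
        last_in_row = j == p - 1
        hi = min(rem[i], rem[j], _MAX_ORDER)
        for v in range(hi + 1):
            A[i][j] = A[j][i] = v
            rem[i] -= v
            rem[j] -= v
            feasible = True
            if last_in_row and rem[i] != 0:
                feasible = False
            if feasible and not last_in_row:
                open_cap = sum(
                    min(rem[c2], _MAX_ORDER) for c2 in range(j + 1, p)
                )
                if rem[i] > open_cap:
                    feasible = False
            if feasible:
                yield from rec(c + 1)
            rem[i] += v
            rem[j] += v
            A[i][j] = A[j][i] = 0

    if p == 1:
        if degrees[0] == 0:
            yield [[0]]
        return
    yield from rec(0)


def _connected(matrix: Sequence[Sequence[int]]) -> bool:
    p = len(matrix)
    seen = {0}
    stack = [0]
    while stack:
        v = stack.pop()
        for u in range(p):
            if matrix[v][u] and u not in seen:
                seen.add(u)
                stack.append(u)
    return len(seen) == p


def brute_force_count(
    formula: "MolecularFormula | str",
    *,
    max_heavy: int = 7,
    collect_keys: bool = False,
) -> "int | tuple[int, set[CanonicalKey]]":
    """Count connected, valence-exact multigraph isomorphism classes.

    Enumerates every hydrogen assignment and every bond matrix outright and
    deduplicates through :func:`canonical_key`.  Refuses formulae with more
    than ``max_heavy`` heavy atoms.
    """
    formula = parse_formula(formula) if isinstance(formula, str) else formula
    atoms, _part = canonical_atom_order(formula)
    p = len(atoms)
    if p > max_heavy:
        raise CapacityError(f"{p} heavy atoms exceed the oracle bound {max_heavy}")
    if p == 0:
        n = 1 if formula.hydrogen_count == 2 else 0
        return (n, set()) if collect_keys else n
    keys: set[CanonicalKey] = set()
    for hvec in _hydrogen_assignments(atoms, formula.hydrogen_count):
        degrees = [val - h for (sym, val), h in zip(atoms, hvec)]
        if any(d < 0 for d in degrees) or sum(degrees) % 2:
            continue
        colors = [(sym, h) for (sym, _val), h in zip(atoms, hvec)]
        for A in _iter_matrices(degrees):
            if _connected(A):
                keys.add(canonical_key(colors, A))
    return (len(keys), keys) if collect_keys else len(keys)


def naive_maximality(
    matrix: Sequence[Sequence[int]],
    partition: OrderedPartition,
    *,
    max_size: int = 1_000_000,
) -> bool:
    """Exhaustive maximality check: A ≥ Aπ for every π in S_λ.

    The permuted matrix has entries (Aπ)[x][y] = A[π(x)][π(y)]; comparison is
    row-major lexicographic over the full matrix.
    """
    p = len(matrix)
    for pi in young_subgroup_elements(partition, max_size=max_size):
        for x in range(p):
            row = matrix[x]
            prow = matrix[pi[x]]
            for y in range(p):
                a = row[y]
                b = prow[pi[y]]
                if b > a:
                    return False
                if b < a:
                    break
            else:
                continue
            break
    return True
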