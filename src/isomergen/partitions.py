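"""Ordered partitions of the atom index range and Young-subgroup machinery.

An *ordered partition* λ = (λ₁, λ₂, ...) splits the index range ``0..p-1``
into contiguous blocks of interchangeable atoms (same element, same target
degree, and — as the bond matrix grows — identical bond patterns in all
completed rows).  The symmetry group respected by such a colouring is the
Young subgroup S_λ: the direct product of the symmetric groups acting on each
block independently.

During orderly generation the partition is refined row by row.  Two distinct
refinement steps occur for every row ``i``:

* :func:`refine_partition` splits index ``i`` off as a singleton before the
  canonical test of row ``i`` (the coset decomposition below needs it);
* :func:`partition_from_row` further subdivides the remaining blocks wherever
  the completed row's entries change value, because atoms that received
  different bond orders from atom ``i`` are no longer interchangeable.

The link between two consecutive refined Young subgroups is the coset
decomposition  S_{λ_prev} = ⋃_j (i,j)·S_{λ_refined},  where the *cycle
transpositions* (i,j) run over the block of λ_prev that starts at ``i``.
:func:`cycle_transpositions` enumerates exactly these coset representatives;
they drive the canonical maximality test.

All indices are 0-based.  Permutations are represented as tuples ``perm`` of
length ``p`` with ``perm[x]`` the image of ``x``.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterator, Sequence

from .errors import CapacityError, InvalidInput

__all__ = [
    "OrderedPartition",
    "Transposition",
    "refine_partition",
    "cycle_transpositions",
    "partition_from_row",
    "young_subgroup_elements",
    "identity_permutation",
    "compose",
    "permutation_from_cycles",
]


@dataclass(frozen=True)
class OrderedPartition:
    """A composition of ``0..p-1`` into contiguous blocks.

    Parameters
    ----------
    blocks
        Block sizes, all ≥ 1; their sum is the number of atoms ``p``.
    """

    blocks: tuple[int, ...]

    def __init__(self, blocks: Sequence[int]) -> None:
        blocks = tuple(int(b) for b in blocks)
        if any(b < 1 for b in blocks):
            raise InvalidInput(f"partition blocks must be >= 1, got {blocks}")
        object.__setattr__(self, "blocks", blocks)

    @property
    def p(self) -> int:
        """Total number of indices covered."""
        return sum(self.blocks)

    def starts(self) -> list[int]:
        """Start index of every block, in order."""
        out, acc = [], 0
        for b in self.blocks:
            out.append(acc)
            acc += b
        return out

    def ranges(self) -> list[tuple[int, int]]:
        """Half-open index range ``(start, end)`` of every block."""
        out, acc = [], 0
        for b in self.blocks:
            out.append((acc, acc + b))
            acc += b
        return out

    def block_at(self, index: int) -> tuple[int, int]:
        """Half-open range of the block containing ``index``."""
        if not 0 <= index < self.p:
            raise IndexError(f"index {index} out of range for p={self.p}")
        for start, end in self.ranges():
            if start <= index < end:
                return start, end
        raise AssertionError("unreachable")

    def is_discrete(self) -> bool:
        """True when every block is a singleton."""
        return all(b == 1 for b in self.blocks)

    def order(self) -> int:
        """Order of the Young subgroup S_λ, i.e. Π blockᵢ!."""
        n = 1
        for b in self.blocks:
            n *= math.factorial(b)
        return n

    def __iter__(self) -> Iterator[int]:
        return iter(self.blocks)

    def __len__(self) -> int:
        return len(self.blocks)


@dataclass(frozen=True)
class Transposition:
    """A transposition ``(i, j)`` with ``i <= j``; ``(i, i)`` is the identity."""

    i: int
    j: int

    def __post_init__(self) -> None:
        if self.i > self.j:
            raise InvalidInput(f"transposition requires i <= j, got ({self.i}, {self.j})")

    def as_permutation(self, p: int) -> tuple[int, ...]:
        """Embed into S_p as a full index map."""
        if self.j >= p:
            raise IndexError(f"transposition ({self.i},{self.j}) does not fit p={p}")
        perm = list(range(p))
        perm[self.i], perm[self.j] = perm[self.j], perm[self.i]
        return tuple(perm)


def identity_permutation(p: int) -> tuple[int, ...]:
    return tuple(range(p))


def compose(outer: Sequence[int], inner: Sequence[int]) -> tuple[int, ...]:
    """Composition *outer ∘ inner*: apply ``inner`` first, then ``outer``."""
    return tuple(outer[x] for x in inner)


def permutation_from_cycles(
    cycles: Sequence[Sequence[int]], p: int, *, one_based: bool = False
) -> tuple[int, ...]:
    """Build a permutation of ``0..p-1`` from disjoint cycles.

    With ``one_based=True`` the cycle entries are taken in the 1-based
    convention common in the group-theory literature, e.g.
    ``permutation_from_cycles([(1, 2), (3, 5)], 5, one_based=True)``.
    """
    perm = list(range(p))
    off = 1 if one_based else 0
    for cyc in cycles:
        cyc = [c - off for c in cyc]
        if any(not 0 <= c < p for c in cyc):
            raise IndexError(f"cycle {cyc} out of range for p={p}")
        for k, a in enumerate(cyc):
            perm[a] = cyc[(k + 1) % len(cyc)]
    return tuple(perm)


def _block_starting_at(partition: OrderedPartition, i: int) -> int:
    """Size of the block of ``partition`` that starts exactly at index ``i``.

    The row-wise protocol guarantees that, before row ``i`` is processed, all
    indices < i are singletons, hence the block containing ``i`` starts at
    ``i``.  A partition violating that invariant is rejected.
    """
    if not 0 <= i < partition.p:
        raise IndexError(f"row index {i} out of range for p={partition.p}")
    start, end = partition.block_at(i)
    if start != i:
        raise InvalidInput(
            f"block containing index {i} starts at {start}; "
            "indices before the current row must already be singletons"
        )
    return end - start


def refine_partition(partition: OrderedPartition, i: int) -> OrderedPartition:
    """Split index ``i`` off as a singleton block (pre-row refinement).

    If the block containing ``i`` has size s > 1 it becomes ``1, s-1``;
    a singleton block is returned unchanged.
    """
    size = _block_starting_at(partition, i)
    if size == 1:
        return partition
    out: list[int] = []
    for start, end in partition.ranges():
        if start == i:
            out.extend([1, size - 1])
        else:
            out.append(end - start)
    return OrderedPartition(out)


def cycle_transpositions(partition: OrderedPartition, i: int) -> list[Transposition]:
    """Coset representatives ``(i,i), (i,i+1), ..., (i,i+s-1)`` for row ``i``.

    ``s`` is the size of the block of ``partition`` starting at ``i``; the
    number of transpositions returned therefore equals that block size.
    """
    size = _block_starting_at(partition, i)
    return [Transposition(i, i + t) for t in range(size)]


def partition_from_row(
    partition: OrderedPartition, row: Sequence[int], i: int
) -> OrderedPartition:
    """Subdivide the blocks beyond index ``i`` at value changes of ``row``.

    ``partition`` is the refined partition used while testing row ``i`` (so
    indices ≤ i are singletons) and ``row`` is the completed row.  Atoms in
    one block that received different bond orders from atom ``i`` are no
    longer interchangeable, so each block is split at every boundary where
    the row entry changes; runs of equal consecutive entries stay grouped.
    """
    if len(row) != partition.p:
        raise InvalidInput(f"row length {len(row)} != p={partition.p}")
    out: list[int] = []
    for start, end in partition.ranges():
        if end <= i + 1 or end - start == 1:
            out.append(end - start)
            continue
        run = 1
        for k in range(start + 1, end):
            if row[k] == row[k - 1]:
                run += 1
            else:
                out.append(run)
                run = 1
        out.append(run)
    return OrderedPartition(out)


def young_subgroup_elements(
    partition: OrderedPartition, *, max_size: int = 1_000_000
) -> Iterator[tuple[int, ...]]:
    """Yield every permutation of S_λ (each block mapped onto itself).

    The number of elements is Π blockᵢ!; enumeration is refused beyond
    ``max_size``.  Intended for oracles and tests, not for generation.
    """
    if partition.order() > max_size:
        raise CapacityError(
            f"Young subgroup order {partition.order()} exceeds bound {max_size}"
        )
    ranges = partition.ranges()
    pools = [list(itertools.permutations(range(start, end))) for start, end in ranges]
    for pick in itertools.product(*pools):
        perm: list[int] = []
        for images in pick:
            perm.extend(images)
        yield tuple(perm)
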