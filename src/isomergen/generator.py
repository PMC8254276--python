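"""Orderly block-wise construction of all canonical bond matrices.

For every hydrogen distribution (a :class:`~isomergen.formula.DegreeState`)
the generator fills the upper triangle of a p×p bond-order matrix row-major,
always trying the largest feasible entry first, so the very first completed
matrix is the lexicographic maximum and all candidates appear in descending
order.  A single working matrix is modified in place through all candidate
completions ("build-and-forget"): when a candidate is finished or rejected,
the last relevant entry is decremented and the fill resumes after it.

Three tests steer the walk:

* a cheap feasibility check — a row that can no longer reach its exact
  target degree with the columns that remain is abandoned immediately;
* the canonical maximality test, run every time all rows of an initial
  partition block are complete; a non-canonical verdict comes with a witness
  entry, and the fill resumes right there (every continuation that keeps the
  prefix up to the witness is provably non-canonical as well);
* the connectivity test, run on every completed canonical matrix; for a
  disconnected candidate the fill resumes at the last entry of the row of
  the first component's maximum index, skipping the whole region of the
  search that can only produce disconnected graphs.

Bond orders are bounded by min(remaining degree of both atoms, 3): bond
multiplicities above triple do not occur in constitutional isomer spaces.

Everything emitted is therefore connected, canonical (maximal in its Young
subgroup orbit), valence-exact, and appears exactly once, in a
deterministic order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterator, Sequence

from . import connectivity as _conn
from .canon import _test_block
from .errors import GraphNonexistent, InvalidInput, StateError
from .formula import (
    DegreeState,
    MolecularFormula,
    canonical_atom_order,
    distribute_hydrogens,
    graph_exists,
    parse_formula,
)

__all__ = [
    "BondMatrix",
    "Molecule",
    "GenerationResult",
    "max_entry_bound",
    "forward_fill",
    "backward_step",
    "generate",
    "generate_structures",
]

#: No quadruple bonds: hard cap on any single bond order.
MAX_BOND_ORDER = 3


@dataclass
class BondMatrix:
    """A symmetric p×p bond-order matrix under construction.

    ``entries`` is the full symmetric matrix (zero diagonal); ``cursor`` is
    the index into the row-major upper-triangle fill order of the next entry
    to fill; ``remaining`` tracks the unconsumed degree of every atom.
    """

    state: DegreeState
    entries: list[list[int]]
    remaining: list[int]
    cursor: int = 0

    @classmethod
    def for_state(cls, state: DegreeState) -> "BondMatrix":
        p = state.p
        return cls(
            state=state,
            entries=[[0] * p for _ in range(p)],
            remaining=list(state.degrees),
        )

    @property
    def p(self) -> int:
        return self.state.p

    def positions(self) -> list[tuple[int, int]]:
        p = self.p
        return [(i, j) for i in range(p - 1) for j in range(i + 1, p)]

    def is_complete(self) -> bool:
        return self.cursor >= len(self.positions()) and all(
            r == 0 for r in self.remaining
        )


def max_entry_bound(i: int, j: int, state: DegreeState, matrix: BondMatrix) -> int:
    """Largest bond order currently placeable between atoms ``i`` and ``j``.

    The bound is the smaller of both atoms' remaining degrees, capped at 3
    (no quadruple bonds).
    """
    if i >= j:
        raise InvalidInput("max_entry_bound requires i < j")
    rem = matrix.remaining
    return min(rem[i], rem[j], MAX_BOND_ORDER)


def forward_fill(matrix: BondMatrix) -> tuple[int, int] | None:
    """Fill the entry at the cursor with its maximal feasible value.

    Returns the position filled, or ``None`` when the matrix has no entry
    left to fill.  This is the single-step, inspectable version of the
    generator's forward pass; :func:`generate` runs the same policy in a
    fused loop.
    """
    pos = matrix.positions()
    if matrix.cursor >= len(pos):
        return None
    i, j = pos[matrix.cursor]
    v = max_entry_bound(i, j, matrix.state, matrix)
    matrix.entries[i][j] = matrix.entries[j][i] = v
    matrix.remaining[i] -= v
    matrix.remaining[j] -= v
    matrix.cursor += 1
    return (i, j)


def backward_step(
    matrix: BondMatrix, from_entry: tuple[int, int]
) -> tuple[int, int] | None:
    """Decrement at the back-jump target and return the resume position.

    Entries filled after ``from_entry`` are cleared.  If the target entry is
    positive it is decremented by one and the fill resumes at the following
    position; a zero entry moves the target to the previous upper-triangle
    entry.  Returns ``None`` when the walk is exhausted.
    """
    pos = matrix.positions()
    index = {pq: k for k, pq in enumerate(pos)}
    if from_entry not in index:
        raise InvalidInput(f"{from_entry} is not an upper-triangle entry")
    t = index[from_entry]
    for k in range(min(matrix.cursor, len(pos)) - 1, t, -1):
        i, j = pos[k]
        v = matrix.entries[i][j]
        if v:
            matrix.remaining[i] += v
            matrix.remaining[j] += v
            matrix.entries[i][j] = matrix.entries[j][i] = 0
    while t >= 0:
        i, j = pos[t]
        v = matrix.entries[i][j]
        if v:
            matrix.entries[i][j] = matrix.entries[j][i] = v - 1
            matrix.remaining[i] += 1
            matrix.remaining[j] += 1
            matrix.cursor = t + 1
            return pos[t + 1] if t + 1 < len(pos) else pos[t]
        t -= 1
    matrix.cursor = 0
    return None


@dataclass(frozen=True)
class Molecule:
    """One emitted structure: heavy-atom skeleton plus hydrogen counts."""

    elements: tuple[str, ...]
    hydrogens: tuple[int, ...]
    bonds: tuple[tuple[int, int, int], ...]

    def atom_symbols(self) -> list[str]:
        """All atoms, hydrogens re-attached after the heavy atoms."""
        syms = list(self.elements)
        for h in self.hydrogens:
            syms.extend(["H"] * h)
        return syms

    def all_bonds(self) -> list[tuple[int, int, int]]:
        """Heavy-heavy bonds followed by one single bond per hydrogen,
        attached in heavy-atom index order."""
        out = list(self.bonds)
        nxt = len(self.elements)
        for a, h in enumerate(self.hydrogens):
            for _ in range(h):
                out.append((a, nxt, 1))
                nxt += 1
        return out

    def formula_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for sym in self.elements:
            counts[sym] = counts.get(sym, 0) + 1
        n_h = sum(self.hydrogens)
        if n_h:
            counts["H"] = counts.get("H", 0) + n_h
        return counts


@dataclass
class GenerationResult:
    """Total structure count plus the per-hydrogen-distribution breakdown."""

    formula: MolecularFormula
    count: int
    per_state: list[tuple[DegreeState, int]]


# ---------------------------------------------------------------------------
# Core enumeration loop (build-and-forget)
# ---------------------------------------------------------------------------


def _iter_state_matrices(
    state: DegreeState, *, learning: bool = True
) -> Iterator[list[list[int]]]:
    """Yield every connected canonical bond matrix for one degree state.

    The yielded object is the live working matrix: consume or copy it before
    advancing the iterator.
    """
    p = state.p
    degrees = state.degrees
    if p == 1:
        if degrees[0] == 0:
            yield [[0]]
        return

    lam0 = list(state.partition.blocks)
    pos = [(i, j) for i in range(p - 1) for j in range(i + 1, p)]
    npos = len(pos)
    pidx = [[0] * p for _ in range(p)]
    k = 0
    for i, j in pos:
        pidx[i][j] = k
        k += 1

    # Last row of every initial-partition block, and for each row the number
    # of blocks that stay valid when that row is modified.
    bends: list[int] = []
    acc = 0
    for sz in lam0:
        acc += sz
        bends.append(acc - 1)
    nblocks = len(bends)
    blocks_before_row = [0] * p
    for row in range(p):
        blocks_before_row[row] = sum(1 for be in bends if be < row)
    bstarts = [0] + [be + 1 for be in bends[:-1]]

    identity = tuple(range(p))
    chain_lam: list[list[int] | None] = [None] * nblocks
    chain_f: list[list[tuple[int, ...]] | None] = [None] * nblocks
    blocks_done = 0

    A = [[0] * p for _ in range(p)]
    rem = list(degrees)
    component_of_first = _conn._component_of_first

    k = 0
    override = -1
    while True:
        i, j = pos[k]
        if override >= 0:
            v = override
            override = -1
        else:
            v = rem[i] if rem[i] < rem[j] else rem[j]
            if v > MAX_BOND_ORDER:
                v = MAX_BOND_ORDER
        if v:
            A[i][j] = A[j][i] = v
            rem[i] -= v
            rem[j] -= v

        target = -1  # -1: continue forward
        if j == p - 1:
            # Row i is complete; its degree must be met exactly.
            if rem[i] != 0 or (i == p - 2 and rem[p - 1] != 0):
                target = k
            else:
                last_complete = p - 1 if i == p - 2 else i
                while blocks_done < nblocks and bends[blocks_done] <= last_complete:
                    b = blocks_done
                    lam_in = chain_lam[b - 1] if b else lam0
                    f_in = chain_f[b - 1] if b else [identity]
                    ok, payload, f_out = _test_block(
                        A, p, bstarts[b], bends[b], lam_in, f_in
                    )
                    if ok:
                        chain_lam[b] = payload
                        chain_f[b] = f_out
                        blocks_done += 1
                    else:
                        if learning:
                            wr, wc = payload
                            target = pidx[wr][wc]
                        else:
                            be = bends[b] if bends[b] < p - 1 else p - 2
                            target = pidx[be][p - 1]
                        break
                if target < 0 and i == p - 2:
                    connected, max_first = component_of_first(A, p)
                    if connected:
                        yield A
                        target = npos - 1
                    elif learning and max_first < p - 1:
                        target = pidx[max_first][p - 1]
                    else:
                        target = npos - 1
        else:
            # Row-feasibility: remaining degree must fit in the open columns.
            need = rem[i]
            if need:
                cap = 0
                for c in range(j + 1, p):
                    rc = rem[c]
                    cap += MAX_BOND_ORDER if rc > MAX_BOND_ORDER else rc
                    if cap >= need:
                        break
                if cap < need:
                    target = k

        if target < 0:
            k += 1
            continue

        # Backward: clear everything after the target, decrement at it.
        for idx in range(k, target, -1):
            ii, jj = pos[idx]
            a = A[ii][jj]
            if a:
                rem[ii] += a
                rem[jj] += a
                A[ii][jj] = A[jj][ii] = 0
        t = target
        while True:
            ii, jj = pos[t]
            a = A[ii][jj]
            if a:
                rem[ii] += a
                rem[jj] += a
                A[ii][jj] = A[jj][ii] = 0
                override = a - 1
                break
            t -= 1
            if t < 0:
                return
        if blocks_before_row[pos[t][0]] < blocks_done:
            blocks_done = blocks_before_row[pos[t][0]]
        k = t


def _molecule_from(state: DegreeState, A: Sequence[Sequence[int]]) -> Molecule:
    bonds = tuple(
        (i, j, A[i][j])
        for i in range(state.p - 1)
        for j in range(i + 1, state.p)
        if A[i][j]
    )
    return Molecule(elements=state.elements, hydrogens=state.hydrogens, bonds=bonds)


def _checked_formula(formula: "MolecularFormula | str") -> MolecularFormula:
    formula = parse_formula(formula) if isinstance(formula, str) else formula
    full = formula.full_degree_sequence()
    if not full:
        raise GraphNonexistent("formula contains no atoms")
    if not graph_exists(full):
        raise GraphNonexistent(
            f"no connected graph exists for formula {formula} "
            "(degree sum odd or too small)"
        )
    return formula


def generate(
    formula: "MolecularFormula | str",
    *,
    learning: bool = True,
    callback: "Callable[[DegreeState, Sequence[Sequence[int]]], None] | None" = None,
) -> GenerationResult:
    """Count (and optionally stream) all constitutional isomers of a formula.

    Iterates every hydrogen distribution and runs the orderly fill on each;
    the result carries the total and the per-distribution counts.  When
    ``callback`` is given it is invoked with the degree state and the live
    matrix for every emitted structure.  Raises :class:`GraphNonexistent`
    when the formula cannot form any connected graph.
    """
    formula = _checked_formula(formula)
    if formula.heavy_count == 0:
        # Hydrogen only: H2 is the single two-atom graph.
        n = 1 if formula.hydrogen_count == 2 else 0
        return GenerationResult(formula=formula, count=n, per_state=[])
    per_state: list[tuple[DegreeState, int]] = []
    total = 0
    for state in distribute_hydrogens(formula):
        n = 0
        for A in _iter_state_matrices(state, learning=learning):
            n += 1
            if callback is not None:
                callback(state, A)
        per_state.append((state, n))
        total += n
    return GenerationResult(formula=formula, count=total, per_state=per_state)


def generate_structures(
    formula: "MolecularFormula | str", *, learning: bool = True
) -> Iterator[Molecule]:
    """Stream every isomer of ``formula`` as a :class:`Molecule`.

    Structures appear in the same deterministic order as :func:`generate`
    counts them.
    """
    formula = _checked_formula(formula)
    if formula.heavy_count == 0:
        if formula.hydrogen_count == 2:
            yield Molecule(elements=("H",), hydrogens=(1,), bonds=())
        return
    for state in distribute_hydrogens(formula):
        for A in _iter_state_matrices(state, learning=learning):
            yield _molecule_from(state, A)
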