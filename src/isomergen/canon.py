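"""Row-wise canonical (maximality) testing under Young subgroups.

A bond matrix A is *canonical* when it is the lexicographically maximal
member of its orbit under the Young subgroup S_λ of the initial atom
partition: A ≥ Aπ for all π ∈ S_λ, matrices compared row by row.  Orderly
generation keeps only canonical matrices, which makes the output
duplicate-free without ever storing previously generated structures.

Testing all |S_λ| permutations is hopeless; instead the test walks the
matrix row by row and maintains two objects:

* the *refined partition chain*: before row i all earlier indices are
  singletons and the remaining blocks group columns that are
  indistinguishable so far (same element, same degree, identical entries in
  all rows < i);
* the *automorphism list* F⁽ⁱ⁾: a complete set of permutations that fix the
  partial matrix through row i, modulo the Young subgroup of the current
  refined partition.

Row i then only needs to be compared against the candidates τ·ς, with τ from
F⁽ⁱ⁻¹⁾ and ς a cycle transposition of the block at i.  For each candidate
the permuted row may additionally be reordered inside every refined block
(a later-row adjustment the adversary is always allowed), so the comparison
is made against the block-wise descending-sorted permuted row:

* sorted permuted row > original row → the matrix is not maximal.  The test
  reports a *witness*: the latest-filled matrix entry among those that prove
  the violation.  Every continuation of the fill that keeps the entries up
  to the witness unchanged is provably non-canonical too (adding or altering
  entries beyond the witness can only raise the adversary's sorted prefix),
  so the generator may back-jump straight to the witness.
* equal per block → a block-wise matching σ turns τ·ς·σ into an automorphism
  of the partial matrix; it is added to F⁽ⁱ⁾.
* smaller → the candidate is exhausted; testing continues.

All indices 0-based; permutations are tuples mapping position → image.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

from .errors import InvalidInput, StateError
from .partitions import (
    OrderedPartition,
    Transposition,
    identity_permutation,
    partition_from_row,
    refine_partition,
)

__all__ = [
    "AutomorphismLedger",
    "CanonicalVerdict",
    "compare_rows",
    "find_canonical_permutation",
    "update_automorphisms",
    "test_block_canonical",
]

Matrix = Sequence[Sequence[int]]
Perm = tuple[int, ...]


@dataclass
class AutomorphismLedger:
    """Per-row automorphism lists F⁽ⁱ⁾ of the partial matrix.

    ``current`` is the list valid after the last tested row; ``per_row``
    keeps the history keyed by row index.  F⁽⁻¹⁾ (before any row) is the
    identity alone.
    """

    p: int
    current: list[Perm] = field(default_factory=list)
    per_row: dict[int, list[Perm]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.current:
            self.current = [identity_permutation(self.p)]

    def record(self, row: int, perms: list[Perm]) -> None:
        self.per_row[row] = perms
        self.current = perms


@dataclass(frozen=True)
class CanonicalVerdict:
    """Outcome of a block canonical test.

    ``witness`` is present iff ``canonical`` is false; it is the fill
    position (row, column), row < column, at which the generator may resume.
    ``partition_after`` / ``ledger`` carry the advanced chain state when the
    block is canonical.
    """

    canonical: bool
    witness: tuple[int, int] | None = None
    partition_after: OrderedPartition | None = None
    ledger: AutomorphismLedger | None = None


def compare_rows(
    row_a: Sequence[int], row_b: Sequence[int], partition: OrderedPartition
) -> Literal["greater", "equal", "smaller"]:
    """Blockwise lexicographic comparison of two rows of equal length.

    Entries within one block are compared as an ordered tuple, blocks in
    order — which coincides with plain left-to-right comparison; the
    partition argument documents (and bounds) the comparison domain.
    """
    if len(row_a) != len(row_b):
        raise InvalidInput("rows must have equal length")
    for start, end in partition.ranges():
        for k in range(start, min(end, len(row_a))):
            if row_a[k] != row_b[k]:
                return "greater" if row_a[k] > row_b[k] else "smaller"
    return "equal"


def find_canonical_permutation(
    original_row: Sequence[int],
    permuted_row: Sequence[int],
    lam_refined: OrderedPartition,
) -> Perm | None:
    """Find σ ∈ S_{λ_refined} with ``permuted_row[σ[k]] == original_row[k]``.

    The search is deterministic: within every block, equal values are matched
    in ascending position order (first valid match).  Returns ``None`` when
    the rows differ as block-wise multisets, in which case no such σ exists.
    """
    if len(original_row) != len(permuted_row):
        raise InvalidInput("rows must have equal length")
    if len(original_row) != lam_refined.p:
        raise InvalidInput("row length does not match partition")
    sigma: list[int] = list(range(lam_refined.p))
    for start, end in lam_refined.ranges():
        free = list(range(start, end))
        for k in range(start, end):
            target = original_row[k]
            for idx, cand in enumerate(free):
                if permuted_row[cand] == target:
                    sigma[k] = cand
                    del free[idx]
                    break
            else:
                return None
    return tuple(sigma)


def update_automorphisms(
    f_prev: list[Perm],
    cycles: Sequence[Transposition],
    matrix: Matrix,
    i: int,
    lam_refined: OrderedPartition,
) -> list[Perm]:
    """Grow the automorphism list for row ``i``.

    For every τ in ``f_prev`` and cycle transposition ς the composite τ·ς is
    formed; if it maps row ``i`` onto itself — possibly after a canonical
    permutation σ within the refined blocks — the full composite τ·ς·σ is
    stored.  Duplicates are dropped; the result always contains at least the
    identity when row ``i`` is in canonical form.
    """
    p = len(matrix)
    row_i = matrix[i]
    out: list[Perm] = []
    seen: set[Perm] = set()
    for tau in f_prev:
        for t in cycles:
            pi = list(tau)
            pi[t.i], pi[t.j] = tau[t.j], tau[t.i]
            r = pi[i]
            permuted = [matrix[r][pi[k]] for k in range(p)]
            sigma = find_canonical_permutation(row_i, permuted, lam_refined)
            if sigma is None:
                continue
            rho = tuple(pi[sigma[k]] for k in range(p))
            # Keep only genuine fixers of row i (columns before the diagonal
            # are fixed automatically by construction).
            if all(matrix[rho[i]][rho[k]] == row_i[k] for k in range(p)):
                if rho not in seen:
                    seen.add(rho)
                    out.append(rho)
    return out


# ---------------------------------------------------------------------------
# Core row test shared by the public block test and the matrix generator.
# Partitions are handled as plain size lists for speed; the generator calls
# _row_test/_test_block directly in its hot loop.
# ---------------------------------------------------------------------------


def _blocks_after(lam_sizes: Sequence[int], i: int) -> tuple[int, list[tuple[int, int]]]:
    """Block size at position i plus the refined half-open blocks after i.

    Requires the invariant that all positions < i are singletons, hence the
    block containing i starts at i.
    """
    acc = 0
    bi = 0
    for bi, sz in enumerate(lam_sizes):
        if acc == i:
            break
        acc += sz
    if acc != i:
        raise InvalidInput(f"partition {tuple(lam_sizes)} has no block starting at {i}")
    s = lam_sizes[bi]
    blocks: list[tuple[int, int]] = []
    pos = i + s
    if s > 1:
        blocks.append((i + 1, i + s))
    for sz in lam_sizes[bi + 1 :]:
        blocks.append((pos, pos + sz))
        pos += sz
    return s, blocks


def _row_test(
    A: Matrix,
    i: int,
    lam_sizes: Sequence[int],
    f_prev: list[Perm],
):
    """Canonical test of row ``i``.

    Returns ``("ok", f_new, lam_next_sizes)`` when the row is maximal, or
    ``("fail", (wr, wc))`` with the witness fill position otherwise.
    """
    p = len(A)
    s, blocks = _blocks_after(lam_sizes, i)
    row_i = A[i]
    new_f: list[Perm] = []
    seen: set[Perm] = set()

    for tau in f_prev:
        ti = tau[i]
        for j in range(i, i + s):
            r = tau[j]
            row_r = A[r]
            equal = True
            fail_at = -1
            fail_block = None
            # Walk refined blocks left to right.
            for b0, b1 in blocks:
                if b1 - b0 == 1:
                    c = ti if b0 == j else tau[b0]
                    v = row_r[c]
                    o = row_i[b0]
                    if v == o:
                        continue
                    if v > o:
                        fail_at, fail_block = b0, (b0, b1)
                    equal = False
                    break
                vals = []
                for k in range(b0, b1):
                    vals.append(row_r[ti] if k == j else row_r[tau[k]])
                svals = sorted(vals, reverse=True)
                stop = False
                for off in range(b1 - b0):
                    v = svals[off]
                    o = row_i[b0 + off]
                    if v == o:
                        continue
                    if v > o:
                        fail_at, fail_block = b0 + off, (b0, b1)
                    equal = False
                    stop = True
                    break
                if stop:
                    break
            if fail_at >= 0:
                witness = _witness(p, A, i, j, r, tau, ti, blocks, fail_at, fail_block)
                return "fail", witness
            if not equal:
                continue
            # Automorphism found: build τ·ς·σ by matching values per block.
            rho = list(tau)
            rho[i], rho[j] = tau[j], ti
            ok = True
            for b0, b1 in blocks:
                if b1 - b0 == 1:
                    continue
                pool: dict[int, list[int]] = {}
                for k in range(b0, b1):
                    c = ti if k == j else tau[k]
                    pool.setdefault(row_r[c], []).append(c)
                for lst in pool.values():
                    lst.reverse()  # pop() then yields ascending columns
                for k in range(b0, b1):
                    lst = pool.get(row_i[k])
                    if not lst:
                        ok = False
                        break
                    rho[k] = lst.pop()
                if not ok:
                    break
            if ok:
                rt = tuple(rho)
                if rt not in seen:
                    seen.add(rt)
                    new_f.append(rt)

    lam_next = _split_by_row(lam_sizes, row_i, i)
    return "ok", new_f, lam_next


def _witness(p, A, i, j, r, tau, ti, blocks, fail_at, fail_block):
    """Latest-filled entry among those certifying the violation at ``fail_at``.

    The certificate consists of the original row entries up to the failing
    position and, on the permuted side, one source entry of row ``r`` per
    compared position: whole blocks before the failing one, and for the
    failing block the columns realising the sorted prefix (ties resolved
    toward smaller columns, which back-jumps furthest while staying safe).

    When the automorphism τ maps some earlier row onto a row m ≥ i, the fact
    that τ fixes the partial matrix is itself certified by entries of row m,
    so the certificate widens to the whole of row m: continuations that
    alter row m could make τ lose its automorphism property, and skipping
    them would be unsound.
    """
    best = (i, fail_at)
    m = -1
    for x in range(i):
        tx = tau[x]
        if tx >= i and tx > m:
            m = tx
    if m >= 0:
        best = max(best, (m, p - 1) if m < p - 1 else (p - 2, p - 1))
    sources: list[int] = []
    for b0, b1 in blocks:
        if (b0, b1) == fail_block:
            pairs = []
            for k in range(b0, b1):
                c = ti if k == j else tau[k]
                pairs.append((-A[r][c], c))
            pairs.sort()
            sources.extend(c for _negv, c in pairs[: fail_at - b0 + 1])
            break
        for k in range(b0, b1):
            sources.append(ti if k == j else tau[k])
    for c in sources:
        entry = (r, c) if r < c else (c, r)
        if entry > best:
            best = entry
    return best


def _split_by_row(lam_sizes: Sequence[int], row: Sequence[int], i: int) -> list[int]:
    """Size-list version of :func:`partitions.partition_from_row`."""
    out: list[int] = []
    acc = 0
    for sz in lam_sizes:
        start, end = acc, acc + sz
        acc += sz
        if end <= i + 1 or sz == 1:
            out.append(sz)
            continue
        run = 1
        for k in range(start + 1, end):
            if row[k] == row[k - 1]:
                run += 1
            else:
                out.append(run)
                run = 1
        out.append(run)
    return out


def _refine_at(lam_sizes: Sequence[int], i: int) -> list[int]:
    """Size-list version of :func:`partitions.refine_partition`."""
    out: list[int] = []
    acc = 0
    for sz in lam_sizes:
        if acc == i and sz > 1:
            out.extend([1, sz - 1])
        else:
            out.append(sz)
        acc += sz
    return out


def _test_block(
    A: Matrix,
    p: int,
    bs: int,
    be: int,
    lam_sizes: Sequence[int],
    f_in: list[Perm],
):
    """Test rows ``bs..be`` of a completed block.

    Returns ``(True, lam_out, f_out)`` or ``(False, (wr, wc), None)``.
    The refined-partition/automorphism chain advances with each passing row;
    row p-1 has no entries beyond the diagonal and is trivially canonical.
    """
    lam = list(lam_sizes)
    f = f_in
    for i in range(bs, min(be, p - 2) + 1):
        res = _row_test(A, i, lam, f)
        if res[0] == "fail":
            return False, res[1], None
        _tag, f, lam_after = res
        # Split i off as a singleton for the next row, then apply the
        # row-entry subdivision already computed by _row_test.
        lam = _refine_at(lam_after, i)
    return True, lam, f


def test_block_canonical(
    matrix: Matrix,
    block_rows: Sequence[int],
    partition: OrderedPartition,
    ledger: AutomorphismLedger | None = None,
) -> CanonicalVerdict:
    """Canonical test of one completed block of rows.

    ``partition`` is the refined partition valid before the first row of the
    block and ``ledger`` the automorphism state after the previous block
    (identity-only when omitted).  All rows of the block — and all earlier
    rows — must be filled.
    """
    p = len(matrix)
    if any(len(row) != p for row in matrix):
        raise StateError("matrix must be square and completely filled")
    rows = sorted(block_rows)
    if not rows:
        raise InvalidInput("empty block")
    if rows[-1] >= p:
        raise IndexError(f"block row {rows[-1]} out of range for p={p}")
    ledger = ledger or AutomorphismLedger(p)
    ok, payload, f_out = _test_block(matrix, p, rows[0], rows[-1], list(partition.blocks), list(ledger.current))
    if not ok:
        return CanonicalVerdict(canonical=False, witness=payload)
    out_ledger = AutomorphismLedger(p, current=list(f_out))
    out_ledger.record(rows[-1], list(f_out))
    return CanonicalVerdict(
        canonical=True,
        witness=None,
        partition_after=OrderedPartition(payload),
        ledger=out_ledger,
    )
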