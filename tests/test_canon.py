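"""Canonical (maximality) testing: row comparison, canonical permutations,
automorphism accumulation and block verdicts with witnesses."""

from __future__ import annotations

import pytest

from isomergen import (
    AutomorphismLedger,
    InvalidInput,
    OrderedPartition,
    Transposition,
    compare_rows,
    cycle_transpositions,
    find_canonical_permutation,
    naive_maximality,
    permutation_from_cycles,
    refine_partition,
    update_automorphisms,
    young_subgroup_elements,
)
from isomergen import test_block_canonical as block_canonical
from isomergen.canon import _test_block

from conftest import random_partition, random_symmetric_matrix


def _sym(rows):
    """Build a symmetric p×p matrix from (a prefix of) full-width row specs."""
    p = len(rows[0])
    A = [[0] * p for _ in range(p)]
    for i, row in enumerate(rows):
        for j, v in enumerate(row):
            if v:
                A[i][j] = A[j][i] = v
    return A


class TestCompareRows:
    lam = OrderedPartition([4])

    def test_identical_rows_equal(self):
        assert compare_rows([2, 1, 1, 0], [2, 1, 1, 0], self.lam) == "equal"

    def test_first_difference_decides(self):
        assert compare_rows([2, 1, 0, 0], [2, 0, 1, 0], self.lam) == "greater"
        assert compare_rows([2, 0, 1, 0], [2, 1, 0, 0], self.lam) == "smaller"

    def test_length_mismatch_rejected(self):
        with pytest.raises(InvalidInput):
            compare_rows([1], [1, 2], self.lam)


class TestFindCanonicalPermutation:
    def test_identical_rows_yield_identity(self):
        lam = OrderedPartition([1, 4])
        row = [0, 2, 1, 1, 0]
        assert find_canonical_permutation(row, row, lam) == (0, 1, 2, 3, 4)

    def test_block_swap_recovered(self):
        # The permuted row differs from the original by exchanging the
        # entries at (1-based) positions 3 and 5; the deterministic search
        # must return exactly that transposition of the {2..5} block.
        lam = OrderedPartition([1, 4])
        original = [0, 2, 1, 2, 0]
        permuted = [0, 2, 0, 2, 1]
        sigma = find_canonical_permutation(original, permuted, lam)
        assert sigma == permutation_from_cycles([(3, 5)], 5, one_based=True)
        assert [permuted[sigma[k]] for k in range(5)] == original

    def test_mismatched_multisets_return_none(self):
        lam = OrderedPartition([1, 4])
        assert find_canonical_permutation([0, 2, 2, 0, 0], [0, 1, 1, 1, 0], lam) is None

    def test_sigma_respects_blocks(self):
        lam = OrderedPartition([2, 3])
        original = [1, 0, 2, 1, 0]
        permuted = [1, 0, 0, 2, 1]
        sigma = find_canonical_permutation(original, permuted, lam)
        assert sigma is not None
        assert {sigma[0], sigma[1]} == {0, 1}
        assert {sigma[2], sigma[3], sigma[4]} == {2, 3, 4}


class TestUpdateAutomorphisms:
    def test_row_fixing_cycle_is_added(self):
        # Rows 0 and 1 have identical bond patterns: the transposition (0,1)
        # maps row 0 onto itself and must be recorded.
        A = _sym([
            [0, 1, 1, 0, 0],
            [0, 0, 1, 0, 0],
        ])
        lam = OrderedPartition([5])
        ref = refine_partition(lam, 0)
        cycles = cycle_transpositions(lam, 0)
        f = update_automorphisms([tuple(range(5))], cycles, A, 0, ref)
        assert permutation_from_cycles([(1, 2)], 5, one_based=True) in f

    def test_cycle_needs_canonical_completion(self):
        # (0,1) alone does not fix row 0, but combined with a swap inside
        # the refined block it does; the stored automorphism is the product.
        A = _sym([
            [0, 2, 1, 2, 0],
            [0, 0, 0, 2, 1],
        ])
        lam = OrderedPartition([5])
        ref = refine_partition(lam, 0)
        cycles = cycle_transpositions(lam, 0)
        f = update_automorphisms([tuple(range(5))], cycles, A, 0, ref)
        expected = permutation_from_cycles([(1, 2), (3, 5)], 5, one_based=True)
        assert expected in f
        row0 = A[0]
        for rho in f:
            assert [A[rho[0]][rho[k]] for k in range(5)] == row0

    def test_identity_cycle_retains_identity(self):
        A = _sym([[0, 1, 0], [0, 0, 1]])
        lam = OrderedPartition([1, 1, 1])
        f = update_automorphisms(
            [tuple(range(3))], [Transposition(0, 0)], A, 0, lam
        )
        assert f == [(0, 1, 2)]


class TestBlockCanonical:
    def test_zero_matrix_is_canonical(self):
        A = [[0] * 4 for _ in range(4)]
        verdict = block_canonical(A, range(4), OrderedPartition([4]))
        assert verdict.canonical
        assert verdict.witness is None

    def test_noncanonical_witness_entry(self):
        # Row 0 is [0,1,1,1,0] but row 2 carries a double bond at (2,3):
        # permuting 0↔2 (with a block adjustment) beats row 0, and the entry
        # proving it is exactly the (2,3) double bond.
        C = _sym([
            [0, 1, 1, 1, 0],
            [0, 0, 1, 0, 0],
            [0, 0, 0, 2, 0],
            [0, 0, 0, 0, 0],
        ])
        verdict = block_canonical(C, range(5), OrderedPartition([5]))
        assert not verdict.canonical
        assert verdict.witness == (2, 3)
        assert not naive_maximality(C, OrderedPartition([5]))

    def test_ledger_permutations_fix_partial_matrix(self):
        A = _sym([
            [0, 3, 1, 1, 1],
            [0, 0, 1, 0, 0],
            [0, 0, 0, 0, 0],
            [0, 0, 0, 0, 0],
        ])
        lam = OrderedPartition([1, 1, 3])
        verdict = block_canonical(A, range(5), lam)
        if verdict.canonical:
            assert verdict.ledger is not None
            p = 5
            for rho in verdict.ledger.current:
                for x in range(p):
                    assert all(A[rho[x]][rho[y]] == A[x][y] for y in range(p))

    def test_unfilled_block_rejected(self):
        from isomergen import StateError

        with pytest.raises(StateError):
            block_canonical([[0, 1], [1]], range(2), OrderedPartition([2]))

    def test_matches_naive_maximality_on_random_matrices(self, rng):
        # The row-wise engine must agree with brute-force A ≥ Aπ over the
        # whole Young subgroup, for arbitrary matrices and partitions.
        checked = 0
        for _ in range(300):
            p = rng.randint(2, 5)
            A = random_symmetric_matrix(rng, p)
            lam = random_partition(rng, p)
            ok = True
            lam_sizes = list(lam.blocks)
            f = [tuple(range(p))]
            start = 0
            for size in lam.blocks:
                res = _test_block(A, p, start, start + size - 1, lam_sizes, f)
                if not res[0]:
                    ok = False
                    break
                _flag, lam_sizes, f = res
                start += size
            assert ok == naive_maximality(A, lam), (A, lam)
            checked += 1
        assert checked == 300


class TestLedger:
    def test_initial_list_is_identity(self):
        ledger = AutomorphismLedger(4)
        assert ledger.current == [(0, 1, 2, 3)]

    def test_record_advances_current(self):
        ledger = AutomorphismLedger(3)
        ledger.record(0, [(0, 1, 2), (1, 0, 2)])
        assert ledger.per_row[0] == [(0, 1, 2), (1, 0, 2)]
        assert ledger.current == [(0, 1, 2), (1, 0, 2)]
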