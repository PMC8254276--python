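"""The orderly generator: exactness against the oracle, duplicate-freeness,
maximality/connectivity of emissions, determinism, and edge cases."""

from __future__ import annotations

import pytest

from isomergen import (
    BondMatrix,
    GraphNonexistent,
    InvalidInput,
    backward_step,
    brute_force_count,
    canonical_key,
    connectivity_test,
    distribute_hydrogens,
    forward_fill,
    generate,
    generate_structures,
    max_entry_bound,
    naive_maximality,
)
from isomergen.generator import _iter_state_matrices

from conftest import ORACLE_PANEL

# A slice of the panel keeps the per-module runtime small; the full panel is
# exercised by the acceptance suite.
SMALL_PANEL = ORACLE_PANEL[:12]


class TestMaxEntryBound:
    def _matrix(self, formula):
        state = distribute_hydrogens(formula)[0]
        return state, BondMatrix.for_state(state)

    def test_two_fresh_carbons_bound_three(self):
        state, m = self._matrix("C3O2H4")  # first state: bare carbons first
        assert state.degrees[0] == state.degrees[1] == 4
        assert max_entry_bound(0, 1, state, m) == 3

    def test_remaining_degree_caps_bond(self):
        state, m = self._matrix("C3O2H4")
        oxygen = state.elements.index("O")
        m.remaining[oxygen] = 1
        assert max_entry_bound(0, oxygen, state, m) == 1

    def test_exhausted_atom_bound_zero(self):
        state, m = self._matrix("C3O2H4")
        m.remaining[1] = 0
        assert max_entry_bound(0, 1, state, m) == 0

    def test_requires_upper_triangle(self):
        state, m = self._matrix("C3O2H4")
        with pytest.raises(InvalidInput):
            max_entry_bound(2, 1, state, m)


class TestForwardBackward:
    def test_forward_fill_takes_maximum(self):
        state = next(
            s for s in distribute_hydrogens("C2H2") if s.degrees == (3, 3)
        )
        m = BondMatrix.for_state(state)
        assert forward_fill(m) == (0, 1)
        assert m.entries[0][1] == 3
        assert m.remaining == [0, 0]
        assert forward_fill(m) is None

    def test_backward_decrements_and_resumes(self):
        state = next(
            s for s in distribute_hydrogens("C2H2") if s.degrees == (3, 3)
        )
        m = BondMatrix.for_state(state)
        forward_fill(m)
        backward_step(m, (0, 1))
        assert m.entries[0][1] == 2
        assert m.remaining == [1, 1]

    def test_backward_exhausts_at_zero_first_entry(self):
        state = distribute_hydrogens("C2H6")[0]  # degrees (1, 1)
        m = BondMatrix.for_state(state)
        forward_fill(m)
        backward_step(m, (0, 1))  # 1 -> 0
        assert backward_step(m, (0, 1)) is None


class TestGenerateSmall:
    @pytest.mark.parametrize(
        "formula, expected",
        [
            ("CH4", 1),
            ("C2H6", 1),
            ("C2H2", 1),
            ("H2", 1),
            ("C4H10", 2),
            ("C3H8O", 3),
            ("C6H6", 217),
        ],
    )
    def test_known_counts(self, formula, expected):
        assert generate(formula).count == expected

    def test_single_heavy_atom_emits_once(self):
        result = generate("CH4")
        assert result.count == 1
        mols = list(generate_structures("CH4"))
        assert len(mols) == 1
        assert mols[0].elements == ("C",)
        assert mols[0].hydrogens == (4,)

    def test_two_atom_state_emits_ethane_once(self):
        mols = list(generate_structures("C2H6"))
        assert len(mols) == 1
        assert mols[0].bonds == ((0, 1, 1),)

    def test_nonexistent_graph_raises(self):
        with pytest.raises(GraphNonexistent):
            generate("C2H8")
        with pytest.raises(GraphNonexistent):
            generate("CH3")  # odd degree sum

    def test_total_is_sum_over_hydrogen_distributions(self):
        result = generate("C6H6")
        assert result.count == sum(n for _state, n in result.per_state)
        assert len(result.per_state) == 7


class TestExactness:
    @pytest.mark.parametrize("formula", SMALL_PANEL)
    def test_count_matches_brute_force(self, formula):
        assert generate(formula).count == brute_force_count(formula)

    @pytest.mark.parametrize("formula", ["C4H6O", "C3H4N2"])
    def test_learning_backjumps_change_nothing(self, formula):
        assert generate(formula).count == generate(formula, learning=False).count

    @pytest.mark.parametrize(
        "formula_a, formula_b",
        [("C3H5N", "C3H5P"), ("C2H6O", "C2H6S"), ("C3H7Cl", "C3H7Br"), ("C3H7F", "C3H7I")],
    )
    def test_valence_swap_invariance(self, formula_a, formula_b):
        # N<->P, O<->S and halogen exchanges preserve the degree sequences,
        # hence the isomer count.
        assert generate(formula_a).count == generate(formula_b).count


class TestEmissionProperties:
    @pytest.mark.parametrize("formula", ["C4H6", "C3H4O", "C3H5N"])
    def test_emitted_matrices_are_maximal_and_connected(self, formula):
        for state in distribute_hydrogens(formula):
            for A in _iter_state_matrices(state):
                assert naive_maximality(A, state.partition)
                assert connectivity_test(A).connected
                for i in range(state.p):
                    assert sum(A[i]) == state.degrees[i]

    @pytest.mark.parametrize("formula", ["C5H8", "C4H6O"])
    def test_no_duplicate_isomorphism_classes(self, formula):
        keys = []
        for mol in generate_structures(formula):
            colors = list(zip(mol.elements, mol.hydrogens))
            p = len(mol.elements)
            A = [[0] * p for _ in range(p)]
            for a, b, order in mol.bonds:
                A[a][b] = A[b][a] = order
            keys.append(canonical_key(colors, A))
        assert len(keys) == len(set(keys))

    def test_key_set_equals_oracle_key_set(self):
        formula = "C3H6O"
        _n, oracle_keys = brute_force_count(formula, collect_keys=True)
        gen_keys = set()
        for mol in generate_structures(formula):
            colors = list(zip(mol.elements, mol.hydrogens))
            p = len(mol.elements)
            A = [[0] * p for _ in range(p)]
            for a, b, order in mol.bonds:
                A[a][b] = A[b][a] = order
            gen_keys.add(canonical_key(colors, A))
        assert gen_keys == oracle_keys

    def test_deterministic_output_sequence(self):
        first = [m for m in generate_structures("C4H8O")]
        second = [m for m in generate_structures("C4H8O")]
        assert first == second
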