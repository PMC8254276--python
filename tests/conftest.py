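"""Shared fixtures and helpers for the isomergen test suite."""

from __future__ import annotations

import random

import pytest

from isomergen import OrderedPartition

#: Formulae small enough for the brute-force oracle but covering all
#: supported elements, saturation levels and ring/multiple-bond regimes.
ORACLE_PANEL = [
    "CH4", "C2H6", "C2H4", "C2H2", "C3H8", "C3H6", "C3H4",
    "C4H10", "C4H8", "C4H6", "C5H12", "C5H10", "C5H8",
    "C6H14", "C6H12", "C2H6O", "C3H8O", "C2H4O", "C3H6O", "C4H8O",
    "C2H6S", "C3H5N", "C3H5P", "C2H7N", "C4H4O", "C2H3N", "C3H9N",
    "C4H5N", "C3H4O2", "C2H4N2", "C3H7Cl", "C4H9Br", "CH5N", "C5H6", "C6H6",
]


@pytest.fixture(scope="session")
def rng() -> random.Random:
    return random.Random(20240613)


def random_symmetric_matrix(rng: random.Random, p: int, max_order: int = 3):
    """A random symmetric bond-order matrix with zero diagonal."""
    A = [[0] * p for _ in range(p)]
    for i in range(p - 1):
        for j in range(i + 1, p):
            v = rng.choice([0, 0, 0, 1, 1, 2, max_order])
            A[i][j] = A[j][i] = v
    return A


def random_partition(rng: random.Random, p: int) -> OrderedPartition:
    """A random ordered partition of 0..p-1."""
    blocks = []
    left = p
    while left:
        b = rng.randint(1, left)
        blocks.append(b)
        left -= b
    return OrderedPartition(blocks)
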