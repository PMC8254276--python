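"""Label-propagation connectivity test on completed bond matrices.

Every node starts with its own index as label.  Scanning nodes in index
order, the closed neighbourhood of each node (the node plus its bonded
neighbours) is collapsed to the minimum label occurring in it, and that
minimum is written back to the node and all its neighbours.  The sweep is
repeated until no label changes; at the fixpoint the labels are constant on
every connected component and equal the component's smallest node index.
The matrix is connected exactly when every label is 0.

For a disconnected candidate the *first component* (the one containing node
0) tells the generator where the matrix can be minimally repaired: every
entry after the last entry of the first component's maximum-index row can
only produce further disconnected graphs, so the generator back-jumps there
(:func:`disconnection_backjump`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .errors import StateError

__all__ = ["ConnectivityReport", "connectivity_test", "disconnection_backjump"]

Matrix = Sequence[Sequence[int]]


@dataclass(frozen=True)
class ConnectivityReport:
    """Result of :func:`connectivity_test`.

    ``labels`` are the fixpoint labels (0-based); ``first_component`` is the
    sorted set of node indices reachable from node 0, and ``max_index`` its
    largest member.  ``history`` records the label vector after each node
    update of the first sweep (diagnostic aid).
    """

    connected: bool
    labels: tuple[int, ...]
    first_component: tuple[int, ...]
    max_index: int
    history: tuple[tuple[int, ...], ...] = field(default=(), repr=False)


def connectivity_test(matrix: Matrix) -> ConnectivityReport:
    """Run the label-propagation connectivity test on a complete matrix."""
    p = len(matrix)
    if p == 0 or any(len(row) != p for row in matrix):
        raise StateError("connectivity test requires a complete square matrix")
    labels = list(range(p))
    history: list[tuple[int, ...]] = []
    first_sweep = True
    changed = True
    while changed:
        changed = False
        for v in range(p):
            row = matrix[v]
            nbrs = [u for u in range(p) if u != v and row[u] > 0]
            mini = labels[v]
            for u in nbrs:
                if labels[u] < mini:
                    mini = labels[u]
            for u in nbrs:
                if labels[u] != mini:
                    labels[u] = mini
                    changed = True
            if labels[v] != mini:
                labels[v] = mini
                changed = True
            if first_sweep:
                history.append(tuple(labels))
        first_sweep = False
    first = tuple(i for i in range(p) if labels[i] == 0)
    return ConnectivityReport(
        connected=all(l == 0 for l in labels),
        labels=tuple(labels),
        first_component=first,
        max_index=first[-1],
        history=tuple(history),
    )


def disconnection_backjump(report: ConnectivityReport, p: int) -> tuple[int, int]:
    """Back-jump target for a disconnected matrix: ``(max_index, p-1)``.

    The maximum index m of the first component identifies where the graph
    gets disconnected: entries filled after (m, p-1) touch only rows outside
    the first component and can never reconnect it.  Raises
    :class:`StateError` when called on a connected report.
    """
    if report.connected:
        raise StateError("back-jump requested for a connected matrix")
    m = report.max_index
    if m >= p - 1:
        # Component of node 0 reaches the last row; fall back to the last
        # fillable entry of the matrix.
        return (p - 2, p - 1)
    return (m, p - 1)


def _component_of_first(matrix: Matrix, p: int) -> tuple[bool, int]:
    """Fast traversal equivalent of :func:`connectivity_test`.

    Returns ``(connected, max_index_of_first_component)``; used in the
    generator's hot loop.  Equivalence with the label-propagation fixpoint is
    asserted by the test suite.
    """
    seen = bytearray(p)
    seen[0] = 1
    stack = [0]
    count = 1
    max_index = 0
    while stack:
        v = stack.pop()
        row = matrix[v]
        for u in range(p):
            if row[u] and not seen[u]:
                seen[u] = 1
                count += 1
                if u > max_index:
                    max_index = u
                stack.append(u)
    return count == p, max_index
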