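"""Brute-force reference implementations for validation.

These deliberately naive routines recompute, by exhaustive enumeration
over *all* internal-node labelings, quantities that the main modules
obtain with dynamic programming: parsimony scores, MPR sets, and the
unambiguous-synapomorphy definition applied literally to the enumerated
MPR list.  Also plain graph reachability as the reference for homolog
closure.  Exponential-time; intended for small instances in tests and
acceptance checks only.
"""

from __future__ import annotations

import numpy as np

from .parsimony import CharacterColumn
from .trees import PhyloTree
from .types import AlignedMatrix

_GRID_LIMIT = 2_000_000


def _labeling_grid(tree: PhyloTree, column: CharacterColumn):
    """Enumerate every assignment of observed states to internal nodes.

    Returns (internal nodes, observed states, state-index grid of shape
    (n_internal, n_assignments), cost vector per assignment).
    """
    internals = [n for n in tree.postorder() if not n.is_tip]
    observed = column.observed()
    S, I = len(observed), len(internals)
    if S ** I > _GRID_LIMIT:
        raise ValueError("instance too large for the brute-force oracle")
    grids = np.indices((S,) * I).reshape(I, -1)
    node_states = {id(n): grids[k] for k, n in enumerate(internals)}
    cost = np.zeros(grids.shape[1], dtype=np.int64)
    for n in tree.postorder():
        if n is tree.root:
            continue
        parent = node_states[id(n.parent)]
        if n.is_tip:
            st = column.states[n.label]
            if st is not None:
                cost += parent != observed.index(st)
        else:
            cost += parent != node_states[id(n)]
    return internals, observed, grids, cost


def brute_force_parsimony(tree: PhyloTree, matrix: AlignedMatrix) -> int:
    """Minimum changes over all internal labelings, summed over columns."""
    total = 0
    for j in range(matrix.n_cols):
        column = CharacterColumn.from_matrix(matrix, j)
        if len(column.observed()) <= 1:
            continue
        _, _, _, cost = _labeling_grid(tree, column)
        total += int(cost.min())
    return total


def brute_force_mprs(tree: PhyloTree, column: CharacterColumn,
                     ) -> list[dict[str, str]]:
    """All minimum-change internal labelings, as node-id -> state dicts."""
    if any(n.id is None for n in tree.postorder()):
        tree.assign_ids()
    observed = column.observed()
    if not observed:
        return [{}]
    internals, observed, grids, cost = _labeling_grid(tree, column)
    opt = np.nonzero(cost == cost.min())[0]
    return [
        {n.id: observed[grids[k, o]] for k, n in enumerate(internals)}
        for o in opt
    ]


def brute_force_synapomorphies(tree: PhyloTree, matrix: AlignedMatrix,
                               ) -> set[tuple[str, int, str]]:
    """(node_id, column, derived) triples: branches into internal nodes
    that change in every MPR with one fixed derived state."""
    if any(n.id is None for n in tree.postorder()):
        tree.assign_ids()
    out: set[tuple[str, int, str]] = set()
    for j in range(matrix.n_cols):
        column = CharacterColumn.from_matrix(matrix, j)
        if len(column.observed()) < 2:
            continue
        internals, observed, grids, cost = _labeling_grid(tree, column)
        opt = cost == cost.min()
        index_of = {id(n): k for k, n in enumerate(internals)}
        for k, n in enumerate(internals):
            if n is tree.root:
                continue
            mine = grids[k, opt]
            parents = grids[index_of[id(n.parent)], opt]
            states = np.unique(mine)
            if len(states) == 1 and np.all(mine != parents):
                out.add((n.id, j, observed[int(states[0])]))
    return out


def reachability_closure(seeds, edges) -> set[str]:
    """Members reachable from the seeds in a directed hit graph.

    ``edges`` is an iterable of (query_id, subject_id) pairs that pass the
    threshold; plain breadth-first reachability, independent of the
    iterative fixed-point implementation.
    """
    adj: dict[str, list[str]] = {}
    for q, s in edges:
        adj.setdefault(q, []).append(s)
    seen = set(seeds)
    frontier = list(seeds)
    while frontier:
        nxt = []
        for q in frontier:
            for s in adj.get(q, ()):
                if s not in seen:
                    seen.add(s)
                    nxt.append(s)
        frontier = nxt
    return seen
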