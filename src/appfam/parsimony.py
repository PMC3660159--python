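"""Maximum-parsimony machinery.

Fitch/Hartigan scoring, most-parsimonious-reconstruction (MPR) enumeration,
unambiguous synapomorphy calling, multi-start SPR tree search, consensus
trees and bootstrap supports.

Definitions
-----------
An *unambiguous synapomorphy* at an internal node, for one alignment
column, requires that **every** most-parsimonious reconstruction of that
column places a state change on the branch entering the node and that the
derived state is identical across all MPRs.  Rather than materialising all
MPRs, `detect_synapomorphies` uses an equivalent min-cost characterisation:
state ``s`` is unambiguously derived at node ``v`` iff ``v`` can carry only
``s`` in optimal reconstructions while its parent can never carry ``s``
(checked with inside/outside Sankoff costs).  The equivalence is exercised
against explicit MPR enumeration in the test suite.

Gaps and ``X`` are treated as missing data (any state, no forced change),
not as a 21st state.  Synapomorphies are reported for internal nodes only;
changes on terminal branches (autapomorphies) are counted separately.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .trees import Node, PhyloTree, read_newick_string
from .types import AA_ALPHABET, GAP, MISSING, NT_ALPHABET, AlignedMatrix

log = logging.getLogger(__name__)

_INF = float("inf")


class MprSizeError(ValueError):
    """Raised when MPR enumeration would be explosive; sample instead."""


# ----------------------------------------------------------------------
# state encoding
# ----------------------------------------------------------------------

class EncodedMatrix:
    """Bitmask encoding of an alignment: one uint32 per cell, one bit per
    state; gap/X cells carry the full-alphabet mask (missing data)."""

    def __init__(self, matrix: AlignedMatrix):
        alphabet = AA_ALPHABET if matrix.alphabet == "aa" else NT_ALPHABET
        self.alphabet = alphabet
        self.n_states = len(alphabet)
        self.full = np.uint32((1 << self.n_states) - 1)
        self.n_cols = matrix.n_cols
        index = {c: i for i, c in enumerate(alphabet)}
        self.masks: dict[str, np.ndarray] = {}
        for rid in matrix.row_ids:
            row = matrix.row(rid)
            m = np.empty(len(row), dtype=np.uint32)
            for j, c in enumerate(row):
                if c in index:
                    m[j] = np.uint32(1) << index[c]
                elif c in (GAP, MISSING, "?"):
                    m[j] = self.full
                else:
                    raise ValueError(f"unencodable state {c!r} in row {rid}")
            self.masks[rid] = m
        self._shifts = np.arange(self.n_states, dtype=np.uint32)
        self._weights = np.ones(self.n_cols, dtype=np.int64)

    def resample_columns(self, cols: np.ndarray) -> "EncodedMatrix":
        new = EncodedMatrix.__new__(EncodedMatrix)
        new.alphabet = self.alphabet
        new.n_states = self.n_states
        new.full = self.full
        new.n_cols = len(cols)
        new.masks = {rid: m[cols] for rid, m in self.masks.items()}
        new._shifts = self._shifts
        new._weights = np.ones(len(cols), dtype=np.int64)
        return new


def _as_encoded(matrix) -> EncodedMatrix:
    return matrix if isinstance(matrix, EncodedMatrix) else EncodedMatrix(matrix)


# ----------------------------------------------------------------------
# Fitch / Hartigan scoring
# ----------------------------------------------------------------------

def fitch_score(tree: PhyloTree, matrix) -> int:
    """Minimum number of state changes summed over columns.

    Implements Hartigan's generalisation (state-count maximisation over the
    children of each node), which coincides with Fitch on binary trees and
    is exact on polytomies.  Missing states contribute no forced changes.
    """
    enc = _as_encoded(matrix)
    changes = np.zeros(enc.n_cols, dtype=np.int64)
    stash: dict[int, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_tip:
            try:
                stash[id(node)] = enc.masks[node.label]
            except KeyError:
                raise KeyError(
                    f"tip {node.label!r} has no row in the matrix") from None
            continue
        kids = [stash.pop(id(c)) for c in node.children]
        if len(kids) == 2:
            a, b = kids
            inter = a & b
            nz = inter != 0
            stash[id(node)] = np.where(nz, inter, a | b)
            changes += ~nz
        else:
            bits = np.stack(
                [((k[:, None] >> enc._shifts) & 1).astype(np.int16)
                 for k in kids])
            counts = bits.sum(axis=0)              # (n_cols, n_states)
            K = counts.max(axis=1)
            changes += len(kids) - K
            sel = counts == K[:, None]
            stash[id(node)] = (
                sel.astype(np.uint32) << enc._shifts[None, :]
            ).sum(axis=1).astype(np.uint32)
    return int((changes * enc._weights).sum())


# ----------------------------------------------------------------------
# MPR enumeration and synapomorphy detection
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class CharacterColumn:
    """One alignment column: per-tip single state, with gaps/X as None."""

    index: int
    states: dict[str, str | None]

    @classmethod
    def from_matrix(cls, matrix: AlignedMatrix, j: int) -> "CharacterColumn":
        states = {}
        for rid in matrix.row_ids:
            c = matrix.row(rid)[j]
            states[rid] = None if c in (GAP, MISSING, "?") else c
        return cls(j, states)

    def observed(self) -> list[str]:
        return sorted({s for s in self.states.values() if s is not None})


def _sankoff_inside(tree: PhyloTree, column: CharacterColumn,
                    observed: list[str]) -> dict[int, list[float]]:
    """inside[v][i] = min changes in v's subtree given v carries state i.

    Optimal labelings of unordered characters only ever use observed
    states, so the state space is restricted to them.  Tips with missing
    data cost 0 under any state.
    """
    S = len(observed)
    idx = {s: i for i, s in enumerate(observed)}
    inside: dict[int, list[float]] = {}
    for node in tree.postorder():
        if node.is_tip:
            st = column.states.get(node.label)
            if st is None:
                inside[id(node)] = [0.0] * S
            else:
                inside[id(node)] = [0.0 if i == idx[st] else _INF
                                    for i in range(S)]
            continue
        total = [0.0] * S
        for child in node.children:
            ci = inside[id(child)]
            cmin = min(ci)
            for i in range(S):
                total[i] += min(ci[i], 1.0 + cmin)
        inside[id(node)] = total
    return inside


def enumerate_mprs(tree: PhyloTree, column: CharacterColumn,
                   max_tips: int = 20) -> list[dict[str, str]]:
    """All most-parsimonious internal labelings for one column.

    Returns one dict per MPR mapping internal-node id -> state.  Constant
    columns yield the single all-ancestral labeling.  Guarded against
    large trees, where the MPR set can be astronomically large.
    """
    if tree.n_tips() > max_tips:
        raise MprSizeError(
            f"tree has {tree.n_tips()} tips (> {max_tips}); enumerate_mprs "
            "is for small instances — sample MPRs or use "
            "detect_synapomorphies, which avoids enumeration")
    if any(n.id is None for n in tree.postorder()):
        tree.assign_ids()
    observed = column.observed()
    if not observed:
        return [{}]
    inside = _sankoff_inside(tree, column, observed)

    def expand(node: Node, state_i: int) -> list[dict[str, str]]:
        if node.is_tip:
            return [{}]
        partials: list[list[dict[str, str]]] = []
        for child in node.children:
            ci = inside[id(child)]
            cmin = min(ci)
            best = min(ci[state_i], 1.0 + cmin)
            opts: list[dict[str, str]] = []
            for j in range(len(observed)):
                cost = ci[j] + (0.0 if j == state_i else 1.0)
                if cost == best:
                    for sub in expand(child, j):
                        if not child.is_tip:
                            sub = {**sub, child.id: observed[j]}
                        opts.append(sub)
            # a missing tip yields duplicate empty labelings; collapse
            if child.is_tip:
                opts = [{}]
            partials.append(opts)
        out = []
        for combo in itertools.product(*partials):
            merged: dict[str, str] = {}
            for d in combo:
                merged.update(d)
            out.append(merged)
        return out

    root = tree.root
    ri = inside[id(root)]
    m = min(ri)
    labelings = []
    for i, s in enumerate(observed):
        if ri[i] == m:
            for sub in expand(root, i):
                sub[root.id] = s
                labelings.append(sub)
    # deduplicate (missing data can make different expansions coincide)
    seen = set()
    unique = []
    for lab in labelings:
        key = tuple(sorted(lab.items()))
        if key not in seen:
            seen.add(key)
            unique.append(lab)
    return unique


@dataclass(frozen=True)
class SynapoEntry:
    node_id: str
    column: int  # 0-based alignment column
    ancestral: str  # '/'-joined if ambiguous across MPRs
    derived: str


@dataclass
class SynapomorphyTable:
    entries: list[SynapoEntry]
    tree: PhyloTree
    autapomorphy_count: int = 0

    @property
    def total(self) -> int:
        return len(self.entries)

    def by_node(self) -> dict[str, list[SynapoEntry]]:
        out: dict[str, list[SynapoEntry]] = {}
        for e in self.entries:
            out.setdefault(e.node_id, []).append(e)
        return out

    def restrict_nodes(self, node_ids) -> "SynapomorphyTable":
        keep = set(node_ids)
        return SynapomorphyTable(
            [e for e in self.entries if e.node_id in keep], self.tree,
            self.autapomorphy_count)

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("node_id\tcolumn_1based\tancestral\tderived\n")
            for e in sorted(self.entries,
                            key=lambda e: (e.column, e.node_id)):
                fh.write(f"{e.node_id}\t{e.column + 1}\t{e.ancestral}\t"
                         f"{e.derived}\n")


def detect_synapomorphies(tree: PhyloTree, matrix: AlignedMatrix,
                          ) -> SynapomorphyTable:
    """Unambiguous synapomorphies at every internal node.

    Requires a rooted tree (ancestral→derived polarity is meaningless
    otherwise).  See the module docstring for the exact definition and the
    min-cost characterisation used.
    """
    if not tree.rooted:
        raise ValueError(
            "tree is unrooted; root it first (e.g. "
            "tree.root_with_outgroup([...])) so ancestral/derived polarity "
            "is defined")
    missing = set(tree.tip_labels()) - set(matrix.row_ids)
    if missing:
        raise KeyError(f"tips without matrix rows: {sorted(missing)}")
    if any(n.id is None for n in tree.postorder()):
        tree.assign_ids()

    entries: list[SynapoEntry] = []
    autapo = 0
    parent_of = {id(n): n.parent for n in tree.postorder()}

    for j in range(matrix.n_cols):
        column = CharacterColumn.from_matrix(matrix, j)
        observed = column.observed()
        if len(observed) < 2:
            continue
        S = len(observed)
        inside = _sankoff_inside(tree, column, observed)

        # outside[v][i] = min changes outside v's subtree given v carries i
        outside: dict[int, list[float]] = {id(tree.root): [0.0] * S}
        for node in tree.preorder():
            if node.is_tip:
                continue
            out_u = outside[id(node)]
            contribs = []
            for child in node.children:
                ci = inside[id(child)]
                cmin = min(ci)
                contribs.append([min(ci[i], 1.0 + cmin) for i in range(S)])
            tot = [out_u[i] + sum(c[i] for c in contribs) for i in range(S)]
            for k, child in enumerate(node.children):
                g = [tot[i] - contribs[k][i] for i in range(S)]
                gmin = min(g)
                outside[id(child)] = [min(g[i], 1.0 + gmin)
                                      for i in range(S)]

        M = min(inside[id(tree.root)])
        possible: dict[int, set[int]] = {}
        for node in tree.postorder():
            tot_v = inside[id(node)]
            out_v = outside[id(node)]
            possible[id(node)] = {i for i in range(S)
                                  if tot_v[i] + out_v[i] == M}

        for node in tree.postorder():
            if node is tree.root:
                continue
            parent_possible = possible[id(parent_of[id(node)])]
            if node.is_tip:
                st = column.states.get(node.label)
                if st is not None and observed.index(st) not in parent_possible:
                    autapo += 1
                continue
            poss = possible[id(node)]
            if len(poss) == 1:
                (i,) = poss
                if i not in parent_possible:
                    anc = "/".join(observed[k]
                                   for k in sorted(parent_possible))
                    entries.append(SynapoEntry(node.id, j, anc, observed[i]))

    return SynapomorphyTable(entries, tree, autapomorphy_count=autapo)


# ----------------------------------------------------------------------
# heuristic tree search
# ----------------------------------------------------------------------

@dataclass
class SearchResult:
    trees: list[PhyloTree]
    score: int
    n_starts: int
    log: list[tuple[int, int]] = field(default_factory=list)  # (start, score)


def _three_taxon_tree(a: str, b: str, c: str) -> PhyloTree:
    root = Node()
    inner = root.add_child(Node())
    inner.add_child(Node(label=a))
    inner.add_child(Node(label=b))
    root.add_child(Node(label=c))
    return PhyloTree(root, rooted=False)


def _insertable_edges(tree: PhyloTree) -> list[Node]:
    """Nodes whose parent edge can receive a regraft (all but the root)."""
    return [n for n in tree.postorder() if n is not tree.root]


def _insert_at_edge(tree: PhyloTree, edge_child: Node,
                    subtree: Node) -> None:
    """Split the edge above ``edge_child`` and attach ``subtree``."""
    parent = edge_child.parent
    joint = Node()
    parent.children[parent.children.index(edge_child)] = joint
    joint.parent = parent
    joint.add_child(edge_child)
    joint.add_child(subtree)


def _detach(tree: PhyloTree, node: Node) -> None:
    """Remove ``node``'s subtree, splicing out its (binary) parent."""
    parent = node.parent
    grand = parent.parent
    sibling = next(c for c in parent.children if c is not node)
    if grand is None:
        sibling.parent = None
        tree.root = sibling
    else:
        grand.children[grand.children.index(parent)] = sibling
        sibling.parent = grand
    node.parent = None


def _add_taxon_best(tree: PhyloTree, label: str, enc: EncodedMatrix,
                    rng: np.random.Generator) -> PhyloTree:
    best_tree, best_score = None, None
    edges = _insertable_edges(tree)
    order = rng.permutation(len(edges))
    for k in order:
        cand = tree.copy()
        cand_edges = _insertable_edges(cand)
        _insert_at_edge(cand, cand_edges[int(k)], Node(label=label))
        cand = PhyloTree(cand.root, rooted=False)
        s = fitch_score(cand, enc)
        if best_score is None or s < best_score:
            best_tree, best_score = cand, s
    return best_tree


def _spr_neighbors(tree: PhyloTree, rng: np.random.Generator):
    """Yield (prune_index, regraft_index) pairs in random order; indices
    refer to the postorder position of non-root nodes."""
    nodes = [n for n in tree.postorder() if n is not tree.root]
    n = len(nodes)
    pairs = [(i, j) for i in range(n) for j in range(n) if i != j]
    for k in rng.permutation(len(pairs)):
        yield pairs[int(k)]


def _apply_spr(tree: PhyloTree, prune_i: int, regraft_i: int,
               ) -> PhyloTree | None:
    cand = tree.copy()
    nodes = [n for n in cand.postorder() if n is not cand.root]
    prune, target = nodes[prune_i], nodes[regraft_i]
    # target must not be inside the pruned subtree, nor its sibling
    anc = target
    while anc is not None:
        if anc is prune:
            return None
        anc = anc.parent
    parent = prune.parent
    sibling = next(c for c in parent.children if c is not prune)
    if target is sibling or target is parent:
        return None  # no-op move
    _detach(cand, prune)
    _insert_at_edge(cand, target, prune)
    return PhyloTree(cand.root, rooted=False)


def heuristic_search(matrix, n_starts: int = 8, seed: int = 0,
                     swap: str = "SPR", keep_max: int = 64) -> SearchResult:
    """Multi-start maximum-parsimony search.

    Each start builds a random-addition tree (greedy stepwise insertion in
    a shuffled taxon order) and hill-climbs with subtree-prune-regraft
    moves (first-improvement sweeps) to a local optimum.  All distinct
    topologies at the best score seen across starts are retained.
    Deterministic for a fixed seed.
    """
    if swap != "SPR":
        raise ValueError(f"unsupported swap strategy {swap!r}")
    enc = _as_encoded(matrix)
    labels = sorted(enc.masks)
    if len(labels) < 4:
        raise ValueError("heuristic search needs >= 4 taxa")
    rng = np.random.default_rng(seed)
    best_score: int | None = None
    best: list[PhyloTree] = []
    best_splits: set[frozenset[frozenset[str]]] = set()
    trace: list[tuple[int, int]] = []

    for start in range(n_starts):
        order = [labels[int(i)] for i in rng.permutation(len(labels))]
        tree = _three_taxon_tree(*order[:3])
        for lab in order[3:]:
            tree = _add_taxon_best(tree, lab, enc, rng)
        score = fitch_score(tree, enc)
        improved = True
        while improved:
            improved = False
            for pi, ri in _spr_neighbors(tree, rng):
                cand = _apply_spr(tree, pi, ri)
                if cand is None:
                    continue
                s = fitch_score(cand, enc)
                if s < score:
                    tree, score = cand, s
                    improved = True
                    break
        trace.append((start, score))
        if best_score is None or score < best_score:
            best_score = score
            best = [tree]
            best_splits = {frozenset(tree.splits())}
        elif score == best_score and len(best) < keep_max:
            key = frozenset(tree.splits())
            if key not in best_splits:
                best_splits.add(key)
                best.append(tree)
    return SearchResult(trees=best, score=int(best_score),
                        n_starts=n_starts, log=trace)


# ----------------------------------------------------------------------
# consensus and bootstrap
# ----------------------------------------------------------------------

def consensus(trees: list[PhyloTree], rule: str = "majority",
              cutoff: float = 0.5) -> PhyloTree:
    """Strict or majority-rule consensus of trees over one tip set.

    Majority keeps clades occurring in more than ``cutoff`` of the trees;
    strict keeps clades in all trees.  Delegates split bookkeeping to
    dendropy.
    """
    if not trees:
        raise ValueError("need at least one tree")
    tipsets = {frozenset(t.tip_labels()) for t in trees}
    if len(tipsets) != 1:
        raise ValueError("trees have mismatched tip sets")
    if len(trees) == 1:
        return trees[0].copy()
    if rule == "strict":
        min_freq = 1.0
    elif rule == "majority":
        # "more than cutoff" semantics; dendropy includes splits at
        # exactly min_freq, so nudge past the cutoff
        min_freq = min(1.0, cutoff + 1e-9)
    else:
        raise ValueError(f"unknown consensus rule {rule!r}")
    tns = dendropy.TaxonNamespace()
    tl = dendropy.TreeList(taxon_namespace=tns)
    for t in trees:
        tl.append(dendropy.Tree.get(
            data=t.to_newick(branch_lengths=False), schema="newick",
            taxon_namespace=tns, preserve_underscores=True))
    ct = tl.consensus(min_freq=min_freq)
    for e in ct.preorder_edge_iter():
        e.length = None
    for nd in ct:
        nd.label = None
    newick = ct.as_string(schema="newick", suppress_rooting=True,
                          unquoted_underscores=True)
    out = read_newick_string(newick)
    out.rooted = False
    return out


def bootstrap_support(matrix, n_reps: int = 100, seed: int = 0,
                      n_starts: int = 2) -> tuple[PhyloTree,
                                                  dict[frozenset, float]]:
    """Nonparametric bootstrap: resample columns, re-search, report clade
    frequencies (0–100) on the majority consensus of replicate trees."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    enc = _as_encoded(matrix)
    rng = np.random.default_rng(seed)
    rep_trees = []
    for rep in range(n_reps):
        cols = rng.integers(enc.n_cols, size=enc.n_cols)
        sub = enc.resample_columns(cols)
        res = heuristic_search(sub, n_starts=n_starts,
                               seed=int(rng.integers(2**31)))
        rep_trees.append(res.trees[0])
    counts: dict[frozenset, int] = {}
    for t in rep_trees:
        for split in t.splits():
            counts[split] = counts.get(split, 0) + 1
    freqs = {s: 100.0 * c / n_reps for s, c in counts.items()}
    cons = consensus(rep_trees, rule="majority", cutoff=0.5)
    all_tips = frozenset(cons.tip_labels())
    anchor = min(all_tips)
    for node in cons.internal_nodes():
        if node is cons.root:
            continue
        clade = cons.clade_tips(node)
        side = all_tips - clade if anchor in clade else clade
        if side in freqs:
            node.support = round(freqs[side], 1)
    return cons, freqs
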