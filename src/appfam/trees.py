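"""Rooted phylogenetic trees and annotated Newick I/O.

Trees are plain parent/child node structures; parsing goes through dendropy
(which understands the ``[&key=value,...]`` comment dialect used for branch
supports and per-tip classification colours), while serialization is done
here so the same dialect round-trips losslessly.
"""

from __future__ import annotations

from typing import Iterable, Iterator, Optional

import dendropy


class NewickParseError(ValueError):
    pass


class Node:
    __slots__ = ("label", "children", "parent", "length", "support",
                 "annotations", "id")

    def __init__(self, label: Optional[str] = None,
                 length: Optional[float] = None):
        self.label = label
        self.children: list[Node] = []
        self.parent: Optional[Node] = None
        self.length = length
        self.support: Optional[float] = None
        self.annotations: dict[str, str] = {}
        self.id: Optional[str] = None

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_tip(self) -> bool:
        return not self.children

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"<Node {self.label or self.id or '?'}>"


class PhyloTree:
    """A rooted tree with uniquely labelled tips.

    ``rooted`` records whether the root placement is meaningful (outgroup
    rooting or a simulation's true root) as opposed to an arbitrary
    serialization anchor for an unrooted topology.
    """

    def __init__(self, root: Node, rooted: bool = True):
        self.root = root
        self.rooted = rooted
        labels = [n.label for n in self.tips()]
        if any(l is None for l in labels):
            raise ValueError("every tip must be labelled")
        if len(set(labels)) != len(labels):
            raise ValueError("tip labels must be unique")

    # ------------------------------------------------------------------
    # traversal
    # ------------------------------------------------------------------
    def postorder(self) -> Iterator[Node]:
        stack, out = [self.root], []
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return reversed(out)

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def tips(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_tip]

    def tip_labels(self) -> list[str]:
        return [n.label for n in self.tips()]

    def internal_nodes(self) -> list[Node]:
        return [n for n in self.postorder() if not n.is_tip]

    def n_tips(self) -> int:
        return len(self.tips())

    def is_binary(self) -> bool:
        return all(len(n.children) == 2 for n in self.internal_nodes())

    # ------------------------------------------------------------------
    # identity and lookup
    # ------------------------------------------------------------------
    def assign_ids(self) -> None:
        """Stable node ids: tips get their label, internals n0, n1, ... in
        postorder."""
        k = 0
        for node in self.postorder():
            if node.is_tip:
                node.id = node.label
            else:
                node.id = f"n{k}"
                k += 1

    def node_by_id(self, node_id: str) -> Node:
        for node in self.postorder():
            if node.id == node_id:
                return node
        raise KeyError(f"no node with id {node_id!r}")

    def clade_tips(self, node: Node) -> frozenset[str]:
        return frozenset(
            n.label for n in _subtree_postorder(node) if n.is_tip)

    def mrca(self, tip_labels: Iterable[str]) -> Node:
        wanted = set(tip_labels)
        missing = wanted - set(self.tip_labels())
        if missing:
            raise KeyError(f"tips not in tree: {sorted(missing)}")
        node_sets: dict[int, set[str]] = {}
        for node in self.postorder():
            if node.is_tip:
                s = {node.label}
            else:
                s = set().union(*(node_sets[id(c)] for c in node.children))
            node_sets[id(node)] = s
            if wanted <= s:
                return node
        return self.root

    def find_monophyletic(self, tip_labels: Iterable[str]) -> Node:
        """MRCA of the tips, required to contain exactly those tips."""
        wanted = set(tip_labels)
        node = self.mrca(wanted)
        have = self.clade_tips(node)
        extra = have - wanted
        if extra:
            raise ValueError(
                f"tip set is not monophyletic; clade also contains "
                f"{sorted(extra)}"
            )
        return node

    # ------------------------------------------------------------------
    # manipulation
    # ------------------------------------------------------------------
    def copy(self) -> "PhyloTree":
        def clone(node: Node) -> Node:
            c = Node(node.label, node.length)
            c.support = node.support
            c.annotations = dict(node.annotations)
            c.id = node.id
            for ch in node.children:
                c.add_child(clone(ch))
            return c

        return PhyloTree(clone(self.root), rooted=self.rooted)

    def root_with_outgroup(self, outgroup_tips: Iterable[str]) -> "PhyloTree":
        """Reroot so the given tips form one side of the basal split.

        Goes through dendropy's rerooting machinery on the unrooted
        topology, then marks the result as rooted.
        """
        out = set(outgroup_tips)
        missing = out - set(self.tip_labels())
        if missing:
            raise KeyError(f"outgroup tips not in tree: {sorted(missing)}")
        dt = dendropy.Tree.get(data=self.to_newick(), schema="newick",
                               preserve_underscores=True)
        dt.is_rooted = True  # treat current seed as root for MRCA queries
        taxa = [t for t in dt.taxon_namespace if t.label in out]
        if len(taxa) == 1:
            edge = dt.find_node_with_taxon_label(taxa[0].label).edge
        else:
            mrca = dt.mrca(taxa=taxa)
            if mrca is dt.seed_node:
                # outgroup spans the current root; reroot on complement
                comp = [t for t in dt.taxon_namespace if t.label not in out]
                mrca = dt.mrca(taxa=comp)
            edge = mrca.edge
        dt.reroot_at_edge(edge, update_bipartitions=False)
        newick = dt.as_string(schema="newick", suppress_rooting=True,
                              unquoted_underscores=True)
        tree = read_newick_string(newick)
        tree.rooted = True
        return tree

    # ------------------------------------------------------------------
    # serialization
    # ------------------------------------------------------------------
    def to_newick(self, annotations: bool = False,
                  branch_lengths: bool = True) -> str:
        def fmt(node: Node) -> str:
            if node.is_tip:
                s = _quote_label(node.label)
            else:
                s = "(" + ",".join(fmt(c) for c in node.children) + ")"
                if node.label:
                    s += _quote_label(node.label)
            if annotations:
                pairs = {}
                if node.support is not None:
                    pairs["support"] = _fmt_num(node.support)
                pairs.update(node.annotations)
                if pairs:
                    s += "[&" + ",".join(f"{k}={v}" for k, v in pairs.items()) + "]"
            if branch_lengths and node.length is not None:
                s += f":{_fmt_num(node.length)}"
            return s

        return fmt(self.root) + ";"

    def splits(self) -> set[frozenset[str]]:
        """Non-trivial bipartitions, each as the tip set of one side chosen
        canonically (the side not containing the alphabetically first tip)."""
        all_tips = frozenset(self.tip_labels())
        anchor = min(all_tips)
        out = set()
        for node in self.postorder():
            if node.is_tip or node is self.root:
                continue
            clade = self.clade_tips(node)
            if len(clade) <= 1 or len(clade) >= len(all_tips) - 1:
                continue
            side = all_tips - clade if anchor in clade else clade
            out.add(side)
        return out

    def clades(self) -> set[frozenset[str]]:
        """Tip sets of all internal nodes except the root (rooted view)."""
        return {self.clade_tips(n) for n in self.internal_nodes()
                if n is not self.root}


def _subtree_postorder(node: Node) -> Iterator[Node]:
    stack, out = [node], []
    while stack:
        n = stack.pop()
        out.append(n)
        stack.extend(n.children)
    return reversed(out)


def _quote_label(label: str) -> str:
    if any(c in label for c in " ()[]:;,'"):
        return "'" + label.replace("'", "''") + "'"
    return label


def _fmt_num(x: float) -> str:
    if float(x) == int(x):
        return str(int(x))
    return repr(float(x))


# ----------------------------------------------------------------------
# Newick I/O (parse via dendropy, serialize via PhyloTree.to_newick)
# ----------------------------------------------------------------------

def _from_dendropy(dt: dendropy.Tree) -> PhyloTree:
    def convert(dnode) -> Node:
        label = None
        if dnode.taxon is not None:
            label = dnode.taxon.label
        elif dnode.is_leaf() and dnode.label:
            label = dnode.label
        node = Node(label=label, length=dnode.edge.length)
        if not dnode.is_leaf() and dnode.label:
            node.label = dnode.label
        for ann in dnode.annotations:
            if ann.name == "support":
                node.support = float(ann.value)
            else:
                node.annotations[ann.name] = str(ann.value)
        # bare internal labels that look numeric are bootstrap supports
        if (not dnode.is_leaf() and node.label
                and node.support is None):
            try:
                node.support = float(node.label)
                node.label = None
            except ValueError:
                pass
        for child in dnode.child_nodes():
            node.add_child(convert(child))
        return node

    return PhyloTree(convert(dt.seed_node))


def read_newick_string(text: str) -> PhyloTree:
    try:
        dt = dendropy.Tree.get(
            data=text, schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
            extract_comment_metadata=True,
        )
    except Exception as exc:  # dendropy error classes vary by failure mode
        raise NewickParseError(f"malformed Newick: {exc}") from exc
    return _from_dendropy(dt)


def read_newick(path) -> PhyloTree:
    with open(path) as fh:
        text = fh.read()
    if not text.strip():
        raise NewickParseError(f"{path}: empty Newick file")
    return read_newick_string(text)


def write_newick(tree: PhyloTree, path, annotations: bool = True,
                 branch_lengths: bool = True) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick(annotations=annotations,
                                branch_lengths=branch_lengths) + "\n")


# ----------------------------------------------------------------------
# tree comparison
# ----------------------------------------------------------------------

def robinson_foulds(a: PhyloTree, b: PhyloTree) -> int:
    """Unrooted symmetric-difference (RF) distance."""
    if set(a.tip_labels()) != set(b.tip_labels()):
        raise ValueError("trees have different tip sets")
    sa, sb = a.splits(), b.splits()
    return len(sa ^ sb)
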