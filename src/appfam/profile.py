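"""Synapomorphy frequency profiles and per-domain conservation tables.

Turns a synapomorphy table into the statistics used to read domain
conservation off a gene-family tree: per-column percentages, binned
histograms (default 5-residue bins), and per-domain percentage tables for
the whole tree and for named major branches (clades).

Two denominator conventions exist and both are supported:

* ``scope="whole"`` — every percentage is relative to the total number of
  synapomorphies on the whole tree (so values for one branch row sum, over
  all domains plus the implicit inter-domain remainder, to that branch's
  share of the tree total).
* ``scope="branch"`` — percentages are relative to the synapomorphy count
  within each branch (each branch column sums to 100 over the full domain
  partition).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .parsimony import SynapomorphyTable
from .trees import PhyloTree
from .types import AlignedMatrix, DomainMap

INTER_DOMAIN = "inter-domain"


@dataclass
class FrequencyProfile:
    counts: np.ndarray        # per-column synapomorphy counts
    total: int
    percentages: np.ndarray   # 100 * count / total (all-zero if total == 0)
    bin_width: int | None = None
    bin_edges: np.ndarray | None = None     # (n_bins, 2) column windows
    binned_percentages: np.ndarray | None = None

    @property
    def empty(self) -> bool:
        return self.total == 0

    @property
    def n_columns(self) -> int:
        return len(self.counts)


def column_frequencies(table: SynapomorphyTable,
                       n_columns: int) -> FrequencyProfile:
    """Per-column synapomorphy counts scaled to percentages of the total."""
    counts = np.zeros(n_columns, dtype=np.int64)
    for e in table.entries:
        if not 0 <= e.column < n_columns:
            raise ValueError(
                f"entry column {e.column} outside 0..{n_columns - 1}")
        counts[e.column] += 1
    total = int(counts.sum())
    if total > 0:
        pct = 100.0 * counts / total
    else:
        pct = np.zeros(n_columns)
    return FrequencyProfile(counts=counts, total=total, percentages=pct)


def bin_histogram(profile: FrequencyProfile,
                  bin_width: int = 5) -> FrequencyProfile:
    """Sum column percentages into fixed-width bins anchored at column 0.

    The final bin may be partial.  Binning conserves total mass exactly.
    """
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    n = profile.n_columns
    edges = [(lo, min(lo + bin_width, n)) for lo in range(0, n, bin_width)]
    binned = np.array([profile.percentages[lo:hi].sum() for lo, hi in edges])
    return FrequencyProfile(
        counts=profile.counts, total=profile.total,
        percentages=profile.percentages, bin_width=bin_width,
        bin_edges=np.array(edges), binned_percentages=binned)


def histogram_frame(profile: FrequencyProfile) -> pd.DataFrame:
    if profile.binned_percentages is None:
        raise ValueError("profile is not binned; call bin_histogram first")
    return pd.DataFrame({
        "bin_start_1based": profile.bin_edges[:, 0] + 1,
        "bin_end_1based": profile.bin_edges[:, 1],
        "percent": profile.binned_percentages,
    })


# ----------------------------------------------------------------------
# branch stratification
# ----------------------------------------------------------------------

def clade_node_ids(tree: PhyloTree, clade_tips, *,
                   include_stem: bool = True,
                   internal_only: bool = True) -> set[str]:
    """Ids of nodes inside the named clade.

    ``include_stem`` keeps the clade's own MRCA node (the node whose
    entering branch is the clade's stem); synapomorphies on the stem are
    what diagnose the clade, so it defaults to True.
    """
    node = tree.find_monophyletic(clade_tips)
    ids: set[str] = set()
    stack = [node]
    while stack:
        n = stack.pop()
        if not internal_only or not n.is_tip:
            ids.add(n.id)
        stack.extend(n.children)
    if not include_stem:
        ids.discard(node.id)
    return ids


def branch_stratify(table: SynapomorphyTable, tree: PhyloTree, clade_tips,
                    include_stem: bool = True) -> SynapomorphyTable:
    """Restrict a synapomorphy table to nodes within one monophyletic
    clade (stem node included by default)."""
    ids = clade_node_ids(tree, clade_tips, include_stem=include_stem)
    return table.restrict_nodes(ids)


# ----------------------------------------------------------------------
# per-domain tables
# ----------------------------------------------------------------------

def domain_column_sets(domain_map: DomainMap,
                       matrix: AlignedMatrix) -> dict[str, set[int]]:
    """Alignment columns of each domain (projected through the reference
    row), plus the implicit inter-domain remainder."""
    out: dict[str, set[int]] = {}
    covered: set[int] = set()
    for dom in domain_map:
        c0, c1 = matrix.columns_of_reference_interval(
            domain_map.reference_id, dom.start, dom.end)
        cols = set(range(c0, c1))
        out[dom.name] = cols
        covered |= cols
    out[INTER_DOMAIN] = set(range(matrix.n_cols)) - covered
    return out


@dataclass
class DomainFrequencyTable:
    frame: pd.DataFrame       # rows = domains (+ inter-domain), cols = scopes
    scope: str                # "whole" | "branch"
    totals: dict[str, int]    # per column: synapomorphy count in that scope

    def write_tsv(self, path) -> None:
        self.frame.round(2).to_csv(path, sep="\t", index_label="domain")


def domain_frequencies(table: SynapomorphyTable, domain_map: DomainMap,
                       matrix: AlignedMatrix, tree: PhyloTree,
                       branches: dict[str, list[str]] | None = None,
                       scope: str = "whole") -> DomainFrequencyTable:
    """Per-domain synapomorphy percentages, whole-tree and per branch.

    ``branches`` maps branch names to monophyletic tip sets (the major
    clades of the family).  With ``scope="whole"`` every cell is a
    percentage of the whole-tree synapomorphy total; with
    ``scope="branch"`` each branch column is a percentage of that branch's
    own total.  Columns belonging to two overlapping domains (βA4 within
    E3) are counted once per domain, so such rows are reported separately
    and only disjoint domains are additive.
    """
    if scope not in ("whole", "branch"):
        raise ValueError(f"unknown scope {scope!r}")
    branches = branches or {}
    colsets = domain_column_sets(domain_map, matrix)
    whole_total = table.total

    scopes: dict[str, SynapomorphyTable] = {"whole tree": table}
    for name, tips in branches.items():
        scopes[name] = branch_stratify(table, tree, tips)

    data: dict[str, list[float]] = {}
    totals: dict[str, int] = {}
    domains = list(colsets)
    for scope_name, sub in scopes.items():
        denom = whole_total if scope == "whole" else sub.total
        totals[scope_name] = sub.total
        col = []
        for dom in domains:
            hits = sum(1 for e in sub.entries if e.column in colsets[dom])
            col.append(100.0 * hits / denom if denom else 0.0)
        data[scope_name] = col
    frame = pd.DataFrame(data, index=domains)
    if scope == "branch":
        frame = frame.drop(columns=["whole tree"], errors="ignore") \
            if branches else frame
    return DomainFrequencyTable(frame=frame, scope=scope, totals=totals)
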