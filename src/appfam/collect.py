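"""Iterative homolog collection over a local sequence database.

Reproduces the closure logic of an iterative stringent similarity search:
start from seed sequences, add every database subject whose best hit from
any current member passes the E-value threshold, and repeat until a fixed
point.  The search backend is pluggable; the built-in backend is exact
Smith–Waterman local alignment (affine gaps, BLOSUM matrix) with
Karlin–Altschul E-values, standing in for the blastp role.

"E-value = 0.0" stringency is interpreted as E <= a configurable epsilon
(default 1e-180) since a literal floating zero is representation-dependent.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from Bio import Align
from Bio.Align import substitution_matrices

from .types import SequenceRecord

log = logging.getLogger(__name__)

#: default stand-in for a printed E-value of exactly 0.0
EVALUE_EPSILON = 1e-180

# Karlin-Altschul parameters for BLOSUM62 with affine 11/1 gaps (ungapped
# approximations; the absolute scale matters less than monotonicity here).
DEFAULT_K = 0.041
DEFAULT_LAMBDA = 0.267


@dataclass(frozen=True)
class SearchHit:
    query_id: str
    subject_id: str
    raw_score: float
    bit_score: float
    evalue: float
    query_span: tuple[int, int]  # 0-based half-open
    subject_span: tuple[int, int]

    def __post_init__(self):
        if self.evalue < 0:
            raise ValueError("E-value must be >= 0")
        if not math.isfinite(self.bit_score):
            raise ValueError("bit score must be finite")


def local_align_score(a: str, b: str, matrix_name: str = "BLOSUM62",
                      gap_open: float = -11.0, gap_extend: float = -1.0,
                      ) -> tuple[float, tuple[int, int], tuple[int, int]]:
    """Smith–Waterman local alignment optimum with affine gaps.

    Returns (raw score, span on a, span on b), spans 0-based half-open.
    A score of 0 (nothing aligns positively) yields empty spans.  Residues
    outside the 20-letter alphabet are scored as X.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    mat = substitution_matrices.load(matrix_name)
    aligner.substitution_matrix = mat
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    fold = {c: (c if c in mat.alphabet else "X") for c in set(a) | set(b)}
    a2 = "".join(fold[c] for c in a)
    b2 = "".join(fold[c] for c in b)
    score = aligner.score(a2, b2)
    if score <= 0:
        return 0.0, (0, 0), (0, 0)
    aln = aligner.align(a2, b2)[0]
    blocks_a, blocks_b = aln.aligned
    span_a = (int(blocks_a[0][0]), int(blocks_a[-1][1]))
    span_b = (int(blocks_b[0][0]), int(blocks_b[-1][1]))
    return float(score), span_a, span_b


def evalue_from_score(raw_score: float, m: int, n: int,
                      K: float = DEFAULT_K,
                      lam: float = DEFAULT_LAMBDA) -> float:
    """Karlin–Altschul expectation: E = K * m * n * exp(-lambda * S)."""
    if K <= 0 or lam <= 0:
        raise ValueError("K and lambda must be positive")
    if m < 1 or n < 1:
        raise ValueError("sequence lengths must be >= 1")
    return K * m * n * math.exp(-lam * raw_score)


def bit_score(raw_score: float, K: float = DEFAULT_K,
              lam: float = DEFAULT_LAMBDA) -> float:
    return (lam * raw_score - math.log(K)) / math.log(2.0)


class SmithWatermanBackend:
    """Built-in all-vs-database search backend."""

    def __init__(self, matrix_name: str = "BLOSUM62",
                 gap_open: float = -11.0, gap_extend: float = -1.0,
                 K: float = DEFAULT_K, lam: float = DEFAULT_LAMBDA):
        self.matrix_name = matrix_name
        self.gap_open = gap_open
        self.gap_extend = gap_extend
        self.K = K
        self.lam = lam

    def search(self, query: SequenceRecord,
               subjects) -> list[SearchHit]:
        hits = []
        for subj in subjects:
            score, qs, ss = local_align_score(
                query.residues, subj.residues, self.matrix_name,
                self.gap_open, self.gap_extend)
            hits.append(SearchHit(
                query_id=query.id, subject_id=subj.id, raw_score=score,
                bit_score=bit_score(score, self.K, self.lam),
                evalue=evalue_from_score(score, query.length, subj.length,
                                         self.K, self.lam),
                query_span=qs, subject_span=ss))
        hits.sort(key=lambda h: (h.evalue, h.subject_id))
        return hits


class TabularBackend:
    """Search backend serving precomputed hits.

    ``hits`` maps a query id to (subject_id, evalue) pairs — handy for
    closure experiments on synthetic hit graphs and for replaying an
    externally produced tabular search report.
    """

    def __init__(self, hits: dict[str, list[tuple[str, float]]]):
        self.hits = hits

    def search(self, query: SequenceRecord, subjects) -> list[SearchHit]:
        known = {s.id: s for s in subjects}
        out = []
        for subject_id, evalue in self.hits.get(query.id, ()):
            if subject_id not in known:
                continue
            out.append(SearchHit(
                query_id=query.id, subject_id=subject_id, raw_score=0.0,
                bit_score=0.0, evalue=evalue,
                query_span=(0, 0), subject_span=(0, 0)))
        out.sort(key=lambda h: (h.evalue, h.subject_id))
        return out


class SequenceDatabase:
    """A local id → record store with a search backend attached."""

    def __init__(self, records, backend=None):
        self.records: dict[str, SequenceRecord] = {}
        for r in records:
            if r.id in self.records:
                raise ValueError(f"duplicate id {r.id!r} in database")
            self.records[r.id] = r
        self.backend = backend or SmithWatermanBackend()

    def __len__(self):
        return len(self.records)

    def __contains__(self, seq_id):
        return seq_id in self.records

    def get(self, seq_id: str) -> SequenceRecord:
        return self.records[seq_id]

    def search(self, query_id: str) -> list[SearchHit]:
        query = self.records[query_id]
        return self.backend.search(query, self.records.values())


@dataclass
class ClosureResult:
    members: list[SequenceRecord]
    rounds: list[list[str]]  # new ids added per round (round 0 = seeds)
    hits: list[SearchHit]    # all passing non-self hits encountered

    @property
    def member_ids(self) -> set[str]:
        return {r.id for r in self.members}

    @property
    def n_iterations(self) -> int:
        return len(self.rounds) - 1


def iterative_closure(seed_ids, database: SequenceDatabase,
                      evalue_threshold: float = EVALUE_EPSILON,
                      ) -> ClosureResult:
    """Least fixed point of the iterative similarity search.

    Each round queries every newly added member against the whole database;
    a subject joins if any member's hit to it has E <= threshold.  Self
    hits are ignored.  The result is independent of seed processing order
    (union semantics); termination is guaranteed by the visited set.
    """
    seeds = sorted(set(seed_ids))
    if not seeds:
        raise ValueError("seed set must be non-empty")
    for s in seeds:
        if s not in database:
            raise KeyError(f"seed {s!r} not present in database")
    members: set[str] = set(seeds)
    frontier = list(seeds)
    rounds: list[list[str]] = [list(seeds)]
    kept_hits: list[SearchHit] = []
    while frontier:
        added: set[str] = set()
        for qid in frontier:
            for hit in database.search(qid):
                if hit.subject_id == qid:
                    continue
                if hit.evalue <= evalue_threshold:
                    kept_hits.append(hit)
                    if hit.subject_id not in members:
                        added.add(hit.subject_id)
        members |= added
        frontier = sorted(added)
        if frontier:
            rounds.append(list(frontier))
        log.info("closure round %d: %d new member(s)",
                 len(rounds) - 1, len(added))
    ordered = sorted(members)
    return ClosureResult(
        members=[database.get(i) for i in ordered],
        rounds=rounds, hits=kept_hits)


def dedupe_longest_per_taxon_gene(records) -> list[SequenceRecord]:
    """Keep exactly the longest record per (taxon, gene label) group.

    This mirrors keeping the one longest representative isoform per taxon
    (e.g. the 770-residue APP isoform over the 695/751 splice forms).
    Ties break to the lexicographically smallest id.  Records labelled
    ``other`` group by taxon alone, with a logged warning.
    """
    groups: dict[tuple[str, str], list[SequenceRecord]] = {}
    for r in records:
        if r.gene_label == "other":
            log.warning("record %s has gene label 'other'; grouping by "
                        "taxon only", r.id)
            key = (r.taxon, "other")
        else:
            key = (r.taxon, r.gene_label)
        groups.setdefault(key, []).append(r)
    kept = []
    for group in groups.values():
        best = min(group, key=lambda r: (-r.length, r.id))
        kept.append(best)
    kept.sort(key=lambda r: r.id)
    return kept


def write_hit_table(hits, path) -> None:
    """Tabular hit report (in the spirit of tabular blastp output)."""
    with open(path, "w") as fh:
        fh.write("query\tsubject\traw_score\tbit_score\tevalue\t"
                 "q_start\tq_end\ts_start\ts_end\n")
        for h in hits:
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{h.raw_score:g}\t"
                f"{h.bit_score:.2f}\t{h.evalue:.3g}\t"
                f"{h.query_span[0] + 1}\t{h.query_span[1]}\t"
                f"{h.subject_span[0] + 1}\t{h.subject_span[1]}\n")
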