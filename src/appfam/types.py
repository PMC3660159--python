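"""Core domain types shared by every analysis stage.

The analyses operate on three kinds of objects: individual protein (or
nucleotide) sequences with gene-family metadata, gapped character matrices
produced by multiple sequence alignment, and named domain intervals on a
reference sequence (signal peptide, E1, E2, E3, the amyloid-forming βA4
region, ...).  Coordinates are 0-based half-open everywhere in memory;
on-disk tables and printed reports use 1-based inclusive coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

log = logging.getLogger(__name__)

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
NT_ALPHABET = "ACGT"
GAP = "-"
MISSING = "X"

#: gene-family labels recognised by the FASTA header dialect
KNOWN_GENE_LABELS = ("APP", "APLP1", "APLP2", "APL-1", "APPL-1", "other")

# Ambiguity codes folded into X on ingest (B=N/D, Z=Q/E, J=I/L, U, O).
_AA_FOLD_TO_X = str.maketrans({c: "X" for c in "BZJUO"})


class DomainError(ValueError):
    """Invalid domain-interval definition."""


@dataclass(frozen=True)
class SequenceRecord:
    """One sequence with its taxon and gene-family assignment.

    ``residues`` is the degapped sequence; stop symbols ``*`` are stripped
    and rare ambiguity codes are folded into ``X`` on construction.
    """

    id: str
    taxon: str
    residues: str
    gene_label: str = "other"
    molecule: str = "aa"  # "aa" | "nt"

    def __post_init__(self):
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        res = self.residues.upper().replace("*", "").replace(".", "")
        if self.molecule == "aa":
            res = res.translate(_AA_FOLD_TO_X)
            alphabet = set(AA_ALPHABET + MISSING)
        elif self.molecule == "nt":
            res = res.replace("N", "X")
            alphabet = set(NT_ALPHABET + MISSING)
        else:
            raise ValueError(f"unknown molecule type {self.molecule!r}")
        if not res:
            raise ValueError(f"record {self.id!r} has an empty sequence")
        bad = set(res) - alphabet
        if bad:
            raise ValueError(
                f"record {self.id!r} contains symbols outside the "
                f"{self.molecule} alphabet: {sorted(bad)}"
            )
        object.__setattr__(self, "residues", res)

    @property
    def length(self) -> int:
        return len(self.residues)

    def with_residues(self, residues: str) -> "SequenceRecord":
        return replace(self, residues=residues)


@dataclass(frozen=True)
class MappedInterval:
    """A reference interval projected onto one row of an alignment."""

    row_id: str
    start: int
    end: int
    subsequence: str

    @property
    def empty(self) -> bool:
        return self.start == self.end


class AlignedMatrix:
    """Taxa × columns character matrix with gap characters ``-``.

    Degapping any row recovers the source sequence; ``.`` gaps are
    normalised to ``-`` on construction.
    """

    def __init__(self, row_ids, rows, alphabet: str = "aa"):
        row_ids = list(row_ids)
        rows = [str(r).upper().replace(".", GAP) for r in rows]
        if len(row_ids) != len(rows):
            raise ValueError("row_ids and rows differ in length")
        if len(set(row_ids)) != len(row_ids):
            raise ValueError("duplicate row ids in alignment")
        if rows:
            ncol = len(rows[0])
            for rid, r in zip(row_ids, rows):
                if len(r) != ncol:
                    raise ValueError(
                        f"row {rid!r} has length {len(r)}, expected {ncol}"
                    )
        self.row_ids = row_ids
        self.rows = rows
        self.alphabet = alphabet
        self._index = {rid: i for i, rid in enumerate(row_ids)}

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, row_id: str) -> str:
        try:
            return self.rows[self._index[row_id]]
        except KeyError:
            raise KeyError(f"row {row_id!r} not present in alignment") from None

    def degapped(self, row_id: str) -> str:
        return self.row(row_id).replace(GAP, "")

    def column(self, j: int) -> str:
        if not 0 <= j < self.n_cols:
            raise IndexError(f"column {j} out of range 0..{self.n_cols - 1}")
        return "".join(r[j] for r in self.rows)

    def subset(self, row_ids) -> "AlignedMatrix":
        return AlignedMatrix(list(row_ids), [self.row(r) for r in row_ids],
                             alphabet=self.alphabet)

    # ------------------------------------------------------------------
    # coordinate mapping
    # ------------------------------------------------------------------
    def columns_of_reference_interval(self, reference_id: str,
                                      start: int, end: int) -> tuple[int, int]:
        """Alignment-column window spanned by reference residues [start, end).

        The window runs from the column of residue ``start`` to one past the
        column of residue ``end - 1``, so insertions relative to the
        reference that fall inside the interval are included.
        """
        ref = self.row(reference_id)
        if not 0 <= start < end:
            raise ValueError(f"bad interval ({start}, {end})")
        residue_cols = [j for j, c in enumerate(ref) if c != GAP]
        if end > len(residue_cols):
            raise ValueError(
                f"interval ({start}, {end}) exceeds degapped length "
                f"{len(residue_cols)} of reference {reference_id!r}"
            )
        return residue_cols[start], residue_cols[end - 1] + 1

    def map_reference_interval(self, reference_id: str, start: int,
                               end: int) -> dict[str, MappedInterval]:
        """Project a reference residue interval onto every row.

        Returns, per row, the 0-based half-open residue interval of that
        row's own (degapped) sequence falling under the reference window,
        together with the extracted subsequence.  Rows entirely gapped under
        the window yield an empty interval.
        """
        c0, c1 = self.columns_of_reference_interval(reference_id, start, end)
        out: dict[str, MappedInterval] = {}
        for rid, row in zip(self.row_ids, self.rows):
            before = sum(1 for c in row[:c0] if c != GAP)
            sub = row[c0:c1].replace(GAP, "")
            out[rid] = MappedInterval(rid, before, before + len(sub), sub)
        return out


@dataclass(frozen=True)
class DomainInterval:
    name: str
    start: int  # 0-based half-open on the reference's degapped sequence
    end: int
    allow_overlap: bool = False

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise DomainError(
                f"domain {self.name!r}: bad interval ({self.start}, {self.end})"
            )


class DomainMap:
    """Named intervals on a reference sequence.

    Intervals may not overlap unless flagged; the βA4 region overlapping the
    E3 C-terminal region is the motivating exception and both intervals are
    kept explicitly — per-domain statistics count a column once per domain
    it belongs to.
    """

    def __init__(self, reference_id: str, entries):
        self.reference_id = reference_id
        self.entries: list[DomainInterval] = list(entries)
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            raise DomainError(f"duplicate domain names in {names}")
        for i, a in enumerate(self.entries):
            for b in self.entries[i + 1:]:
                if a.start < b.end and b.start < a.end:
                    if not (a.allow_overlap or b.allow_overlap):
                        raise DomainError(
                            f"domains {a.name!r} and {b.name!r} overlap; "
                            "flag one with allow_overlap"
                        )

    def __iter__(self):
        return iter(self.entries)

    def __len__(self):
        return len(self.entries)

    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    def get(self, name: str) -> DomainInterval:
        for e in self.entries:
            if e.name == name:
                return e
        raise KeyError(f"no domain named {name!r}")

    def validate_against(self, reference_length: int) -> None:
        for e in self.entries:
            if e.end > reference_length:
                raise DomainError(
                    f"domain {e.name!r} ends at {e.end} beyond reference "
                    f"length {reference_length}"
                )
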