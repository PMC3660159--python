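"""File formats: FASTA with metadata headers, alignment FASTA, domain-map TSV.

FASTA header dialect
--------------------
``>id|taxon|gene_label`` — e.g. ``>NP_000475|Homo sapiens|APP``.  The taxon
and gene label ride along in the header because the analyses group and
deduplicate records by (taxon, gene).  A header with fewer fields is
tolerated: a missing gene label becomes ``other`` (with a logged warning),
a missing taxon becomes ``unknown``.  More than three fields is an error.

Domain maps are TSV: ``name<TAB>start<TAB>end[<TAB>overlap]`` with 1-based
inclusive coordinates on disk (0-based half-open in memory), preceded by a
``#reference=<row id>`` line naming the reference sequence.
"""

from __future__ import annotations

import logging
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from .types import (GAP, AlignedMatrix, DomainInterval, DomainMap,
                    SequenceRecord)

log = logging.getLogger(__name__)


class FastaParseError(ValueError):
    pass


def _parse_header(header: str, line_no: int) -> tuple[str, str, str]:
    fields = [f.strip() for f in header.split("|")]
    if len(fields) > 3:
        raise FastaParseError(
            f"line {line_no}: header {header!r} has {len(fields)} fields; "
            "expected id|taxon|gene_label"
        )
    if not fields[0]:
        raise FastaParseError(f"line {line_no}: header with empty id")
    seq_id = fields[0]
    taxon = fields[1] if len(fields) > 1 and fields[1] else "unknown"
    if len(fields) > 2 and fields[2]:
        gene = fields[2]
    else:
        gene = "other"
        log.warning("header %r (line %d) lacks a gene label; using 'other'",
                    header, line_no)
    return seq_id, taxon, gene


def _header_lines(path) -> list[int]:
    out = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if line.startswith(">"):
                out.append(i)
    return out


def read_fasta(path, molecule: str = "aa") -> list[SequenceRecord]:
    """Read sequences with the id|taxon|gene_label header dialect.

    Order is preserved; ``*`` stop symbols are stripped by the record
    constructor.  Raises on an empty file, duplicate ids, or malformed
    headers (naming the offending line).
    """
    lines = _header_lines(path)
    records = []
    seen = set()
    for line_no, bio in zip(lines, SeqIO.parse(str(path), "fasta")):
        seq_id, taxon, gene = _parse_header(bio.description, line_no)
        if seq_id in seen:
            raise FastaParseError(f"line {line_no}: duplicate id {seq_id!r}")
        seen.add(seq_id)
        records.append(SequenceRecord(id=seq_id, taxon=taxon,
                                      residues=str(bio.seq),
                                      gene_label=gene, molecule=molecule))
    if not records:
        raise FastaParseError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path) -> None:
    bios = [
        BioSeqRecord(Seq(r.residues),
                     id=f"{r.id}|{r.taxon}|{r.gene_label}",
                     description="")
        for r in records
    ]
    SeqIO.write(bios, str(path), "fasta")  # wraps at standard line width


# ----------------------------------------------------------------------
# alignment FASTA
# ----------------------------------------------------------------------

def read_alignment(path, alphabet: str = "aa") -> AlignedMatrix:
    """Read a gapped FASTA alignment; row ids are the header id field."""
    row_ids, rows = [], []
    for bio in SeqIO.parse(str(path), "fasta"):
        row_ids.append(bio.description.split("|")[0].strip())
        rows.append(str(bio.seq))
    if not rows:
        raise FastaParseError(f"{path}: no alignment rows found")
    return AlignedMatrix(row_ids, rows, alphabet=alphabet)


def write_alignment(matrix: AlignedMatrix, path,
                    records: dict[str, SequenceRecord] | None = None) -> None:
    """Write a gapped FASTA alignment; if the source records are supplied,
    their full metadata headers are reproduced."""
    bios = []
    for rid in matrix.row_ids:
        if records and rid in records:
            r = records[rid]
            header = f"{r.id}|{r.taxon}|{r.gene_label}"
        else:
            header = rid
        bios.append(BioSeqRecord(Seq(matrix.row(rid)), id=header,
                                 description=""))
    SeqIO.write(bios, str(path), "fasta")


# ----------------------------------------------------------------------
# domain map TSV
# ----------------------------------------------------------------------

def read_domain_map(path, reference_id: str | None = None) -> DomainMap:
    entries = []
    ref = reference_id
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                if line.startswith("#reference="):
                    ref = line.split("=", 1)[1].strip()
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path} line {line_no}: expected name\\tstart\\tend")
            name, start1, end1 = fields[0], int(fields[1]), int(fields[2])
            overlap = len(fields) > 3 and fields[3].strip().lower() in (
                "1", "true", "overlap", "yes")
            entries.append(DomainInterval(name, start1 - 1, end1,
                                          allow_overlap=overlap))
    if ref is None:
        raise ValueError(
            f"{path}: no reference id (expected a '#reference=' line or an "
            "explicit reference_id argument)")
    return DomainMap(ref, entries)


def write_domain_map(dmap: DomainMap, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#reference={dmap.reference_id}\n")
        fh.write("#name\tstart\tend\toverlap  (1-based inclusive)\n")
        for e in dmap:
            flag = "\t1" if e.allow_overlap else ""
            fh.write(f"{e.name}\t{e.start + 1}\t{e.end}{flag}\n")
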