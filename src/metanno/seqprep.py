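"""Input contig validation, cleaning, and length filtering.

Every assembled contig is inspected before annotation: identifiers must be
unique (duplicates reject the whole input), ambiguous nucleotides are
replaced by ``N``, gap (``-``) and pad (``*``) characters are removed, and
contigs shorter than a user-defined minimum length are dropped.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import DegenerateSequenceError, DuplicateIdError, EmptyInputError

#: Default minimum contig length in bp (user-overridable).
DEFAULT_MIN_CONTIG_LEN = 200

_CLEAN_ALPHABET = frozenset("ACGTN")
# '-' and '*' are deleted; every other non-ACGT character (incl. IUPAC
# ambiguity codes and U) becomes N.
_TRANSLATE = {ord(c): None for c in "-*"}


@dataclass
class RawSequenceRecord:
    """A FASTA record as parsed, before any cleaning."""

    id: str
    description: str
    sequence: str


@dataclass
class CleanContig:
    """A validated contig over the {A,C,G,T,N} alphabet."""

    id: str
    sequence: str
    description: str = ""

    @property
    def length(self) -> int:
        return len(self.sequence)


def read_fasta(path: str | Path) -> list[RawSequenceRecord]:
    """Read a (possibly wrapped) multi-record FASTA file.

    The id is the first whitespace-delimited header token; the remainder of
    the header line is kept as the description.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        records.append(RawSequenceRecord(rec.id, desc, str(rec.seq)))
    return records


def validate_ids(records: Sequence[RawSequenceRecord]) -> None:
    """Reject the whole input on any duplicated id or on zero records."""
    if len(records) == 0:
        raise EmptyInputError("input FASTA contains no records")
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise DuplicateIdError(rec.id)
        seen.add(rec.id)


def clean_sequence(seq: str) -> str:
    """Uppercase, drop '-' and '*', and replace non-ACGT characters by N.

    Raises :class:`DegenerateSequenceError` when nothing remains after gap
    and pad removal. Idempotent on its own output.
    """
    out = seq.upper().translate(_TRANSLATE)
    if not out:
        raise DegenerateSequenceError("sequence empty after gap/pad removal")
    return "".join(c if c in "ACGT" else "N" for c in out)


def filter_short(
    contigs: Sequence[CleanContig], min_len: int = DEFAULT_MIN_CONTIG_LEN
) -> list[CleanContig]:
    """Keep contigs with length >= min_len ("shorter than" is strict)."""
    if min_len < 0:
        raise ValueError("min_len must be >= 0")
    return [c for c in contigs if c.length >= min_len]


@dataclass
class PreprocessResult:
    contigs: list[CleanContig]
    report: pd.DataFrame = field(repr=False)

    @property
    def n_removed(self) -> int:
        return int((~self.report["kept"]).sum())


def preprocess(
    records: Sequence[RawSequenceRecord],
    min_len: int = DEFAULT_MIN_CONTIG_LEN,
) -> PreprocessResult:
    """Validate, clean and length-filter raw records.

    Returns the kept contigs (input order preserved) plus a per-record
    report (id, original_length, cleaned_length, kept) that also logs the
    ids of removed sequences.
    """
    validate_ids(records)
    rows = []
    kept: list[CleanContig] = []
    for rec in records:
        cleaned = clean_sequence(rec.sequence)
        keep = len(cleaned) >= min_len
        rows.append(
            {
                "id": rec.id,
                "original_length": len(rec.sequence),
                "cleaned_length": len(cleaned),
                "kept": keep,
            }
        )
        if keep:
            kept.append(CleanContig(rec.id, cleaned, rec.description))
    report = pd.DataFrame(rows, columns=["id", "original_length", "cleaned_length", "kept"])
    return PreprocessResult(kept, report)


def write_fasta(contigs: Iterable[CleanContig], path: str | Path, width: int = 60) -> None:
    """Write contigs as 60-column wrapped FASTA."""
    recs = [
        SeqRecord(Seq(c.sequence), id=c.id, description=c.description)
        for c in contigs
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


def write_report(report: pd.DataFrame, path: str | Path) -> None:
    report.to_csv(path, sep="\t", index=False)
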