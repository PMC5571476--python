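"""FASTA ingestion and machine-readable report emission.

All sequences are normalized on ingest: upper-cased, RNA ``U`` converted to
``T``, and validated against the IUPAC nucleotide alphabet (ambiguity codes
are accepted; they score as mismatches everywhere downstream).  All
user-facing coordinates in reports are 1-based inclusive, matching rCRS
convention.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.SeqRecord import SeqRecord
from Bio.Seq import Seq

#: IUPAC nucleotide alphabet, including ambiguity codes and gap-free only.
IUPAC_NUCLEOTIDES = frozenset("ACGTRYSWKMBDHVN")

#: Unambiguous bases; everything else in IUPAC_NUCLEOTIDES is an ambiguity code.
UNAMBIGUOUS = frozenset("ACGT")

REPORT_FORMATS = ("tsv", "json")


class SequenceError(ValueError):
    """Raised for malformed or non-nucleotide sequence input."""


@dataclass(frozen=True)
class SequenceRecord:
    """A single nucleotide sequence with identifier and description.

    ``bases`` is always upper-case DNA (``U`` already converted to ``T``).
    """

    id: str
    bases: str
    description: str = ""

    def __post_init__(self) -> None:
        normalized = normalize_bases(self.bases, record_id=self.id)
        object.__setattr__(self, "bases", normalized)

    def __len__(self) -> int:
        return len(self.bases)


def normalize_bases(bases: str, record_id: str = "<anonymous>") -> str:
    """Upper-case, convert U->T, and validate against the IUPAC alphabet.

    Idempotent by construction.  Raises :class:`SequenceError` naming the
    record and the first offending character.
    """
    s = bases.upper().replace("U", "T")
    if not s:
        raise SequenceError(f"record {record_id!r}: empty sequence")
    bad = set(s) - IUPAC_NUCLEOTIDES
    if bad:
        ch = sorted(bad)[0]
        raise SequenceError(
            f"record {record_id!r}: non-nucleotide character {ch!r}"
        )
    return s


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a (multi-record) FASTA file into normalized records.

    Arbitrary line wrapping, lower case, and RNA ``U`` are accepted.
    Raises :class:`SequenceError` on an empty file or invalid characters.
    """
    records = [
        SequenceRecord(id=rec.id, bases=str(rec.seq), description=rec.description)
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise SequenceError(f"{path}: no records")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records to FASTA (60-column wrapping)."""
    bio = [
        SeqRecord(Seq(r.bases), id=r.id, description=r.description)
        for r in records
    ]
    SeqIO.write(bio, str(path), "fasta")


def write_report(
    rows: Sequence[dict[str, Any]],
    path: str | Path,
    format: str = "tsv",
    columns: Sequence[str] | None = None,
) -> None:
    """Write result rows as TSV (with header) or JSON (array of objects).

    Rows are plain dicts sharing a schema; coordinates they carry are
    1-based inclusive.  A round-trip through :func:`read_report` reproduces
    the row values.
    """
    if format not in REPORT_FORMATS:
        raise ValueError(f"unknown report format {format!r}; expected one of {REPORT_FORMATS}")
    if columns is None:
        columns = list(rows[0].keys()) if rows else []
    df = pd.DataFrame(list(rows), columns=columns)
    if format == "tsv":
        df.to_csv(path, sep="\t", index=False)
    else:
        Path(path).write_text(json.dumps(df.to_dict(orient="records"), indent=1) + "\n")


def read_report(path: str | Path, format: str = "tsv") -> list[dict[str, Any]]:
    """Read back a report written by :func:`write_report`."""
    if format not in REPORT_FORMATS:
        raise ValueError(f"unknown report format {format!r}; expected one of {REPORT_FORMATS}")
    if format == "tsv":
        df = pd.read_csv(path, sep="\t")
        return df.to_dict(orient="records")
    return json.loads(Path(path).read_text())
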