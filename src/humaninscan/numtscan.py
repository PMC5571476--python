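"""Screening long nuclear sequences for Humanin-like NUMT copies.

NUMTs (nuclear mitochondrial DNA segments) are fragmentary mtDNA copies in
chromosomal DNA; the human genome carries Humanin-like NUMTs essentially
identical to the mitochondrial gene.  Both strands are scanned (the reverse
strand via reverse complement); every window at or above the reporting
identity threshold is kept, overlapping windows are merged down to the
best-identity representative, and each surviving hit is classified with the
standard genetic code — NUMT transcripts are translated cytoplasmically, so
table 1 applies regardless of the mitochondrial origin of the sequence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.Seq import Seq

from .classifier import GeneStatus, PeptideCall, classify_status, load_genetic_code
from .locator import (
    DEFAULT_BAND,
    MatchQuery,
    MatchResult,
    count_matches_all_offsets,
    refine_with_gaps,
)
from .seqio import SequenceRecord


@dataclass(frozen=True)
class NumtHit:
    """One merged Humanin-like window on a contig.

    ``start``/``end`` are 1-based inclusive forward-strand coordinates even
    for minus-strand hits.
    """

    contig_id: str
    start: int
    end: int
    strand: str
    identity: float
    matches: int
    status: GeneStatus
    peptide: str = ""
    notes: str = ""


def _candidate_windows(bases: str, query: str, min_matches: int) -> list[tuple[int, int]]:
    """(0-based offset, match count) of every window scoring >= min_matches."""
    counts = count_matches_all_offsets(bases, query)
    idx = np.nonzero(counts >= min_matches)[0]
    return [(int(i), int(counts[i])) for i in idx]


def _merge(hits: list[NumtHit]) -> list[NumtHit]:
    """Collapse hits whose intervals overlap by >= 1 base, keeping the
    higher-identity one (ties: leftmost, then '+' strand).  Idempotent."""
    ordered = sorted(hits, key=lambda h: (-h.identity, h.start, 0 if h.strand == "+" else 1))
    kept: list[NumtHit] = []
    for h in ordered:
        if all(h.end < k.start or h.start > k.end for k in kept):
            kept.append(h)
    return sorted(kept, key=lambda h: h.start)


def scan_long_sequence(
    contig: SequenceRecord,
    query: MatchQuery | None = None,
    report_threshold: float = 0.60,
    band: int = DEFAULT_BAND,
) -> list[NumtHit]:
    """Report all Humanin-like windows on both strands of a contig.

    Raises ``ValueError`` if the contig is shorter than the query.
    """
    query = query or MatchQuery()
    if not 0 < report_threshold <= 1:
        raise ValueError(f"report threshold must be in (0, 1], got {report_threshold}")
    if len(contig) < query.length:
        raise ValueError(
            f"contig too short: {contig.id!r} has {len(contig)} bases "
            f"< query length {query.length}"
        )
    L = len(contig)
    qlen = query.length
    min_matches = int(np.ceil(report_threshold * qlen))
    code = load_genetic_code(1)

    raw: list[NumtHit] = []
    rc = str(Seq(contig.bases).reverse_complement())
    for strand, bases in (("+", contig.bases), ("-", rc)):
        strand_record = SequenceRecord(id=contig.id, bases=bases)
        for off, matches in _candidate_windows(bases, query.bases, min_matches):
            identity = matches / qlen
            anchor = MatchResult(
                target_id=contig.id,
                start=off + 1,
                end=off + qlen,
                matches=matches,
                identity=identity,
                is_hit=True,
                strand=strand,
            )
            aln = refine_with_gaps(strand_record, query, anchor, band=band)
            call = classify_status(strand_record, anchor, aln, code=code)
            if strand == "+":
                start, end = anchor.start, anchor.end
            else:  # mirror scanned coordinates back to the forward strand
                start, end = L - anchor.end + 1, L - anchor.start + 1
            raw.append(
                NumtHit(
                    contig_id=contig.id,
                    start=start,
                    end=end,
                    strand=strand,
                    identity=identity,
                    matches=matches,
                    status=call.status,
                    peptide=call.peptide,
                    notes=call.notes,
                )
            )
    return _merge(raw)
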