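"""Functional-gene versus pseudogene calls for located Humanin copies.

A pseudogene is recognized by one of three marks: loss of the start codon,
a premature stop codon, or a frameshifting insertion/deletion.  A copy that
translates cleanly through about 24 codons is called functional, allowing a
small length change from in-frame indels (the Tuatara carries a functional
peptide one residue longer than human).

The choice of genetic code matters: the standard code (table 1) reads the
rCRS region as a 24-residue peptide ending ...KRRA, whereas the vertebrate
mitochondrial code (table 2) would stop at the AGG arginine codon 22.  The
24-residue peptide implies cytoplasmic (standard-code) translation, so
table 1 is the default; table 2 is available for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Mapping

from Bio.Data import CodonTable

from .locator import GappedAlignment, MatchResult
from .seqio import SequenceRecord, UNAMBIGUOUS

DEFAULT_TABLE_ID = 1
DEFAULT_PREMATURE_CUTOFF = 20
DEFAULT_MAX_EXTRA_RESIDUES = 3
#: bases searched for a stop beyond the aligned window
STOP_SEARCH_EXTENSION = 9

#: accepted start codons; the lenient set adds the mitochondrial alternatives
STRICT_STARTS = frozenset({"ATG"})
LENIENT_STARTS = frozenset({"ATG", "ATA", "ATT"})

STOP_SYMBOL = "*"


class GeneStatus(str, Enum):
    FUNCTIONAL = "FUNCTIONAL"
    PSEUDO_NO_START = "PSEUDO_NO_START"
    PSEUDO_PREMATURE_STOP = "PSEUDO_PREMATURE_STOP"
    PSEUDO_FRAMESHIFT = "PSEUDO_FRAMESHIFT"
    AMBIGUOUS = "AMBIGUOUS"


@dataclass(frozen=True)
class GeneticCode:
    """A complete 64-codon translation table.

    table 1 = standard code; table 2 = vertebrate mitochondrial code
    (AGA/AGG become stops, ATA reads Met, TGA reads Trp).
    """

    table_id: int
    codon_map: Mapping[str, str]  # codon -> amino acid letter or '*'

    def is_stop(self, codon: str) -> bool:
        # codons containing ambiguity codes never count as stops
        return self.codon_map.get(codon) == STOP_SYMBOL


@dataclass(frozen=True)
class PeptideCall:
    """Translation outcome and, when classified, the gene status verdict."""

    peptide: str
    stop_codon_index: int | None  # 1-based codon index of the first stop
    has_start: bool = False
    net_indel: int = 0
    status: GeneStatus | None = None
    notes: str = ""


def load_genetic_code(table_id: int = DEFAULT_TABLE_ID) -> GeneticCode:
    """Load translation table 1 (standard) or 2 (vertebrate mitochondrial)."""
    if table_id not in (1, 2):
        raise ValueError(f"unsupported genetic code table {table_id}; use 1 or 2")
    table = CodonTable.unambiguous_dna_by_id[table_id]
    codon_map = dict(table.forward_table)
    for stop in table.stop_codons:
        codon_map[stop] = STOP_SYMBOL
    return GeneticCode(table_id=table_id, codon_map=codon_map)


def translate(orf: str, code: GeneticCode | None = None) -> PeptideCall:
    """Translate from base 1 until the first stop or the end of sequence.

    A trailing 1- or 2-base remainder is an incomplete stop (the Humanin
    stop is a single thymine completed by polyadenylation): translation
    terminates there without adding a residue, and the stop index points at
    that partial codon.  Codons containing ambiguity codes emit ``X`` (and
    never count as stops); this is flagged in ``notes``.
    """
    code = code or load_genetic_code()
    if len(orf) < 3:
        raise ValueError(f"ORF too short to translate: {len(orf)} bases")
    residues: list[str] = []
    notes: list[str] = []
    stop_index: int | None = None
    n_full = len(orf) // 3
    for k in range(n_full):
        codon = orf[3 * k : 3 * k + 3]
        if code.is_stop(codon):
            stop_index = k + 1
            break
        aa = code.codon_map.get(codon)
        if aa is None:  # ambiguity code inside the codon
            residues.append("X")
            notes.append(f"ambiguous codon {codon} at index {k + 1}")
        else:
            residues.append(aa)
    else:
        remainder = len(orf) - 3 * n_full
        if remainder:
            stop_index = n_full + 1
            notes.append(f"incomplete terminal stop ({orf[3 * n_full:]})")
    return PeptideCall(
        peptide="".join(residues),
        stop_codon_index=stop_index,
        notes="; ".join(notes),
    )


def classify_status(
    target: SequenceRecord,
    anchor: MatchResult,
    alignment: GappedAlignment,
    code: GeneticCode | None = None,
    premature_cutoff: int = DEFAULT_PREMATURE_CUTOFF,
    max_extra_residues: int = DEFAULT_MAX_EXTRA_RESIDUES,
    lenient_start: bool = False,
) -> PeptideCall:
    """Apply the three pseudogene criteria, in precedence order.

    1. a frameshifting net indel (``net_indel % 3 != 0``) pseudogenizes
       outright, since it corrupts all downstream codon evidence;
    2. otherwise a missing start codon (ATG; optionally ATA/ATT with
       ``lenient_start``) pseudogenizes;
    3. otherwise translation from the aligned start decides: a stop before
       ``premature_cutoff`` codons is premature; a stop between the cutoff
       and 24 codons is AMBIGUOUS; a stop (or incomplete terminal stop) at
       roughly full length — 24 plus the in-frame indel shift, give or take
       ``max_extra_residues`` — is FUNCTIONAL; no stop within the window
       plus 9 bases is AMBIGUOUS ("no stop located").
    """
    code = code or load_genetic_code()
    if not anchor.is_hit:
        raise ValueError("classification requires a located hit")
    if alignment.target_start < 1 or alignment.target_start > len(target):
        raise ValueError("alignment does not cover the anchor window")

    n_query = sum(1 for c in alignment.aligned_query if c != "-")
    if n_query == 0:
        raise ValueError("alignment contains no query bases")

    net_indel = alignment.net_indel
    if net_indel % 3 != 0:
        return PeptideCall(
            peptide="",
            stop_codon_index=None,
            has_start=False,
            net_indel=net_indel,
            status=GeneStatus.PSEUDO_FRAMESHIFT,
            notes=f"net indel {net_indel:+d} shifts the reading frame",
        )

    orf_start = alignment.target_start  # 1-based target coordinate of query base 1
    n_target = sum(1 for c in alignment.aligned_target if c != "-")
    orf_end = min(orf_start + n_target - 1 + STOP_SEARCH_EXTENSION, len(target))
    orf = target.bases[orf_start - 1 : orf_end]
    if orf_end < len(target):
        # a partial trailing codon is an incomplete terminal stop only at the
        # true end of the target, not at a mid-sequence window boundary
        orf = orf[: 3 * (len(orf) // 3)]

    starts = LENIENT_STARTS if lenient_start else STRICT_STARTS
    start_codon = orf[:3]
    if start_codon not in starts:
        return PeptideCall(
            peptide="",
            stop_codon_index=None,
            has_start=False,
            net_indel=net_indel,
            status=GeneStatus.PSEUDO_NO_START,
            notes=f"no start codon (found {start_codon})",
        )

    call = translate(orf, code)
    expected = 24 + net_indel // 3  # residues, shifted by in-frame indels
    notes = [call.notes] if call.notes else []
    if call.stop_codon_index is None:
        status = GeneStatus.AMBIGUOUS
        notes.append("no stop located")
        peptide = call.peptide
    else:
        idx = call.stop_codon_index
        peptide = call.peptide
        if idx < premature_cutoff:
            status = GeneStatus.PSEUDO_PREMATURE_STOP
            notes.append(f"premature stop at codon {idx}")
        elif idx < 24:
            status = GeneStatus.AMBIGUOUS
            notes.append(f"stop at codon {idx}, shorter than expected {expected} residues")
        elif idx <= 24 + net_indel // 3 + max_extra_residues:
            status = GeneStatus.FUNCTIONAL
            if idx - 1 != expected:
                notes.append(f"peptide {idx - 1} residues (expected {expected})")
        else:
            status = GeneStatus.AMBIGUOUS
            notes.append(f"stop at codon {idx}, beyond expected length")
    return PeptideCall(
        peptide=peptide,
        stop_codon_index=call.stop_codon_index,
        has_start=True,
        net_indel=net_indel,
        status=status,
        notes="; ".join(notes),
    )
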