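"""Substitution calling against the rCRS Humanin region, with codon-level
consequences, known-variant annotation, and cohort summaries.

Variants are labelled in the plain "rCRS allele, position, derived allele"
style used throughout the mtDNA literature (e.g. ``T2638C``); an HGVS form
(``m.2638T>C``) is available on request.  Consequences come from codon
arithmetic in the fixed 73-base frame: position 2633 is codon 1 position 1,
and position 2705 sits in the incomplete terminal stop.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from .classifier import GeneStatus, GeneticCode, classify_status, load_genetic_code
from .locator import MatchQuery, best_fit_scan, refine_with_gaps
from .reference import HUMANIN_PEPTIDE, HUMANIN_QUERY, RCRS_END, RCRS_START, load_known_variants_table
from .seqio import SequenceRecord, UNAMBIGUOUS

_LABEL_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")

STOP_REGION = "stop-region"
INDETERMINATE = "indeterminate"
SYNONYMOUS = "synonymous"


@dataclass(frozen=True)
class KnownVariantAnnotation:
    """One bundled annotation row: haplogroup association and GenBank count."""

    label: str
    haplogroup: str
    n_genbank: int
    consequence: str


@dataclass(frozen=True)
class Variant:
    """A single substitution in rCRS coordinates with its codon context."""

    position: int  # rCRS coordinate, 1-based
    ref: str
    alt: str
    codon_index: int
    codon_position: int
    aa_change: str = ""

    @property
    def label(self) -> str:
        return f"{self.ref}{self.position}{self.alt}"


@dataclass(frozen=True)
class SurveySummary:
    """Cohort-level tallies from :func:`survey_cohort`."""

    n_sequences: int
    n_unmutated: int
    fraction_unmutated: float
    variant_counts: Mapping[str, int]
    status_counts: Mapping[str, int]


class HumaninReference:
    """The rCRS anchor: 73-base query, peptide, and known-variant table."""

    def __init__(self) -> None:
        self.rcrs_start = RCRS_START
        self.rcrs_end = RCRS_END
        self.query = HUMANIN_QUERY
        self.peptide = HUMANIN_PEPTIDE
        table = load_known_variants_table()
        self.known_variants = [
            KnownVariantAnnotation(
                label=row.label,
                haplogroup=row.haplogroup,
                n_genbank=int(row.n_genbank),
                consequence=row.consequence,
            )
            for row in table.itertuples()
        ]
        self._by_label = {ann.label: ann for ann in self.known_variants}

    def codon(self, codon_index: int) -> str:
        return self.query[3 * (codon_index - 1) : 3 * codon_index]


def parse_label(label: str) -> tuple[str, int, str]:
    """Split 'T2638C' into (ref, position, alt)."""
    m = _LABEL_RE.match(label.strip().upper())
    if not m:
        raise ValueError(f"malformed variant label {label!r}")
    return m.group(1), int(m.group(2)), m.group(3)


def hgvs_label(variant: Variant) -> str:
    """HGVS-style mitochondrial name, e.g. m.2638T>C."""
    return f"m.{variant.position}{variant.ref}>{variant.alt}"


def variant_from_label(label: str, reference: HumaninReference | None = None) -> Variant:
    """Build a Variant (with consequence) from a label like 'C2639T'."""
    reference = reference or HumaninReference()
    ref, pos, alt = parse_label(label)
    if not RCRS_START <= pos <= RCRS_END:
        raise ValueError(f"position {pos} outside the Humanin region [{RCRS_START}, {RCRS_END}]")
    expected_ref = reference.query[pos - RCRS_START]
    if ref != expected_ref:
        raise ValueError(f"label {label!r}: rCRS base at {pos} is {expected_ref}, not {ref}")
    if ref == alt:
        raise ValueError(f"label {label!r}: ref and alt are identical")
    off = pos - RCRS_START
    v = Variant(position=pos, ref=ref, alt=alt, codon_index=off // 3 + 1, codon_position=off % 3 + 1)
    return replace(v, aa_change=consequence(v, reference))


def consequence(
    variant: Variant,
    reference: HumaninReference | None = None,
    code: GeneticCode | None = None,
) -> str:
    """Codon-level consequence of a substitution.

    Mutates the reference codon, translates old and new: identical amino
    acids give "synonymous", otherwise "<old><codon_index><new>" (a stop
    gain prints ``*``).  Position 2705 lies in the incomplete terminal stop
    and is labelled "stop-region"; ambiguity-code alternates are
    "indeterminate".
    """
    reference = reference or HumaninReference()
    code = code or load_genetic_code()
    if not RCRS_START <= variant.position <= RCRS_END:
        raise ValueError(f"position {variant.position} outside [{RCRS_START}, {RCRS_END}]")
    if variant.codon_index > 24:
        return STOP_REGION
    if variant.alt not in UNAMBIGUOUS:
        return INDETERMINATE
    old_codon = reference.codon(variant.codon_index)
    new_codon = (
        old_codon[: variant.codon_position - 1]
        + variant.alt
        + old_codon[variant.codon_position :]
    )
    old_aa = code.codon_map[old_codon]
    new_aa = code.codon_map[new_codon]
    if old_aa == new_aa:
        return SYNONYMOUS
    return f"{old_aa}{variant.codon_index}{new_aa}"


def call_variants(
    sample_region: str,
    reference: HumaninReference | None = None,
    code: GeneticCode | None = None,
) -> list[Variant]:
    """Call substitutions in a gap-free 73-base region aligned to the rCRS frame.

    One Variant per mismatching position, sorted by position.  Samples whose
    located region carries indels must go through the gapped classifier
    path, not here.
    """
    reference = reference or HumaninReference()
    if len(sample_region) != 73:
        raise ValueError(
            f"sample region is {len(sample_region)} bases, not 73; regions with "
            "indels must be classified via the gapped alignment path"
        )
    sample = sample_region.upper().replace("U", "T")
    out: list[Variant] = []
    for off, (r, a) in enumerate(zip(reference.query, sample)):
        if r == a:
            continue
        v = Variant(
            position=RCRS_START + off,
            ref=r,
            alt=a,
            codon_index=off // 3 + 1,
            codon_position=off % 3 + 1,
        )
        out.append(replace(v, aa_change=consequence(v, reference, code)))
    return out


def annotate_known(
    variant: Variant, reference: HumaninReference | None = None
) -> KnownVariantAnnotation | None:
    """Exact label lookup in the bundled known-variant table."""
    reference = reference or HumaninReference()
    return reference._by_label.get(variant.label)


def apply_variants(labels: Iterable[str], reference: HumaninReference | None = None) -> str:
    """Return the 73-base region carrying the given variants."""
    reference = reference or HumaninReference()
    bases = list(reference.query)
    for label in labels:
        ref, pos, alt = parse_label(label)
        if not RCRS_START <= pos <= RCRS_END:
            raise ValueError(
                f"variant {label!r}: position {pos} outside [{RCRS_START}, {RCRS_END}]"
            )
        if bases[pos - RCRS_START] != ref:
            raise ValueError(f"variant {label!r} does not match the current region")
        bases[pos - RCRS_START] = alt
    return "".join(bases)


def survey_cohort(
    records: Sequence[SequenceRecord],
    reference: HumaninReference | None = None,
    hit_threshold: float = 0.60,
) -> SurveySummary:
    """Summarize a cohort of human Humanin regions against the rCRS.

    Records of exactly 73 bases are compared in place; longer records are
    located first with the ungapped scan and, when the gapped refinement
    reveals indels, are excluded from substitution calling and tallied
    under their gene status instead.
    """
    if not records:
        raise ValueError("cohort is empty")
    reference = reference or HumaninReference()
    query = MatchQuery(reference.query)
    n_unmutated = 0
    variant_counts: dict[str, int] = {}
    status_counts: dict[str, int] = {}
    for rec in records:
        if len(rec) == 73:
            region = rec.bases
        else:
            anchor = best_fit_scan(rec, query, hit_threshold=hit_threshold)
            if not anchor.is_hit:
                status_counts["NO_HIT"] = status_counts.get("NO_HIT", 0) + 1
                continue
            aln = refine_with_gaps(rec, query, anchor)
            if aln.net_indel != 0 or aln.n_insertions or aln.n_deletions:
                call = classify_status(rec, anchor, aln)
                key = call.status.value
                status_counts[key] = status_counts.get(key, 0) + 1
                continue
            region = rec.bases[anchor.start - 1 : anchor.end]
        calls = call_variants(region, reference)
        if not calls:
            n_unmutated += 1
        for v in calls:
            variant_counts[v.label] = variant_counts.get(v.label, 0) + 1
    n = len(records)
    return SurveySummary(
        n_sequences=n,
        n_unmutated=n_unmutated,
        fraction_unmutated=n_unmutated / n,
        variant_counts=variant_counts,
        status_counts=status_counts,
    )
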