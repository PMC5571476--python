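"""Seeded synthetic fixtures with known ground truth.

Everything downstream of this module can be tested without a single
download: random 16S-like backgrounds (default 1,559 nt, the human MT-RNR2
length scale), embedded Humanin homologs at controlled substitution
divergence, pseudogenizing events (start loss, premature stops,
frameshifting and in-frame indels), and human-like cohorts with configured
variant frequencies.  The same seed always yields byte-identical output.

The divergence model for embedded homologs is conditioned on the intended
truth class: substitutions that would themselves destroy the start codon or
introduce an in-frame stop are resampled, and the terminal thymine of the
incomplete stop is exempt.  This mirrors purifying selection — a diverged
homolog that is still functional by definition carries no pseudogenizing
change — and keeps the recorded truth label the real label of the emitted
sequence.  The two background bases immediately downstream of an embedded
copy are set to complete the terminal T into a full stop codon, emulating
the in-situ termination context.  Unconstrained per-site substitution is
available separately as :func:`mutate_sequence` for null calibrations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classifier import GeneStatus, load_genetic_code
from .locator import MatchQuery
from .reference import HUMANIN_QUERY
from .seqio import SequenceRecord
from .variants import HumaninReference, apply_variants, parse_label

BASES = "ACGT"
DEFAULT_BACKGROUND_LENGTH = 1559  # human MT-RNR2 scale

_STOP_COMPLETIONS = ("AA", "AG", "GA")  # complete a terminal T into TAA/TAG/TGA


@dataclass(frozen=True)
class Event:
    """A pseudogenizing (or neutral) event applied to an embedded copy."""

    kind: str  # none | start_loss | premature_stop | indel
    stop_codon: int | None = None
    indel_size: int | None = None  # signed: >0 insertion, <0 deletion

    @staticmethod
    def none() -> "Event":
        return Event("none")

    @staticmethod
    def start_loss() -> "Event":
        return Event("start_loss")

    @staticmethod
    def premature_stop(codon: int) -> "Event":
        if not 2 <= codon <= 24:
            raise ValueError(f"premature stop codon index must be in [2, 24], got {codon}")
        return Event("premature_stop", stop_codon=codon)

    @staticmethod
    def indel(size: int) -> "Event":
        if size == 0 or abs(size) > 12:
            raise ValueError(f"indel size must be nonzero and |size| <= 12, got {size}")
        return Event("indel", indel_size=size)

    @property
    def in_frame(self) -> bool:
        return self.kind == "indel" and self.indel_size % 3 == 0

    def describe(self) -> str:
        if self.kind == "premature_stop":
            return f"premature_stop({self.stop_codon})"
        if self.kind == "indel":
            return f"indel({self.indel_size:+d})"
        return self.kind

    def expected_status(self, premature_cutoff: int = 20) -> GeneStatus:
        """The status the classifier should assign under default settings."""
        if self.kind == "start_loss":
            return GeneStatus.PSEUDO_NO_START
        if self.kind == "premature_stop":
            if self.stop_codon < premature_cutoff:
                return GeneStatus.PSEUDO_PREMATURE_STOP
            return GeneStatus.AMBIGUOUS
        if self.kind == "indel" and not self.in_frame:
            return GeneStatus.PSEUDO_FRAMESHIFT
        return GeneStatus.FUNCTIONAL


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth serialized alongside every generated fixture."""

    record_id: str
    planted_offset: int  # 1-based
    divergence: float
    event: Event
    seed: int
    copy_length: int
    expected_status: GeneStatus
    variants_applied: tuple[str, ...] = ()

    def as_row(self) -> dict:
        return {
            "record_id": self.record_id,
            "planted_offset": self.planted_offset,
            "divergence": self.divergence,
            "event": self.event.describe(),
            "seed": self.seed,
            "copy_length": self.copy_length,
            "expected_status": self.expected_status.value,
            "variants_applied": ",".join(self.variants_applied),
        }


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def make_background(
    length: int = DEFAULT_BACKGROUND_LENGTH,
    composition: dict[str, float] | None = None,
    seed: int | None = None,
    record_id: str = "background",
) -> SequenceRecord:
    """A random nucleotide background, uniform composition by default."""
    if length < 73:
        raise ValueError(f"background length must be >= 73, got {length}")
    if composition is None:
        probs = np.full(4, 0.25)
    else:
        probs = np.array([composition.get(b, 0.0) for b in BASES], dtype=float)
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError(f"base frequencies must sum to 1, got {probs.sum()}")
    rng = _rng(seed)
    bases = "".join(np.array(list(BASES))[rng.choice(4, size=length, p=probs)])
    return SequenceRecord(id=record_id, bases=bases)


def mutate_sequence(bases: str, divergence: float, rng: np.random.Generator) -> str:
    """Plain per-site substitution: each base mutates with probability
    ``divergence``, uniformly among the three alternatives.  No functional
    constraints — use for null calibrations."""
    if not 0 <= divergence <= 1:
        raise ValueError(f"divergence must be in [0, 1], got {divergence}")
    out = list(bases)
    hit = np.nonzero(rng.random(len(out)) < divergence)[0]
    for i in hit:
        alts = [b for b in BASES if b != out[i]]
        out[i] = alts[rng.integers(3)]
    return "".join(out)


def _diverge_preserving_function(
    query: str, divergence: float, rng: np.random.Generator, code
) -> str:
    """Per-site substitution constrained to keep the copy translatable:
    codon 1 keeps a valid start, no codon becomes a stop, and the terminal
    incomplete-stop thymine is exempt."""
    n_codons = (len(query)) // 3
    out: list[str] = []
    for k in range(n_codons):
        codon = query[3 * k : 3 * k + 3]
        for _ in range(100):
            mutated = mutate_sequence(codon, divergence, rng)
            if k == 0 and mutated != "ATG":
                continue
            if code.is_stop(mutated):
                continue
            break
        else:  # pragma: no cover - resampling virtually never exhausts
            mutated = codon
        out.append(mutated)
    out.append(query[3 * n_codons :])  # terminal (incomplete stop) bases kept
    return "".join(out)


def _apply_event(copy: str, event: Event, rng: np.random.Generator, code) -> str:
    if event.kind == "none":
        return copy
    if event.kind == "start_loss":
        lost = ["GTG", "ACG", "ATC"][rng.integers(3)]
        return lost + copy[3:]
    if event.kind == "premature_stop":
        k = event.stop_codon
        return copy[: 3 * (k - 1)] + "TAA" + copy[3 * k :]
    # indel
    s = event.indel_size
    if event.in_frame:
        # codon-aligned so no junction codon can become a spurious stop
        boundary = int(rng.integers(2, 24))  # between codons, inside the ORF
        pos = 3 * boundary
        if s > 0:
            ins_codons = []
            for _ in range(s // 3):
                while True:
                    cod = "".join(BASES[i] for i in rng.integers(0, 4, 3))
                    if not code.is_stop(cod):
                        break
                ins_codons.append(cod)
            return copy[:pos] + "".join(ins_codons) + copy[pos:]
        n_del = -s
        if pos + n_del > 72:
            pos = 72 - n_del
        return copy[:pos] + copy[pos + n_del :]
    # frameshifting: position inside the copy, clear of the start codon
    if s > 0:
        pos = int(rng.integers(3, 70))
        ins = "".join(BASES[i] for i in rng.integers(0, 4, s))
        return copy[:pos] + ins + copy[pos:]
    n_del = -s
    pos = int(rng.integers(3, 70 - n_del))
    return copy[:pos] + copy[pos + n_del :]


def embed_homolog(
    background: SequenceRecord,
    query: MatchQuery | None = None,
    offset: int = 101,
    divergence: float = 0.0,
    event: Event | None = None,
    seed: int | None = None,
    stop_context: bool = True,
) -> tuple[SequenceRecord, TruthRecord]:
    """Splice a (possibly diverged, possibly pseudogenized) query copy into a
    background at a 1-based offset, recording the ground truth.

    The copy replaces the corresponding background stretch; with
    ``stop_context`` the two following background bases complete the
    terminal T into a stop codon.
    """
    query = query or MatchQuery()
    event = event or Event.none()
    rng = _rng(seed)
    code = load_genetic_code(1)
    copy = _diverge_preserving_function(query.bases, divergence, rng, code)
    copy = _apply_event(copy, event, rng, code)
    tail = 2 if stop_context else 0
    if offset < 1 or offset - 1 + len(copy) + tail > len(background):
        raise ValueError(
            f"offset {offset} leaves no room for a {len(copy)}-base copy "
            f"(+{tail} context) in a {len(background)}-base background"
        )
    ctx = _STOP_COMPLETIONS[rng.integers(3)] if stop_context else ""
    bg = background.bases
    bases = bg[: offset - 1] + copy + ctx + bg[offset - 1 + len(copy) + tail :]
    rec = SequenceRecord(id=background.id, bases=bases, description=background.description)
    truth = TruthRecord(
        record_id=background.id,
        planted_offset=offset,
        divergence=divergence,
        event=event,
        seed=-1 if seed is None else int(seed),
        copy_length=len(copy),
        expected_status=event.expected_status(),
    )
    return rec, truth


def make_cohort(
    n: int,
    variant_spec: dict[str, float] | None = None,
    seed: int | None = None,
) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """A cohort of 73-base human Humanin regions with variants planted at
    configured per-record frequencies (independently per variant).

    Returns the records and a truth table (record_id, variants_applied).
    """
    if n < 1:
        raise ValueError(f"cohort size must be >= 1, got {n}")
    variant_spec = variant_spec or {}
    reference = HumaninReference()
    for label, freq in variant_spec.items():
        parse_label(label)  # raises on malformed labels
        apply_variants([label], reference)  # raises on wrong ref allele
        if not 0 <= freq <= 1:
            raise ValueError(f"frequency for {label} must be in [0, 1], got {freq}")
    rng = _rng(seed)
    labels = list(variant_spec)
    width = max(4, len(str(n)))
    records: list[SequenceRecord] = []
    rows: list[dict] = []
    for i in range(n):
        applied = [lab for lab in labels if rng.random() < variant_spec[lab]]
        bases = apply_variants(applied, reference) if applied else reference.query
        rid = f"cohort_{i + 1:0{width}d}"
        records.append(SequenceRecord(id=rid, bases=bases))
        rows.append({"record_id": rid, "variants_applied": ",".join(applied)})
    return records, pd.DataFrame(rows)
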