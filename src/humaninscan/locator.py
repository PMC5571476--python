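"""Ungapped best-fit location of the Humanin query, plus gapped refinement.

The scan steps the 73-base query along the target one offset at a time,
counts identical bases at each offset, and keeps the best-scoring offset
(ties go to the smallest start coordinate).  A typical non-matching 16S
background scores about 30/73 (about 40% identity); a true Humanin homolog
scores about 50/73 (about 70%) even in distant vertebrates.

The ungapped scan cannot see indels, so hits can be refined with a small
fitting alignment (query aligned globally against a band around the anchor,
target overhangs free) that reports insertion/deletion counts for the
frameshift test.

Forward strand only; reverse-complement handling lives in
:mod:`humaninscan.numtscan`.  The circular mitochondrial genome is treated
as linear (positions 2633-2705 are far from the origin).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .reference import HUMANIN_QUERY
from .seqio import SequenceRecord, normalize_bases

DEFAULT_HIT_THRESHOLD = 0.60
DEFAULT_BAND = 12

MATCH_SCORE = 1
MISMATCH_SCORE = -1
GAP_SCORE = -2  # per gapped base, linear

_ACGT = frozenset(b"ACGT")


@dataclass(frozen=True)
class MatchQuery:
    """The probe sequence stepped along targets (default: the 73-base rCRS
    Humanin gene)."""

    bases: str = HUMANIN_QUERY

    def __post_init__(self) -> None:
        object.__setattr__(self, "bases", normalize_bases(self.bases, "<query>"))

    @property
    def length(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class MatchResult:
    """Best ungapped placement of the query in one target.

    ``start``/``end`` are 1-based inclusive; ``identity`` is
    ``matches / query_length``; ``is_hit`` applies the configured identity
    threshold.
    """

    target_id: str
    start: int
    end: int
    matches: int
    identity: float
    is_hit: bool
    strand: str = "+"


@dataclass(frozen=True)
class GappedAlignment:
    """Fitting alignment of the query against a window around an anchor.

    ``n_insertions`` counts bases present in the target but absent from the
    query; ``n_deletions`` the reverse; target-window overhangs beyond the
    fitted query extent are free and not counted.  ``target_start`` is the
    1-based coordinate (in the full target) of the first fitted target base.
    """

    aligned_query: str
    aligned_target: str
    n_insertions: int
    n_deletions: int
    net_indel: int
    score: int
    target_start: int
    clipped: bool = False
    note: str = ""


def _encode(bases: str) -> np.ndarray:
    return np.frombuffer(bases.encode("ascii"), dtype=np.uint8)


def count_matches_all_offsets(target: str, query: str) -> np.ndarray:
    """Exact-match count of ``query`` at every ungapped offset of ``target``.

    Ambiguity codes (including N) on either side never match.  Returns an
    int array of length ``len(target) - len(query) + 1``.
    """
    t = _encode(target)
    q = _encode(query)
    q_ok = np.isin(q, np.frombuffer(b"ACGT", dtype=np.uint8))
    t_ok = np.isin(t, np.frombuffer(b"ACGT", dtype=np.uint8))
    n_off = len(t) - len(q) + 1
    counts = np.empty(n_off, dtype=np.int64)
    # chunk offsets so the window view stays small on long contigs
    chunk = 1 << 20
    for lo in range(0, n_off, chunk):
        hi = min(lo + chunk, n_off)
        wins = sliding_window_view(t[lo : hi + len(q) - 1], len(q))
        wins_ok = sliding_window_view(t_ok[lo : hi + len(q) - 1], len(q))
        counts[lo:hi] = ((wins == q) & wins_ok & q_ok).sum(axis=1)
    return counts


def best_fit_scan(
    target: SequenceRecord,
    query: MatchQuery | None = None,
    hit_threshold: float = DEFAULT_HIT_THRESHOLD,
) -> MatchResult:
    """Find the best ungapped fit of the query in the target.

    ``matches`` is the maximum, over all offsets, of the number of positions
    with identical unambiguous bases; ties break to the smallest start.
    Raises ``ValueError`` if the target is shorter than the query.
    """
    query = query or MatchQuery()
    if len(target) < query.length:
        raise ValueError(
            f"target too short: {target.id!r} has {len(target)} bases "
            f"< query length {query.length}"
        )
    counts = count_matches_all_offsets(target.bases, query.bases)
    best = int(np.argmax(counts))  # argmax returns the first (smallest) offset on ties
    matches = int(counts[best])
    result = MatchResult(
        target_id=target.id,
        start=best + 1,
        end=best + query.length,
        matches=matches,
        identity=matches / query.length,
        is_hit=False,
    )
    return classify_hit(result, query, hit_threshold)


def classify_hit(
    result: MatchResult,
    query: MatchQuery | None = None,
    hit_threshold: float = DEFAULT_HIT_THRESHOLD,
) -> MatchResult:
    """Set ``is_hit`` by comparing identity to the threshold (inclusive)."""
    if not 0 < hit_threshold <= 1:
        raise ValueError(f"hit threshold must be in (0, 1], got {hit_threshold}")
    return replace(result, is_hit=result.identity >= hit_threshold)


def refine_with_gaps(
    target: SequenceRecord,
    query: MatchQuery | None = None,
    anchor: MatchResult | None = None,
    band: int = DEFAULT_BAND,
) -> GappedAlignment:
    """Gapped refinement of an anchored hit to expose indels.

    Aligns the full query against the target window
    ``[anchor.start - band, anchor.end + band]`` (clipped at the target
    boundary, which is noted in the result).  Scoring: +1 match, -1
    mismatch, -2 per gapped base (linear); among equal-scoring alignments
    the one with fewer gapped bases wins, then the traceback prefers
    substitutions over gaps deterministically.  Target bases outside the
    fitted query extent are free overhang.
    """
    query = query or MatchQuery()
    if anchor is None:
        anchor = best_fit_scan(target, query)
    if not anchor.is_hit:
        raise ValueError(
            f"anchor for {target.id!r} is not a hit (identity {anchor.identity:.2f}); "
            "gapped refinement requires a hit"
        )
    win_lo = anchor.start - band  # 1-based
    win_hi = anchor.end + band
    clipped = win_lo < 1 or win_hi > len(target)
    win_lo = max(win_lo, 1)
    win_hi = min(win_hi, len(target))
    window = target.bases[win_lo - 1 : win_hi]
    aln_q, aln_t, score, t_used_start = _fitting_alignment(query.bases, window)
    n_ins = aln_q.count("-")
    n_del = aln_t.count("-")
    return GappedAlignment(
        aligned_query=aln_q,
        aligned_target=aln_t,
        n_insertions=n_ins,
        n_deletions=n_del,
        net_indel=n_ins - n_del,
        score=score,
        target_start=win_lo + t_used_start,
        clipped=clipped,
        note="window clipped at target boundary" if clipped else "",
    )


def _pair_score(a: str, b: str) -> int:
    # ambiguity codes never match, consistent with the ungapped scan
    if a == b and a in "ACGT":
        return MATCH_SCORE
    return MISMATCH_SCORE


def _fitting_alignment(query: str, window: str) -> tuple[str, str, int, int]:
    """Query-global / window-free-ends alignment by dynamic programming.

    Maximizes (score, -gapped_bases) lexicographically.  Returns
    (aligned_query, aligned_window_slice, score, window_offset_of_first_used_base).
    """
    m, n = len(query), len(window)
    NEG = -(10**9)
    # DP tables: score and gap count; i over query, j over window
    S = np.full((m + 1, n + 1), NEG, dtype=np.int64)
    G = np.zeros((m + 1, n + 1), dtype=np.int64)
    S[0, :] = 0  # free leading overhang in window
    for i in range(1, m + 1):
        S[i, 0] = S[i - 1, 0] + GAP_SCORE
        G[i, 0] = G[i - 1, 0] + 1
    for i in range(1, m + 1):
        qi = query[i - 1]
        for j in range(1, n + 1):
            diag = (S[i - 1, j - 1] + _pair_score(qi, window[j - 1]), G[i - 1, j - 1])
            up = (S[i - 1, j] + GAP_SCORE, G[i - 1, j] + 1)  # query base deleted
            left = (S[i, j - 1] + GAP_SCORE, G[i, j - 1] + 1)  # window base inserted
            best = max(diag, up, left, key=lambda sg: (sg[0], -sg[1]))
            S[i, j], G[i, j] = best
    # free trailing overhang: best cell in the last row; ties -> fewer gaps,
    # then smallest j (shortest window consumption)
    j_end = 0
    best_key = (S[m, 0], -G[m, 0], 0)
    for j in range(1, n + 1):
        key = (S[m, j], -G[m, j], -j)
        if key > best_key:
            best_key, j_end = key, j
    score = int(S[m, j_end])
    # traceback, preferring substitution over gaps on ties
    aln_q: list[str] = []
    aln_t: list[str] = []
    i, j = m, j_end
    while i > 0:
        here = (S[i, j], G[i, j])
        if (
            j > 0
            and (S[i - 1, j - 1] + _pair_score(query[i - 1], window[j - 1]), G[i - 1, j - 1]) == here
        ):
            aln_q.append(query[i - 1])
            aln_t.append(window[j - 1])
            i, j = i - 1, j - 1
        elif (S[i - 1, j] + GAP_SCORE, G[i - 1, j] + 1) == here:
            aln_q.append(query[i - 1])
            aln_t.append("-")
            i -= 1
        else:
            aln_q.append("-")
            aln_t.append(window[j - 1])
            j -= 1
    return "".join(reversed(aln_q)), "".join(reversed(aln_t)), score, j
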