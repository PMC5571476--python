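import numpy as np
import pytest
from Bio import Align

from humaninscan.locator import (
    GAP_SCORE,
    MATCH_SCORE,
    MISMATCH_SCORE,
    MatchQuery,
    MatchResult,
    best_fit_scan,
    classify_hit,
    count_matches_all_offsets,
    refine_with_gaps,
)
from humaninscan.reference import HUMANIN_QUERY
from humaninscan.seqio import SequenceRecord
from humaninscan.synthetic import make_background, mutate_sequence

BASES = "ACGT"


def brute_force_best(target: str, query: str) -> tuple[int, int]:
    """Independent naive double-loop scan: (best 0-based offset, matches)."""
    best_off, best_matches = 0, -1
    for off in range(len(target) - len(query) + 1):
        m = sum(
            1
            for a, b in zip(target[off : off + len(query)], query)
            if a == b and a in BASES
        )
        if m > best_matches:
            best_off, best_matches = off, m
    return best_off, best_matches


def random_seq(rng, n):
    return "".join(rng.choice(list(BASES), size=n))


class TestBestFitScan:
    def test_query_against_itself(self, reference_record):
        res = best_fit_scan(reference_record)
        assert (res.start, res.end, res.matches, res.identity) == (1, 73, 73, 1.0)
        assert res.is_hit

    def test_planted_exact_copy_recovered(self):
        rng = np.random.default_rng(42)
        bg = random_seq(rng, 1559)
        target = bg[:100] + HUMANIN_QUERY + bg[100 + 73 :]
        res = best_fit_scan(SequenceRecord(id="t", bases=target))
        assert (res.start, res.matches) == (101, 73)

    @pytest.mark.parametrize("case_seed", range(40))
    def test_matches_brute_force_oracle(self, case_seed):
        """The vectorized scan equals a naive double-loop on random instances."""
        rng = np.random.default_rng(10_000 + case_seed)
        qlen = int(rng.integers(5, 74))
        tlen = int(rng.integers(qlen, 301))
        target, query = random_seq(rng, tlen), random_seq(rng, qlen)
        off, matches = brute_force_best(target, query)
        res = best_fit_scan(
            SequenceRecord(id="t", bases=target), MatchQuery(query), hit_threshold=0.5
        )
        assert (res.start - 1, res.matches) == (off, matches)

    def test_tie_breaks_to_smallest_start(self):
        # two identical perfect placements; the first must win
        target = "AAAA" + "ACGTACGT" + "TTTT" + "ACGTACGT" + "AAAA"
        res = best_fit_scan(SequenceRecord(id="t", bases=target), MatchQuery("ACGTACGT"))
        assert res.start == 5

    def test_ambiguity_codes_never_match(self):
        counts = count_matches_all_offsets("NNNN", "NN")
        assert counts.tolist() == [0, 0, 0]

    def test_target_shorter_than_query_is_an_error(self):
        with pytest.raises(ValueError, match="target too short"):
            best_fit_scan(SequenceRecord(id="t", bases="ACGT"))

    def test_substitutions_never_increase_matches_at_true_offset(self):
        rng = np.random.default_rng(7)
        bg = random_seq(rng, 400)
        copy = HUMANIN_QUERY
        prev = 74
        for div in (0.0, 0.05, 0.1, 0.2, 0.3, 0.5):
            mutated = mutate_sequence(copy, div, np.random.default_rng(99))
            target = bg[:50] + mutated + bg[50 + 73 :]
            counts = count_matches_all_offsets(target, HUMANIN_QUERY)
            at_true = int(counts[50])
            assert at_true <= prev
            prev = at_true


class TestClassifyHit:
    @pytest.mark.parametrize(
        "identity,expected",
        [(0.70, True), (0.41, False), (0.60, True), (0.5999, False)],
    )
    def test_threshold_is_inclusive(self, identity, expected):
        res = MatchResult("t", 1, 73, int(identity * 73), identity, False)
        assert classify_hit(res).is_hit is expected

    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.5])
    def test_threshold_validation(self, bad):
        res = MatchResult("t", 1, 73, 73, 1.0, False)
        with pytest.raises(ValueError, match="threshold"):
            classify_hit(res, hit_threshold=bad)


def _fitting_oracle_score(query: str, window: str) -> float:
    """Biopython global aligner with free end gaps on the window side."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = MATCH_SCORE
    aligner.mismatch_score = MISMATCH_SCORE
    aligner.open_gap_score = GAP_SCORE
    aligner.extend_gap_score = GAP_SCORE
    aligner.end_deletion_score = 0.0  # free end gaps on the window side
    return aligner.score(window, query)


class TestRefineWithGaps:
    def _scan(self, target):
        rec = SequenceRecord(id="t", bases=target)
        return rec, best_fit_scan(rec)

    def test_exact_window_has_no_gaps(self, reference_record):
        aln = refine_with_gaps(reference_record)
        assert (aln.n_insertions, aln.n_deletions, aln.net_indel) == (0, 0, 0)
        assert aln.score == 73
        assert aln.aligned_query == aln.aligned_target == HUMANIN_QUERY

    def test_single_deletion_detected(self):
        bg = make_background(seed=3).bases
        copy = HUMANIN_QUERY[:30] + HUMANIN_QUERY[31:]  # one base deleted
        rec, anchor = self._scan(bg[:200] + copy + bg[200 + 72 :])
        aln = refine_with_gaps(rec, anchor=anchor)
        assert (aln.n_deletions, aln.net_indel) == (1, -1)
        assert aln.score == _fitting_oracle_score(
            HUMANIN_QUERY, rec.bases[anchor.start - 13 : anchor.end + 12]
        )

    def test_three_base_insertion_detected(self):
        bg = make_background(seed=4).bases
        copy = HUMANIN_QUERY[:36] + "ACG" + HUMANIN_QUERY[36:]
        rec, anchor = self._scan(bg[:200] + copy + bg[200 + 76 :])
        aln = refine_with_gaps(rec, anchor=anchor)
        assert (aln.n_insertions, aln.net_indel) == (3, 3)

    @pytest.mark.parametrize("case_seed", range(12))
    def test_score_matches_pairwise_aligner_oracle(self, case_seed):
        """DP score equals an independent aligner under identical scoring."""
        rng = np.random.default_rng(500 + case_seed)
        query = random_seq(rng, 30)
        window = random_seq(rng, int(rng.integers(30, 60)))
        from humaninscan.locator import _fitting_alignment

        _, _, score, _ = _fitting_alignment(query, window)
        assert score == _fitting_oracle_score(query, window)

    def test_gapless_strings_recover_originals(self):
        bg = make_background(seed=9).bases
        copy = HUMANIN_QUERY[:20] + HUMANIN_QUERY[22:]  # 2-base deletion
        rec, anchor = self._scan(bg[:150] + copy + bg[150 + 71 :])
        aln = refine_with_gaps(rec, anchor=anchor)
        assert aln.aligned_query.replace("-", "") == HUMANIN_QUERY
        fitted = aln.aligned_target.replace("-", "")
        assert fitted in rec.bases
        assert rec.bases.index(fitted) + 1 == aln.target_start

    def test_window_clipped_at_boundary_is_noted(self, reference_record):
        aln = refine_with_gaps(reference_record, band=12)
        assert aln.clipped
        assert "clipped" in aln.note

    def test_non_hit_anchor_rejected(self, reference_record):
        anchor = MatchResult("rcrs_humanin", 1, 73, 30, 30 / 73, False)
        with pytest.raises(ValueError, match="not a hit"):
            refine_with_gaps(reference_record, anchor=anchor)
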