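"""Global alignment, percent identity, and transcript specificity calls."""

import numpy as np
import pytest
import promstr as ps
from promstr.io_model import ValidationError
from promstr.utr_identity import (
    AlignmentScoreScheme, classify_transcript, global_align, identity_matrix,
    pairwise_identity, percent_identity,
)

SCHEME = AlignmentScoreScheme()


def brute_force_score(a, b, scheme=SCHEME):
    """Exhaustive enumeration over all global alignments (move sequences)."""
    best = [-np.inf]

    def rec(i, j, score):
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            s = scheme.match if a[i] == b[j] else scheme.mismatch
            rec(i + 1, j + 1, score + s)
        if i < len(a):
            rec(i + 1, j, score + scheme.gap)
        if j < len(b):
            rec(i, j + 1, score + scheme.gap)

    rec(0, 0, 0.0)
    return best[0]


def rand_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestGlobalAlign:
    def test_identity_alignment(self):
        aa, ab, score = global_align("GATTACA", "GATTACA")
        assert (aa, ab) == ("GATTACA", "GATTACA")
        assert score == 7

    def test_single_mismatch(self):
        aa, ab, score = global_align("GATTACA", "GATCACA")
        assert score == 5
        assert "-" not in aa and "-" not in ab
        assert sum(x != y for x, y in zip(aa, ab)) == 1

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            global_align("", "ACGT")

    def test_ungapping_recovers_inputs(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            a, b = rand_dna(rng, 20), rand_dna(rng, 15)
            aa, ab, _ = global_align(a, b)
            assert aa.replace("-", "") == a
            assert ab.replace("-", "") == b
            assert len(aa) == len(ab)

    def test_score_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(7)
        for _ in range(40):
            na, nb = rng.integers(1, 9), rng.integers(1, 9)
            a, b = rand_dna(rng, na), rand_dna(rng, nb)
            aa, ab, score = global_align(a, b)
            assert score == brute_force_score(a, b)
            # the reported alignment realises the reported score
            realised = sum(
                SCHEME.gap if "-" in (x, y)
                else (SCHEME.match if x == y else SCHEME.mismatch)
                for x, y in zip(aa, ab))
            assert realised == score

    def test_score_matches_biopython_aligner(self):
        from Bio import Align
        aligner = Align.PairwiseAligner(
            mode="global", match_score=1, mismatch_score=-1,
            open_gap_score=-2, extend_gap_score=-2)
        rng = np.random.default_rng(11)
        for _ in range(25):
            a, b = rand_dna(rng, 60), rand_dna(rng, 55)
            _, _, score = global_align(a, b)
            assert score == aligner.score(a, b)

    def test_deterministic(self):
        a, b = "GCGCGTATA", "GCGTATAGC"
        assert global_align(a, b) == global_align(a, b)


class TestPercentIdentity:
    def test_identical(self):
        s = "A" * 15 + "CGT" * 5
        assert percent_identity(s, s) == 100.0

    def test_six_of_seven(self):
        assert round(percent_identity("GATTACA", "GATCACA"), 2) == 85.71

    def test_floor_is_zero(self):
        assert percent_identity("AAAA----", "----CCCC") == 0.0
        assert percent_identity("AAAA", "CCCC") == 0.0

    def test_gap_columns_count_in_denominator(self):
        assert percent_identity("ACGT-", "ACGTA") == 80.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            percent_identity("ACGT", "ACG")

    def test_symmetric(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            a, b = rand_dna(rng, 25), rand_dna(rng, 25)
            aa, ab, _ = global_align(a, b)
            assert percent_identity(aa, ab) == percent_identity(ab, aa)

    def test_invariant_under_column_permutation(self):
        rng = np.random.default_rng(14)
        aa, ab, _ = global_align(rand_dna(rng, 30), rand_dna(rng, 28))
        perm = rng.permutation(len(aa))
        pa = "".join(aa[i] for i in perm)
        pb = "".join(ab[i] for i in perm)
        assert percent_identity(pa, pb) == percent_identity(aa, ab)


class TestIdentityMatrix:
    def _utr(self, species, seq, gene="G1", **kw):
        return ps.UtrRecord(gene=gene, transcript_id=f"{gene}.1",
                            species=species, sequence=seq, **kw)

    def test_identical_ortholog_scores_100(self, panel):
        seq = "ACGT" * 25
        m = identity_matrix(
            [self._utr("human", seq), self._utr("chimpanzee", seq)], panel)
        assert m == {"chimpanzee": 100.0}

    def test_species_without_utr_omitted(self, panel):
        m = identity_matrix([self._utr("human", "ACGT" * 25)], panel)
        assert m == {}

    def test_no_human_record_errors(self, panel):
        with pytest.raises(ValidationError):
            identity_matrix([self._utr("mouse", "ACGT" * 25)], panel)

    def test_divergence_targets_recovered(self, panel):
        """Calibrated divergent copies land within +-5 points of the
        configured identity targets, even near the unrelated baseline."""
        from promstr.synth_data import tuned_copy
        rng = np.random.default_rng(3)
        for target in (60.0, 45.0):
            for _ in range(10):
                human = rand_dna(rng, 150)
                mutant = tuned_copy(rng, human, target, tol=5.0)
                got = pairwise_identity(human, mutant)
                assert abs(got - target) <= 5.0


class TestClassifyTranscript:
    def _records(self, panel, identities, rng, tol=5.0):
        from promstr.synth_data import tuned_copy
        human = rand_dna(rng, 150)
        recs = [ps.UtrRecord("G1", "G1.1", "human", human,
                             transcript_length=1000, exon_count=5, aa_count=300)]
        for sp, ident in identities.items():
            recs.append(ps.UtrRecord(
                "G1", "G1.1", sp, tuned_copy(rng, human, ident, tol=tol),
                transcript_length=1000, exon_count=5, aa_count=300))
        return recs

    def test_unrelated_band_identities_are_human_specific(self, panel):
        rng = np.random.default_rng(21)
        recs = self._records(panel, {"chimpanzee": 42.0, "mouse": 40.0}, rng,
                             tol=4.0)
        call = classify_transcript(recs, panel)
        assert call.human_specific
        assert call.max_identity < 50.0
        assert set(call.pairwise_identity) == {"chimpanzee", "mouse"}

    def test_exactly_threshold_is_not_specific(self, panel):
        """The rule is strict (<): a species at exactly 50.0 blocks the call."""
        recs = [
            ps.UtrRecord("G1", "G1.1", "human", "AC" * 50),
            # ungapped optimum: alternating match/mismatch -> exactly 50%
            ps.UtrRecord("G1", "G1.1", "chimpanzee",
                         "AG" * 50),
        ]
        call = classify_transcript(recs, panel)
        assert call.pairwise_identity["chimpanzee"] == 50.0
        assert not call.human_specific

    def test_no_orthologs_means_human_specific(self, panel):
        recs = [ps.UtrRecord("G1", "G1.1", "human", "ACGT" * 30)]
        call = classify_transcript(recs, panel)
        assert call.human_specific
        assert call.max_identity is None
        assert len(call.missing_species) == 24

    def test_threshold_monotonicity(self, panel):
        rng = np.random.default_rng(23)
        recs = self._records(panel, {"chimpanzee": 55.0, "mouse": 40.0}, rng)
        called = [classify_transcript(recs, panel, threshold=t).human_specific
                  for t in (40.0, 50.0, 60.0, 70.0)]
        # raising the threshold never flips human_specific -> not
        assert called == sorted(called)

    def test_composition_divergence_flag(self, panel):
        human = ps.UtrRecord("G1", "G1.1", "human", "ACGT" * 30,
                             transcript_length=1000, exon_count=5, aa_count=300)
        same = ps.UtrRecord("G1", "G1.1", "chimpanzee", "ACGT" * 30,
                            transcript_length=1050, exon_count=5, aa_count=300)
        diff = ps.UtrRecord("G1", "G1.1", "mouse", "ACGT" * 30,
                            transcript_length=2000, exon_count=9, aa_count=500)
        call_same = classify_transcript([human, same, diff], panel)
        assert not call_same.composition_divergent  # one species matches human
        call_diff = classify_transcript([human, diff], panel)
        assert call_diff.composition_divergent


class TestUnrelatedSequenceBaseline:
    def test_random_pairs_score_below_55(self):
        """Unrelated equal-length random sequences at GC 50% stay below 55%
        identity in >=99% of 1,000 seeded trials — the empirical basis for
        the 50% specificity threshold."""
        rng = np.random.default_rng(99)
        below = 0
        trials = 1000
        for _ in range(trials):
            a, b = rand_dna(rng, 150), rand_dna(rng, 150)
            if pairwise_identity(a, b) < 55.0:
                below += 1
        assert below >= 0.99 * trials
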