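"""Scanner correctness: primitivity, phase behaviour, oracle equivalence,
formula grammar, synthesis closure."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import promstr as ps
from promstr.io_model import ValidationError, offset_to_index, index_to_offset
from promstr.str_scan import ScanConfig, is_primitive_unit, synthesize_window

from conftest import random_window


def brute_force_loci(record, config=ScanConfig()):
    """Independent enumerator: tests every (start, unit, copies) triple."""
    seq, tss = record.sequence, record.tss_index
    n = len(seq)
    win_lo = offset_to_index_unchecked(config.core_window[0], tss)
    win_hi = offset_to_index_unchecked(config.core_window[1], tss)
    scan_lo = max(0, win_lo - config.scan_buffer_upstream)
    out = []
    for u in config.unit_lengths:
        for i in range(scan_lo, min(win_hi, n - 1) + 1):
            unit = seq[i:i + u]
            if len(unit) < u or "N" in unit or not is_primitive_unit(unit):
                continue
            # maximal copies for this phase
            k = 0
            while seq[i + k * u:i + (k + 1) * u] == unit:
                k += 1
            if k < config.min_copies:
                continue
            if i - u >= 0 and seq[i - u:i] == unit:
                continue  # left-extendable
            end = i + k * u - 1
            if end < win_lo or i > win_hi:
                continue
            out.append((index_to_offset(i, tss), u, unit, k))
    return sorted(out)


def offset_to_index_unchecked(offset, tss):
    return tss + offset - 1 if offset > 0 else tss + offset


def as_tuples(loci):
    return sorted((l.start_offset, l.unit_length, l.motif, l.copies)
                  for l in loci)


class TestPrimitivity:
    @pytest.mark.parametrize("unit,expected", [
        ("GGC", True), ("CCC", False), ("ATAT", False), ("GGGC", True),
        ("AAAA", False), ("ACGT", True), ("A", True), ("AA", False),
    ])
    def test_examples(self, unit, expected):
        assert is_primitive_unit(unit) is expected

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            is_primitive_unit("")

    @given(st.text(alphabet="ACGT", min_size=1, max_size=4))
    def test_matches_divisor_enumeration(self, unit):
        n = len(unit)
        brute = not any(unit == unit[:d] * (n // d)
                        for d in range(1, n) if n % d == 0)
        assert is_primitive_unit(unit) is brute


class TestFindStrLoci:
    def test_planted_gca11(self):
        rec = ps.synthesize_from_formula("- 88 (GCA)11", seed=2)
        loci = ps.find_str_loci(rec)
        assert ("- 88 (GCA)11") in [l.formula for l in loci]
        # the planted phase is maximal and not left-extendable
        planted = next(l for l in loci if l.formula == "- 88 (GCA)11")
        i = offset_to_index(planted.start_offset, rec.tss_index)
        assert rec.sequence[i - 3:i] != "GCA"
        assert rec.sequence[i + 33:i + 36] != "GCA"

    def test_phase_shifted_reporting(self):
        """One G+(CCG)x3 run yields both a GCC-phase and a CCG-phase locus."""
        rec = synthesize_window(["- 48 (GCC)3", "- 47 (CCG)3"], seed=4)
        got = as_tuples(ps.find_str_loci(rec))
        assert (-48, 3, "GCC", 3) in got
        assert (-47, 3, "CCG", 3) in got
        assert len(got) == 2  # the 10-nt run carries no third phase

    def test_period_five_sequence_has_no_loci(self):
        seq = ("ACGTT" * 31)[:121]
        rec = ps.PromoterRecord("G", "G.1", "", "human", seq, 120)
        assert ps.find_str_loci(rec) == []

    def test_n_terminates_runs(self):
        seq = "T" * 100 + "GCAGCANGCAGCAGCA" + "TT"
        rec = ps.PromoterRecord("G", "G.1", "", "human", seq, len(seq) - 1)
        got = as_tuples(ps.find_str_loci(rec))
        assert all(m == "GCA" and k == 3 for (_, _, m, k) in got)
        assert len(got) == 1  # only the 3-copy run right of the N

    def test_short_window_yields_empty_not_error(self):
        rec = ps.PromoterRecord("G", "G.1", "", "human", "ACGTA", 4)
        assert ps.find_str_loci(rec) == []

    def test_output_sorted_and_within_window(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            rec = random_window(rng, 150, gc=0.6)
            loci = ps.find_str_loci(rec)
            keys = [(l.start_offset, l.unit_length, l.motif) for l in loci]
            assert keys == sorted(keys)
            for l in loci:
                assert l.end_offset >= -120 and l.start_offset <= 1
                assert l.copies >= 3

    def test_oracle_equivalence_exhaustive_small(self):
        """Scanner == brute-force enumerator on every short {A,C,G} string."""
        import itertools
        cfg = ScanConfig(core_window=(-9, 1), scan_buffer_upstream=0)
        for length in (9, 10):
            sub = ScanConfig(core_window=(-(length - 1), 1),
                             scan_buffer_upstream=0)
            for tup in itertools.product("ACG", repeat=length):
                seq = "".join(tup)
                rec = ps.PromoterRecord("G", "G.1", "", "human", seq,
                                        length - 1)
                got = [(l.start_offset, l.unit_length, l.motif, l.copies)
                       for l in ps.find_str_loci(rec, sub)]
                assert sorted(got) == brute_force_loci(rec, sub), seq

    def test_oracle_equivalence_sampled_longer(self):
        rng = np.random.default_rng(12)
        for length in (11, 12):
            sub = ScanConfig(core_window=(-(length - 1), 1),
                             scan_buffer_upstream=0)
            for _ in range(400):
                seq = "".join(rng.choice(list("ACG"), size=length))
                rec = ps.PromoterRecord("G", "G.1", "", "human", seq,
                                        length - 1)
                got = [(l.start_offset, l.unit_length, l.motif, l.copies)
                       for l in ps.find_str_loci(rec, sub)]
                assert sorted(got) == brute_force_loci(rec, sub), seq

    def test_oracle_equivalence_random_windows(self):
        """400 seeded 150-nt windows at GC 40-60%, default window rules."""
        rng = np.random.default_rng(42)
        for _ in range(400):
            gc = rng.uniform(0.4, 0.6)
            rec = random_window(rng, 150, gc=gc)
            got = [(l.start_offset, l.unit_length, l.motif, l.copies)
                   for l in ps.find_str_loci(rec)]
            assert sorted(got) == brute_force_loci(rec), rec.sequence

    def test_min_copies_monotonicity(self):
        rng = np.random.default_rng(9)
        for _ in range(40):
            rec = random_window(rng, 150, gc=0.65)
            sets = []
            for mc in (2, 3, 4):
                cfg = ScanConfig(min_copies=mc)
                sets.append({(l.start_offset, l.motif) for l in
                             ps.find_str_loci(rec, cfg)})
            assert sets[2] <= sets[1] <= sets[0]

    def test_emitted_loci_maximal_per_phase(self):
        rng = np.random.default_rng(77)
        checked = 0
        for _ in range(600):
            rec = random_window(rng, 150, gc=0.7)
            for l in ps.find_str_loci(rec):
                i = offset_to_index(l.start_offset, rec.tss_index)
                u, k = l.unit_length, l.copies
                assert rec.sequence[i:i + u * k] == l.motif * k
                assert rec.sequence[i + u * k:i + u * (k + 1)] != l.motif
                if i >= u:
                    assert rec.sequence[i - u:i] != l.motif
                checked += 1
        assert checked > 20


class TestFormulaGrammar:
    @pytest.mark.parametrize("offset,motif,copies,expected", [
        (-48, "CCA", 3, "- 48 (CCA)3"),
        (-123, "GATA", 13, "- 123 (GATA)13"),
        (1, "GGC", 3, "+ 1 (GGC)3"),
    ])
    def test_format(self, offset, motif, copies, expected):
        locus = ps.StrLocus("G", "G.1", "human", motif, len(motif), copies,
                            offset, offset + len(motif) * copies - 1)
        assert ps.format_formula(locus) == expected

    def test_parse_accepts_typographic_minus(self):
        assert ps.parse_formula("− 48 (CCA)3") == (-48, "CCA", 3)
        assert ps.parse_formula("- 48 (CCA)3") == (-48, "CCA", 3)

    @pytest.mark.parametrize("bad", [
        "", "48 CCA 3", "- 48 (CCX)3", "- 48 (CCC)3", "- 0 (CCA)3",
        "- 48 (CCA)1",
    ])
    def test_parse_rejects_malformed(self, bad):
        with pytest.raises(ValidationError):
            ps.parse_formula(bad)

    @given(offset=st.integers(-150, -1),
           motif=st.sampled_from(["GCC", "CCG", "GCA", "GAA", "CTCC", "GCCC",
                                  "GATA", "GGCT"]),
           copies=st.integers(3, 13))
    def test_round_trip(self, offset, motif, copies):
        locus = ps.StrLocus("G", "G.1", "human", motif, len(motif), copies,
                            offset, offset + len(motif) * copies - 1)
        assert ps.parse_formula(ps.format_formula(locus)) == (offset, motif,
                                                              copies)


class TestSynthesis:
    def test_determinism(self):
        a = ps.synthesize_from_formula("- 31 (GAA)10", seed=8)
        b = ps.synthesize_from_formula("- 31 (GAA)10", seed=8)
        assert a.sequence == b.sequence

    def test_scan_recovers_planted_formula(self):
        rec = ps.synthesize_from_formula("- 31 (GAA)10", seed=8)
        assert "- 31 (GAA)10" in [l.formula for l in ps.find_str_loci(rec)]

    def test_unplaceable_formula_errors(self):
        with pytest.raises(ValidationError):
            ps.synthesize_from_formula("- 300 (GCC)3", window_length=181)

    def test_conflicting_formulas_error(self):
        with pytest.raises(ValidationError):
            synthesize_window(["- 50 (GCC)3", "- 50 (GAA)3"], seed=0)

    def test_no_loci_outside_planted_run(self):
        for seed in range(5):
            rec = ps.synthesize_from_formula("- 54 (GCCC)3", seed=seed)
            loci = ps.find_str_loci(
                rec, ScanConfig(core_window=(-180, 1), scan_buffer_upstream=0))
            for l in loci:
                assert -54 <= l.start_offset and l.end_offset <= -43
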