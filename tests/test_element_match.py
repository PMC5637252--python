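"""Barcode/primer matching: alignment kernels vs oracles, tagging, trimming."""
import random

import pytest
from Bio import Align
from hypothesis import given
from hypothesis import strategies as st

from repseqprep.element_match import (
    MatchElement,
    MatchSpec,
    best_match,
    load_combinatorial_csv,
    local_align,
    resolve_combinatorial,
    reverse_complement,
)
from repseqprep.errors import ConfigError, ContractError
from repseqprep.fixtures import DEFAULT_BARCODES, FixtureSpec, build_fixture

from _oracles import min_mismatch_scan, sw_score_dp, sw_score_enumerate
from conftest import make_read


def el(seq, eid="e"):
    return MatchElement(eid, seq)


def random_pairs(seed, n, with_n=False, max_el=30, max_seg=100):
    rng = random.Random(seed)
    alphabet = "ACGTN" if with_n else "ACGT"
    for _ in range(n):
        m = rng.randint(1, max_el)
        k = rng.randint(1, max_seg)
        yield (
            "".join(rng.choice(alphabet) for _ in range(m)),
            "".join(rng.choice(alphabet) for _ in range(k)),
        )


class TestReverseComplement:
    @pytest.mark.parametrize("seq,expected", [("ACGT", "ACGT"), ("AACN", "NGTT"), ("acGT", "ACgt")])
    def test_examples(self, seq, expected):
        assert reverse_complement(seq) == expected

    def test_invalid_character(self):
        with pytest.raises(ContractError):
            reverse_complement("ACGU")

    @given(st.text(alphabet="ACGTNacgtn", max_size=50))
    def test_involution(self, seq):
        assert reverse_complement(reverse_complement(seq)) == seq


class TestLocalAlignScore:
    def test_perfect_match_scores_plus_two_per_base(self):
        result = local_align(el("ACGT"), "ACGT", mode="score")
        assert result.score == 8
        assert result.read_span == (0, 4)
        assert result.element_span == (0, 4)
        assert result.mismatches == 0

    def test_internal_match(self):
        result = local_align(el("CGT"), "AACGTAA", mode="score")
        assert result.score == 6
        assert result.read_span == (2, 5)

    def test_n_never_matches(self):
        # N vs N is still a mismatch; the best local alignment avoids it
        result = local_align(el("NA"), "NA", mode="score")
        assert result.score == 2
        assert result.read_span == (1, 2)

    def test_ungapped_matches_dp_oracle(self):
        for element, segment in random_pairs(seed=5, n=300, with_n=True):
            result = local_align(el(element), segment, mode="score")
            expected = sw_score_dp(element, segment)
            got = 0 if result is None else result.score
            assert got == expected, (element, segment)

    def test_ungapped_matches_exhaustive_enumeration_on_small_inputs(self):
        for element, segment in random_pairs(seed=6, n=60, max_el=8, max_seg=20):
            result = local_align(el(element), segment, mode="score")
            got = 0 if result is None else result.score
            assert got == sw_score_enumerate(element, segment)

    def test_reported_span_scores_the_reported_score(self):
        for element, segment in random_pairs(seed=7, n=100):
            result = local_align(el(element), segment, mode="score")
            if result is None:
                continue
            s, e = result.read_span
            i, j = result.element_span
            assert e - s == j - i  # ungapped
            rescore = sum(
                2 if (a == b and a != "N") else -2
                for a, b in zip(element[i:j], segment[s:e])
            )
            assert rescore == result.score

    def test_gapped_matches_biopython_aligner(self):
        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.match_score = 2
        aligner.mismatch_score = -2
        aligner.open_gap_score = -3
        aligner.extend_gap_score = -3
        for element, segment in random_pairs(seed=8, n=150, max_el=20, max_seg=60):
            result = local_align(el(element), segment, mode="score", gapped=True)
            expected = aligner.score(element, segment)
            got = 0 if result is None else result.score
            if expected <= 0:
                assert got <= 0 or result is None
            else:
                assert got == expected, (element, segment)

    def test_gapped_finds_alignment_across_deletion(self):
        # element ACGTACGT vs segment with the middle deleted: one gap of 1
        result = local_align(el("ACGTACGT"), "TTACGTCGTTT", mode="score", gapped=True)
        assert result.score == 7 * 2 - 3


class TestMismatchMode:
    def test_exact_and_offset(self):
        result = local_align(el("ACGT"), "TTACGATT", mode="mismatch")
        assert result.mismatches == 1
        assert result.read_span == (2, 6)

    def test_no_fit_sentinel(self):
        result = local_align(el("ACGTACGT"), "ACG", mode="mismatch")
        assert result.mismatches == float("inf")

    def test_matches_offset_scan_oracle(self):
        for element, segment in random_pairs(seed=9, n=300, with_n=True, max_el=15, max_seg=60):
            result = local_align(el(element), segment, mode="mismatch")
            mm, off = min_mismatch_scan(element, segment)
            assert result.mismatches == mm
            if mm != float("inf"):
                assert result.read_span[0] == off  # same smallest-offset tie-break


class TestBestMatch:
    def test_prefix_barcode_trim_and_tag(self):
        read = make_read("ACGTTTTTT", "flat40")
        spec = MatchSpec(
            elements=[el("ACGT", "S1")], tag_name="MID", mode="mismatch",
            threshold=0, window_start=0, window_end=6, trim="cut_leading",
        )
        outcome = best_match(read, spec)
        assert outcome.read.sequence == "TTTTT"
        assert outcome.read.quality == [40] * 5
        assert outcome.read.tags == {"MID": "S1"}
        assert outcome.result.read_span == (0, 4)

    def test_fewest_mismatches_wins(self):
        read = make_read("ACGTTTTTT")
        spec = MatchSpec(
            elements=[MatchElement("S2", "ACGA"), MatchElement("S1", "ACGT")],
            tag_name="MID", mode="mismatch", threshold=1, window_end=4,
        )
        assert best_match(read, spec).read.tags["MID"] == "S1"

    def test_panel_order_breaks_exact_ties(self):
        read = make_read("AAAA")
        spec = MatchSpec(
            elements=[MatchElement("first", "AAAA"), MatchElement("second", "AAAA")],
            tag_name="MID", mode="mismatch", threshold=0,
        )
        assert best_match(read, spec).read.tags["MID"] == "first"

    def test_require_match_drops(self):
        read = make_read("TTTTTTTT")
        spec = MatchSpec(
            elements=[el("ACGC", "S1")], tag_name="MID", mode="mismatch",
            threshold=0, require_match=True,
        )
        assert best_match(read, spec).outcome == "drop"
        spec.require_match = False
        outcome = best_match(read, spec)
        assert outcome.passed and "MID" not in outcome.read.tags

    def test_window_outside_read(self):
        read = make_read("ACGT")
        spec = MatchSpec(
            elements=[el("ACGT", "S1")], tag_name="MID", mode="mismatch",
            threshold=0, window_start=100, window_end=120,
        )
        outcome = best_match(read, spec)
        assert outcome.window_outside and outcome.outcome == "drop"

    def test_negative_window_start_anchors_three_prime(self):
        read = make_read("TTTTTTACGT")
        spec = MatchSpec(
            elements=[el("ACGT", "P3")], tag_name="P3", mode="mismatch",
            threshold=0, window_start=-4, trim="cut_trailing",
        )
        outcome = best_match(read, spec)
        assert outcome.result.read_span == (6, 10)
        assert outcome.read.sequence == "TTTTTT"

    def test_cut_element_splices_flanks(self):
        read = make_read("AAACGTACCC", "flat40")
        spec = MatchSpec(
            elements=[el("CGTA", "P")], tag_name="P", mode="mismatch",
            threshold=0, trim="cut_element",
        )
        outcome = best_match(read, spec)
        assert outcome.read.sequence == "AAACCC"
        assert len(outcome.read.sequence) == len(read.sequence) - 4

    def test_reverse_strand_equals_rc_element_forward(self):
        rng = random.Random(13)
        for _ in range(50):
            seq = "".join(rng.choice("ACGT") for _ in range(40))
            element = "".join(rng.choice("ACGT") for _ in range(8))
            read = make_read(seq)
            rev_spec = MatchSpec(
                elements=[el(element, "e")], tag_name="T", mode="score",
                threshold=1, strand="reverse",
            )
            fwd_spec = MatchSpec(
                elements=[el(reverse_complement(element), "e")], tag_name="T",
                mode="score", threshold=1, strand="forward",
            )
            a, b = best_match(read, rev_spec), best_match(read, fwd_spec)
            assert a.passed == b.passed
            if a.passed:
                assert a.result.read_span == b.result.read_span
                assert a.result.score == b.result.score

    def test_fixture_demultiplexing_truth(self):
        fx = build_fixture(
            FixtureSpec(
                n_templates=400,
                template_length=(40, 80),
                barcodes=DEFAULT_BARCODES,  # pairwise Hamming distance >= 3
                substitution_rate=0.02,
                seed=17,
            )
        )
        bc_len = len(DEFAULT_BARCODES[0][1])
        spec = MatchSpec(
            elements=[MatchElement(i, s, "barcode") for i, s in DEFAULT_BARCODES],
            tag_name="MID", mode="mismatch", threshold=1,
            window_start=0, window_end=bc_len,
        )
        for read in fx.reads:
            outcome = best_match(read, spec)
            assert outcome.passed
            assert outcome.read.tags["MID"] == fx.truth_by_id[read.read_id].sample_id


class TestCombinatorial:
    def write_table(self, tmp_path, text):
        p = tmp_path / "combo.csv"
        p.write_text(text)
        return p

    def test_resolution(self, tmp_path):
        table = load_combinatorial_csv(
            str(self.write_table(tmp_path, "MID1,MID2,sample_id\nA,X,patient1\nB,Y,patient2\n"))
        )
        read = make_read("ACGT", tags={"MID1": "A", "MID2": "X"})
        assert resolve_combinatorial(read, table).tags["sample"] == "patient1"

    def test_missing_component_leaves_read_unchanged(self, tmp_path):
        table = load_combinatorial_csv(
            str(self.write_table(tmp_path, "MID1,MID2,sample_id\nA,X,patient1\n"))
        )
        read = make_read("ACGT", tags={"MID1": "A"})
        assert "sample" not in resolve_combinatorial(read, table).tags
        unknown = make_read("ACGT", tags={"MID1": "B", "MID2": "Z"})
        assert "sample" not in resolve_combinatorial(unknown, table).tags

    @pytest.mark.parametrize(
        "text",
        ["MID1,MID2,sample_id\nA,X\n", "MID1,MID2,sample_id\nA,X,p1\nA,X,p2\n", "one_column\n"],
    )
    def test_malformed_csv(self, tmp_path, text):
        with pytest.raises(ConfigError):
            load_combinatorial_csv(str(self.write_table(tmp_path, text)))

    def test_three_by_three_design_counts(self):
        fx = build_fixture(
            FixtureSpec(
                n_templates=90,
                template_length=(30, 60),
                barcodes=DEFAULT_BARCODES,
                barcodes2=[("X1", "GGATCCAT"), ("X2", "CTTGAGGA"), ("X3", "TACCTGTC")],
                seed=23,
            )
        )
        assert len({s for _, _, s in fx.combo_rows}) == 9
        counts = fx.sample_counts()
        assert sum(counts.values()) == 90
        assert set(counts.values()) == {10}  # balanced 3x3 design
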