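"""Filter predicates: boundary conventions, trims, and brute-force oracles."""
import pytest
from hypothesis import given
from hypothesis import strategies as st

from repseqprep.errors import ContractError
from repseqprep.io_formats import SequenceRead
from repseqprep.read_filters import (
    filter_ambiguous,
    filter_average_quality,
    filter_homopolymer,
    filter_length,
    filter_per_base_quality,
    filter_window_quality,
)

from _oracles import longest_run
from conftest import make_read


class TestAverageQuality:
    @pytest.mark.parametrize(
        "quality,min_avg,expected",
        [
            ([40, 40, 40, 40], 35, "pass"),
            ([10, 10, 10, 10], 10, "pass"),  # boundary is inclusive
            ([10, 10, 10, 10], 10.1, "drop"),
        ],
    )
    def test_examples(self, quality, min_avg, expected):
        result = filter_average_quality(make_read("A" * len(quality), quality), min_avg)
        assert result.outcome == expected

    def test_missing_quality_is_contract_error(self):
        with pytest.raises(ContractError):
            filter_average_quality(make_read("ACGT"), 10)

    def test_pass_set_matches_brute_force(self, random_reads):
        threshold = 20
        expected = {
            r.read_id for r in random_reads if sum(r.quality) / len(r.quality) >= threshold
        }
        got = {
            r.read_id
            for r in random_reads
            if filter_average_quality(r, threshold).passed
        }
        assert got == expected


class TestWindowQuality:
    def test_all_good_windows_untrimmed(self):
        r = make_read("A" * 10, [40] * 10)
        result = filter_window_quality(r, 5, 30, action="trim")
        assert result.passed and len(result.read.sequence) == 10

    def test_trim_at_first_failing_window(self):
        # windows of 4: [40,40,40,2]=30.5 ok, [40,40,2,2]=21 ok, [40,2,2,2]=11.5 fails
        # -> first failing window starts at p=2, kept length 2
        r = make_read("ACGTACGT", [40, 40, 40, 2, 2, 2, 2, 2])
        result = filter_window_quality(r, 4, 20, action="trim")
        assert result.passed
        assert result.read.sequence == "AC"
        assert result.read.quality == [40, 40]

    def test_drop_action(self):
        r = make_read("ACGTACGT", [40, 40, 40, 2, 2, 2, 2, 2])
        assert filter_window_quality(r, 4, 20, action="drop").outcome == "drop"

    def test_short_read_single_window(self):
        r = make_read("ACG", [10, 10, 10])
        assert filter_window_quality(r, 5, 9, action="drop").passed
        assert filter_window_quality(r, 5, 11, action="drop").outcome == "drop"

    def test_empty_read_is_contract_error(self):
        with pytest.raises(ContractError):
            filter_window_quality(make_read("", []), 4, 20)

    def test_matches_sliding_window_oracle(self, random_reads):
        w, threshold = 5, 18
        for read in random_reads[:300]:
            # oracle: direct scan over every window position
            n = len(read.quality)
            size = min(w, n)
            cut = None
            for start in range(n - size + 1):
                if sum(read.quality[start : start + size]) / size < threshold:
                    cut = start
                    break
            result = filter_window_quality(read, w, threshold, action="trim")
            assert len(result.read.sequence) == (n if cut is None else cut)

    def test_trim_is_idempotent_above_window_length(self, random_reads):
        # Idempotence holds whenever the trimmed read still spans a full
        # window: every window inside the kept prefix already passed.  A
        # shorter remnant is re-evaluated as one full-length window (a window
        # the first pass never saw), so it is excluded here.
        for read in random_reads[:100]:
            once = filter_window_quality(read, 5, 18, action="trim").read
            if len(once.sequence) < 5:
                continue
            twice = filter_window_quality(once, 5, 18, action="trim").read
            assert twice.sequence == once.sequence


class TestPerBaseQuality:
    def test_trim_at_first_low_base(self):
        r = make_read("ACGTA", [40, 40, 5, 40, 40])
        result = filter_per_base_quality(r, 10, action="trim")
        assert result.read.sequence == "AC"
        assert result.read.quality == [40, 40]

    def test_drop_if_any_low_base(self):
        r = make_read("ACGTA", [40, 40, 5, 40, 40])
        assert filter_per_base_quality(r, 10, action="drop").outcome == "drop"
        assert filter_per_base_quality(r, 5, action="drop").passed


class TestLength:
    @pytest.mark.parametrize(
        "length,min_len,max_len,expected",
        [
            (250, 100, None, "pass"),
            (99, 100, None, "drop"),
            (100, 100, 100, "pass"),  # both bounds inclusive
            (101, None, 100, "drop"),
        ],
    )
    def test_examples(self, length, min_len, max_len, expected):
        result = filter_length(make_read("A" * length), min_len, max_len)
        assert result.outcome == expected
        if expected == "drop":
            assert result.reason == "length"

    def test_histogram_truncation_oracle(self, random_reads):
        lo, hi = 20, 60
        survivors = [r for r in random_reads if filter_length(r, lo, hi).passed]
        assert {len(r.sequence) for r in survivors} == {
            len(r.sequence) for r in random_reads if lo <= len(r.sequence) <= hi
        }
        assert len(survivors) == sum(1 for r in random_reads if lo <= len(r.sequence) <= hi)


class TestAmbiguous:
    @pytest.mark.parametrize(
        "seq,max_n,expected",
        [("ACGTN", 0, "drop"), ("ACGTN", 1, "pass"), ("acgtn", 0, "drop"), ("ACGT", 0, "pass")],
    )
    def test_examples(self, seq, max_n, expected):
        assert filter_ambiguous(make_read(seq), max_n).outcome == expected

    def test_pass_set_matches_count_oracle(self, random_reads):
        got = {r.read_id for r in random_reads if filter_ambiguous(r, 2).passed}
        expected = {
            r.read_id for r in random_reads if r.sequence.upper().count("N") <= 2
        }
        assert got == expected


class TestHomopolymer:
    @pytest.mark.parametrize(
        "seq,max_run,expected",
        [("AAAACGT", 3, "drop"), ("AAAACGT", 4, "pass"), ("aAAa", 3, "drop"), ("NNNN", 3, "drop")],
    )
    def test_examples(self, seq, max_run, expected):
        assert filter_homopolymer(make_read(seq), max_run).outcome == expected

    def test_planted_runs_match_rle_oracle(self, rng):
        for _ in range(200):
            run = rng.randint(1, 12)
            base = rng.choice("ACGT")
            left = "".join(rng.choice("ACGT") for _ in range(rng.randint(0, 20)))
            right = "".join(rng.choice("ACGT") for _ in range(rng.randint(0, 20)))
            seq = left + base * run + right
            read = make_read(seq)
            threshold = rng.randint(1, 12)
            assert filter_homopolymer(read, threshold).passed == (
                longest_run(seq) <= threshold
            )


@given(st.lists(st.integers(min_value=0, max_value=42), min_size=1, max_size=60))
def test_trimming_never_lengthens_and_stays_aligned(quality):
    read = SequenceRead(read_id="r", sequence="A" * len(quality), quality=quality)
    for result in (
        filter_window_quality(read, 5, 20, action="trim"),
        filter_per_base_quality(read, 20, action="trim"),
    ):
        assert len(result.read.sequence) <= len(read.sequence)
        assert len(result.read.quality) == len(result.read.sequence)
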