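import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pyroqc import refine
from pyroqc.refine import FilterConfig
from pyroqc.seqio import ReadSet

from conftest import make_read


def random_read_set(rng: random.Random, n: int, max_len: int = 60) -> ReadSet:
    reads = []
    for i in range(n):
        length = rng.randint(1, max_len)
        bases = "".join(rng.choice("ACGTN") for _ in range(length))
        quals = tuple(rng.randint(0, 40) for _ in range(length))
        reads.append(make_read(f"r{i}", bases, quals=quals))
    return ReadSet(reads)


class TestComputeTrimLength:
    def test_constant_lengths(self):
        rs = ReadSet([make_read(f"r{i}", "A" * 250) for i in range(3)])
        assert refine.compute_trim_length(rs) == 250

    def test_mean_minus_sample_sd(self):
        # lengths 300, 250, 200: mean 250, sample sd 50 -> 200
        rs = ReadSet(
            [make_read("a", "A" * 300), make_read("b", "A" * 250), make_read("c", "A" * 200)]
        )
        assert refine.compute_trim_length(rs) == 200

    def test_single_read_returns_its_length(self):
        rs = ReadSet([make_read("a", "ACGT")])
        assert refine.compute_trim_length(rs) == 4

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            refine.compute_trim_length(ReadSet([]))


class TestTrimReads:
    def test_short_removed_long_truncated(self):
        rs = ReadSet([make_read("s", "ACGTA"), make_read("l", "ACGTACGTAC")])
        out, removed = refine.trim_reads(rs, 6)
        assert removed == 1
        assert out.ids() == ["l"]
        assert len(out["l"]) == 6

    def test_no_removal_when_all_long(self):
        rs = ReadSet([make_read("a", "ACGTACGT")])
        _, removed = refine.trim_reads(rs, 4)
        assert removed == 0

    def test_five_prime_truncation(self):
        rs = ReadSet([make_read("a", "ACGTACGT", quals=(30,) * 8)])
        out, _ = refine.trim_reads(rs, 4)
        assert out["a"].bases == "ACGT"
        assert out["a"].quals == (30, 30, 30, 30)


class TestQualityFilterFraction:
    def test_boundary_kept(self):
        quals = (26,) * 10 + (40,) * 90
        rs = ReadSet([make_read("a", "A" * 100, quals=quals)])
        kept, removed = refine.quality_filter_fraction(rs, 27, 0.10)
        assert (len(kept), removed) == (1, 0)

    def test_just_over_removed(self):
        quals = (26,) * 10 + (40,) * 90
        rs = ReadSet([make_read("a", "A" * 100, quals=quals)])
        kept, removed = refine.quality_filter_fraction(rs, 27, 0.09)
        assert (len(kept), removed) == (0, 1)

    def test_cutoff_is_strict_inequality(self):
        rs = ReadSet([make_read("a", "A" * 20, q=27)])
        kept, _ = refine.quality_filter_fraction(rs, 27, 0.0)
        assert len(kept) == 1

    def test_matches_brute_force_oracle(self):
        rng = random.Random(7)
        rs = random_read_set(rng, 200)
        for cutoff in (25, 27, 30, 32):
            for frac in (0.10, 0.15):
                kept, removed = refine.quality_filter_fraction(rs, cutoff, frac)
                kept_ids = set(kept.ids())
                for r in rs:
                    below = len([q for q in r.quals if q < cutoff])
                    expect = below / len(r) <= frac
                    assert (r.read_id in kept_ids) == expect
                assert removed == len(rs) - len(kept)


class TestQualityEndTrim:
    def test_truncates_at_first_low_base(self):
        rs = ReadSet([make_read("a", "ACGT", quals=(40, 40, 20, 40))])
        kept, removed = refine.quality_end_trim(rs, 27, 2)
        assert removed == 0
        assert kept["a"].bases == "AC"

    def test_low_first_base_removes_read(self):
        rs = ReadSet([make_read("a", "ACGT", quals=(20, 40, 40, 40))])
        kept, removed = refine.quality_end_trim(rs, 27, 1)
        assert (len(kept), removed) == (0, 1)

    def test_all_good_read_unchanged(self):
        rs = ReadSet([make_read("a", "ACGT", q=30)])
        kept, _ = refine.quality_end_trim(rs, 27, 1)
        assert kept["a"].bases == "ACGT"


class TestAmbiguousFilter:
    @pytest.mark.parametrize(
        "bases,expect_kept", [("ACGT", True), ("ACNT", False), ("NNNN", False)]
    )
    def test_n_removal(self, bases, expect_kept):
        kept, removed = refine.ambiguous_filter(ReadSet([make_read("a", bases)]))
        assert (len(kept) == 1) is expect_kept

    def test_empty_set(self):
        kept, removed = refine.ambiguous_filter(ReadSet([]))
        assert (len(kept), removed) == (0, 0)


class TestPrimerFilter:
    # the printed V4/V6 forward primer with its barcode prefix
    PRIMER = "tagtgtagatGTGCCAGCMGCNGCGG"

    def test_degenerate_match_kept(self):
        read = make_read("a", "TAGTGTAGATGTGCCAGCAGCTGCGG" + "ACGT")
        kept, removed = refine.primer_filter(ReadSet([read]), self.PRIMER)
        assert (len(kept), removed) == (1, 0)

    def test_degenerate_mismatch_removed(self):
        # G at the M={A,C} position
        read = make_read("a", "TAGTGTAGATGTGCCAGCGGCTGCGG" + "ACGT")
        kept, removed = refine.primer_filter(ReadSet([read]), self.PRIMER)
        assert (len(kept), removed) == (0, 1)

    def test_strip_removes_prefix(self):
        read = make_read("a", "TAGTGTAGATGTGCCAGCAGCTGCGGACGT")
        kept, _ = refine.primer_filter(ReadSet([read]), self.PRIMER, strip=True)
        assert kept["a"].bases == "ACGT"
        assert len(kept["a"].quals) == 4

    def test_read_shorter_than_primer_is_error(self):
        kept, removed = refine.primer_filter(ReadSet([make_read("a", "TAGT")]), self.PRIMER)
        assert (len(kept), removed) == (0, 1)


class TestRunRefinement:
    def test_planted_fixture_ledger(self, planted_fixture):
        rs, expected = planted_fixture
        config = FilterConfig(q_cutoff=27, allowed_fraction=0.15, primer=expected["primer"])
        out, ledger = refine.run_refinement(rs, config)
        assert ledger.stage_removals == expected["ledger"]
        assert ledger.remaining == len(out) == expected["remaining"]

    def test_identity_pipeline(self):
        rs = ReadSet([make_read(f"r{i}", "ACGT") for i in range(5)])
        out, ledger = refine.run_refinement(
            rs, FilterConfig(mode="none", trim_rule="none")
        )
        assert ledger.remaining == len(rs)
        assert all(n == 0 for _, n in ledger.stage_removals)

    def test_conservation_over_random_configs(self):
        rng = random.Random(11)
        rs = random_read_set(rng, 120)
        for _ in range(25):
            config = FilterConfig(
                q_cutoff=rng.choice((25, 27, 30, 32)),
                allowed_fraction=rng.choice((0.03, 0.10, 0.15)),
                mode=rng.choice(("fraction", "end_trim", "none")),
                trim_rule=rng.choice(("mean_minus_sd", "none", "fixed:10")),
            )
            _, ledger = refine.run_refinement(rs, config)
            ledger.validate()
            assert ledger.raw_count == len(rs)

    def test_monotone_in_stringency(self):
        rng = random.Random(13)
        rs = random_read_set(rng, 150, max_len=40)
        remaining = {}
        for cutoff in (25, 27, 30, 32):
            for frac in (0.10, 0.15):
                _, ledger = refine.run_refinement(
                    rs,
                    FilterConfig(q_cutoff=cutoff, allowed_fraction=frac, trim_rule="fixed:5"),
                )
                remaining[(cutoff, frac)] = ledger.remaining
        for frac in (0.10, 0.15):
            assert (
                remaining[(25, frac)]
                >= remaining[(27, frac)]
                >= remaining[(30, frac)]
                >= remaining[(32, frac)]
            )
        for cutoff in (25, 27, 30, 32):
            assert remaining[(cutoff, 0.15)] >= remaining[(cutoff, 0.10)]

    def test_idempotent_with_fixed_trim(self):
        rng = random.Random(17)
        rs = random_read_set(rng, 80)
        first = FilterConfig(q_cutoff=27, allowed_fraction=0.10)
        out1, ledger1 = refine.run_refinement(rs, first)
        L = len(out1.reads[0]) if len(out1) else 1
        again = FilterConfig(q_cutoff=27, allowed_fraction=0.10, trim_rule=f"fixed:{L}")
        out2, ledger2 = refine.run_refinement(out1, again)
        assert ledger2.remaining == len(out1)
        assert all(n == 0 for _, n in ledger2.stage_removals)


class TestQualitySummary:
    def test_single_read(self):
        assert refine.quality_summary(ReadSet([make_read("a", "AC", q=30)])) == 30.0

    def test_unweighted_across_reads(self):
        rs = ReadSet(
            [make_read("a", "A" * 10, q=20), make_read("b", "AC", q=40)]
        )
        assert refine.quality_summary(rs) == 30.0

    def test_trimming_low_tail_raises_summary(self):
        # 3' tails carry the lowest-Q run of each read
        reads = [
            make_read(f"r{i}", "ACGTACGTAC", quals=(35,) * 7 + (5, 5, 5))
            for i in range(4)
        ]
        rs = ReadSet(reads)
        before = refine.quality_summary(rs)
        trimmed, _ = refine.trim_reads(rs, 7)
        assert refine.quality_summary(trimmed) >= before

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            refine.quality_summary(ReadSet([]))


@settings(max_examples=50, deadline=None)
@given(
    quals=st.lists(st.integers(0, 40), min_size=1, max_size=80),
    cutoff=st.integers(0, 40),
    frac=st.floats(0.0, 1.0),
)
def test_fraction_filter_property(quals, cutoff, frac):
    rs = ReadSet([make_read("a", "A" * len(quals), quals=tuple(quals))])
    kept, removed = refine.quality_filter_fraction(rs, cutoff, frac)
    below = sum(1 for q in quals if q < cutoff)
    assert (len(kept) == 1) == (below / len(quals) <= frac)
    assert len(kept) + removed == 1
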