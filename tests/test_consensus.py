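"""CIGAR filtering, plurality consensus, and reading-frame checks."""

import itertools
import re

import numpy as np
import pytest

from mtblot.consensus import (
    ConsensusResult,
    call_consensus,
    cigar_filter,
    cigar_match_length,
    consensus_quality_filter,
    orf_intact,
)
from mtblot.model import ClassifierConfig, PileupColumn


def columns_from_counts(counts_list, gene="g"):
    return [
        PileupColumn(gene, i, dict(zip("ACGT", c)))
        for i, c in enumerate(counts_list)
    ]


class TestCigarFilter:
    @pytest.mark.parametrize(
        "cigar,kept",
        [("30M", True), ("20M", False), ("10M5I20M", True), ("25M", True), ("24M1S", False)],
    )
    def test_examples(self, cigar, kept):
        assert (cigar_filter([cigar], 25) == [cigar]) is kept

    def test_matches_independent_parser_on_operator_combinations(self):
        # independent oracle: regex run-length parse, sum of M/=/X lengths
        def oracle(cigar):
            return sum(
                int(n) for n, op in re.findall(r"(\d+)([A-Z=])", cigar) if op in "M=X"
            )

        ops = ["M", "I", "D", "S", "=", "X", "N"]
        lengths = [5, 13, 25]
        for combo in itertools.product(ops, repeat=3):
            for lens in itertools.product(lengths, repeat=3):
                cigar = "".join(f"{n}{op}" for n, op in zip(lens, combo))
                assert cigar_match_length(cigar, "total") == oracle(cigar)
                kept = cigar_filter([cigar], 25) == [cigar]
                assert kept is (oracle(cigar) >= 25)

    def test_longest_run_mode_merges_adjacent_match_ops(self):
        assert cigar_match_length("10M5=3X", "longest_run") == 18
        assert cigar_match_length("10M5I20M", "longest_run") == 20
        assert cigar_match_length("10M5I20M", "total") == 30

    def test_idempotent_and_order_preserving(self):
        records = ["30M", "20M", "40M", "10M20M"]
        once = cigar_filter(records, 25)
        assert once == ["30M", "40M", "10M20M"]
        assert cigar_filter(once, 25) == once

    def test_malformed_cigar_dropped_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            kept = cigar_filter(["30M", "oops", "*"], 25)
        assert kept == ["30M"]
        assert caplog.text.count("unusable CIGAR") == 2

    def test_accepts_objects_with_cigarstring(self):
        class Rec:
            def __init__(self, c):
                self.cigarstring = c

        recs = [Rec("30M"), Rec("5M")]
        assert cigar_filter(recs, 25) == [recs[0]]


class TestCallConsensus:
    def test_majority_base(self):
        res = call_consensus(columns_from_counts([(5, 0, 1, 0)]))
        assert res.sequence == "A"

    def test_tie_yields_iupac_code(self):
        res = call_consensus(columns_from_counts([(3, 0, 3, 0)]))
        assert res.sequence == "R"

    def test_zero_depth_yields_n(self):
        cols = [PileupColumn("g", 2, {"A": 4})]
        res = call_consensus(cols, length=4)
        assert res.sequence == "NNAN"

    def test_mean_depth_acceptance_rule(self):
        # 100 columns averaging depth 5.9 -> rejected but still returned
        counts = [(6, 0, 0, 0)] * 90 + [(5, 0, 0, 0)] * 10
        res = call_consensus(columns_from_counts(counts))
        assert res.mean_depth == pytest.approx(5.9)
        assert not res.accepted
        assert res.sequence == "A" * 100

    def test_unsorted_or_duplicate_positions_rejected(self):
        cols = columns_from_counts([(5, 0, 0, 0), (5, 0, 0, 0)])
        cols[1].position = 0
        with pytest.raises(ValueError, match="sorted"):
            call_consensus(cols)

    def test_matches_per_column_argmax_oracle(self):
        rng = np.random.default_rng(42)
        counts = rng.integers(0, 30, size=(200, 4))
        res = call_consensus(columns_from_counts(counts.tolist()))
        bases = np.array(list("ACGT"))
        for i, row in enumerate(counts):
            ties = (row == row.max()).sum()
            if row.sum() == 0:
                assert res.sequence[i] == "N"
            elif ties == 1:
                assert res.sequence[i] == bases[row.argmax()]

    def test_truth_recovery_at_depth(self):
        # pileups simulated from a known truth at depth >= 20 with 5% error
        # recover the truth exactly wherever no tie occurs
        rng = np.random.default_rng(7)
        for _ in range(10):
            truth = "".join(rng.choice(list("ACGT"), 150))
            depths = rng.integers(20, 40, 150)
            counts = []
            for base, d in zip(truth, depths):
                p = np.full(4, 0.05 / 3)
                p["ACGT".index(base)] = 0.95
                counts.append(tuple(rng.multinomial(d, p)))
            res = call_consensus(columns_from_counts(counts))
            assert res.sequence == truth


class TestOrfIntact:
    @pytest.mark.parametrize(
        "seq,intact,needle",
        [
            ("ATGAAATAA", True, None),
            ("ATGTAAAAATAA", False, "internal stop"),
            ("ATGAAATA", False, "multiple of 3"),
            ("ATGAAAAAA", False, "no terminal stop"),
            ("TTGAAATAA", False, "start set"),
            ("", False, "empty"),
        ],
    )
    def test_examples(self, seq, intact, needle):
        ok, diags = orf_intact(seq)
        assert ok is intact
        if needle:
            assert any(needle in d for d in diags)

    def test_ambiguity_cap_and_stop_exclusion(self):
        # codons containing N are not counted as stops...
        ok, diags = orf_intact("ATGTNAAAATAA", ClassifierConfig(orf_max_ambiguous_frac=0.2))
        assert ok
        # ...but too many ambiguous bases break the frame
        ok, diags = orf_intact("ATGNNNNNNTAA")
        assert not ok and any("ambiguous fraction" in d for d in diags)


class TestQualityFilter:
    @staticmethod
    def result(depth, seq="ACGT" * 25):
        return ConsensusResult("g", seq, mean_depth=depth, accepted=depth >= 6.0)

    def test_depth_and_n_fraction_gates(self):
        good = self.result(10.0)
        shallow = self.result(4.0)
        gappy = self.result(10.0, "N" * 50 + "A" * 50)
        kept = consensus_quality_filter([good, shallow, gappy])
        assert kept == [good]
        assert gappy.n_fraction == pytest.approx(0.5)
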