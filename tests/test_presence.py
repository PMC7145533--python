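"""Tier classification, heat maps, and coverage-plot series."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mtblot.consensus import ConsensusResult
from mtblot.depth_norm import normalize
from mtblot.model import ClassifierConfig, NormalizedProfile, PresenceCall, Tier
from mtblot.presence import (
    classify,
    coverage_plot_series,
    heat_value,
    heatmap_matrix,
    min_window_nfold,
)

from conftest import make_factor, make_profile


def nprof(values, gene="g"):
    return NormalizedProfile(gene, "rs1", np.asarray(values, dtype=float))


def classify_depths(depths, factor_value=40.0, consensus=None, cfg=ClassifierConfig()):
    prof = make_profile("g", depths)
    factor = make_factor(factor_value)
    return classify(prof, normalize(prof, factor), factor, consensus, cfg)


class TestHeatValue:
    @pytest.mark.parametrize(
        "mean_depth,expected",
        [(20, 0.5), (80, 2.0), (0, 0.0)],
        ids=["half", "duplicated-regime", "zero"],
    )
    def test_examples(self, mean_depth, expected):
        prof = make_profile("g", [mean_depth] * 10)
        assert heat_value(prof, make_factor(40.0)) == expected


class TestMinWindowNfold:
    def brute_force(self, values, window):
        v = np.asarray(values, dtype=float)
        w = min(window, len(v))
        return min(v[i:i + w].mean() for i in range(len(v) - w + 1))

    def test_constant(self):
        assert min_window_nfold(nprof([1.0] * 100), 25) == 1.0

    def test_window_one_is_pointwise_min(self):
        assert min_window_nfold(nprof([1, 1, 0, 1, 1]), 1) == 0.0

    def test_zero_block_produces_zero_window(self):
        values = [0.2] * 50 + [0.0] * 50
        assert min_window_nfold(nprof(values), 25) == 0.0
        assert self.brute_force(values, 25) == 0.0

    def test_window_clamps_to_length(self):
        values = [1.0, 0.0]
        assert min_window_nfold(nprof(values), 25) == 0.5

    @given(
        st.lists(st.floats(0, 10), min_size=1, max_size=60),
        st.integers(1, 70),
    )
    @settings(derandomize=True, max_examples=60)
    def test_matches_brute_force(self, values, window):
        got = min_window_nfold(nprof(values), window)
        assert got == pytest.approx(self.brute_force(values, window), rel=1e-9, abs=1e-12)


def intact_consensus(gene="g", accepted=True):
    return ConsensusResult(gene, "ATGAAATAA", mean_depth=40.0,
                           accepted=accepted, orf_intact=True)


class TestClassify:
    def test_first_tier_intact_orf(self):
        call = classify_depths([40] * 300, consensus=intact_consensus())
        assert call.tier is Tier.FIRST

    def test_second_tier_continuous_low_coverage(self):
        # constant n-fold 0.2 across the full length, no intact ORF
        call = classify_depths([8] * 300)
        assert call.tier is Tier.SECOND
        assert call.min_window_nfold == pytest.approx(0.2)

    def test_third_tier_partial_coverage(self):
        # 60% of positions at n-fold 0.6 (depth 24 > 5), 40% zero:
        # heat 0.36 > 0.25 but continuity broken by the zero block
        call = classify_depths([24] * 180 + [0] * 120)
        assert call.heat_value == pytest.approx(0.36)
        assert call.tier is Tier.THIRD

    def test_absent_with_adequate_controls(self):
        call = classify_depths([0] * 300, factor_value=40.0)
        assert call.tier is Tier.ABSENT

    def test_ambiguous_in_shallow_readset(self):
        call = classify_depths([0] * 300, factor_value=8.0)
        assert call.tier is Tier.AMBIGUOUS

    def test_rejected_consensus_cannot_reach_first(self):
        call = classify_depths([40] * 300, consensus=intact_consensus(accepted=False))
        assert call.tier is Tier.SECOND

    def test_consensus_for_other_gene_rejected(self):
        with pytest.raises(ValueError, match="consensus"):
            classify_depths([40] * 300, consensus=intact_consensus(gene="other"))

    def test_gene_mismatch_rejected(self):
        prof = make_profile("g", [1] * 10)
        with pytest.raises(ValueError, match="gene mismatch"):
            classify(prof, nprof([1.0] * 10, gene="h"), make_factor(40.0))

    @given(st.integers(0, 2**16))
    @settings(derandomize=True, max_examples=40)
    def test_scaling_gene_depth_never_lowers_the_tier(self, seed):
        rng = np.random.default_rng(seed)
        length = int(rng.integers(30, 200))
        depths = rng.integers(0, 13, length)
        factor_value = float(rng.choice([8.0, 40.0]))
        ranks = []
        for k in (1, 2, 3, 10):
            call = classify_depths(depths * k, factor_value=factor_value)
            ranks.append(call.tier.rank)
        assert ranks == sorted(ranks)


class TestHeatmapMatrix:
    @staticmethod
    def call(gene, rs, heat, frac=1.0, tier=Tier.THIRD):
        return PresenceCall(gene, rs, tier, heat, frac, 0.0, 40.0)

    def test_single_cell(self):
        values, tiers = heatmap_matrix([self.call("g", "rs", 1.0)])
        assert values.shape == (1, 1) and values.iloc[0, 0] == 1.0

    def test_gate_failure_displays_zero(self):
        values, _ = heatmap_matrix([self.call("g", "rs", 0.4, frac=0.3, tier=Tier.ABSENT)])
        assert values.iloc[0, 0] == 0.0

    def test_row_order_preserved(self):
        calls = [
            self.call(g, rs, 0.5)
            for rs in ("rs3", "rs1", "rs2")
            for g in ("gB", "gA")
        ]
        values, tiers = heatmap_matrix(calls)
        assert values.shape == (3, 2)
        assert list(values.index) == ["rs3", "rs1", "rs2"]
        assert list(values.columns) == ["gB", "gA"]
        assert (tiers == Tier.THIRD.symbol).all().all()

    def test_ragged_panels_rejected(self):
        calls = [self.call("g1", "rs1", 0.5), self.call("g2", "rs2", 0.5)]
        with pytest.raises(ValueError, match="ragged"):
            heatmap_matrix(calls)

    def test_cells_equal_recomputed_heat_values(self):
        rng = np.random.default_rng(5)
        calls = []
        expected = {}
        factor = make_factor(40.0, readset_id="rs")
        for g in ("a", "b", "c"):
            depths = rng.integers(6, 80, 120)
            prof = make_profile(g, depths, readset_id="rs")
            calls.append(classify(prof, normalize(prof, factor), factor))
            expected[g] = depths.mean() / 40.0
        values, _ = heatmap_matrix(calls)
        for g, want in expected.items():
            assert values.loc["rs", g] == pytest.approx(want)


class TestCoverageSeries:
    def test_series_length_and_bounds(self):
        series = coverage_plot_series(nprof([1.0] * 300))
        assert len(series.x) == len(series.y) == 300
        assert series.upper_bound == pytest.approx(math.log(6), abs=1e-4)
        assert series.upper_bound == pytest.approx(1.7918, abs=1e-4)
        assert series.lower_bound == -series.upper_bound

    def test_nuclear_residual_sits_below_lower_bound(self):
        series = coverage_plot_series(nprof([0.01] * 50))
        assert (series.y < series.lower_bound).all()

    def test_fold_boundary_must_exceed_one(self):
        with pytest.raises(ValueError):
            coverage_plot_series(nprof([1.0]), ClassifierConfig(fold_boundary=1.0))
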