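"""Consensus filtering, hotspot clustering, alignment splitting, site rates."""

import math

import numpy as np
import pytest
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from hypothesis import given, strategies as st

from tdrpclock.regions import (
    ExcisionRule,
    RecombinationEvent,
    RegionSpec,
    cluster_breakpoints,
    consensus_filter,
    moving_average,
    rate_ratio,
    region_rate_summary,
    scale_rates,
    split_alignment,
)

PROGRAMMES = ["RDP", "GENECONV", "Chimaera", "MaxChi", "BootScan", "SiScan", "3Seq"]


def _event(p_values):
    return RecombinationEvent(
        "rec", 10, 20, dict(zip(PROGRAMMES, p_values))
    )


def _alignment(n_seq, length, seed=0):
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    return MultipleSeqAlignment(
        [
            SeqRecord(
                Seq("".join(bases[rng.integers(0, 4, length)])),
                id=f"seq{i}",
                description="",
            )
            for i in range(n_seq)
        ]
    )


class TestConsensusFilter:
    def test_event_supported_by_all_seven_is_kept(self):
        ev = _event([0.01] * 7)
        assert consensus_filter([ev]) == [ev]

    def test_three_significant_detections_removed(self):
        ev = _event([0.01, 0.02, 0.04, 0.5, 0.6, 0.7, 0.8])
        assert consensus_filter([ev]) == []

    def test_empty_input(self):
        assert consensus_filter([]) == []

    @given(
        st.lists(
            st.lists(st.floats(0.0, 1.0, allow_nan=False), min_size=7, max_size=7),
            max_size=20,
        ),
        st.integers(0, 8),
        st.integers(0, 8),
    )
    def test_monotone_in_threshold_and_alpha(self, tables, k1, k2):
        events = [_event(ps) for ps in tables]
        lo, hi = sorted((k1, k2))
        # stricter programme count keeps a subset
        assert set(map(id, consensus_filter(events, hi))) <= set(
            map(id, consensus_filter(events, lo))
        )
        # larger alpha keeps a superset
        assert set(map(id, consensus_filter(events, 4, 0.01))) <= set(
            map(id, consensus_filter(events, 4, 0.10))
        )


class TestClusterBreakpoints:
    def test_two_hotspot_clusters(self):
        got = cluster_breakpoints([640, 700, 760, 1400, 1500], gap=100)
        assert got == [(640, 760), (1400, 1500)]

    def test_single_breakpoint_zero_width(self):
        assert cluster_breakpoints([700], gap=50) == [(700, 700)]

    def test_empty(self):
        assert cluster_breakpoints([], gap=50) == []

    def test_unsorted_input_is_sorted_first(self):
        assert cluster_breakpoints([1500, 640, 1400], gap=150) == [
            (640, 640),
            (1400, 1500),
        ]


ENV_HOTSPOTS = [RegionSpec("RH1", 631, 768), RegionSpec("RH2", 1369, 1521)]


class TestSplitAlignment:
    def test_env_geometry_region_lengths(self):
        aln = _alignment(5, 2883)
        parts = split_alignment(aln, ENV_HOTSPOTS)
        lengths = [a.get_alignment_length() for a in parts.values()]
        assert lengths == [630, 600, 1362]

    def test_column_conservation(self):
        aln = _alignment(4, 2883)
        parts = split_alignment(aln, ENV_HOTSPOTS)
        total = sum(a.get_alignment_length() for a in parts.values())
        total += sum(len(h) for h in ENV_HOTSPOTS)
        assert total == 2883

    def test_round_trip_reconstruction(self):
        aln = _alignment(3, 500, seed=2)
        hotspots = [RegionSpec("h", 101, 150)]
        parts = split_alignment(aln, hotspots, region_names=["left", "right"])
        for k, rec in enumerate(aln):
            rebuilt = (
                str(parts["left"][k].seq)
                + str(rec.seq)[100:150]
                + str(parts["right"][k].seq)
            )
            assert rebuilt == str(rec.seq)

    def test_no_hotspots_identity(self):
        aln = _alignment(3, 100)
        parts = split_alignment(aln, [])
        (only,) = parts.values()
        assert [str(r.seq) for r in only] == [str(r.seq) for r in aln]

    def test_excision_blanks_one_record_tail(self):
        aln = _alignment(6, 2883, seed=4)
        aln[0].id = "Bad316"
        parts = split_alignment(
            aln, ENV_HOTSPOTS, excisions=[ExcisionRule("Bad316", 481, 630)]
        )
        region1 = parts["region_1"]
        bad = str(region1[0].seq)
        assert bad[480:630] == "-" * 150  # 630 - 481 + 1 = 150 blanked columns
        assert "-" not in bad[:480]
        for rec, orig in zip(region1[1:], list(aln)[1:]):
            assert str(rec.seq) == str(orig.seq)[:630]

    def test_overlapping_hotspots_rejected(self):
        aln = _alignment(2, 200)
        with pytest.raises(ValueError, match="overlap"):
            split_alignment(
                aln, [RegionSpec("a", 10, 60), RegionSpec("b", 50, 80)]
            )


class TestScaleRates:
    def test_constant_vector(self):
        assert scale_rates(np.array([2.0, 2.0, 2.0])) == pytest.approx([1, 1, 1])

    def test_linear_vector(self):
        assert scale_rates(np.array([1.0, 2.0, 3.0])) == pytest.approx([0.5, 1.0, 1.5])

    def test_mean_is_one_for_random_input(self):
        rates = np.random.default_rng(9).gamma(2.0, size=(20, 300))
        scaled = scale_rates(rates)
        assert scaled.mean(axis=1) == pytest.approx(np.ones(20), abs=1e-9)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            scale_rates(np.zeros(5))


class TestRegionRateSummary:
    def test_unit_rates_give_unit_means(self):
        out = region_rate_summary(
            np.ones(10), [RegionSpec("a", 1, 4), RegionSpec("b", 5, 10)]
        )
        assert out["mean"].tolist() == [1.0, 1.0]

    def test_block_means(self):
        out = region_rate_summary(
            np.array([1.0, 1.0, 3.0, 3.0]),
            [RegionSpec("a", 1, 2), RegionSpec("b", 3, 4)],
        )
        assert out["mean"].tolist() == [1.0, 3.0]

    def test_whole_alignment_mean_is_one_after_scaling(self):
        rates = scale_rates(np.random.default_rng(2).gamma(1.5, size=400))
        out = region_rate_summary(rates, [RegionSpec("all", 1, 400)])
        assert out.loc["all", "mean"] == pytest.approx(1.0, abs=1e-12)

    def test_out_of_bounds_region_rejected(self):
        with pytest.raises(ValueError, match="past column"):
            region_rate_summary(np.ones(10), [RegionSpec("a", 5, 11)])

    def test_posterior_matrix_adds_hpd_columns(self):
        rates = np.random.default_rng(0).gamma(2.0, size=(50, 40))
        out = region_rate_summary(scale_rates(rates), [RegionSpec("a", 1, 20)])
        assert {"median", "hpd95_lower", "hpd95_upper"} <= set(out.columns)
        assert out.loc["a", "hpd95_lower"] <= out.loc["a", "median"]


class TestMovingAverage:
    def test_matches_mean_filter_oracle(self):
        rng = np.random.default_rng(8)
        rates = rng.gamma(1.0, size=200)
        got = moving_average(rates, window=10)
        expected = [rates[i : i + 10].mean() for i in range(191)]
        assert got == pytest.approx(expected)


class TestRateRatio:
    def test_identical_regions_give_unit_ratio(self):
        rates = np.tile(np.array([1.0, 1.0, 1.0, 1.0]), (10, 1))
        res = rate_ratio(rates, RegionSpec("f", 1, 2))
        assert res.mean == pytest.approx(1.0)
        assert res.hpd_linear == (1.0, 1.0)
        assert res.hpd_log == (0.0, 0.0)

    def test_hand_computed_two_sample_ratios(self):
        # sample 1: focal 2, complement 1 -> 2; sample 2: focal 1, complement 2 -> 0.5
        rates = np.array([[2.0, 2.0, 1.0, 1.0], [1.0, 1.0, 2.0, 2.0]])
        res = rate_ratio(rates, RegionSpec("f", 1, 2))
        assert sorted(res.ratios) == [0.5, 2.0]
        assert res.mean == pytest.approx(1.25)
        assert res.hpd_log[0] == pytest.approx(-res.hpd_log[1])

    def test_lognormal_ratios_linear_asymmetric_log_symmetric(self):
        rng = np.random.default_rng(12)
        n = 10_000
        # one focal and one complement column, lognormal rates: ratio lognormal
        rates = np.exp(rng.normal(0.0, 1.0, size=(n, 2)))
        res = rate_ratio(rates, RegionSpec("f", 1, 1))
        lin_lo, lin_hi = res.hpd_linear
        log_lo, log_hi = res.hpd_log
        # linear interval is strongly right-skewed around 1
        assert (lin_hi - 1.0) > 3.0 * (1.0 - lin_lo)
        # log interval is symmetric about 0 within sampling noise
        assert abs(log_hi + log_lo) < 0.15 * (log_hi - log_lo)

    def test_zero_complement_samples_dropped(self):
        rates = np.array([[1.0, 0.0], [1.0, 2.0], [3.0, 1.0]])
        res = rate_ratio(rates, RegionSpec("f", 1, 1))
        assert res.n_dropped == 1
        assert len(res.ratios) == 2

    def test_overlapping_focal_complement_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            rate_ratio(
                np.ones((3, 10)),
                RegionSpec("f", 1, 5),
                complement=[RegionSpec("c", 5, 10)],
            )
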