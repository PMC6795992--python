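"""Power-law clock fitting, prediction, HPD intervals, and pooled dating."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from tdrpclock.calibration import CalibrationPoint, Clade, HostDate
from tdrpclock.dating import (
    SingularFitError,
    TdrpDatingModel,
    fit_power_law,
    hpd_interval,
    predict_time,
    run_dating,
)
from tdrpclock.simulate import (
    demo_calibrations,
    demo_sim_spec,
    demo_targets,
    simulate_posterior_trees,
)


class TestFitPowerLaw:
    def test_exact_log_line_recovered(self):
        # t = e^2 * s^1.5 in natural-log space
        s = np.array([1.0, math.e, math.e**2])
        t = math.e**2 * s**1.5
        alpha, beta = fit_power_law(s, t)
        assert alpha == pytest.approx(2.0, abs=1e-10)
        assert beta == pytest.approx(1.5, abs=1e-10)

    def test_flat_line(self):
        alpha, beta = fit_power_law([1.0, 10.0], [10.0, 10.0])
        assert beta == pytest.approx(0.0, abs=1e-12)
        assert alpha == pytest.approx(math.log(10.0), abs=1e-12)

    def test_two_points_interpolate_exactly(self):
        alpha, beta = fit_power_law([0.1, 1.0], [2.0, 50.0])
        for s, t in [(0.1, 2.0), (1.0, 50.0)]:
            assert predict_time(alpha, beta, s) == pytest.approx(t, rel=1e-12)

    def test_identical_heights_singular(self):
        with pytest.raises(SingularFitError):
            fit_power_law([1.0, 1.0], [2.0, 3.0])

    @pytest.mark.parametrize("s, t", [([0.0, 1.0], [1.0, 2.0]), ([1.0, 2.0], [-1.0, 2.0])])
    def test_nonpositive_inputs_rejected(self, s, t):
        with pytest.raises(ValueError, match="positive"):
            fit_power_law(s, t)

    def test_log_base_invariance_of_predictions(self):
        rng = np.random.default_rng(5)
        s = rng.uniform(0.05, 2.0, 6)
        t = rng.uniform(0.5, 120.0, 6)
        a_n, b_n = fit_power_law(s, t, "natural")
        a_10, b_10 = fit_power_law(s, t, "base10")
        assert b_10 == pytest.approx(b_n, abs=1e-9)
        assert a_10 == pytest.approx(a_n / math.log(10), abs=1e-9)
        for q in (0.01, 0.3, 1.7):
            assert predict_time(a_10, b_10, q, "base10") == pytest.approx(
                predict_time(a_n, b_n, q, "natural"), rel=1e-9
            )

    def test_time_unit_covariance(self):
        """Rescaling t by c shifts alpha by log c; beta and relative fits stay."""
        rng = np.random.default_rng(6)
        s = rng.uniform(0.05, 2.0, 5)
        t = rng.uniform(0.5, 120.0, 5)
        c = 1000.0  # e.g. Myr -> kyr
        a1, b1 = fit_power_law(s, t)
        a2, b2 = fit_power_law(s, c * t)
        assert b2 == pytest.approx(b1, abs=1e-9)
        assert a2 == pytest.approx(a1 + math.log(c), abs=1e-9)
        assert predict_time(a2, b2, 0.4) == pytest.approx(
            c * predict_time(a1, b1, 0.4), rel=1e-9
        )


class TestPredictTime:
    def test_identity_map(self):
        assert predict_time(0.0, 1.0, 0.5) == pytest.approx(0.5)

    def test_scale_by_two(self):
        assert predict_time(math.log(2.0), 1.0, 3.0) == pytest.approx(6.0)

    def test_published_point_estimates_give_100myr(self):
        # exp(4.114 + 1.762 ln 1.321) evaluated independently = 99.935...
        t = predict_time(4.114, 1.762, 1.321)
        assert t == pytest.approx(99.9351487, abs=1e-4)
        assert t == pytest.approx(100.0, abs=0.1)

    def test_monotone_in_height_for_positive_beta(self):
        s = np.linspace(0.01, 2.0, 50)
        t = predict_time(1.3, 0.8, s)
        assert np.all(np.diff(t) > 0)

    def test_nonpositive_height_rejected(self):
        with pytest.raises(ValueError):
            predict_time(1.0, 1.0, 0.0)


def brute_force_hpd(samples, mass):
    """Oracle: exhaustive enumeration of all contiguous sorted windows."""
    x = sorted(samples)
    n = len(x)
    m = math.ceil(mass * n)
    best = None
    for i in range(n - m + 1):
        width = x[i + m - 1] - x[i]
        if best is None or width < best[0]:
            best = (width, x[i], x[i + m - 1])
    return best[1], best[2]


class TestHpdInterval:
    def test_constant_samples(self):
        assert hpd_interval([3.0] * 10) == (3.0, 3.0)

    def test_uniform_grid_leftmost_tie(self):
        lo, hi = hpd_interval(np.arange(1, 101, dtype=float), 0.95)
        assert (lo, hi) == (1.0, 95.0)

    def test_standard_normal_endpoints(self):
        x = np.random.default_rng(0).standard_normal(100_000)
        lo, hi = hpd_interval(x, 0.95)
        assert lo == pytest.approx(-1.96, abs=0.05)
        assert hi == pytest.approx(1.96, abs=0.05)

    def test_contains_at_least_mass(self):
        x = np.random.default_rng(3).exponential(size=999)
        lo, hi = hpd_interval(x, 0.95)
        assert ((x >= lo) & (x <= hi)).mean() >= 0.95

    @given(
        st.lists(
            st.floats(-1e6, 1e6, allow_nan=False), min_size=2, max_size=200
        ),
        st.sampled_from([0.5, 0.8, 0.95]),
    )
    def test_matches_brute_force_enumeration(self, xs, mass):
        assert hpd_interval(xs, mass) == brute_force_hpd(xs, mass)


class TestRunDating:
    def test_noiseless_recovery_is_exact(self, demo_tree_set_noiseless):
        ts, truth = demo_tree_set_noiseless
        res = run_dating(ts, demo_calibrations(sd_zero=True), demo_targets(), seed=0)
        assert res.alpha == pytest.approx(truth.alpha, abs=1e-9)
        assert res.beta == pytest.approx(truth.beta, abs=1e-9)
        for est in res.time_estimates:
            clade = next(t for t in demo_targets() if t.name == est.name)
            assert est.median == pytest.approx(truth.true_time(clade.taxa), rel=1e-9)

    def test_noisy_medians_near_truth(self, demo_tree_set_noisy):
        ts, truth = demo_tree_set_noisy
        res = run_dating(ts, demo_calibrations(), demo_targets(), seed=0)
        assert res.alpha == pytest.approx(truth.alpha, rel=0.05)
        assert res.beta == pytest.approx(truth.beta, rel=0.05)

    def test_pooled_summary_invariant_to_draw_order(self, demo_tree_set_noisy):
        """Medians/HPDs pool a multiset of per-tree draws; order is irrelevant."""
        ts, _ = demo_tree_set_noisy
        res = run_dating(ts, demo_calibrations(), demo_targets(), seed=0)
        col = res.draws["t_env variant origin"].to_numpy()
        shuffled = np.random.default_rng(1).permutation(col)
        from tdrpclock.dating import hpd_interval as hpd

        assert np.median(shuffled) == res.time_estimates[2].median
        assert hpd(shuffled) == (
            res.time_estimates[2].hpd_lower,
            res.time_estimates[2].hpd_upper,
        )

    def test_zero_height_calibration_clade_skips_tree(self):
        from tdrpclock.trees import PhyloTree, PosteriorTreeSet

        good = PhyloTree.from_newick("((A:0.1,B:0.1):0.2,(C:0.2,D:0.2):0.1);")
        bad = PhyloTree.from_newick("((A:0.0,B:0.0):0.3,(C:0.2,D:0.2):0.1);")
        cal = [
            CalibrationPoint("ab", {"A", "B"}, HostDate(1.0, 1.0, 1.0)),
            CalibrationPoint("cd", {"C", "D"}, HostDate(2.0, 2.0, 2.0)),
        ]
        tgt = [Clade("root", {"A", "B", "C", "D"})]
        ts = PosteriorTreeSet([good] * 9 + [bad])
        res = TdrpDatingModel(ts, cal, tgt).fit(0)
        assert res.skipped_trees == [9]
        assert res.n_trees_used == 9
        # too many skipped trees aborts
        ts_bad = PosteriorTreeSet([good, bad, bad])
        with pytest.raises(RuntimeError, match="skipped"):
            TdrpDatingModel(ts_bad, cal, tgt).fit(0)

    def test_unresolvable_taxa_fail_fast(self, demo_tree_set_noiseless):
        ts, _ = demo_tree_set_noiseless
        bad_target = [Clade("ghost", {"FFV", "NOSUCHTIP"})]
        with pytest.raises(KeyError, match="NOSUCHTIP"):
            TdrpDatingModel(ts, demo_calibrations(), bad_target)

    def test_empty_targets_rejected(self, demo_tree_set_noiseless):
        ts, _ = demo_tree_set_noiseless
        with pytest.raises(ValueError, match="target"):
            TdrpDatingModel(ts, demo_calibrations(), [])


class TestReportTable:
    def test_constant_draws_collapse_to_point(self, demo_tree_set_noiseless):
        ts, truth = demo_tree_set_noiseless
        res = run_dating(ts, demo_calibrations(sd_zero=True), demo_targets(), seed=0)
        tab = res.report_table()
        row = tab.loc["mandrill N-S split (variant II)"]
        assert row["median_Myr"] == pytest.approx(0.415, rel=1e-9)
        assert row["hpd95_lower_Myr"] == pytest.approx(row["hpd95_upper_Myr"])

    def test_summary_mentions_parameters_and_targets(self, demo_tree_set_noiseless):
        ts, _ = demo_tree_set_noiseless
        res = run_dating(ts, demo_calibrations(sd_zero=True), demo_targets(), seed=0)
        text = res.summary()
        assert "alpha" in text and "beta" in text
        assert "env variant origin" in text
        assert isinstance(res.report_table(), pd.DataFrame)
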