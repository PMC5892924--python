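"""ΔΔCt quantification, Grubbs screening and Mann-Whitney comparison."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from exonshift import (
    delta_delta_ct,
    grubbs_test,
    group_comparison,
    mann_whitney,
    mann_whitney_exact_p,
    simulate_qpcr,
)
from exonshift.errors import InsufficientDataError, ValidationError


def _ct_table(rows):
    return pd.DataFrame(rows, columns=["sample_id", "group", "target", "ct",
                                       "replicate"])


class TestDeltaDeltaCt:
    def test_calibrator_identity(self):
        t = _ct_table(
            [
                ("s1", "fetal", "GAPDH", 20.0, 1),
                ("s1", "fetal", "total_tau", 26.0, 1),
                ("s1", "fetal", "4R", 26.0, 1),
            ]
        )
        rel = delta_delta_ct(t).set_index("target")
        assert rel.at["total_tau", "rel_to_calibrator"] == 1.0
        assert rel.at["4R", "rel_to_calibrator"] == 1.0  # same ΔCt as calibrator

    def test_one_cycle_difference_halves(self):
        t = _ct_table(
            [
                ("s1", "fetal", "GAPDH", 20.0, 1),
                ("s1", "fetal", "total_tau", 26.0, 1),  # ΔCt 6
                ("s1", "fetal", "4R", 27.0, 1),  # ΔCt 7
            ]
        )
        rel = delta_delta_ct(t).set_index("target")
        assert rel.at["4R", "rel_to_calibrator"] == pytest.approx(0.5)

    def test_hand_computed_instance(self):
        # ΔCt target 3.68, calibrator 5.94 -> 2^2.26 ≈ 4.79
        t = _ct_table(
            [
                ("s1", "adult", "GAPDH", 20.0, 1),
                ("s1", "adult", "total_tau", 25.94, 1),
                ("s1", "adult", "4R", 23.68, 1),
            ]
        )
        rel = delta_delta_ct(t).set_index("target")
        assert rel.at["4R", "rel_to_calibrator"] == pytest.approx(2**2.26, rel=1e-9)

    def test_replicates_averaged_before_delta(self):
        t = _ct_table(
            [
                ("s1", "fetal", "GAPDH", 19.0, 1),
                ("s1", "fetal", "GAPDH", 21.0, 2),
                ("s1", "fetal", "total_tau", 26.0, 1),
                ("s1", "fetal", "4R", 27.0, 1),
            ]
        )
        rel = delta_delta_ct(t).set_index("target")
        assert rel.at["4R", "delta_ct"] == pytest.approx(7.0)

    def test_missing_reference_sample_excluded(self):
        t = _ct_table(
            [
                ("s1", "fetal", "GAPDH", 20.0, 1),
                ("s1", "fetal", "total_tau", 26.0, 1),
                ("s2", "fetal", "total_tau", 25.0, 1),
            ]
        )
        rel = delta_delta_ct(t)
        assert set(rel["sample_id"]) == {"s1"}

    def test_non_detect_censors_result(self):
        t = _ct_table(
            [
                ("s1", "fetal", "GAPDH", 20.0, 1),
                ("s1", "fetal", "total_tau", 26.0, 1),
                ("s1", "fetal", "2N", 40.0, 1),  # at the 40-cycle ceiling
            ]
        )
        rel = delta_delta_ct(t).set_index("target")
        assert bool(rel.at["2N", "censored"])
        assert not bool(rel.at["total_tau", "censored"])

    def test_ct_outside_range_rejected(self):
        t = _ct_table([("s1", "fetal", "GAPDH", 41.0, 1)])
        with pytest.raises(ValidationError):
            delta_delta_ct(t)

    @pytest.mark.parametrize("shift", [-3.0, 2.5])
    def test_constant_ct_shift_cancels(self, shift):
        rows = [
            ("s1", "fetal", "GAPDH", 20.0, 1),
            ("s1", "fetal", "total_tau", 26.0, 1),
            ("s1", "fetal", "4R", 28.5, 1),
            ("s1", "fetal", "0N", 23.0, 1),
        ]
        base = delta_delta_ct(_ct_table(rows)).set_index("target")
        shifted_rows = [(s, g, t, ct + shift, r) for s, g, t, ct, r in rows]
        shifted = delta_delta_ct(_ct_table(shifted_rows)).set_index("target")
        np.testing.assert_allclose(
            base["rel_to_calibrator"], shifted["rel_to_calibrator"], atol=1e-12
        )


class TestGrubbs:
    def test_flags_gross_outlier(self):
        values = [1, 1.1, 0.9, 1.05, 0.95, 5]
        idx, g, g_crit = grubbs_test(values, alpha=0.05)
        assert idx == 5
        assert g == pytest.approx(2.039, abs=2e-3)
        assert g_crit == pytest.approx(1.887, abs=2e-3)

    def test_critical_value_formula(self):
        # G_crit = ((n-1)/sqrt(n)) * sqrt(t^2 / (n-2+t^2)), t upper alpha/(2n) on n-2 df
        n, alpha = 6, 0.05
        t = stats.t.ppf(1 - alpha / (2 * n), n - 2)
        expected = (n - 1) / np.sqrt(n) * np.sqrt(t**2 / (n - 2 + t**2))
        _, _, g_crit = grubbs_test([1, 2, 3, 4, 5, 6], alpha=alpha)
        assert g_crit == pytest.approx(expected, abs=1e-12)

    def test_constant_values_no_outlier(self):
        idx, g, _ = grubbs_test([1, 1, 1, 1])
        assert idx is None and g == 0.0

    def test_symmetric_extremes_tie_break_and_ns(self):
        idx, g, _ = grubbs_test([-2, 0, 2])
        assert idx is None  # G = 1.0 is never significant at n = 3
        assert g == pytest.approx(1.0)

    def test_never_flags_within_one_sd(self):
        # |x_i - mean| <= sd for all i forces G <= 1 < G_crit, so no flag
        rng = np.random.default_rng(0)
        checked = 0
        for _ in range(50):
            x = np.tile([-1.0, 1.0], 4) + rng.normal(0, 0.05, size=8)
            if np.abs(x - x.mean()).max() > x.std(ddof=1):
                continue
            checked += 1
            idx, g, g_crit = grubbs_test(x)
            assert g <= 1.0 + 1e-9 and idx is None
        assert checked >= 10

    def test_needs_three_values(self):
        with pytest.raises(InsufficientDataError):
            grubbs_test([1, 2])


class TestMannWhitney:
    def test_separated_seven_vs_seven(self):
        u, p = mann_whitney(np.arange(7), np.arange(10, 17))
        assert u == 49
        assert p == pytest.approx(2 / 3432, rel=1e-9)

    def test_identical_groups(self):
        _, p = mann_whitney([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    def test_two_vs_two(self):
        u, p = mann_whitney([1, 2], [3, 4])
        assert u == 4
        assert p == pytest.approx(2 / 6, rel=1e-9)

    def test_all_tied_convention(self):
        u, p = mann_whitney([5, 5], [5, 5, 5])
        assert p == 1.0

    @pytest.mark.parametrize("na,nb", [(2, 3), (3, 3), (4, 5), (5, 2), (6, 6), (7, 7)])
    def test_exact_p_matches_enumeration(self, na, nb):
        rng = np.random.default_rng(na * 10 + nb)
        a = rng.permutation(np.arange(na + nb))[:na].astype(float)
        b = np.setdiff1d(np.arange(na + nb), a).astype(float)
        _, p = mann_whitney(a, b)
        assert p == pytest.approx(mann_whitney_exact_p(a, b), rel=1e-12)


class TestGroupComparison:
    def test_simulated_panel_recovers_direction(self):
        table = simulate_qpcr(seed=7)
        rel = delta_delta_ct(table)
        comp = group_comparison(rel, "fetal", "adult").set_index("target")
        assert comp.at["4R", "p"] < 0.01
        assert comp.at["4R", "mean_adult"] > comp.at["4R", "mean_fetal"]
        assert comp.at["0N", "mean_fetal"] > comp.at["0N", "mean_adult"]

    def test_grubbs_screen_drops_injected_outlier(self):
        table = simulate_qpcr(ct_noise_sd=0.05, seed=1)
        rel = delta_delta_ct(table)
        # corrupt one fetal 4R measurement by a huge factor
        mask = (rel["group"] == "fetal") & (rel["target"] == "4R")
        first = rel.index[mask][0]
        rel.loc[first, "rel_to_calibrator"] *= 500
        screened = group_comparison(rel, "fetal", "adult", grubbs_alpha=0.05)
        unscreened = group_comparison(rel, "fetal", "adult", grubbs_alpha=None)
        s = screened.set_index("target")
        u = unscreened.set_index("target")
        assert s.at["4R", "n_fetal"] == u.at["4R", "n_fetal"] - 1
        assert s.at["4R", "mean_fetal"] < u.at["4R", "mean_fetal"]
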