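"""Unit tests for the sum-of-squares decomposition and the four estimators."""

import math

import numpy as np
import pytest

from iccbias import (
    AnovaSummary,
    MeasurementTable,
    anova_icc,
    bias_corrected_icc,
    decompose,
    estimate_F,
    estimate_all,
    log_bias_approx,
    rho_tilde,
    var_F,
)
from iccbias.exceptions import (
    DegenerateDesignError,
    IccError,
    InfiniteFError,
    InsufficientDfError,
    NoVariationError,
    UnbalancedDesignError,
    VarianceUndefinedError,
)


class TestDecompose:
    def test_toy_dataset(self, toy_table):
        s = decompose(toy_table)
        assert s.n == 3 and s.k == 2
        assert s.SSE == pytest.approx(4.5, abs=1e-12)
        assert s.SSB == pytest.approx(43.0, abs=1e-12)
        assert s.BMS == pytest.approx(21.5)
        assert s.EMS == pytest.approx(1.5)
        assert s.df_between == 2 and s.df_within == 3

    def test_no_variation_gives_zero_ss(self):
        t = MeasurementTable.from_records(
            [(c, 7.0) for c in "AABBCC"]
        )
        s = decompose(t)
        assert s.SSB == 0.0 and s.SSE == 0.0

    def test_location_invariance(self, random_table):
        s0 = decompose(random_table)
        shifted = MeasurementTable(random_table.cluster_ids, random_table.values + 123.4)
        s1 = decompose(shifted)
        assert s1.SSB == pytest.approx(s0.SSB, rel=1e-9)
        assert s1.SSE == pytest.approx(s0.SSE, rel=1e-9)

    def test_conserves_total_ss(self, random_table):
        s = decompose(random_table)
        total = np.sum((random_table.values - random_table.values.mean()) ** 2)
        assert s.SSB + s.SSE == pytest.approx(total, rel=1e-10)

    def test_mean_square_identities(self, random_table):
        s = decompose(random_table)
        assert s.BMS * s.df_between == pytest.approx(s.SSB, rel=1e-12)
        assert s.EMS * s.df_within == pytest.approx(s.SSE, rel=1e-12)

    def test_unbalanced_names_offenders(self):
        t = MeasurementTable.from_records(
            [("A", 1.0), ("A", 2.0), ("B", 3.0), ("B", 5.0), ("B", 6.0)]
        )
        with pytest.raises(UnbalancedDesignError, match="unbalanced design.*A"):
            decompose(t)

    @pytest.mark.parametrize(
        "records",
        [
            [("A", 1.0), ("A", 2.0)],  # single cluster
            [("A", 1.0), ("B", 2.0)],  # k = 1
        ],
    )
    def test_degenerate_designs(self, records):
        with pytest.raises(DegenerateDesignError, match="degenerate design"):
            decompose(MeasurementTable.from_records(records))

    def test_nonfinite_values_rejected(self):
        with pytest.raises(IccError, match="finite"):
            MeasurementTable.from_records([("A", 1.0), ("A", np.nan)])


class TestAnovaIcc:
    def test_toy_value(self, toy_table):
        assert anova_icc(decompose(toy_table)) == pytest.approx(20 / 23, abs=1e-12)

    def test_equal_mean_squares_gives_zero(self):
        s = AnovaSummary(n=10, k=5, SSB=9 * 2.0, SSE=40 * 2.0, grand_mean=3.0)
        assert anova_icc(s) == pytest.approx(0.0, abs=1e-15)

    def test_zero_within_variance_gives_one(self):
        s = AnovaSummary(n=10, k=5, SSB=18.0, SSE=0.0, grand_mean=3.0)
        assert anova_icc(s) == pytest.approx(1.0)

    def test_all_identical_raises(self):
        t = MeasurementTable.from_records([(c, 7.0) for c in "AABBCC"])
        with pytest.raises(NoVariationError, match="no variation"):
            anova_icc(decompose(t))

    def test_matches_pingouin_icc1(self):
        """Independent cross-check against pingouin's one-way random ICC."""
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(99)
        n, k = 8, 4
        y = rng.normal(10, 3, size=n)[:, None] + rng.normal(0, 2, size=(n, k))
        df = pd.DataFrame(
            {
                "targets": np.repeat(np.arange(n), k),
                "raters": np.tile(np.arange(k), n),
                "ratings": y.ravel(),
            }
        )
        tab = pingouin.intraclass_corr(
            data=df, targets="targets", raters="raters", ratings="ratings"
        )
        # the one-way single-rater ICC is labelled ICC1 or ICC(1,1) depending
        # on the pingouin version
        icc1 = tab.loc[tab["Type"].isin(["ICC1", "ICC(1,1)"]), "ICC"].iloc[0]
        ours = anova_icc(
            decompose(MeasurementTable(np.repeat(np.arange(n), k), y.ravel()))
        )
        assert ours == pytest.approx(icc1, rel=1e-9)


class TestEstimateF:
    def test_numerator_root_is_zero(self):
        s = AnovaSummary(n=10, k=10, SSB=9.0, SSE=88.0, grand_mean=0.0)
        assert estimate_F(s) == pytest.approx(0.0, abs=1e-15)

    def test_toy_value(self, toy_table):
        f = estimate_F(decompose(toy_table))
        assert f == pytest.approx((1 * 43 / 4.5 - 2) / 4, abs=1e-12)
        assert f == pytest.approx(1.88889, abs=5e-6)

    def test_zero_sse_raises(self):
        s = AnovaSummary(n=10, k=10, SSB=18.0, SSE=0.0)
        with pytest.raises(InfiniteFError, match="infinite F"):
            estimate_F(s)

    def test_insufficient_df_raises(self):
        s = AnovaSummary(n=2, k=2, SSB=1.0, SSE=1.0)
        with pytest.raises(InsufficientDfError, match="insufficient within-cluster df"):
            estimate_F(s)

    def test_can_be_negative(self):
        s = AnovaSummary(n=10, k=10, SSB=1.0, SSE=100.0)
        assert estimate_F(s) < 0


class TestVarF:
    def test_known_values(self):
        # reference values printed to 5 significant figures
        assert var_F(10, 10, 0.0) == pytest.approx(0.0025064, abs=1e-7)
        assert var_F(10, 10, 1.0) == pytest.approx(0.30327, abs=2e-5)

    def test_scaling_in_kF_plus_1_squared(self):
        for n, k, F in [(10, 10, 2.3), (30, 5, 0.7), (7, 4, 9.0)]:
            assert var_F(n, k, F) / var_F(n, k, 0.0) == pytest.approx(
                (k * F + 1) ** 2, rel=1e-12
            )

    def test_design_without_fourth_moment_raises(self):
        with pytest.raises(VarianceUndefinedError, match="variance undefined"):
            var_F(3, 2, 1.0)  # n(k-1) = 3 <= 4

    def test_negative_F_rejected(self):
        with pytest.raises(IccError):
            var_F(10, 10, -0.5)


class TestRhoTilde:
    @pytest.mark.parametrize("f, expected", [(0.0, 0.0), (1.0, 0.5)])
    def test_fixed_points(self, f, expected):
        assert rho_tilde(f) == expected

    def test_toy_value(self, toy_table):
        assert rho_tilde(estimate_F(decompose(toy_table))) == pytest.approx(
            0.653846, abs=5e-7
        )

    def test_pole_guarded(self):
        with pytest.raises(IccError):
            rho_tilde(-1.0)

    def test_monotone_and_below_one(self):
        fs = np.linspace(-0.9, 50, 200)
        vals = [rho_tilde(f) for f in fs]
        assert np.all(np.diff(vals) > 0)
        assert max(vals) < 1.0


class TestLogBiasApprox:
    def test_zero_variance_gives_zero(self):
        assert log_bias_approx(2.0, 0.0) == 0.0

    def test_worked_value(self):
        assert log_bias_approx(1.0, 0.30327) == pytest.approx(-0.11373, abs=5e-6)

    def test_always_negative(self):
        for f in (0.1, 0.5, 1.0, 4.0, 25.0):
            assert log_bias_approx(f, 0.3) < 0

    def test_vanishes_for_large_F(self):
        assert abs(log_bias_approx(1e6, 0.3)) < 1e-11

    def test_nonpositive_F_directed_to_small_F_branch(self):
        with pytest.raises(IccError, match="small-F"):
            log_bias_approx(0.0, 0.3)


class TestBiasCorrectedIcc:
    def test_no_variance_no_correction_both_branches(self):
        for f in (0.1, 4.0):  # one per branch at the default threshold
            bc = bias_corrected_icc(f, 0.0)
            assert bc.value == pytest.approx(rho_tilde(f), abs=1e-15)

    def test_primary_branch_worked_example(self):
        v = var_F(10, 10, 4.0)
        assert v == pytest.approx(4.213, abs=5e-4)
        bc = bias_corrected_icc(4.0, v)
        assert bc.branch == "primary"
        assert bc.value == pytest.approx(0.83884, abs=5e-5)

    def test_small_F_branch_worked_example(self):
        v = var_F(10, 10, 0.25)
        assert v == pytest.approx(0.030703, abs=2e-6)
        bc = bias_corrected_icc(0.25, v)
        assert bc.branch == "small_F"
        assert bc.value == pytest.approx(0.20782, abs=5e-6)

    def test_branch_selection_around_threshold(self):
        assert bias_corrected_icc(0.39, 0.1, threshold=0.4).branch == "small_F"
        assert bias_corrected_icc(0.41, 0.1, threshold=0.4).branch == "primary"
        assert bias_corrected_icc(-0.2, 0.1).branch == "small_F"

    def test_correction_inflates_rho_tilde(self):
        for f in (-0.3, 0.1, 0.4, 1.0, 8.0):
            bc = bias_corrected_icc(f, 0.05)
            assert bc.raw > rho_tilde(f)

    def test_emitted_value_capped_at_one(self):
        bc = bias_corrected_icc(1.01, 50.0)
        assert bc.raw > 1.0
        assert bc.value == 1.0

    def test_negative_variance_rejected(self):
        with pytest.raises(IccError):
            bias_corrected_icc(2.0, -0.1)


class TestEstimateAll:
    def test_toy_composition(self, toy_table):
        with pytest.warns(UserWarning, match="undefined for design"):
            est = estimate_all(toy_table)
        assert est.rho_hat == pytest.approx(0.869565, abs=5e-7)
        assert est.F_hat == pytest.approx(1.88889, abs=5e-6)
        assert est.rho_tilde == pytest.approx(0.653846, abs=5e-7)
        assert est.var_F_hat is None
        assert est.rho_bc == est.rho_tilde  # no correction possible at n(k-1) <= 4

    def test_perfectly_clustered_raises(self):
        t = MeasurementTable.from_records(
            [("A", 1.0), ("A", 1.0), ("B", 2.0), ("B", 2.0), ("C", 5.0), ("C", 5.0)]
        )
        with pytest.raises(InfiniteFError):
            estimate_all(t)

    def test_negative_F_floored_inside_variance(self):
        # SSB/SSE below the root: F_hat < 0, variance evaluated at F = 0
        rng = np.random.default_rng(7)
        n, k = 10, 10
        y = rng.normal(0, 1, size=(n, k))  # rho = 0: F_hat often negative
        for _ in range(50):
            y = rng.normal(0, 1, size=(n, k))
            t = MeasurementTable(np.repeat(np.arange(n), k), y.ravel())
            est = estimate_all(t)
            if est.F_hat < 0:
                assert est.var_F_hat == pytest.approx(var_F(n, k, 0.0), rel=1e-12)
                assert est.branch_used == "small_F"
                break
        else:
            pytest.fail("no negative F_hat draw found at rho=0")

    def test_truncation_flag(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            y = rng.normal(0, 1, size=(10, 10))
            t = MeasurementTable(np.repeat(np.arange(10), 10), y.ravel())
            est = estimate_all(t)
            if est.rho_hat < 0:
                trunc = estimate_all(t, truncate=True)
                assert trunc.rho_hat == 0.0 and trunc.rho_tilde == 0.0
                break
        else:
            pytest.fail("no negative rho_hat draw found at rho=0")
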